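#!/usr/bin/env python
"""Detect and characterize evoked monophasic IPSCs (emIPSCs).

Brief-pulse trials are classified into failures / monophasic /
multiphasic events; the mean failure trace (isolated photocurrent) is
subtracted; events are measured (peak amplitude, single-exponential
tau_decay), aligned, averaged and fit with the cell-type product forms.
The DSGC average requires a slow second decay term (tau ~ 54 ms) that
the SAC average lacks -- the postsynaptic contribution to cell
type-specific filtering.
"""

import argparse
from pathlib import Path

import pandas as pd

from sacsyn.events import (
    amplitude_decay_association,
    average_and_fit,
    detect_events,
    events_table,
    measure_event,
    subtract_failure_baseline,
)
from sacsyn.exceptions import FitFailureError
from sacsyn.synthetic import reference_models, simulate_emipsc_session


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-trials", type=int, default=60)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    summary = []
    for label, model in zip(("ONOFF_DSGC", "ON_SAC"), reference_models(seed=args.seed)):
        pulses, _ = simulate_emipsc_session(model, n_trials=args.n_trials, seed=args.seed + 400)
        det = detect_events(pulses)
        cleaned, _ = subtract_failure_baseline(det.events, det.failures)
        measured = []
        for ev in cleaned:
            try:
                measured.append(measure_event(ev))
            except FitFailureError:
                continue
        ens = average_and_fit(measured, model.cell_type)
        kendall, p = amplitude_decay_association(measured)
        events_table(measured).to_csv(args.out / f"events_{label}.tsv", sep="\t", index=False)
        summary.append(
            {
                "cell_type": label,
                "n_trials": args.n_trials,
                "n_monophasic": len(det.events),
                "n_multiphasic": len(det.multiphasic),
                "failure_fraction": round(det.failure_fraction, 3),
                "fit_form": ens.fit.form,
                "tau_ms": "/".join(f"{t:.1f}" for t in ens.fit.tau_ms),
                "kendall_tau": round(kendall, 3),
                "kendall_p": round(p, 4),
            }
        )
    df = pd.DataFrame(summary)
    df.to_csv(args.out / "emipsc_summary.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(
        "\ntau_ms lists the fitted decay constants (fast/slow then rise for the DSGC "
        "form; decay then rise for the SAC form).  Near-zero Kendall tau between "
        "amplitude and tau_decay supports linear summation of unitary events."
    )


if __name__ == "__main__":
    main()
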