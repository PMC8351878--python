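#!/usr/bin/env python
"""Isolate presynaptic release dynamics and build hybrid IPSCs.

Each WN-evoked IPSC is Wiener-deconvolved with its cell type's average
emIPSC to estimate instantaneous release rates.  The release trains are
(1) reconvolved with the *other* type's kernel to form hybrid IPSCs,
whose LN filter widths fall between the SAC and DSGC widths -- so the
postsynaptic kernel alone cannot explain the filtering difference --
and (2) analyzed directly with LN and spectral methods, revealing
low-pass (monophasic, wide) SAC->DSGC presynapses vs band-pass
(biphasic, narrow) SAC->SAC presynapses.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from sacsyn.deconvolution import (
    hybrid_ln,
    make_hybrid,
    presynaptic_ln,
    presynaptic_spectrum,
    wiener_deconvolve,
)
from sacsyn.events import average_and_fit, detect_events, measure_event, subtract_failure_baseline
from sacsyn.exceptions import FitFailureError
from sacsyn.ln import fit_ln_model
from sacsyn.synthetic import reference_models, simulate_emipsc_session, simulate_wn_session
from sacsyn.traces import StimulusProtocol

N_SEEDS = 3


def estimated_kernel(model, seed):
    pulses, _ = simulate_emipsc_session(model, n_trials=60, seed=seed)
    det = detect_events(pulses)
    cleaned, _ = subtract_failure_baseline(det.events, det.failures)
    measured = []
    for ev in cleaned:
        try:
            measured.append(measure_event(ev))
        except FitFailureError:
            continue
    return average_and_fit(measured, model.cell_type).kernel()


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    dsgc, sac = reference_models(seed=args.seed)
    kernels = {
        "ONOFF_DSGC": estimated_kernel(dsgc, args.seed + 400),
        "ON_SAC": estimated_kernel(sac, args.seed + 400),
    }
    presyn_rows, hybrid_rows = [], []
    for k in range(N_SEEDS):
        proto = StimulusProtocol(seed=args.seed + 100 + k)
        sessions = {}
        fits = {}
        trains = {}
        for label, ref in (("ONOFF_DSGC", dsgc), ("ON_SAC", sac)):
            session, _ = simulate_wn_session(
                dataclasses.replace(ref, seed=args.seed + 200 + k), proto
            )
            sessions[label] = session
            fits[label] = fit_ln_model(session)
            trains[label] = wiener_deconvolve(
                session.response(), kernels[label], session.baseline, kernel_ref=label
            )
            pm = presynaptic_ln(trains[label], session)
            spec = presynaptic_spectrum(trains[label])
            presyn_rows.append(
                {
                    "cell": f"{label}_{k}",
                    "cell_type": label,
                    "presyn_width_ms": round(pm.metrics.width_ms, 2),
                    "presyn_biphasicity": round(pm.metrics.biphasicity, 3),
                    "presyn_rectification": round(pm.rectification, 3),
                    "band_power_10_35Hz": round(spec.band_mean(10, 35), 3),
                }
            )
        hyb = make_hybrid(trains["ONOFF_DSGC"], kernels["ON_SAC"], label="ON_SAC")
        w_h = hybrid_ln(hyb, sessions["ONOFF_DSGC"]).metrics.width_ms
        hybrid_rows.append(
            {
                "seed": k,
                "width_sac_ms": round(fits["ON_SAC"].metrics.width_ms, 2),
                "width_hybrid_ms": round(w_h, 2),
                "width_dsgc_ms": round(fits["ONOFF_DSGC"].metrics.width_ms, 2),
                "hybrid_intermediate": fits["ON_SAC"].metrics.width_ms
                < w_h
                < fits["ONOFF_DSGC"].metrics.width_ms,
            }
        )
    presyn = pd.DataFrame(presyn_rows)
    hybrid = pd.DataFrame(hybrid_rows)
    presyn.to_csv(args.out / "presynaptic_ln.tsv", sep="\t", index=False)
    hybrid.to_csv(args.out / "hybrid_widths.tsv", sep="\t", index=False)
    print(presyn.to_string(index=False))
    print()
    print(hybrid.to_string(index=False))
    print(
        "\nHybrid widths between SAC and DSGC widths show the postsynaptic kernel "
        "swap narrows but does not fully convert the DSGC filter; band power "
        ">1 at 10-35 Hz marks the band-pass SAC->SAC presynapse."
    )


if __name__ == "__main__":
    main()
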