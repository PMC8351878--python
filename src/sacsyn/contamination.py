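"""Simulation of IPSC contamination by unclamped ChR2 photocurrent.

Voltage-clamping a ChR2-expressing SAC at the cation reversal potential
nulls most of the direct photocurrent, but incompletely clamped distal
neurites can leak a residual inward current into the recorded IPSC.  This
module tests whether such contamination could make a slow (DSGC-like)
IPSC resemble the fast IPSCs actually recorded in SACs.

The contaminant is the mean photocurrent recorded at E_Cl, scaled by a
conservative bound on the unclamped fraction (mean + 3 SEM of the
E_cation/E_Cl amplitude ratio; 0.146 for the published amplitudes), and
optionally convolved with a unit-integral exponential filter (tau = 10,
31.6, 100 or 316 ms) standing in for cable filtering.  For every
(SAC recording, DSGC recording) pair, the DSGC trace is downscaled to the
SAC trace's standard deviation, the contaminant added, and the change in
squared Pearson correlation with the SAC trace measured:

    delta_r2 = r2(SAC, downscaled DSGC + contaminant) - r2(SAC, downscaled DSGC)

A negative delta_r2 means contamination moves the DSGC waveform *away*
from the SAC waveform, ruling out contamination as the source of the fast
SAC kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .exceptions import DegenerateTraceError
from .traces import SampledTrace, pearson_r

__all__ = [
    "ContaminantModel",
    "ContaminationResult",
    "build_contaminant",
    "contaminate_and_compare",
    "amplitude_ratio_bound",
    "DEFAULT_TAU_VARIANTS_MS",
]

#: exponential cable-filter variants; None = unfiltered contaminant
DEFAULT_TAU_VARIANTS_MS: tuple[float | None, ...] = (None, 10.0, 31.6, 100.0, 316.0)


@dataclass
class ContaminantModel:
    """Photocurrent template plus the scaling/filtering family applied to it."""

    ichr2_template: SampledTrace
    scale: float = 0.146
    tau_variants_ms: tuple[float | None, ...] = DEFAULT_TAU_VARIANTS_MS

    def __post_init__(self) -> None:
        if not (self.scale >= 0):
            raise ValueError("scale must be nonnegative")
        if any(t is not None and t <= 0 for t in self.tau_variants_ms):
            raise ValueError("tau variants must be positive")

    def variants(self) -> list[SampledTrace]:
        return [
            build_contaminant(self.ichr2_template, self.scale, tau)
            for tau in self.tau_variants_ms
        ]


def exponential_filter(tau_ms: float, dt: float, n_tau: float = 10.0) -> np.ndarray:
    """Discrete exponential filter with taps summing to exactly 1.

    Truncated at ``n_tau`` time constants, then renormalized so the DC
    gain is exactly 1 regardless of truncation.
    """
    tau = tau_ms / 1e3
    n = max(2, int(round(n_tau * tau / dt)))
    h = np.exp(-np.arange(n) * dt / tau)
    return h / h.sum()


def build_contaminant(
    template: SampledTrace, scale: float, tau_ms: float | None = None
) -> SampledTrace:
    """Scale the photocurrent template and optionally low-pass it.

    The exponential filter has unit DC gain (tap sum exactly 1), so a
    constant template of value c maps to c * scale for any tau.
    """
    vals = template.values * scale
    if tau_ms is not None:
        h = exponential_filter(tau_ms, template.dt)
        vals = sps.lfilter(h, [1.0], vals)
    return SampledTrace(vals, template.dt, template.t0, template.units)


@dataclass
class ContaminationResult:
    """delta_r2 over (SAC, DSGC, tau-variant), plus the SAC-averaged grid."""

    delta_r2: np.ndarray  # (n_sac, n_dsgc, n_variants)
    r2_contaminated: np.ndarray
    r2_baseline: np.ndarray  # (n_sac, n_dsgc)
    tau_variants_ms: tuple[float | None, ...]

    @property
    def reduced(self) -> np.ndarray:
        """Average over SAC cells: the (n_dsgc, n_variants) grid reported."""
        return self.delta_r2.mean(axis=0)

    @property
    def median_delta_r2(self) -> float:
        return float(np.median(self.reduced))


def contaminate_and_compare(
    sac_ipscs: list[SampledTrace],
    dsgc_ipscs: list[SampledTrace],
    contaminant_model: ContaminantModel,
) -> ContaminationResult:
    """Run the full pairwise contamination comparison.

    All traces must be repeat-segment mean responses on a common time
    base.  For each (SAC, DSGC) pair the DSGC trace is downscaled by the
    ratio of standard deviations, each contaminant variant added, and the
    r^2 against the SAC trace compared with the uncontaminated value.
    """
    variants = contaminant_model.variants()
    n_s, n_d, n_v = len(sac_ipscs), len(dsgc_ipscs), len(variants)
    delta = np.zeros((n_s, n_d, n_v))
    r2_c = np.zeros((n_s, n_d, n_v))
    r2_0 = np.zeros((n_s, n_d))
    for i, s in enumerate(sac_ipscs):
        sd_s = float(np.std(s.values))
        if sd_s == 0:
            raise DegenerateTraceError(f"SAC trace {i} has zero standard deviation")
        for j, d in enumerate(dsgc_ipscs):
            sd_d = float(np.std(d.values))
            if sd_d == 0:
                raise DegenerateTraceError(f"DSGC trace {j} has zero standard deviation")
            down = d.values * (sd_s / sd_d)
            base = pearson_r(s.values, down) ** 2
            r2_0[i, j] = base
            for v, cont in enumerate(variants):
                m = min(down.size, cont.n)
                r2 = pearson_r(s.values[:m], down[:m] + cont.values[:m]) ** 2
                r2_c[i, j, v] = r2
                delta[i, j, v] = r2 - base
    return ContaminationResult(
        delta_r2=delta,
        r2_contaminated=r2_c,
        r2_baseline=r2_0,
        tau_variants_ms=contaminant_model.tau_variants_ms,
    )


def amplitude_ratio_bound(
    amp_ecation: float,
    sem_ecation: float,
    amp_ecl: float,
    sem_ecl: float,
    ratio_sem: float | None = None,
) -> tuple[float, float]:
    """Unclamped-photocurrent fraction and its conservative upper bound.

    The ratio |amp_ecation / amp_ecl| estimates the unclamped ChR2
    fraction at the cation reversal; the bound is mean + 3 SEM.  When
    ``ratio_sem`` is not supplied it is propagated from the two amplitude
    SEMs (independent-ratio first-order approximation).
    """
    if amp_ecl == 0:
        raise ZeroDivisionError("E_Cl amplitude must be nonzero")
    ratio = abs(amp_ecation / amp_ecl)
    if ratio_sem is None:
        if amp_ecation == 0:
            raise ZeroDivisionError("cannot propagate SEM for a zero E_cation amplitude")
        ratio_sem = ratio * float(
            np.sqrt((sem_ecation / amp_ecation) ** 2 + (sem_ecl / amp_ecl) ** 2)
        )
    return float(ratio), float(ratio + 3.0 * ratio_sem)
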