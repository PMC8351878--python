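"""Wiener deconvolution of WN-evoked IPSCs into release trains, hybrid
IPSC synthesis, and LN/spectral analysis of presynaptic dynamics.

Deconvolving a recorded IPSC with the cell type's average unitary emIPSC
removes the postsynaptic waveform and leaves a series of delta-like,
amplitude-scaled events interpreted as bursts of vesicle release.  The
frequency-domain Wiener filter is

    H(f) = conj(K) S / (|K|^2 S + N)

with K the kernel transfer function, N the noise power spectrum estimated
from a >= 1-s pre-stimulus baseline, and S the (smoothed, noise-floored)
signal power estimated from the recording itself.  Reconvolving the
release train with the matched kernel reproduces the recording; convolving
it with the *other* cell type's kernel produces a hybrid IPSC that pairs
one synapse's presynaptic dynamics with the other's postsynaptic filter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .exceptions import (
    DegenerateKernelError,
    InsufficientBaselineError,
    ResolutionError,
)
from .ln import LNModel, fit_ln_model
from .traces import (
    PowerSpectrum,
    SampledTrace,
    WNRecordingSession,
    normalized_power_spectrum,
)

__all__ = [
    "ReleaseTrain",
    "HybridIPSC",
    "wiener_deconvolve",
    "make_hybrid",
    "presynaptic_ln",
    "hybrid_ln",
    "presynaptic_spectrum",
]


@dataclass
class ReleaseTrain:
    """Deconvolved instantaneous release-rate series (delta-like events).

    Amplitudes are scaled such that convolution with the unit-peak kernel
    reproduces current in pA; the train is left unrectified.
    """

    rates: SampledTrace
    kernel_ref: str = ""
    noise_psd_ref: str = ""


@dataclass
class HybridIPSC:
    trace: SampledTrace
    source_release: ReleaseTrain
    applied_kernel: str = ""


def _unit_peak(values: np.ndarray) -> np.ndarray:
    peak = float(np.max(np.abs(values)))
    if peak == 0:
        raise DegenerateKernelError("kernel is identically zero")
    return values / peak


def wiener_deconvolve(
    ipsc: SampledTrace,
    kernel: SampledTrace,
    baseline: SampledTrace,
    smooth_hz: float = 2.0,
    kernel_ref: str = "",
    signal_psd: np.ndarray | None = None,
) -> ReleaseTrain:
    """Estimate the instantaneous release train underlying ``ipsc``.

    ``kernel`` is the average emIPSC of the recorded cell type, starting
    at its onset (so release events are placed causally); it is peak-
    normalized internally.  ``baseline`` is a >= 1-s pre-stimulus sample
    whose Welch spectrum (0.5-s segments) provides the noise power N; the
    signal power S is the recording's periodogram smoothed over
    ``smooth_hz`` and floored at a small positive value after noise
    subtraction.  Supplying ``signal_psd`` (on the rfft grid of the
    recording) fixes S instead, making the operator exactly linear in
    the recording.
    """
    if abs(ipsc.dt - kernel.dt) > 1e-12 or abs(ipsc.dt - baseline.dt) > 1e-12:
        raise ResolutionError("ipsc, kernel and baseline must share dt")
    if baseline.duration < 1.0 - 1e-9:
        raise InsufficientBaselineError("baseline must be at least 1 s")
    n = ipsc.n
    k = _unit_peak(np.asarray(kernel.values, float))
    kf = np.fft.rfft(k, n)
    xf = np.fft.rfft(ipsc.values)
    freqs = np.fft.rfftfreq(n, d=ipsc.dt)

    # noise PSD (density units) from the baseline, interpolated to the FFT grid
    nperseg = min(baseline.n, int(round(0.5 / baseline.dt)))
    f_b, n_psd = sps.welch(
        baseline.values, fs=baseline.fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    noise = np.interp(freqs, f_b, n_psd)

    # signal PSD: smoothed recording periodogram minus noise, floored
    if signal_psd is not None:
        s_sig = np.asarray(signal_psd, float)
        floor = 1e-12 * float(np.max(s_sig)) if np.max(s_sig) > 0 else 1e-30
    else:
        pxx = (np.abs(xf) ** 2) * ipsc.dt / n
        df = freqs[1] - freqs[0] if n > 1 else 1.0
        width = max(1, int(round(smooth_hz / df)))
        sxx = uniform_filter1d(pxx, size=width, mode="nearest")
        floor = 1e-12 * float(np.max(sxx)) if np.max(sxx) > 0 else 1e-30
        s_sig = np.maximum(sxx - noise, floor)
    noise = np.maximum(noise, floor * 1e-6)

    h = np.conj(kf) * s_sig / (np.abs(kf) ** 2 * s_sig + noise)
    rates = np.fft.irfft(h * xf, n)
    return ReleaseTrain(
        rates=SampledTrace(rates, ipsc.dt, ipsc.t0, "pA"),
        kernel_ref=kernel_ref,
        noise_psd_ref=f"baseline[{baseline.duration:.3g}s]",
    )


def make_hybrid(release: ReleaseTrain, kernel_other: SampledTrace, label: str = "") -> HybridIPSC:
    """Convolve a release train with the opposing cell type's kernel.

    Discrete causal convolution (kernel peak-normalized, matching the
    deconvolution convention), truncated to the release-train length.
    """
    if abs(release.rates.dt - kernel_other.dt) > 1e-12:
        raise ResolutionError("release train and kernel must share dt")
    k = _unit_peak(np.asarray(kernel_other.values, float))
    vals = sps.fftconvolve(release.rates.values, k)[: release.rates.n]
    return HybridIPSC(
        trace=SampledTrace(vals, release.rates.dt, release.rates.t0, "pA"),
        source_release=release,
        applied_kernel=label,
    )


def _session_like(session: WNRecordingSession, full_series: np.ndarray) -> WNRecordingSession:
    """Rebuild a session whose trial responses are slices of ``full_series``."""
    npt = session.protocol.samples_per_trial
    trials = [
        SampledTrace(full_series[k * npt : (k + 1) * npt], session.stimulus.dt, 0.0, "pA")
        for k in range(session.protocol.n_trials)
    ]
    return WNRecordingSession(
        stimulus=session.stimulus,
        trials=trials,
        protocol=session.protocol,
        metadata=session.metadata,
        baseline=session.baseline,
    )


def presynaptic_ln(
    release: ReleaseTrain, session: WNRecordingSession, max_lag_s: float = 0.2
) -> LNModel:
    """LN analysis applied directly to the deconvolved release train.

    The release series (analyzed raw: neither rectified nor smoothed) is
    substituted for the session's responses and the standard LN estimation
    run against the same stimulus, yielding presynaptic filter width,
    biphasicity and rectification.
    """
    if release.rates.n != session.stimulus.n:
        raise ResolutionError("release train must cover the full session")
    return fit_ln_model(_session_like(session, release.rates.values), max_lag_s)


def hybrid_ln(
    hybrid: HybridIPSC, session: WNRecordingSession, max_lag_s: float = 0.2
) -> LNModel:
    """LN analysis of a hybrid IPSC against the session's stimulus."""
    if hybrid.trace.n != session.stimulus.n:
        raise ResolutionError("hybrid trace must cover the full session")
    return fit_ln_model(_session_like(session, hybrid.trace.values), max_lag_s)


def presynaptic_spectrum(release: ReleaseTrain, norm_freq_hz: float = 2.5) -> PowerSpectrum:
    """2.5-Hz-normalized Welch power spectrum of the release train."""
    return normalized_power_spectrum(release.rates, norm_freq_hz=norm_freq_hz)
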