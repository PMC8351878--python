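"""Core sampled-signal types and white-noise stimulus machinery.

This module provides the containers every later analysis stage consumes:
uniformly sampled traces, the quasi-white-noise (WN) stimulus protocol used
to probe starburst amacrine cell (SAC) synapses, multi-trial recording
sessions with unique/repeat segmentation, trial-to-trial reliability
gating, and 2.5-Hz-normalized power spectra.

The WN stimulus is a sequence of standard-normal draws, ideally low-pass
filtered at 30 Hz (hard zeroing of FFT bins above the cutoff).  Each 10-s
trial consists of 7.5 s of a unique sequence followed by a 2.5-s sequence
repeated in every trial; responses to unique segments build models, repeat
segments assess them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy import stats as spst

from .exceptions import (
    DegenerateInputError,
    InvalidProtocolError,
    NormalizationError,
    UndefinedCorrelationError,
)

__all__ = [
    "SampledTrace",
    "StimulusProtocol",
    "RecordingMetadata",
    "WNRecordingSession",
    "PowerSpectrum",
    "TrialSegments",
    "WNStimulus",
    "CellType",
    "HoldingLabel",
    "generate_wn_stimulus",
    "compute_reliability",
    "passes_reliability_gate",
    "RELIABILITY_GATE",
    "normalized_power_spectrum",
    "canonicalize_polarity",
    "pearson_r",
]


class CellType(str, enum.Enum):
    ON_SAC = "ON_SAC"
    ONOFF_DSGC = "ONOFF_DSGC"
    ON_DSGC = "ON_DSGC"


class HoldingLabel(str, enum.Enum):
    #: reversal potential for cations (~0 mV): isolates IPSCs (outward)
    E_CATION = "E_cation"
    #: chloride reversal (~-67 mV): isolates EPSCs / ChR2 photocurrent (inward)
    E_CL = "E_Cl"


@dataclass
class SampledTrace:
    """A uniformly sampled signal (current in pA, or stimulus in z-units)."""

    values: np.ndarray
    dt: float
    t0: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("SampledTrace requires a non-empty 1-D sample array")
        if not (self.dt > 0):
            raise ValueError("sampling interval dt must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("all samples must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) * self.dt

    def with_values(self, values: np.ndarray) -> "SampledTrace":
        return SampledTrace(np.asarray(values, dtype=float), self.dt, self.t0, self.units)


@dataclass(frozen=True)
class StimulusProtocol:
    """Parameters of the white-noise stimulation protocol."""

    n_trials: int = 10
    trial_duration_s: float = 10.0
    unique_duration_s: float = 7.5
    repeat_duration_s: float = 2.5
    cutoff_hz: float = 30.0
    sample_rate_hz: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise InvalidProtocolError("n_trials must be >= 1")
        if abs(self.unique_duration_s + self.repeat_duration_s - self.trial_duration_s) > 1e-9:
            raise InvalidProtocolError(
                "unique and repeat durations must sum to the trial duration"
            )
        if self.cutoff_hz >= self.sample_rate_hz / 2:
            raise InvalidProtocolError("low-pass cutoff must lie below the Nyquist frequency")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate_hz

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_duration_s * self.sample_rate_hz))

    @property
    def unique_samples(self) -> int:
        return int(round(self.unique_duration_s * self.sample_rate_hz))

    @property
    def repeat_samples(self) -> int:
        return self.samples_per_trial - self.unique_samples

    @property
    def total_samples(self) -> int:
        return self.n_trials * self.samples_per_trial

    #: transition band excluded from reliability/repeat comparisons; a
    #: 30-Hz-limited signal forgets its past on a ~1/cutoff time scale, and
    #: three time constants make residual cross-segment leakage negligible.
    @property
    def edge_band_s(self) -> float:
        return 3.0 / self.cutoff_hz


@dataclass(frozen=True)
class TrialSegments:
    """Index ranges (into the concatenated 100-s series) of one trial."""

    unique: slice
    repeat: slice


@dataclass(frozen=True)
class RecordingMetadata:
    cell_type: CellType = CellType.ONOFF_DSGC
    holding_label: HoldingLabel = HoldingLabel.E_CATION
    #: sign convention of the recorded synaptic deflection; +1 once canonical
    polarity: int = 1
    pre_stimulus_baseline_s: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cell_type", CellType(self.cell_type))
        object.__setattr__(self, "holding_label", HoldingLabel(self.holding_label))
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")


@dataclass
class WNRecordingSession:
    """Stimulus plus per-trial responses from one cell under WN stimulation."""

    stimulus: SampledTrace
    trials: list[SampledTrace]
    protocol: StimulusProtocol
    metadata: RecordingMetadata = field(default_factory=RecordingMetadata)
    #: optional pre-stimulus baseline recording (noise estimate for deconvolution)
    baseline: SampledTrace | None = None

    def __post_init__(self) -> None:
        if len(self.trials) != self.protocol.n_trials:
            raise ValueError("trial count must equal protocol n_trials")
        npt = self.protocol.samples_per_trial
        for k, tr in enumerate(self.trials):
            if tr.n != npt:
                raise ValueError(f"trial {k} has {tr.n} samples, expected {npt}")
            if abs(tr.dt - self.stimulus.dt) > 1e-12:
                raise ValueError(f"trial {k} dt differs from stimulus dt")
        if self.stimulus.n != self.protocol.total_samples:
            raise ValueError("stimulus length must equal protocol total samples")

    @property
    def segments(self) -> list[TrialSegments]:
        return segment_map(self.protocol)

    def response(self) -> SampledTrace:
        """Responses concatenated into one series aligned with the stimulus."""
        return SampledTrace(
            np.concatenate([tr.values for tr in self.trials]),
            self.stimulus.dt,
            self.stimulus.t0,
            self.trials[0].units,
        )

    def repeat_responses(self, trim_edge: bool = True) -> np.ndarray:
        """(n_trials, n_repeat) matrix of repeat-segment responses.

        The leading edge band (3/cutoff s) of each repeat segment is
        dropped when ``trim_edge`` because it carries memory of the
        preceding (trial-specific) unique segment.
        """
        trim = int(round(self.protocol.edge_band_s * self.protocol.sample_rate_hz)) if trim_edge else 0
        reps = []
        npt = self.protocol.samples_per_trial
        u = self.protocol.unique_samples
        for k, tr in enumerate(self.trials):
            reps.append(tr.values[u + trim : npt])
        return np.asarray(reps)

    def repeat_mean(self, trim_edge: bool = True) -> np.ndarray:
        return self.repeat_responses(trim_edge).mean(axis=0)


def segment_map(protocol: StimulusProtocol) -> list[TrialSegments]:
    """Per-trial unique/repeat index ranges into the concatenated series."""
    out = []
    npt = protocol.samples_per_trial
    u = protocol.unique_samples
    for k in range(protocol.n_trials):
        start = k * npt
        out.append(
            TrialSegments(
                unique=slice(start, start + u),
                repeat=slice(start + u, start + npt),
            )
        )
    return out


@dataclass
class WNStimulus:
    """Result of :func:`generate_wn_stimulus`.

    ``trace`` is the ideally low-pass-filtered stimulus; ``prefilter``
    holds the raw standard-normal draws, in which the repeated segment is
    bitwise identical across trials (filtering the concatenated sequence
    introduces negligible edge differences, handled by the edge band).
    """

    trace: SampledTrace
    prefilter: SampledTrace
    segments: list[TrialSegments]
    protocol: StimulusProtocol


def ideal_lowpass(values: np.ndarray, dt: float, cutoff_hz: float) -> np.ndarray:
    """Hard-zero all Fourier components above ``cutoff_hz``."""
    spec = np.fft.rfft(values)
    freqs = np.fft.rfftfreq(values.size, d=dt)
    spec[freqs > cutoff_hz] = 0.0
    return np.fft.irfft(spec, n=values.size)


def generate_wn_stimulus(protocol: StimulusProtocol) -> WNStimulus:
    """Build the quasi-white-noise stimulus for ``protocol``.

    Standard-normal draws fill the unique portion of every trial; a single
    repeat draw is spliced into the tail of each trial; the concatenated
    100-s sequence is then ideally low-pass filtered at the protocol
    cutoff.  Reproducible: equal seeds give bitwise-equal traces.
    """
    rng = np.random.default_rng(protocol.seed)
    repeat = rng.standard_normal(protocol.repeat_samples)
    chunks = []
    for _ in range(protocol.n_trials):
        chunks.append(rng.standard_normal(protocol.unique_samples))
        chunks.append(repeat)
    raw = np.concatenate(chunks)
    filtered = ideal_lowpass(raw, protocol.dt, protocol.cutoff_hz)
    return WNStimulus(
        trace=SampledTrace(filtered, protocol.dt, 0.0, "z"),
        prefilter=SampledTrace(raw, protocol.dt, 0.0, "z"),
        segments=segment_map(protocol),
        protocol=protocol,
    )


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation, raising on constant inputs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant signal")
    return float(spst.pearsonr(x, y)[0])


def compute_reliability(session: WNRecordingSession) -> float:
    """Trial-to-trial response reliability on the repeated segment.

    For each trial, the Pearson correlation between that trial's repeat
    response and the mean of all other trials' repeat responses; the
    returned reliability is the mean of these per-trial correlations.
    Sessions with reliability <= 0.7 are conventionally excluded from LN
    analysis.
    """
    reps = session.repeat_responses(trim_edge=True)
    n = reps.shape[0]
    if n < 2:
        raise ValueError("reliability needs at least two trials")
    rs = []
    for i in range(n):
        others = np.delete(reps, i, axis=0).mean(axis=0)
        if np.ptp(reps[i]) == 0 or np.ptp(others) == 0:
            raise UndefinedCorrelationError(
                f"repeat segment of trial {i} (or its complement mean) is constant"
            )
        rs.append(pearson_r(reps[i], others))
    return float(np.mean(rs))


#: sessions must *exceed* this reliability to enter LN analysis
RELIABILITY_GATE = 0.7


def passes_reliability_gate(reliability: float, gate: float = RELIABILITY_GATE) -> bool:
    """True when a session's reliability exceeds the exclusion threshold."""
    return reliability > gate


def normalized_power_spectrum(
    trace: SampledTrace,
    norm_freq_hz: float = 2.5,
    segment_duration_s: float = 2.0,
) -> "PowerSpectrum":
    """Welch power spectrum normalized to the power at ``norm_freq_hz``.

    Welch averaging uses Hann-windowed segments (default 2 s, 50 %
    overlap) over the full trace, which resolves 2.5 Hz while averaging
    the entire recording.
    """
    if trace.duration < 1.0 / norm_freq_hz:
        raise ValueError("trace shorter than one period of the normalization frequency")
    nperseg = min(trace.n, int(round(segment_duration_s / trace.dt)))
    freqs, power = sps.welch(
        trace.values, fs=trace.fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    idx = int(np.argmin(np.abs(freqs - norm_freq_hz)))
    if power[idx] <= 0:
        raise NormalizationError(
            f"zero power at normalization frequency {norm_freq_hz} Hz"
        )
    return PowerSpectrum(frequencies_hz=freqs, power=power / power[idx], norm_freq_hz=norm_freq_hz)


@dataclass
class PowerSpectrum:
    frequencies_hz: np.ndarray
    power: np.ndarray
    norm_freq_hz: float = 2.5

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, float)
        self.power = np.asarray(self.power, float)
        if self.frequencies_hz.shape != self.power.shape:
            raise ValueError("frequency and power arrays must have equal length")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")

    def band_mean(self, lo_hz: float, hi_hz: float) -> float:
        """Mean normalized power over [lo_hz, hi_hz]."""
        m = (self.frequencies_hz >= lo_hz) & (self.frequencies_hz <= hi_hz)
        if not np.any(m):
            raise ValueError("no spectral bins in requested band")
        return float(self.power[m].mean())


def canonicalize_polarity(
    trace: SampledTrace, metadata: RecordingMetadata
) -> tuple[SampledTrace, bool]:
    """Return the trace with synaptic deflections positive-going.

    IPSCs recorded at E_cation are outward (positive) by convention;
    recordings stored deflection-negative (polarity -1) are inverted.
    Returns the canonical trace and a flag recording whether inversion
    occurred.  Idempotent: a polarity +1 trace is returned unchanged.
    """
    if metadata.polarity == -1:
        return trace.with_values(-trace.values), True
    return trace, False
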