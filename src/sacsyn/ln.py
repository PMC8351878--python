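"""Linear-nonlinear (LN) cascade estimation for white-noise sessions.

The LN model summarizes a synapse probed with quasi-white-noise optogenetic
stimulation as a linear temporal filter followed by a static (memoryless)
nonlinearity:

    r(t) = N( (f * s)(t) ),    N(x) = beta + alpha * Phi((x - mu) / sigma)

with Phi the standard normal CDF.  The filter is the stimulus-response
cross-correlation computed on responses to the unique stimulus segments;
no whitening by the stimulus autocorrelation is applied, so the estimate
equals the true kernel smoothed by the (30-Hz low-pass) stimulus
autocorrelation.  Model accuracy is the squared Pearson correlation
between the model's response to the repeated segment and the mean recorded
repeat response.

Filter shape metrics follow the field's definitions: peak time, full width
at 25 % of the maximum, and the biphasicity index

    b_phi = 2 f_min / (f_max + f_min),

with f_max = max f(t) and f_min = |min{0, min f(t)}| over 0 < t <= 60 ms;
b_phi is 0 for a monophasic (low-pass-like) filter and 1 when the negative
lobe matches the peak (band-pass-like).  The rectification index

    i_rect = |N(max r_L) + N(min r_L) - 2 N(0)| / (N(max r_L) - N(min r_L))

measures the asymmetry of the nonlinearity about zero linear prediction
(0 symmetric, 1 fully rectified), with the extrema taken over the 100
binned linear-prediction values r_L.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import optimize as spo
from scipy import signal as sps
from scipy.special import ndtr

from .exceptions import (
    DegenerateInputError,
    InsufficientDataError,
    NoPeakError,
    ResolutionError,
    UndefinedCorrelationError,
)
from .traces import SampledTrace, WNRecordingSession, pearson_r

__all__ = [
    "LinearFilter",
    "FilterMetrics",
    "StaticNonlinearity",
    "LNModel",
    "estimate_linear_filter",
    "filter_metrics",
    "fit_static_nonlinearity",
    "rectification_index",
    "ln_predict",
    "model_accuracy",
    "fit_ln_model",
    "pairwise_waveform_similarity",
]

#: window over which f_max / f_min (and the reported peak) are measured
METRICS_WINDOW_S = 0.060


@dataclass
class LinearFilter:
    """Causal FIR filter over lags 0..max_lag, unit L2 norm.

    The raw cross-correlation gain is retained in ``raw_gain``; the scale
    degeneracy of the LN cascade is resolved by absorbing it into the
    nonlinearity, so all shape metrics are gain-free.
    """

    taps: np.ndarray
    dt: float
    raw_gain: float = 1.0
    normalization: str = "unit-L2"
    metrics_window_s: float = METRICS_WINDOW_S

    def __post_init__(self) -> None:
        self.taps = np.asarray(self.taps, float)
        if not np.all(np.isfinite(self.taps)):
            raise ValueError("filter taps must be finite")
        if self.taps.size * self.dt < self.metrics_window_s:
            raise ValueError("filter must cover the metrics window")

    @property
    def lags_s(self) -> np.ndarray:
        return np.arange(self.taps.size) * self.dt

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Causal convolution, output aligned with (and truncated to) input."""
        return sps.fftconvolve(values, self.taps)[: values.size]


@dataclass(frozen=True)
class FilterMetrics:
    peak_time_ms: float
    width_ms: float
    biphasicity: float


@dataclass
class StaticNonlinearity:
    """Gaussian-CDF nonlinearity N(x) = beta + alpha * Phi((x - mu)/sigma)."""

    beta: float
    alpha: float
    mu: float
    sigma: float
    #: 100 (linear-prediction, response) bin means, ordered by prediction
    bin_prediction: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bin_response: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError("sigma must be positive")
        if self.alpha == 0:
            raise ValueError("alpha must be nonzero")
        self.bin_prediction = np.asarray(self.bin_prediction, float)
        self.bin_response = np.asarray(self.bin_response, float)

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.beta + self.alpha * ndtr((np.asarray(x, float) - self.mu) / self.sigma)


@dataclass
class LNModel:
    filter: LinearFilter
    nonlinearity: StaticNonlinearity
    metrics: FilterMetrics | None = None
    rectification: float | None = None
    accuracy_r2: float | None = None

    @property
    def burn_in(self) -> int:
        """Leading output samples contaminated by the filter's zero-padding."""
        return self.filter.taps.size

    def to_json(self) -> str:
        payload = {
            "filter": {
                "taps": self.filter.taps.tolist(),
                "dt": self.filter.dt,
                "raw_gain": self.filter.raw_gain,
                "normalization": self.filter.normalization,
                "metrics_window_s": self.filter.metrics_window_s,
            },
            "nonlinearity": {
                "beta": self.nonlinearity.beta,
                "alpha": self.nonlinearity.alpha,
                "mu": self.nonlinearity.mu,
                "sigma": self.nonlinearity.sigma,
                "bin_prediction": self.nonlinearity.bin_prediction.tolist(),
                "bin_response": self.nonlinearity.bin_response.tolist(),
            },
            "metrics": asdict(self.metrics) if self.metrics else None,
            "rectification": self.rectification,
            "accuracy_r2": self.accuracy_r2,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "LNModel":
        d = json.loads(text)
        filt = LinearFilter(
            np.asarray(d["filter"]["taps"]),
            d["filter"]["dt"],
            d["filter"]["raw_gain"],
            d["filter"]["normalization"],
            d["filter"]["metrics_window_s"],
        )
        nl = StaticNonlinearity(
            d["nonlinearity"]["beta"],
            d["nonlinearity"]["alpha"],
            d["nonlinearity"]["mu"],
            d["nonlinearity"]["sigma"],
            np.asarray(d["nonlinearity"]["bin_prediction"]),
            np.asarray(d["nonlinearity"]["bin_response"]),
        )
        metrics = FilterMetrics(**d["metrics"]) if d["metrics"] else None
        return cls(filt, nl, metrics, d["rectification"], d["accuracy_r2"])


def estimate_linear_filter(
    session: WNRecordingSession, max_lag_s: float = 0.2
) -> LinearFilter:
    """Cross-correlate the WN stimulus with the response over unique segments.

    taps[k] is the mean over t of stimulus(t) * response(t + k dt) for
    k >= 0, accumulated across the unique segment of every trial, then
    rescaled to unit L2 norm (the raw gain is kept on the filter).
    """
    stim = session.stimulus.values
    if np.ptp(stim) == 0:
        raise DegenerateInputError("stimulus has zero variance")
    n_lags = int(round(max_lag_s / session.stimulus.dt)) + 1
    num = np.zeros(n_lags)
    cnt = np.zeros(n_lags)
    for seg, trial in zip(session.segments, session.trials):
        x = stim[seg.unique]
        # response trace covers one trial; unique segment leads the trial
        y = trial.values[: x.size]
        # full cross-correlation: c[len(x)-1+k] = sum_t x[t] y[t+k]
        c = sps.fftconvolve(y, x[::-1])
        num += c[x.size - 1 : x.size - 1 + n_lags]
        cnt += x.size - np.arange(n_lags)
    taps = num / cnt
    gain = float(np.linalg.norm(taps))
    if gain == 0:
        raise DegenerateInputError("response carries no stimulus correlation (zero gain)")
    return LinearFilter(taps / gain, session.stimulus.dt, raw_gain=gain)


def _interp_crossing(lags: np.ndarray, taps: np.ndarray, i_lo: int, i_hi: int, level: float) -> float:
    """Sub-sample position where taps crosses ``level`` between two samples."""
    t0, t1 = taps[i_lo], taps[i_hi]
    if t1 == t0:
        return lags[i_lo]
    frac = (level - t0) / (t1 - t0)
    return lags[i_lo] + frac * (lags[i_hi] - lags[i_lo])


def filter_metrics(filt: LinearFilter) -> FilterMetrics:
    """Peak time, full width at 25 % of maximum, and biphasicity b_phi."""
    lags = filt.lags_s
    window = (lags > 0) & (lags <= filt.metrics_window_s)
    in_win = filt.taps[window]
    if in_win.size == 0 or np.max(in_win) <= 0:
        raise NoPeakError("filter has no positive peak within the metrics window")
    f_max = float(np.max(in_win))
    f_min = float(abs(min(0.0, float(np.min(in_win)))))
    # clip: a negative lobe exceeding the peak would push the raw formula past 1
    b_phi = float(np.clip(2.0 * f_min / (f_max + f_min), 0.0, 1.0))

    win_idx = np.flatnonzero(window)
    peak = int(win_idx[int(np.argmax(in_win))])
    peak_time_ms = lags[peak] * 1e3

    # full width at 25% of max: outermost crossings flanking the peak
    level = 0.25 * f_max
    above = filt.taps >= level
    left_idx = int(np.flatnonzero(above)[0])
    right_idx = int(np.flatnonzero(above)[-1])
    if left_idx > 0:
        t_left = _interp_crossing(lags, filt.taps, left_idx - 1, left_idx, level)
    else:
        t_left = lags[0]
    if right_idx < filt.taps.size - 1:
        t_right = _interp_crossing(lags, filt.taps, right_idx + 1, right_idx, level)
    else:
        t_right = lags[-1]
    width_ms = (t_right - t_left) * 1e3
    if width_ms <= 0:
        raise NoPeakError("degenerate width measurement")
    return FilterMetrics(peak_time_ms=float(peak_time_ms), width_ms=float(width_ms), biphasicity=float(b_phi))


def _gauss_cdf(x: np.ndarray, beta: float, alpha: float, mu: float, sigma: float) -> np.ndarray:
    return beta + alpha * ndtr((x - mu) / sigma)


def fit_static_nonlinearity(
    linear_prediction: SampledTrace | np.ndarray,
    response: SampledTrace | np.ndarray,
    n_bins: int = 100,
) -> StaticNonlinearity:
    """Bin the prediction-response scatter and fit a Gaussian CDF.

    Points are sorted by linear prediction (stable sort), divided into
    ``n_bins`` equal-count bins, and averaged along both axes; the bin
    means are fit by bounded least squares with alpha > 0 enforced so the
    fitted nonlinearity is monotone increasing.
    """
    pred = linear_prediction.values if isinstance(linear_prediction, SampledTrace) else np.asarray(linear_prediction, float)
    resp = response.values if isinstance(response, SampledTrace) else np.asarray(response, float)
    if pred.size != resp.size:
        raise ValueError("prediction and response must have equal length")
    if pred.size < n_bins:
        raise InsufficientDataError(f"need at least {n_bins} samples to form {n_bins} bins")
    order = np.argsort(pred, kind="stable")
    bins_p = [b.mean() for b in np.array_split(pred[order], n_bins)]
    bins_r = [b.mean() for b in np.array_split(resp[order], n_bins)]
    xb = np.asarray(bins_p)
    yb = np.asarray(bins_r)

    span = float(xb[-1] - xb[0]) or 1.0
    rng_y = float(yb.max() - yb.min()) or 1.0
    half = yb.min() + 0.5 * rng_y
    mu0 = float(xb[int(np.argmin(np.abs(yb - half)))])
    p0 = [float(yb.min()), rng_y, mu0, span / 4.0]
    lo = [-np.inf, 1e-12 * rng_y, -np.inf, 1e-6 * span]
    hi = [np.inf, np.inf, np.inf, np.inf]
    popt, _ = spo.curve_fit(
        _gauss_cdf, xb, yb, p0=p0, bounds=(lo, hi), maxfev=20_000
    )
    return StaticNonlinearity(
        beta=float(popt[0]), alpha=float(popt[1]), mu=float(popt[2]), sigma=float(popt[3]),
        bin_prediction=xb, bin_response=yb,
    )


def rectification_index(nl: StaticNonlinearity) -> float:
    """Asymmetry of N about zero linear prediction, clipped to [0, 1]."""
    if nl.bin_prediction.size == 0:
        raise ValueError("nonlinearity carries no bin summary")
    x_max = float(nl.bin_prediction.max())
    x_min = float(nl.bin_prediction.min())
    n_hi = float(nl(x_max))
    n_lo = float(nl(x_min))
    n_0 = float(nl(0.0))
    denom = n_hi - n_lo
    if denom <= 0:
        raise DegenerateInputError("nonlinearity is non-increasing over the bin range")
    val = abs(n_hi + n_lo - 2.0 * n_0) / denom
    return float(np.clip(val, 0.0, 1.0))


def ln_predict(model: LNModel, stimulus: SampledTrace) -> SampledTrace:
    """Pass a stimulus through the LN cascade.

    Causal convolution with the (unit-norm) filter taps followed by the
    pointwise nonlinearity; output has the stimulus length, and the first
    ``model.burn_in`` samples should be treated as burn-in.
    """
    if abs(stimulus.dt - model.filter.dt) > 1e-12:
        raise ResolutionError("stimulus dt does not match filter dt")
    lin = model.filter.apply(stimulus.values)
    out = np.asarray(model.nonlinearity(lin), float)
    return SampledTrace(out, stimulus.dt, stimulus.t0, "pA")


def model_accuracy(model: LNModel, session: WNRecordingSession) -> float:
    """Squared Pearson correlation on the repeated segment.

    r^2 between (1) the model's response to the repeated stimulus and
    (2) the mean recorded response to the repeated stimulus, with burn-in
    and the segment edge band excluded.
    """
    pred_full = ln_predict(model, session.stimulus).values
    trim = int(round(session.protocol.edge_band_s * session.protocol.sample_rate_hz))
    reps = []
    for seg in session.segments:
        start = seg.repeat.start + trim
        if start < model.burn_in:
            continue
        reps.append(pred_full[start : seg.repeat.stop])
    model_rep = np.mean(np.asarray(reps), axis=0)
    recorded = session.repeat_mean(trim_edge=True)
    if np.ptp(model_rep) == 0:
        raise UndefinedCorrelationError("model output constant on the repeat segment")
    return float(pearson_r(model_rep, recorded) ** 2)


def fit_ln_model(session: WNRecordingSession, max_lag_s: float = 0.2) -> LNModel:
    """Full LN estimation on one session (assumed reliability-gated).

    Filter from unique-segment cross-correlation; nonlinearity from the
    unique-segment prediction-response scatter (global burn-in excluded);
    metrics, rectification and repeat-segment accuracy attached.
    """
    filt = estimate_linear_filter(session, max_lag_s)
    lin_full = filt.apply(session.stimulus.values)
    resp_full = session.response().values
    burn = filt.taps.size
    pred_chunks, resp_chunks = [], []
    for seg in session.segments:
        start = max(seg.unique.start, burn)
        pred_chunks.append(lin_full[start : seg.unique.stop])
        resp_chunks.append(resp_full[start : seg.unique.stop])
    nl = fit_static_nonlinearity(np.concatenate(pred_chunks), np.concatenate(resp_chunks))
    model = LNModel(filter=filt, nonlinearity=nl)
    model.metrics = filter_metrics(filt)
    model.rectification = rectification_index(nl)
    model.accuracy_r2 = model_accuracy(model, session)
    return model


def pairwise_waveform_similarity(sessions: list[WNRecordingSession]) -> np.ndarray:
    """Symmetric matrix of r^2 between repeat-segment mean responses."""
    if not sessions:
        raise InsufficientDataError("no sessions given")
    proto = sessions[0].protocol
    for s in sessions[1:]:
        if (
            s.protocol.samples_per_trial != proto.samples_per_trial
            or s.protocol.unique_samples != proto.unique_samples
            or abs(s.protocol.dt - proto.dt) > 1e-12
        ):
            raise ResolutionError("sessions do not share a stimulus protocol")
    means = [s.repeat_mean(trim_edge=True) for s in sessions]
    n = len(means)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r2 = pearson_r(means[i], means[j]) ** 2
            out[i, j] = out[j, i] = r2
    return out
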