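"""LN cascade estimation: filters, metrics, nonlinearity, accuracy."""

import numpy as np
import pytest
from scipy.special import ndtr

from sacsyn.exceptions import (
    DegenerateInputError,
    InsufficientDataError,
    NoPeakError,
    ResolutionError,
)
from sacsyn.ln import (
    LinearFilter,
    LNModel,
    StaticNonlinearity,
    estimate_linear_filter,
    filter_metrics,
    fit_ln_model,
    fit_static_nonlinearity,
    ln_predict,
    model_accuracy,
    pairwise_waveform_similarity,
    rectification_index,
)
from sacsyn.traces import SampledTrace, StimulusProtocol, WNRecordingSession, generate_wn_stimulus


def _white_session(protocol, response_fn, rng):
    """Session whose responses derive deterministically from an unfiltered
    white stimulus (bypassing the 30-Hz low-pass so delta-like
    cross-correlations stay sharp)."""
    stim_vals = rng.standard_normal(protocol.total_samples)
    stim = SampledTrace(stim_vals, protocol.dt, 0.0, "z")
    resp = response_fn(stim_vals)
    npt = protocol.samples_per_trial
    trials = [SampledTrace(resp[k * npt : (k + 1) * npt], protocol.dt) for k in range(protocol.n_trials)]
    return WNRecordingSession(stimulus=stim, trials=trials, protocol=protocol)


class TestEstimateLinearFilter:
    def test_delayed_response_peaks_at_lag(self, small_protocol):
        rng = np.random.default_rng(0)
        lag = 40  # samples (20 ms at 2 kHz)
        session = _white_session(small_protocol, lambda s: np.roll(s, lag), rng)
        filt = estimate_linear_filter(session, max_lag_s=0.1)
        assert int(np.argmax(filt.taps)) == lag
        assert np.linalg.norm(filt.taps) == pytest.approx(1.0)

    def test_known_kernel_recovered(self, small_protocol):
        rng = np.random.default_rng(1)
        t = np.arange(100) * small_protocol.dt
        kernel = (t / 0.02) ** 2 * np.exp(2 * (1 - t / 0.02))
        session = _white_session(
            small_protocol, lambda s: np.convolve(s, kernel)[: s.size], rng
        )
        filt = estimate_linear_filter(session, max_lag_s=0.1)
        padded = np.zeros(filt.taps.size)
        padded[: kernel.size] = kernel
        r = np.corrcoef(filt.taps, padded)[0, 1]
        assert r > 0.95

    def test_zero_response_raises(self, small_protocol):
        rng = np.random.default_rng(2)
        session = _white_session(small_protocol, lambda s: np.zeros_like(s), rng)
        with pytest.raises(DegenerateInputError):
            estimate_linear_filter(session)

    def test_zero_variance_stimulus_raises(self, small_protocol):
        rng = np.random.default_rng(3)
        session = _white_session(small_protocol, lambda s: s.copy(), rng)
        session.stimulus = session.stimulus.with_values(np.ones(session.stimulus.n))
        with pytest.raises(DegenerateInputError):
            estimate_linear_filter(session)


class TestFilterMetrics:
    def _filter(self, taps, dt=1e-3):
        return LinearFilter(np.asarray(taps, float), dt, raw_gain=1.0)

    def test_nonnegative_filter_has_zero_biphasicity(self):
        taps = np.zeros(100)
        taps[10:30] = np.hanning(20)
        m = filter_metrics(self._filter(taps))
        assert m.biphasicity == 0.0

    def test_equal_lobes_give_one(self):
        taps = np.zeros(100)
        taps[10:20] = 1.0
        taps[30:40] = -1.0
        m = filter_metrics(self._filter(taps))
        assert m.biphasicity == pytest.approx(1.0)

    def test_gaussian_bump_width(self):
        # FW at 25% of a Gaussian of SD sigma is 2 sigma sqrt(2 ln 4) = 3.330 sigma
        dt = 1e-4
        t = np.arange(600) * dt
        sigma = 0.006
        taps = np.exp(-0.5 * ((t - 0.020) / sigma) ** 2)
        m = filter_metrics(self._filter(taps, dt))
        assert m.width_ms == pytest.approx(2 * sigma * 1e3 * np.sqrt(2 * np.log(4)), abs=0.1)
        assert m.peak_time_ms == pytest.approx(20.0, abs=0.1)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        taps = np.convolve(rng.standard_normal(80), np.hanning(25), "same")
        f1 = filter_metrics(self._filter(taps))
        f2 = filter_metrics(self._filter(taps * 17.0))
        assert f1 == f2

    def test_no_positive_peak_raises(self):
        with pytest.raises(NoPeakError):
            filter_metrics(self._filter(-np.ones(100)))


class TestStaticNonlinearity:
    def test_self_consistent_cdf_recovery(self):
        rng = np.random.default_rng(5)
        pred = rng.uniform(-4, 4, 20_000)
        resp = ndtr(pred)
        nl = fit_static_nonlinearity(pred, resp)
        assert nl.beta == pytest.approx(0.0, abs=0.01)
        assert nl.alpha == pytest.approx(1.0, rel=0.01)
        assert nl.mu == pytest.approx(0.0, abs=0.01)
        assert nl.sigma == pytest.approx(1.0, rel=0.01)
        assert nl.bin_prediction.size == 100

    def test_linear_response_gives_low_rectification(self):
        rng = np.random.default_rng(6)
        pred = rng.uniform(-3, 3, 20_000)
        nl = fit_static_nonlinearity(pred, pred.copy())
        assert rectification_index(nl) < 0.05

    def test_too_few_samples_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_static_nonlinearity(np.arange(50.0), np.arange(50.0))


class TestRectificationIndex:
    def _nl(self, x_min, x_max, mu=0.0, sigma=1.0):
        xb = np.linspace(x_min, x_max, 100)
        return StaticNonlinearity(0.0, 1.0, mu, sigma, xb, ndtr((xb - mu) / sigma))

    def test_symmetric_gives_zero(self):
        assert rectification_index(self._nl(-2.0, 2.0)) == pytest.approx(0.0, abs=1e-12)

    def test_half_rectified_gives_one(self):
        # N flat at N(0) below zero: N(min) == N(0) => numerator == denominator
        class HalfRect(StaticNonlinearity):
            def __call__(self, x):
                x = np.asarray(x, float)
                return np.where(x <= 0, 0.5, 0.5 + 0.5 * (1 - np.exp(-x)))

        xb = np.linspace(-2, 2, 100)
        hr = HalfRect(0.0, 1.0, 0.0, 1.0, xb, np.zeros(100))
        assert rectification_index(hr) == pytest.approx(1.0, rel=1e-6)

    def test_standard_normal_cdf_case(self):
        # extrema (-1, 2): |Phi(2) + Phi(-1) - 1| / (Phi(2) - Phi(-1)) = 0.1660
        assert rectification_index(self._nl(-1.0, 2.0)) == pytest.approx(0.1660, abs=0.001)

    def test_degenerate_raises(self):
        nl = self._nl(-2.0, 2.0)
        nl.bin_prediction = np.zeros(0)
        with pytest.raises(ValueError):
            rectification_index(nl)


class TestPredictionAndAccuracy:
    def _toy_model(self, dt=5e-4):
        taps = np.zeros(200)
        taps[20:60] = np.hanning(40)
        taps /= np.linalg.norm(taps)
        nl = StaticNonlinearity(1.0, 2.0, 0.0, 1.0, np.linspace(-1, 1, 100), np.linspace(0, 1, 100))
        return LNModel(LinearFilter(taps, dt), nl)

    def test_zero_stimulus_gives_constant_n0(self):
        model = self._toy_model()
        out = ln_predict(model, SampledTrace(np.zeros(5000), model.filter.dt))
        assert np.allclose(out.values, model.nonlinearity(0.0))

    def test_dt_mismatch_raises(self):
        model = self._toy_model()
        with pytest.raises(ResolutionError):
            ln_predict(model, SampledTrace(np.zeros(100), model.filter.dt * 2))

    def test_fitted_model_is_accurate_on_synthetic_session(self, dsgc_session):
        session, _ = dsgc_session
        model = fit_ln_model(session)
        assert model.accuracy_r2 > 0.8
        assert 0.0 <= model.rectification <= 1.0

    def test_accuracy_invariant_to_affine_output(self, dsgc_session):
        session, _ = dsgc_session
        model = fit_ln_model(session)
        scaled = LNModel(
            model.filter,
            StaticNonlinearity(
                2.0 * model.nonlinearity.beta + 5.0,
                2.0 * model.nonlinearity.alpha,
                model.nonlinearity.mu,
                model.nonlinearity.sigma,
                model.nonlinearity.bin_prediction,
                model.nonlinearity.bin_response,
            ),
        )
        assert model_accuracy(scaled, session) == pytest.approx(model.accuracy_r2, rel=1e-9)


class TestSerialization:
    def test_round_trip_exact(self, dsgc_session):
        session, _ = dsgc_session
        model = fit_ln_model(session)
        clone = LNModel.from_json(model.to_json())
        assert np.allclose(clone.filter.taps, model.filter.taps, atol=1e-12, rtol=0)
        assert clone.nonlinearity.sigma == model.nonlinearity.sigma
        assert clone.accuracy_r2 == model.accuracy_r2
        assert clone.metrics == model.metrics


class TestPairwiseSimilarity:
    def test_matrix_properties(self, dsgc_session, sac_session):
        m = pairwise_waveform_similarity([dsgc_session[0], sac_session[0]])
        assert m.shape == (2, 2)
        assert m[0, 0] == m[1, 1] == 1.0
        assert m[0, 1] == m[1, 0]
        assert 0.0 <= m[0, 1] <= 1.0

    def test_same_model_more_similar_than_cross_model(self, ref_models):
        import dataclasses

        from sacsyn.synthetic import simulate_wn_session

        dsgc, sac = ref_models
        proto = StimulusProtocol(seed=5, sample_rate_hz=5000.0)
        sessions = [
            simulate_wn_session(dataclasses.replace(m, seed=s), proto)[0]
            for m in (dsgc, sac)
            for s in (21, 22)
        ]
        m = pairwise_waveform_similarity(sessions)
        within = (m[0, 1] + m[2, 3]) / 2
        between = (m[0, 2] + m[0, 3] + m[1, 2] + m[1, 3]) / 4
        assert within > between
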