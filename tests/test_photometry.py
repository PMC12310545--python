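"""Photometry preprocessing, demodulation, and kernel regression."""

import numpy as np
import pytest

from apesim.photometry import (
    KernelSpec,
    PhotometrySession,
    ProcessedTrace,
    demodulate,
    extract_response,
    explained_variance_pct,
    fit_kernels,
    partial_explained_variance,
    preprocess,
)
from apesim.synthetic_data import KernelShape, SynthConfig, generate_photometry


def _convolved_trace(events, kernels, n, rate, spec):
    """Direct convolution oracle for the kernel-regression design."""
    y = np.zeros(n)
    for name, times in events.items():
        n_pre, n_post = spec.n_lags(name, rate)
        k = kernels[name]
        for t in times:
            c = int(round(t * rate))
            for j, lag in enumerate(range(-n_pre, n_post + 1)):
                if 0 <= c + lag < n:
                    y[c + lag] += k[j]
    return y


class TestDemodulation:
    def test_pure_carrier_recovers_amplitude(self):
        rate = 5000.0
        t = np.arange(0, 20, 1 / rate)
        sig, bg = demodulate(3.0 * np.sin(2 * np.pi * 211.0 * t), rate=rate)
        core = slice(int(2 * rate), int(-2 * rate))
        assert np.allclose(sig[core], 3.0, atol=0.05)
        assert np.allclose(bg[core], 0.0, atol=0.05)

    def test_dual_carrier_envelopes_recovered(self):
        rate = 5000.0
        t = np.arange(0, 30, 1 / rate)
        env_s = 2.0 + np.sin(2 * np.pi * 0.5 * t)
        env_b = 3.0 + 0.5 * np.cos(2 * np.pi * 0.3 * t)
        trace = (env_s * np.sin(2 * np.pi * 211.0 * t)
                 + env_b * np.sin(2 * np.pi * 531.0 * t))
        sig, bg = demodulate(trace, rate=rate)
        core = slice(int(2 * rate), int(-2 * rate))
        rms = lambda x: np.sqrt(np.mean(x ** 2))
        assert rms(sig[core] - env_s[core]) / rms(env_s[core]) < 0.02
        assert rms(bg[core] - env_b[core]) / rms(env_b[core]) < 0.02

    def test_zero_input_gives_zero_envelopes(self):
        sig, bg = demodulate(np.zeros(20_000), rate=5000.0)
        assert np.allclose(sig, 0) and np.allclose(bg, 0)

    def test_carrier_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            demodulate(np.zeros(1000), rate=400.0)


class TestPreprocess:
    def test_output_is_zero_mean_unit_sd(self):
        events = {"cue": np.array([10.0, 50.0, 120.0])}
        sess, _ = generate_photometry(events, SynthConfig(seed=0))
        proc = preprocess(sess)
        assert abs(proc.dff_z.mean()) < 1e-6
        assert abs(proc.dff_z.std() - 1) < 1e-6

    def test_shared_artifact_is_rejected(self):
        events = {"cue": np.sort(np.random.default_rng(0).uniform(5, 290, 50))}
        cfg = SynthConfig(seed=2, motion_sd=0.5)
        sess, truth = generate_photometry(events, cfg)
        proc = preprocess(sess)
        assert abs(np.corrcoef(proc.dff_z, truth.artifact)[0, 1]) < 0.05

    def test_constant_trace_returns_zeros(self):
        sess = PhotometrySession(100.0, np.full(30_000, 5.0), np.full(30_000, 3.0))
        proc = preprocess(sess)
        assert np.allclose(proc.dff_z, 0.0)

    def test_known_transients_survive_with_high_snr(self):
        times = np.arange(20.0, 280.0, 10.0)
        cfg = SynthConfig(seed=3)     # default noise/motion levels
        sess, _ = generate_photometry({"choice": times}, cfg)
        proc = preprocess(sess)
        rate = proc.sampling_rate
        peaks = [extract_response(proc.dff_z, rate, (t, t + 1.0), "max_fallback")
                 for t in times]
        noise_sd = np.std(proc.dff_z[:int(10 * rate)])   # pre-event segment
        assert np.median(peaks) / noise_sd > 5

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            preprocess(PhotometrySession(100.0, np.ones(50), np.ones(50)))


class TestExtractResponse:
    def test_monotone_segment_falls_back_to_endpoint_max(self):
        ramp = np.linspace(0, 1, 100)
        assert extract_response(ramp, 100.0, (0.0, 0.99)) == pytest.approx(1.0)

    def test_triangular_bump_height(self):
        bump = np.concatenate([np.linspace(0, 2, 50), np.linspace(2, 0, 50)])
        assert extract_response(bump, 100.0, (0.0, 0.99)) == pytest.approx(2.0)

    def test_mean_of_linear_ramp(self):
        ramp = np.linspace(0, 1, 101)
        assert extract_response(ramp, 100.0, (0.0, 1.0), "mean") == pytest.approx(0.5)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            extract_response(np.ones(100), 100.0, (2.0, 1.0))


class TestKernelRegression:
    rate = 50.0
    spec = KernelSpec()

    def _events(self, seed=0, n=40, tmax=290.0):
        rng = np.random.default_rng(seed)
        return {"cue": np.sort(rng.uniform(5, tmax, n)),
                "choice": np.sort(rng.uniform(5, tmax, n))}

    def test_noiseless_recovery_to_machine_precision(self):
        events = self._events()
        rng = np.random.default_rng(1)
        true_k = {
            "cue": rng.normal(0, 1, self.spec.n_lags("cue", self.rate)[0]
                              + self.spec.n_lags("cue", self.rate)[1] + 1),
            "choice": rng.normal(0, 1, sum(self.spec.n_lags("choice", self.rate)) + 1),
        }
        n = int(300 * self.rate)
        y = _convolved_trace(events, true_k, n, self.rate, self.spec)
        fit = fit_kernels(ProcessedTrace(y, self.rate), events, self.spec)
        for name in true_k:
            err = np.max(np.abs(fit.kernels[name] - true_k[name]))
            assert err < 1e-6 * np.max(np.abs(true_k[name]))
        assert fit.v_full > 99.999

    def test_zero_trace_gives_zero_kernels(self):
        events = self._events()
        fit = fit_kernels(ProcessedTrace(np.zeros(int(300 * self.rate)), self.rate),
                          events, self.spec)
        assert fit.g0 == pytest.approx(0.0)
        for k in fit.kernels.values():
            assert np.allclose(k, 0.0)

    def test_non_overlapping_events_recovered_independently(self):
        # two event types confined to disjoint halves of the session
        rng = np.random.default_rng(2)
        events = {"cue": np.sort(rng.uniform(5, 140, 30)),
                  "outcome": np.sort(rng.uniform(160, 290, 30))}
        true_k = {"cue": np.sin(np.linspace(0, np.pi, sum(self.spec.n_lags("cue", self.rate)) + 1)),
                  "outcome": np.cos(np.linspace(0, np.pi, sum(self.spec.n_lags("outcome", self.rate)) + 1))}
        n = int(300 * self.rate)
        y = _convolved_trace(events, true_k, n, self.rate, self.spec)
        fit = fit_kernels(ProcessedTrace(y, self.rate), events, self.spec)
        for name in true_k:
            assert np.max(np.abs(fit.kernels[name] - true_k[name])) < 1e-8

    def test_partial_ev_null_and_dominant_regressors(self):
        rng = np.random.default_rng(3)
        events = self._events(seed=3)
        true_k = {"cue": np.zeros(sum(self.spec.n_lags("cue", self.rate)) + 1),
                  "choice": np.sin(np.linspace(0, np.pi, sum(self.spec.n_lags("choice", self.rate)) + 1))}
        n = int(300 * self.rate)
        y = _convolved_trace(events, true_k, n, self.rate, self.spec)
        y += 0.05 * rng.standard_normal(n)
        fit = fit_kernels(ProcessedTrace(y, self.rate), events, self.spec)
        assert partial_explained_variance(fit, "cue") < 5.0
        assert partial_explained_variance(fit, "choice") > 80.0

    def test_partial_ev_nonnegative_and_bounded_by_full(self):
        rng = np.random.default_rng(4)
        events = self._events(seed=5)
        n = int(300 * self.rate)
        y = rng.standard_normal(n)
        fit = fit_kernels(ProcessedTrace(y, self.rate), events, self.spec)
        if fit.v_full > 0:
            for name in events:
                assert partial_explained_variance(fit, name) >= 0.0

    def test_equal_power_orthogonal_regressors_share_equally(self):
        rng = np.random.default_rng(6)
        events = {"cue": np.sort(rng.uniform(5, 140, 40)),
                  "outcome": np.sort(rng.uniform(160, 290, 40))}
        k = np.sin(np.linspace(0, np.pi, sum(self.spec.n_lags("cue", self.rate)) + 1))
        true_k = {"cue": k, "outcome": k}
        n = int(300 * self.rate)
        y = _convolved_trace(events, true_k, n, self.rate, self.spec)
        y += 0.02 * rng.standard_normal(n)
        fit = fit_kernels(ProcessedTrace(y, self.rate), events, self.spec)
        pev = [partial_explained_variance(fit, name) for name in true_k]
        assert abs(pev[0] - pev[1]) < 10.0

    def test_trimmed_scoring_restricted_to_event_epochs(self):
        events = {"cue": np.array([50.0, 150.0, 250.0])}
        true_k = {"cue": np.ones(sum(self.spec.n_lags("cue", self.rate)) + 1)}
        n = int(300 * self.rate)
        y = _convolved_trace(events, true_k, n, self.rate, self.spec)
        rng = np.random.default_rng(7)
        y += 0.5 * rng.standard_normal(n)    # noise everywhere
        full = fit_kernels(ProcessedTrace(y, self.rate), events, self.spec)
        trimmed = fit_kernels(ProcessedTrace(y, self.rate), events, self.spec,
                              trim=True)
        # scoring only where events live raises explained variance
        assert trimmed.v_full > full.v_full

    def test_no_usable_events_rejected(self):
        with pytest.raises(ValueError):
            fit_kernels(ProcessedTrace(np.zeros(1000), 50.0), {"licks": [1.0]})


def test_explained_variance_pct_perfect_and_null():
    y = np.sin(np.linspace(0, 10, 500))
    assert explained_variance_pct(y, y) == pytest.approx(100.0)
    assert explained_variance_pct(y, np.full_like(y, y.mean())) == pytest.approx(0.0)
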