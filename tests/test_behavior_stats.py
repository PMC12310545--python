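"""Behavioural statistics: Weibull fits, shuffle test, regressions, Frechet."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from apesim.behavior_stats import (
    clean_performance,
    dopamine_history_regression,
    fit_weibull,
    frechet_distance,
    log_uncertainty,
    max_binned_performance,
    repeat_choice_logistic,
    residual_trend_regression,
    rolling_performance,
    shuffle_bias_test,
    similarity_regression,
    weibull_curve,
)
from apesim.synthetic_data import generate_cohort, generate_trajectories


def brute_force_frechet(p, q):
    """Exhaustive minimax over all monotone couplings (tiny inputs only)."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    n, m = len(p), len(q)
    d = np.sqrt(((p[:, None, :] - q[None, :, :]) ** 2).sum(axis=2))
    best = [np.inf]

    def walk(i, j, cur):
        cur = max(cur, d[i, j])
        if cur >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cur
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < n and j + dj < m:
                walk(i + di, j + dj, cur)

    walk(0, 0, 0.0)
    return best[0]


class TestWeibull:
    def test_curve_is_fifty_at_zero_trials(self):
        assert weibull_curve(np.array([0.0]), 30, 1000, 1.5)[0] == pytest.approx(50.0)

    def test_flat_chance_data_fits_no_learning(self):
        rng = np.random.default_rng(0)
        raw = 100.0 * (rng.random(3000) < 0.5)
        fit = fit_weibull(raw, seed=0)
        # the fitted curve must stay at chance over the observed range
        # (an end performance below 55% is the usual non-learner bound)
        end = weibull_curve(np.array([3000.0]), fit.a_amp, fit.l_scale,
                            fit.s_shape)[0]
        assert end < 55.0

    def test_parameter_recovery_from_binomial_trials(self):
        true = {"a": 40.0, "l": 1500.0, "s": 1.5}
        df, _ = generate_cohort(1, true, 5000, seed=1)
        fit = fit_weibull(100.0 * df["correct"].to_numpy(), seed=0)
        assert fit.a_amp == pytest.approx(true["a"], abs=6)
        assert fit.l_scale == pytest.approx(true["l"], rel=0.2)
        assert fit.s_shape == pytest.approx(true["s"], abs=0.5)

    def test_fit_invariant_to_order_preserving_reindexing(self):
        df, _ = generate_cohort(1, {"a": 35.0, "l": 800.0, "s": 1.2}, 3000, seed=2)
        raw = 100.0 * df["correct"].to_numpy()
        t = np.arange(1, len(raw) + 1, dtype=float)
        f1 = fit_weibull(raw, trials=t, seed=0)
        f2 = fit_weibull(raw, trials=t, seed=0)   # same order, same answer
        assert f1.a_amp == f2.a_amp and f1.l_scale == f2.l_scale

    def test_rolling_and_binned_performance_helpers(self):
        perf = rolling_performance(np.ones(300), window=100)
        assert np.allclose(perf, 100.0)
        assert max_binned_performance(np.linspace(50, 90, 1000), 200) \
            == pytest.approx(np.median(np.linspace(50, 90, 1000)[800:]))

    def test_engagement_filters(self):
        df = pd.DataFrame({
            "session_idx": [0] * 100 + [1] * 30,
            "trial_idx": list(range(100)) + list(range(30)),
            "inter_trial_interval": [1.0] * 95 + [50.0] * 5 + [1.0] * 30,
        })
        out = clean_performance(df)
        assert set(out.session_idx) == {0}          # short session dropped
        assert out.trial_idx.min() == 5             # first trials dropped
        assert (out.inter_trial_interval <= 3.0).all()


class TestShuffleBias:
    def _null_session(self, rng, n=300):
        levels = np.linspace(0.02, 0.98, 7)
        p_high = rng.choice(levels, n)
        return pd.DataFrame({
            "p_high": p_high,
            "choice": np.where(rng.random(n) < p_high, "right", "left"),
            "opto_stim": rng.random(n) < 0.2,
        })

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(0)
        rej = sum(shuffle_bias_test(self._null_session(rng), 200, seed=s).p_value < 0.05
                  for s in range(400))
        assert 0.03 <= rej / 400 <= 0.07

    def test_extreme_effect_detected(self):
        rng = np.random.default_rng(1)
        n = 400
        p_high = rng.choice(np.linspace(0.02, 0.98, 7), n)
        opto = rng.random(n) < 0.2
        choice = np.where(opto, "right",
                          np.where(rng.random(n) < 0.5, "right", "left"))
        df = pd.DataFrame({"p_high": p_high, "choice": choice, "opto_stim": opto})
        res = shuffle_bias_test(df, 1000, seed=0)
        assert res.session_bias == pytest.approx(0.5, abs=0.1)
        assert res.p_value < 0.01

    def test_identical_distributions_give_null_bias(self):
        rng = np.random.default_rng(2)
        df = self._null_session(rng, n=4000)
        res = shuffle_bias_test(df, 200, seed=0)
        assert abs(res.session_bias) < 0.05

    def test_all_stimulated_type_excluded(self):
        df = pd.DataFrame({
            "p_high": [0.1] * 20 + [0.9] * 20,
            "choice": ["left"] * 20 + ["right"] * 20,
            "opto_stim": [True] * 20 + ([True] * 5 + [False] * 15),
        })
        res = shuffle_bias_test(df, 100, seed=0)
        assert 0.1 in res.excluded_types


class TestChoiceRegressions:
    def test_repeat_logistic_recovers_planted_weight(self):
        rng = np.random.default_rng(3)
        n = 4000
        levels = np.linspace(0.02, 0.98, 7)
        p_high = rng.choice(levels, n)
        da = rng.normal(1, 0.5, n)
        w = 1.2
        choice = ["right"]
        for i in range(1, n):
            p_rep = 1 / (1 + np.exp(-w * (da[i - 1] - 1)))
            choice.append(choice[-1] if rng.random() < p_rep
                          else ("left" if choice[-1] == "right" else "right"))
        df = pd.DataFrame({"p_high": p_high, "choice": choice,
                           "correct_side": np.where(p_high > 0.5, "right", "left"),
                           "dopamine": da})
        res = repeat_choice_logistic(df, seed=0)
        assert res["coef_dopamine"] == pytest.approx(w, abs=0.35)

    def test_repeat_logistic_null_coefficients_near_zero(self):
        rng = np.random.default_rng(4)
        n = 4000
        df = pd.DataFrame({
            "p_high": np.full(n, 0.5),
            "choice": np.where(rng.random(n) < 0.5, "right", "left"),
            "correct_side": np.where(rng.random(n) < 0.5, "right", "left"),
            "dopamine": rng.normal(1, 0.5, n),
        })
        res = repeat_choice_logistic(df, seed=0)
        assert abs(res["coef_dopamine"]) < 0.15

    def test_history_regression_recovers_planted_lag1(self):
        rng = np.random.default_rng(5)
        n = 3000
        p_high = rng.choice([0.98, 0.02], n)
        choice = np.where(rng.random(n) < 0.5, "right", "left")
        da = np.zeros(n)
        last = {}
        for i in range(n):
            prev = last.get(p_high[i])
            da[i] = 1.0 - 0.4 * (prev == "right") + rng.normal(0, 0.1)
            last[p_high[i]] = choice[i]
        df = pd.DataFrame({"trial_idx": np.arange(n), "p_high": p_high,
                           "choice": choice,
                           "correct_side": np.where(p_high > 0.5, "right", "left"),
                           "dopamine": da})
        co = dopamine_history_regression(df, max_lag=3)
        assert co[1] == pytest.approx(-0.4, abs=0.05)
        assert abs(co[2]) < 0.05

    def test_history_regression_null_is_flat(self):
        rng = np.random.default_rng(6)
        n = 2000
        p_high = rng.choice([0.98, 0.02], n)
        df = pd.DataFrame({"trial_idx": np.arange(n), "p_high": p_high,
                           "choice": np.where(rng.random(n) < 0.5, "right", "left"),
                           "correct_side": np.where(p_high > 0.5, "right", "left"),
                           "dopamine": rng.normal(1, 0.3, n)})
        co = dopamine_history_regression(df, max_lag=2)
        assert np.all(np.abs(co.to_numpy()) < 0.06)

    def test_log_uncertainty_ordering(self):
        u = log_uncertainty(np.array([0.98, 0.75, 0.5]))
        assert u[0] < u[1] < u[2]


class TestFrechet:
    def test_identity_and_offset(self):
        t1 = np.column_stack([np.linspace(0, 1, 10), np.zeros(10)])
        assert frechet_distance(t1, t1) == 0.0
        assert frechet_distance(t1, t1 + [0.0, 0.7]) == pytest.approx(0.7)

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.normal(0, 1, (6, 2))
            q = rng.normal(0, 1, (6, 2))
            assert frechet_distance(p, q) == pytest.approx(
                brute_force_frechet(p, q), abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(2, 5), st.integers(2, 5), st.integers(0, 10_000))
    def test_metric_properties(self, n, m, seed):
        rng = np.random.default_rng(seed)
        p = rng.normal(0, 1, (n, 2))
        q = rng.normal(0, 1, (m, 2))
        d = frechet_distance(p, q)
        assert d >= 0
        assert d == pytest.approx(frechet_distance(q, p))
        endpoints = max(np.linalg.norm(p[0] - q[0]), np.linalg.norm(p[-1] - q[-1]))
        assert d >= endpoints - 1e-12

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            frechet_distance(np.empty((0, 2)), np.ones((3, 2)))


class TestSimilarityAndTrendRegressions:
    def test_similarity_regression_recovers_planted_negative_slope(self):
        rng = np.random.default_rng(8)
        responses = rng.uniform(0, 2, 200)
        trajs = generate_trajectories(responses, seed=1, coupling=-1.0)
        res = similarity_regression(responses, trajs)
        assert res["slope"] < 0

    def test_similarity_regression_null_slope(self):
        rng = np.random.default_rng(9)
        responses = rng.uniform(0, 2, 300)
        trajs = generate_trajectories(np.ones(300), seed=2, coupling=0.0)
        res = similarity_regression(responses, trajs)
        assert abs(res["slope"]) < 0.2

    def test_identical_trajectories_give_zero_slope(self):
        traj = np.column_stack([np.arange(5.0), np.arange(5.0)])
        res = similarity_regression(np.array([1.0, 2.0, 3.0]), [traj] * 3)
        assert res["slope"] == 0.0

    def test_residual_trend_recovers_planted_log_trend(self):
        rng = np.random.default_rng(10)
        n = 1000
        speed = rng.lognormal(np.log(20), 0.3, n)
        turn = rng.normal(30, 10, n)
        y = -0.5 * np.log(np.arange(1, n + 1)) + rng.normal(0, 0.1, n)
        res = residual_trend_regression(y, speed, turn)
        assert res["residual_slope"] == pytest.approx(-0.5, abs=0.05)
        assert res["movement_r2"] < 0.05
        assert res["variance_shares"]["log_trial"] > 0.5

    def test_speed_only_signal_leaves_no_trend(self):
        rng = np.random.default_rng(11)
        n = 1000
        speed = rng.lognormal(np.log(20), 0.3, n)
        turn = rng.normal(30, 10, n)
        y = 0.1 * speed + rng.normal(0, 0.05, n)
        res = residual_trend_regression(y, speed, turn)
        assert abs(res["residual_slope"]) < 0.02
        assert res["movement_r2"] > 0.8

    def test_collinear_kinematics_least_norm(self):
        rng = np.random.default_rng(12)
        n = 500
        speed = rng.lognormal(np.log(20), 0.3, n)
        y = 0.1 * speed + rng.normal(0, 0.05, n)
        res = residual_trend_regression(y, speed, 2.0 * speed)  # collinear
        assert np.isfinite(res["residual_slope"])
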