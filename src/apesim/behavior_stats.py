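"""Behavioural and trial-linked statistics.

Covers the learning-curve analysis (modified Weibull fits, maximum
performance and learning rate), the shuffle-null test for optogenetic
choice biases, regressions linking dopamine response size to choice
history, the large/small (65th-percentile) repeat-or-switch logistic
regression, movement-similarity analysis via the discrete Frechet distance,
and the residual trend regression separating kinematic from trial-number
contributions to dopamine response size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Weibull learning curves
# ---------------------------------------------------------------------------

@dataclass
class WeibullFit:
    a_amp: float            # asymptotic amplitude above 50, in %
    l_scale: float          # trials
    s_shape: float
    max_performance: float  # % — max of 200-trial binned medians
    max_learning_rate: float  # % per trial
    converged: bool = True


def weibull_curve(trials: np.ndarray, a: float, l: float, s: float) -> np.ndarray:
    """Modified Weibull learning curve: 50 + a(1 - 2^(-(t/l)^s)).

    Equals 50% (chance) at trial 0 by construction and approaches 50 + a.
    """
    t = np.asarray(trials, dtype=float)
    with np.errstate(invalid="ignore"):
        x = np.where(t > 0, (t / l) ** s, 0.0)
    return 50.0 + a * (1.0 - np.exp2(-x))


def clean_performance(df: pd.DataFrame, min_session_trials: int = 60,
                      drop_first: int = 5, iti_factor: float = 3.0) -> pd.DataFrame:
    """Engagement filters applied before learning-curve fits.

    Drops sessions shorter than ``min_session_trials``, the first
    ``drop_first`` trials of each session, and disengaged trials whose
    inter-trial interval exceeds ``iti_factor`` times the session median.
    Expects columns session_idx, trial_idx, inter_trial_interval.
    """
    out = []
    for _, sess in df.groupby("session_idx"):
        if len(sess) < min_session_trials:
            continue
        sess = sess.sort_values("trial_idx").iloc[drop_first:]
        med = sess["inter_trial_interval"].median()
        sess = sess[sess["inter_trial_interval"] <= iti_factor * med]
        out.append(sess)
    if not out:
        return df.iloc[0:0]
    return pd.concat(out, ignore_index=True)


def rolling_performance(correct: np.ndarray, window: int = 100) -> np.ndarray:
    """Percent correct over the trailing ``window`` trials (growing early)."""
    c = np.asarray(correct, dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(c)])
    n = len(c)
    idx = np.arange(1, n + 1)
    lo = np.maximum(idx - window, 0)
    return 100.0 * (csum[idx] - csum[lo]) / (idx - lo)


def max_binned_performance(performance_pct: np.ndarray, bin_size: int = 200) -> float:
    """Maximum of the per-bin medians of a performance curve (in %)."""
    p = np.asarray(performance_pct, dtype=float)
    n_bins = max(len(p) // bin_size, 1)
    meds = [np.median(p[i * bin_size:(i + 1) * bin_size]) for i in range(n_bins)]
    tail = p[n_bins * bin_size:]
    if len(tail):
        meds.append(np.median(tail))
    return float(np.max(meds))


def fit_weibull(performance_pct: np.ndarray, trials: np.ndarray | None = None,
                seed: int = 0, n_starts: int = 5) -> WeibullFit:
    """Least-squares fit of the modified Weibull curve to a performance
    trajectory (percent correct per trial).

    Multi-start over log-spaced scale values guards against the flat local
    minima typical of sigmoid fits; the maximum learning rate is the
    maximum of the fitted curve's derivative (evaluated on a dense trial
    grid, robust for shape parameters below 1 where the analytic maximum
    sits at zero trials).
    """
    p = np.asarray(performance_pct, dtype=float)
    t = np.arange(1, len(p) + 1, dtype=float) if trials is None \
        else np.asarray(trials, dtype=float)
    if len(p) != len(t):
        raise ValueError("performance and trials must have equal length")

    rng = np.random.default_rng(seed)
    amp0 = max(np.median(p[-max(len(p) // 10, 1):]) - 50.0, 1.0)
    l_starts = np.geomspace(max(len(t) / 50, 10), max(len(t), 20), n_starts)
    best, best_cost = None, np.inf
    for l0 in l_starts:
        s0 = rng.uniform(0.8, 2.0)
        try:
            res = optimize.least_squares(
                lambda th: weibull_curve(t, *th) - p,
                x0=[amp0, l0, s0],
                bounds=([0.0, 1e-3, 0.05], [60.0, 1e7, 20.0]),
                xtol=1e-8, ftol=1e-8,
            )
        except Exception:   # pragma: no cover - optimizer pathologies
            continue
        if res.cost < best_cost:
            best, best_cost = res, res.cost
    if best is None:
        logger.warning("Weibull fit failed to converge from all starts")
        return WeibullFit(np.nan, np.nan, np.nan, np.nan, np.nan, converged=False)

    a, l, s = best.x
    grid = np.linspace(max(t.min(), 1.0), t.max(), 2000)
    curve = weibull_curve(grid, a, l, s)
    rate = np.gradient(curve, grid)
    return WeibullFit(
        a_amp=float(a), l_scale=float(l), s_shape=float(s),
        max_performance=max_binned_performance(p),
        max_learning_rate=float(np.max(rate)),
        converged=bool(best.success),
    )


def bootstrap_weibull_ci(fit: WeibullFit, n_trials: int, n_boot: int = 200,
                         seed: int = 0, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
    """Parametric bootstrap confidence intervals for (a, l, s).

    Regenerates Bernoulli trial outcomes from the fitted curve and refits
    the curve to the raw binary outcomes (the unbiased estimator, unlike
    fitting smoothed rolling performance), taking percentile intervals.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(1, n_trials + 1, dtype=float)
    p_true = np.clip(weibull_curve(t, fit.a_amp, fit.l_scale, fit.s_shape) / 100.0,
                     0.0, 1.0)
    boots = []
    for b in range(n_boot):
        correct = rng.random(n_trials) < p_true
        f = fit_weibull(100.0 * correct.astype(float), seed=seed + b + 1, n_starts=3)
        if f.converged:
            boots.append([f.a_amp, f.l_scale, f.s_shape])
    boots = np.asarray(boots)
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    names = ("a_amp", "l_scale", "s_shape")
    return {n: (float(np.percentile(boots[:, i], lo)),
                float(np.percentile(boots[:, i], hi)))
            for i, n in enumerate(names)}


# ---------------------------------------------------------------------------
# shuffle-null opto bias test
# ---------------------------------------------------------------------------

@dataclass
class BiasTestResult:
    per_type_bias: dict[float, float]
    session_bias: float
    null_distribution: np.ndarray
    p_value: float
    excluded_types: list[float] = field(default_factory=list)


def shuffle_bias_test(trials: pd.DataFrame, n_shuffles: int = 1000,
                      seed: int = 0, side: str = "right") -> BiasTestResult:
    """Shuffle-null test for a stimulation-induced choice bias.

    For every trial type (stimulus level), the observed bias is the
    difference between the chosen-``side`` proportion on stimulated and
    unstimulated trials. The null re-labels, per type, a random subset of
    the same size as the stimulated count as pseudo-stimulated (label
    permutation within type, which is exactly exchangeable under the null)
    and rebuilds the session-level bias (mean over types) ``n_shuffles``
    times; the two-sided p-value is the fraction of null biases at least as
    extreme as the observed one (with the +1 correction). Types with no
    stimulated or no unstimulated trials are excluded and logged.

    Expects columns: p_high, choice, opto_stim (bool).
    """
    rng = np.random.default_rng(seed)
    per_type: dict[float, float] = {}
    null_parts = []
    excluded = []
    for level, grp in trials.groupby("p_high"):
        stim = grp[grp["opto_stim"]]
        unstim = grp[~grp["opto_stim"]]
        if len(stim) == 0 or len(unstim) == 0:
            excluded.append(float(level))
            logger.info("trial type %s excluded from bias test", level)
            continue
        obs = float((stim["choice"] == side).mean()
                    - (unstim["choice"] == side).mean())
        per_type[float(level)] = obs
        chosen = (grp["choice"] == side).to_numpy(dtype=float)
        k, n = len(stim), len(grp)
        # permute the stimulation labels: k pseudo-stimulated vs complement
        order = np.argsort(rng.random((n_shuffles, n)), axis=1)
        picked = order[:, :k]
        rest = order[:, k:]
        null_props = chosen[picked].mean(axis=1) - chosen[rest].mean(axis=1)
        null_parts.append(null_props)
    if not per_type:
        raise ValueError("no trial type has both stimulated and unstimulated trials")

    session_bias = float(np.mean(list(per_type.values())))
    null = np.mean(np.vstack(null_parts), axis=0)
    p = (np.sum(np.abs(null) >= abs(session_bias)) + 1) / (n_shuffles + 1)
    return BiasTestResult(per_type, session_bias, null, float(p), excluded)


# ---------------------------------------------------------------------------
# dopamine history / repeat-switch analyses
# ---------------------------------------------------------------------------

def log_uncertainty(p_high: np.ndarray, eps_floor: float = 1e-3) -> np.ndarray:
    """Perceptual uncertainty of a stimulus level on a log scale.

    Maps the distance of p_high from the category boundary (0.5) into
    -log(2|p - 0.5| + eps): 0-ish for the easiest stimuli, large for the
    ambiguous 50/50 mixture.
    """
    return -np.log(2.0 * np.abs(np.asarray(p_high, dtype=float) - 0.5) + eps_floor)


def repeat_choice_logistic(trials: pd.DataFrame, seed: int = 0,
                           percentile: float = 65.0) -> dict:
    """Logistic regression of repeat-vs-switch on previous-trial dopamine.

    Trials are filtered as in the experimental analysis: correct trials
    only, except for the ambiguous (50%) stimulus where both outcomes enter
    (the relevant dopamine response precedes the outcome). The model
    predicts whether the current choice repeats the previous one from the
    previous trial's dopamine response size and the current trial's log
    uncertainty. Also returns the large/small summary based on the
    ``percentile`` split of responses. On separation the fit falls back to
    an L2-regularised one (flagged in the result).

    Expects columns: choice, correct_side, p_high, dopamine.
    """
    df = trials.reset_index(drop=True).copy()
    df["repeat"] = (df["choice"] == df["choice"].shift(1)).astype(float)
    df["prev_da"] = df["dopamine"].shift(1)
    ambiguous = np.isclose(df["p_high"], 0.5)
    keep = ((df["choice"] == df["correct_side"]) | ambiguous) & df["prev_da"].notna()
    d = df[keep]
    X = sm.add_constant(pd.DataFrame({
        "prev_da": d["prev_da"].to_numpy(),
        "log_uncertainty": log_uncertainty(d["p_high"].to_numpy()),
    }), has_constant="add")
    y = d["repeat"].to_numpy()
    regularized = False
    try:
        fit = sm.Logit(y, X).fit(disp=0)
        params = fit.params
        if not np.all(np.isfinite(fit.bse)):
            raise np.linalg.LinAlgError
    except Exception:
        logger.warning("logistic separation; refitting with L2 penalty")
        fit = sm.Logit(y, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        params = fit.params
        regularized = True

    thresh = np.nanpercentile(d["prev_da"], percentile)
    large = d[d["prev_da"] > thresh]
    small = d[d["prev_da"] <= thresh]
    summary = pd.DataFrame({
        "p_high": sorted(d["p_high"].unique()),
        "repeat_large": [large[large.p_high == p]["repeat"].mean()
                         for p in sorted(d["p_high"].unique())],
        "repeat_small": [small[small.p_high == p]["repeat"].mean()
                         for p in sorted(d["p_high"].unique())],
    })
    return {
        "coef_dopamine": float(params["prev_da"]),
        "coef_log_uncertainty": float(params["log_uncertainty"]),
        "intercept": float(params["const"]),
        "split_percentile": percentile,
        "summary": summary,
        "regularized": regularized,
        "n": int(len(d)),
    }


def dopamine_history_regression(trials: pd.DataFrame, max_lag: int = 5,
                                side: str = "right") -> pd.Series:
    """Per-lag regression of dopamine response size on past same-choices.

    On correct ``side`` (contralateral) trials, the lag-k predictor is
    whether the same side was chosen the k-th previous time the same
    stimulus occurred. A negative coefficient means the response shrinks
    when the action has been paired with that stimulus before — the
    signature of an action prediction error. One OLS per lag.

    Expects columns: trial_idx, p_high, choice, correct_side, dopamine.
    """
    df = trials.reset_index(drop=True)
    coefs = {}
    # choice history per stimulus level
    hist: dict[float, list[str]] = {}
    rows = []   # (lag predictors, response) for correct contralateral trials
    for _, row in df.iterrows():
        level = float(row["p_high"])
        past = hist.setdefault(level, [])
        if row["choice"] == side and row["choice"] == row["correct_side"]:
            preds = {lag: (1.0 if len(past) >= lag and past[-lag] == side else 0.0)
                     for lag in range(1, max_lag + 1)}
            counts = {lag: len(past) >= lag for lag in range(1, max_lag + 1)}
            rows.append((preds, counts, float(row["dopamine"])))
        past.append(row["choice"])
    for lag in range(1, max_lag + 1):
        x = np.array([p[lag] for p, c, _ in rows if c[lag]])
        y = np.array([r for p, c, r in rows if c[lag]])
        if len(x) < 3 or x.std() == 0:
            coefs[lag] = np.nan
            continue
        X = sm.add_constant(x)
        coefs[lag] = float(sm.OLS(y, X).fit().params[1])
    return pd.Series(coefs, name="coefficient").rename_axis("lag")


# ---------------------------------------------------------------------------
# trajectory similarity
# ---------------------------------------------------------------------------

def frechet_distance(t1: np.ndarray, t2: np.ndarray) -> float:
    """Discrete Frechet distance between two 2-D point sequences.

    Computed by the standard recursive coupling recurrence (memoised,
    evaluated iteratively to avoid recursion limits) with the Euclidean
    ground metric: the minimum over monotone couplings of the maximum
    pointwise distance.
    """
    p = np.asarray(t1, dtype=float)
    q = np.asarray(t2, dtype=float)
    if p.ndim != 2 or q.ndim != 2 or len(p) < 1 or len(q) < 1:
        raise ValueError("trajectories must be non-empty arrays of points")
    d = np.sqrt(((p[:, None, :] - q[None, :, :]) ** 2).sum(axis=2))
    n, m = d.shape
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        for j in range(1, m):
            ca[i, j] = max(min(ca[i - 1, j], ca[i - 1, j - 1], ca[i, j - 1]),
                           d[i, j])
    return float(ca[-1, -1])


def similarity_regression(responses: np.ndarray,
                          trajectories: list[np.ndarray]) -> dict:
    """Slope of next-trial movement dissimilarity on dopamine response.

    Regresses the Frechet distance between each trial's trajectory and the
    next trial's on the current trial's dopamine response: a negative slope
    means larger dopamine predicts a more similar (repeated) movement.
    """
    responses = np.asarray(responses, dtype=float)
    if len(trajectories) != len(responses):
        raise ValueError("need one trajectory per response")
    if len(responses) < 3:
        raise ValueError("need at least 3 consecutive trials")
    dists = np.array([frechet_distance(trajectories[i], trajectories[i + 1])
                      for i in range(len(trajectories) - 1)])
    x = responses[:-1]
    if dists.std() == 0:
        return {"slope": 0.0, "intercept": float(dists.mean()), "r2": 1.0}
    X = sm.add_constant(x)
    fit = sm.OLS(dists, X).fit()
    return {"slope": float(fit.params[1]), "intercept": float(fit.params[0]),
            "r2": float(fit.rsquared)}


# ---------------------------------------------------------------------------
# residual trend regression
# ---------------------------------------------------------------------------

def residual_trend_regression(responses: np.ndarray, speed: np.ndarray,
                              turn_angle: np.ndarray,
                              trial_number: np.ndarray | None = None) -> dict:
    """Does a trial-number trend survive after removing kinematics?

    First regresses the dopamine response on speed and turn angle, then
    regresses the residuals on log trial number; also fits the
    three-predictor model and reports each predictor's share of explained
    variance (drop in R-squared when the predictor's fitted contribution is
    removed). Collinear kinematic designs fall back to the least-norm
    solution with a logged warning.
    """
    y = np.asarray(responses, dtype=float)
    n = len(y)
    if trial_number is None:
        trial_number = np.arange(1, n + 1, dtype=float)
    logt = np.log(np.asarray(trial_number, dtype=float))
    M = np.column_stack([np.ones(n), speed, turn_angle])
    coef, _, rank, _ = np.linalg.lstsq(M, y, rcond=None)
    if rank < M.shape[1]:
        logger.warning("collinear kinematic design; least-norm solution used")
    resid = y - M @ coef
    X = sm.add_constant(logt)
    trend = sm.OLS(resid, X).fit()

    full = np.column_stack([np.ones(n), speed, turn_angle, logt])
    cf, _, _, _ = np.linalg.lstsq(full, y, rcond=None)
    pred_full = full @ cf
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2_full = 1.0 - np.sum((y - pred_full) ** 2) / ss_tot if ss_tot > 0 else 0.0
    shares = {}
    for name, col in (("speed", 1), ("turn_angle", 2), ("log_trial", 3)):
        pred_wo = pred_full - full[:, col] * cf[col]
        r2_wo = 1.0 - np.sum((y - pred_wo) ** 2) / ss_tot if ss_tot > 0 else 0.0
        shares[name] = float(r2_full - r2_wo)
    movement_r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 0.0
    return {
        "residual_slope": float(trend.params[1]),
        "residual_slope_p": float(trend.pvalues[1]),
        "movement_r2": float(movement_r2),
        "full_r2": float(r2_full),
        "variance_shares": shares,
    }
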