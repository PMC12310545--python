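"""Semi-Markov actor-critic agent with candidate dopamine signal models.

The agent represents a trial of the cloud-of-tones task as a small chain of
states (Start -> cue -> action-state -> Outcome -> Start) and updates its
estimates only at state transitions, tracking the dwell time spent in each
state. The reward prediction error at transition ``k`` is the average-reward
(dwell-time-scaled) form

    delta_k = r_{k+1} - rho_k * d_k + V(s_{k+1}) - V(s_k)

where ``rho_k`` is the average reward per unit time over the trailing window
of transitions. The broadcast dopamine-like RPE signal is the rectified
``max(0, delta_k + psi)`` with a baseline constant ``psi``.

Alongside the value-based system, a value-free learner maintains
stimulus-action association strengths ``A(s)`` and emits an action
prediction error (APE) at the time of choice: the one-hot action minus the
association vector, rectified so that only the taken action's (positive)
component survives. Novelty (exponentially decaying in visit count),
salience (value/novelty mix) and a pure movement signal (the one-hot action
itself) complete the set of candidate signals compared against photometry.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from apesim.cot_task import (
    CONTRA_SIDE,
    SessionLog,
    TaskConfig,
    TrialRecord,
    _apply_outcome,
    _draw_stimulus,
    correct_side_for,
)

ACTIONS = ("left", "right", "centre", "idle")
ACTION_INDEX = {a: i for i, a in enumerate(ACTIONS)}
CHOICE_ACTIONS = ("left", "right")

#: cue state reached for a mostly-high stimulus (contralateral cue)
CONTRA_CUE = "high"

#: reward magnitude (dimensionless) per delivered volume in microlitres
REWARD_SCALE = {0.0: 0.0, 2.0: 1.0, 6.0: 3.0}


@dataclass
class AgentParams:
    """Learning rates and constants of the candidate-signal models.

    ``alpha``/``beta`` are the critic/actor rates, ``epsilon`` the
    stimulus-action (value-free) rate (0.001 for the predicted-value
    simulation), ``psi`` the baseline dopamine constant added before
    rectification, ``gamma`` the novelty decay rate, ``mu`` the value weight
    in salience, and ``rho_window`` the number of past transitions used for
    the average reward.
    """

    alpha: float = 0.005
    beta: float = 0.005
    epsilon: float = 0.01
    psi: float = 0.2
    gamma: float = 0.01
    mu: float = 0.5
    inverse_temperature: float = 5.0
    rho_window: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "epsilon", "gamma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.inverse_temperature < 0:
            raise ValueError("inverse_temperature must be >= 0")
        if self.rho_window < 1:
            raise ValueError("rho_window must be >= 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class AgentState:
    """Mutable learned quantities: values, actor and stimulus-action
    strengths, visit counts, and the (reward, dwell) history for rho."""

    V: dict = field(default_factory=dict)                 # state -> value
    m: dict = field(default_factory=dict)                 # state -> actor strengths (len 4)
    A: dict = field(default_factory=dict)                 # state -> assoc strengths (len 4)
    I: dict = field(default_factory=dict)                 # state -> visit count
    history: deque = field(default_factory=deque)         # (reward, dwell) pairs

    def value(self, s) -> float:
        return self.V.get(s, 0.0)

    def actor(self, s) -> np.ndarray:
        if s not in self.m:
            self.m[s] = np.zeros(len(ACTIONS))
        return self.m[s]

    def assoc(self, s) -> np.ndarray:
        if s not in self.A:
            self.A[s] = np.zeros(len(ACTIONS))
        return self.A[s]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def average_reward(history: Sequence[tuple[float, float]],
                   window: int | None = None) -> float:
    """Average reward per unit time over the trailing ``window`` transitions.

    Returns 0 for an empty history (a fresh agent has no reward estimate).
    Before ``window`` transitions have elapsed, all available history is
    used (growing window).
    """
    items = list(history)
    if window is not None:
        items = items[-window:]
    if not items:
        return 0.0
    total_dwell = sum(d for _, d in items)
    if total_dwell <= 0:
        return 0.0
    return sum(r for r, _ in items) / total_dwell


def compute_rpe(reward: float, dwell: float, v_from: float, v_to: float,
                rho: float) -> float:
    """Dwell-time-scaled average-reward prediction error (pure function)."""
    return reward - rho * dwell + v_to - v_from


def rpe_output(delta: float, psi: float = 0.2) -> float:
    """Rectified dopamine-like RPE signal: max(0, delta + psi)."""
    return max(0.0, delta + psi)


def compute_ape(action: str, assoc: np.ndarray) -> tuple[np.ndarray, float]:
    """Action prediction error for a taken action.

    The raw vector is the one-hot action minus the association strengths;
    rectification keeps only the taken-action component, and only if it is
    positive (dips are never emitted). Returns (rectified vector, scalar).
    """
    a_vec = np.zeros(len(ACTIONS))
    a_vec[ACTION_INDEX[action]] = 1.0
    raw = a_vec - assoc
    rect = np.zeros_like(raw)
    idx = ACTION_INDEX[action]
    if raw[idx] > 0:
        rect[idx] = raw[idx]
    return rect, float(rect[idx])


def novelty(visit_count: int, gamma: float) -> float:
    """Novelty decays exponentially with exposure: exp(-gamma * I(s))."""
    return float(np.exp(-gamma * visit_count))


def salience(value: float, nov: float, mu: float) -> float:
    """Weighted combination of state value and novelty: V/mu + N."""
    return value / mu + nov


def softmax_probabilities(strengths: np.ndarray, inverse_temperature: float) -> np.ndarray:
    z = inverse_temperature * np.asarray(strengths, dtype=float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


# ---------------------------------------------------------------------------
# the agent
# ---------------------------------------------------------------------------

class SemiMarkovAgent:
    """Actor-critic learner over trial-stage states with a parallel
    value-free stimulus-action learner; emits all five candidate signals at
    every state transition."""

    def __init__(self, params: AgentParams, rng: np.random.Generator | None = None):
        self.params = params
        self.state = AgentState()
        self.rng = rng if rng is not None else np.random.default_rng(params.seed)

    # -- policy ------------------------------------------------------------
    def choose(self, cue_state) -> str:
        """Softmax over actor strengths of the two side choices."""
        m = self.state.actor(cue_state)
        idx = [ACTION_INDEX[a] for a in CHOICE_ACTIONS]
        p = softmax_probabilities(m[idx], self.params.inverse_temperature)
        return CHOICE_ACTIONS[self.rng.choice(len(CHOICE_ACTIONS), p=p)]

    # -- one transition ----------------------------------------------------
    def transition(self, s_from, s_to, action: str, reward: float,
                   dwell: float) -> dict:
        """Process one state transition and return the signal sample.

        Order of operations: the average reward is computed from past
        transitions only, the RPE uses the current values, then the critic,
        actor and stimulus-action strengths are updated and the (reward,
        dwell) pair joins the history.
        """
        if dwell <= 0:
            raise ValueError("dwell time must be positive")
        p = self.params
        st = self.state

        rho = average_reward(st.history)
        delta = compute_rpe(reward, dwell, st.value(s_from), st.value(s_to), rho)
        signal = rpe_output(delta, p.psi)

        # critic / actor updates (only the visited state / taken pair move)
        st.V[s_from] = st.value(s_from) + p.alpha * delta
        st.actor(s_from)[ACTION_INDEX[action]] += p.beta * delta

        # value-free learner: only at choice transitions
        ape_scalar = 0.0
        if action in CHOICE_ACTIONS:
            assoc = st.assoc(s_from)
            rect, ape_scalar = compute_ape(action, assoc)
            assoc += p.epsilon * rect

        # novelty / salience of the state being entered
        st.I[s_to] = st.I.get(s_to, 0) + 1
        nov = novelty(st.I[s_to], p.gamma)
        sal = salience(st.value(s_to), nov, p.mu)

        movement = np.zeros(len(ACTIONS))
        if action != "idle":
            movement[ACTION_INDEX[action]] = 1.0

        st.history.append((reward, dwell))
        while len(st.history) > p.rho_window:
            st.history.popleft()

        return {
            "state_from": _state_label(s_from),
            "state_to": _state_label(s_to),
            "action": action,
            "dwell": dwell,
            "reward": reward,
            "rho": rho,
            "delta_rpe_raw": delta,
            "rpe_signal": signal,
            "delta_ape": ape_scalar,
            "novelty": nov,
            "salience": sal,
            "movement_left": movement[0],
            "movement_right": movement[1],
            "movement_centre": movement[2],
            "movement_idle": movement[3],
        }


def _state_label(s) -> str:
    if isinstance(s, tuple):
        return ":".join(str(x) for x in s)
    return str(s)


# ---------------------------------------------------------------------------
# full simulations
# ---------------------------------------------------------------------------

def _cue_state_for(p_high: float, flags: frozenset) -> str:
    if "white_noise_cue" in flags:
        return "white_noise"
    if "silence" in flags:
        return "silence"
    return "high" if p_high > 0.5 else "low"


def simulate_agent_session(config: TaskConfig, params: AgentParams,
                           n_trials: int,
                           rng: np.random.Generator) -> tuple[pd.DataFrame, SessionLog]:
    """Run one agent through one session, recording every transition.

    Each trial contributes four transitions: trial initiation (Start ->
    cue, action Centre), choice (cue -> action-state, action Left/Right;
    APE is emitted here), port entry (action-state -> Outcome; the scaled
    reward arrives here), and return (Outcome -> Start). Dwell times come
    from the task's event-time model, so the trace is aligned to the same
    clock as the trial log.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    agent = SemiMarkovAgent(params, rng=rng)
    rows: list[dict] = []
    trials: list[TrialRecord] = []
    t = 0.0
    prev_outcome_exit = 0.0
    for i in range(n_trials):
        p_high = _draw_stimulus(config, trials, rng)
        correct = correct_side_for(p_high)
        flags: set[str] = set()
        if config.variant == "state_change" and i >= config.switch_trial \
                and correct == CONTRA_SIDE:
            flags.add("white_noise_cue")
        if config.variant == "silence" and correct == CONTRA_SIDE \
                and rng.random() < config.silence_prob:
            flags.add("silence")

        cue = _cue_state_for(p_high, frozenset(flags))

        dw = config.dwell
        t_start = t
        t_cue_on = t_start + rng.uniform(0.0, 0.05)
        hold = rng.uniform(*config.hold_time)
        t_center_out = t_cue_on + hold + 1e-4
        movement = rng.lognormal(np.log(dw.movement_median_s), dw.movement_sigma)
        t_side_in = t_center_out + movement
        t_outcome = t_side_in + 0.05
        return_dwell = rng.lognormal(np.log(dw.return_median_s), dw.return_sigma)
        iti = dw.outcome_dwell_s + return_dwell

        start_dwell = max(t_cue_on - prev_outcome_exit, 0.05) if i > 0 else 1.0

        # 1) trial initiation: Start -> cue
        row = agent.transition("start", cue, "centre", 0.0, start_dwell)
        row.update(trial_idx=i, event="cue", time=t_cue_on)
        rows.append(row)

        # 2) choice at the cue state
        choice = agent.choose(cue)
        rewarded, reward_ul, extra = _apply_outcome(config, i, choice, correct, rng)
        flags |= extra
        action_state = ("action", cue, choice)
        cue_dwell = t_center_out - t_cue_on
        row = agent.transition(cue, action_state, choice, 0.0, cue_dwell)
        row.update(trial_idx=i, event="choice", time=t_center_out)
        rows.append(row)

        # 3) port entry: action-state -> Outcome, scaled reward delivered
        r = REWARD_SCALE[reward_ul]
        row = agent.transition(action_state, "outcome", "idle", r, movement)
        row.update(trial_idx=i, event="outcome", time=t_outcome)
        rows.append(row)

        # 4) return to Start
        row = agent.transition("outcome", "start", "idle", 0.0, dw.outcome_dwell_s)
        row.update(trial_idx=i, event="return", time=t_outcome + dw.outcome_dwell_s)
        rows.append(row)

        prev_outcome_exit = t_outcome + dw.outcome_dwell_s
        t = t_outcome + iti

        trials.append(TrialRecord(
            trial_idx=i, session_idx=0, p_high=p_high, correct_side=correct,
            choice=choice, rewarded=rewarded, reward_ul=reward_ul,
            t_trial_start=t_start, t_cue_on=t_cue_on, t_center_out=t_center_out,
            t_side_in=t_side_in, t_outcome=t_outcome,
            inter_trial_interval=iti, flags=frozenset(flags),
        ))

    trace = pd.DataFrame(rows)
    return trace, SessionLog(trials, config)


def simulate_learning(config: TaskConfig, params: AgentParams, n_trials: int,
                      n_agents: int, seed: int) -> list[tuple[pd.DataFrame, SessionLog]]:
    """Simulate a cohort of agents (one RNG per agent, seeded seed+i)."""
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    out = []
    for i in range(n_agents):
        rng = np.random.default_rng(seed + i)
        out.append(simulate_agent_session(config, params, n_trials, rng))
    return out


# ---------------------------------------------------------------------------
# condition battery: predicted direction of change per candidate model
# ---------------------------------------------------------------------------

SIGNAL_COLUMNS = {
    "APE": "delta_ape",
    "RPE": "rpe_signal",
    "novelty": "novelty",
    "salience": "salience",
    "movement": "movement_right",
}

#: event at which each candidate signal is read out
SIGNAL_EVENT = {
    "APE": "choice",
    "RPE": "cue",
    "novelty": "cue",
    "salience": "cue",
    "movement": "choice",
}


def _contra_correct(trace: pd.DataFrame, session: SessionLog, event: str) -> pd.DataFrame:
    df = session.to_frame()
    keep = df.loc[(df.choice == CONTRA_SIDE) & (df.choice == df.correct_side),
                  "trial_idx"]
    sub = trace[(trace.event == event) & (trace.trial_idx.isin(set(keep)))]
    return sub


def _mean_signal(traces, model: str, trial_filter) -> float:
    col = SIGNAL_COLUMNS[model]
    event = SIGNAL_EVENT[model]
    vals = []
    for trace, session in traces:
        sub = _contra_correct(trace, session, event)
        sub = trial_filter(sub, session)
        if len(sub):
            vals.append(sub[col].mean())
    return float(np.mean(vals)) if vals else np.nan


def condition_battery(params: AgentParams | None = None, n_agents: int = 20,
                      n_trials: int = 400, seed: int = 0,
                      noise_floor: float = 0.02) -> pd.DataFrame:
    """Predicted sign of change of each candidate signal per manipulation.

    Runs the standard, state-change, outcome-value and predicted-value
    simulations plus an exploratory (low inverse temperature) run, and
    reports ``+``, ``-`` or ``0`` for the mean change of each model's signal
    under each manipulation. Changes smaller than ``noise_floor`` (in signal
    units) count as 0.
    """
    params = params or AgentParams()
    models = list(SIGNAL_COLUMNS)
    result: dict[str, dict[str, str]] = {m: {} for m in models}

    def sign(x: float) -> str:
        if not np.isfinite(x) or abs(x) < noise_floor:
            return "0"
        return "+" if x > 0 else "-"

    # learning: last decile vs first decile of the standard task
    traces = simulate_learning(TaskConfig("standard"), params, n_trials, n_agents, seed)
    dec = max(n_trials // 10, 1)
    for m in models:
        early = _mean_signal(traces, m, lambda s, _: s[s.trial_idx < dec])
        late = _mean_signal(traces, m, lambda s, _: s[s.trial_idx >= n_trials - dec])
        result[m]["learning"] = sign(late - early)

    # previous choice: repeat vs switch under an exploratory policy
    explore = AgentParams(**{**asdict(params), "inverse_temperature": 0.5})
    traces = simulate_learning(TaskConfig("standard"), explore, n_trials, n_agents,
                               seed + 1000)
    for m in models:
        diffs = []
        for trace, session in traces:
            rep, swi = _repeat_switch_means(trace, session, m)
            if np.isfinite(rep) and np.isfinite(swi):
                diffs.append(rep - swi)
        result[m]["previous_choice"] = sign(float(np.mean(diffs)) if diffs else np.nan)

    # state change at the configured switch trial
    cfg = TaskConfig("state_change")
    traces = simulate_learning(cfg, params, cfg.switch_trial + 50, n_agents, seed + 2000)
    for m in models:
        pre = _mean_signal(traces, m,
                           lambda s, _: s[s.trial_idx.between(cfg.switch_trial - 50,
                                                              cfg.switch_trial - 1)])
        post = _mean_signal(traces, m,
                            lambda s, _: s[s.trial_idx >= cfg.switch_trial])
        result[m]["state_change"] = sign(post - pre)

    # outcome value: large reward vs standard, read at each model's event;
    # the learning trend (shared by both randomly assigned groups) is
    # removed by residualising on 50-trial bins before comparing
    traces = simulate_learning(TaskConfig("outcome_value"), params, n_trials,
                               n_agents, seed + 3000)
    for m in models:
        col, event = SIGNAL_COLUMNS[m], SIGNAL_EVENT[m]
        if m == "RPE":
            event = "outcome"
        diffs = []
        for trace, session in traces:
            df = session.to_frame()
            ok = df[(df.choice == df.correct_side) & (df.choice == CONTRA_SIDE)]
            lg = set(ok.loc[ok.reward_ul == 6.0, "trial_idx"])
            st = set(ok.loc[ok.reward_ul == 2.0, "trial_idx"])
            ev = trace[(trace.event == event)
                       & trace.trial_idx.isin(lg | st)].copy()
            if not (lg and st):
                continue
            ev["bin"] = ev.trial_idx // 50
            resid = ev[col] - ev.groupby("bin")[col].transform("mean")
            diffs.append(resid[ev.trial_idx.isin(lg)].mean()
                         - resid[ev.trial_idx.isin(st)].mean())
        result[m]["outcome_value"] = sign(float(np.mean(diffs)) if diffs else np.nan)

    # predicted value: slow value-free learner, post- vs pre-switch
    slow = AgentParams(**{**asdict(params), "epsilon": 0.001})
    cfg = TaskConfig("predicted_value")
    traces = simulate_learning(cfg, slow, cfg.switch_trial + 100, n_agents, seed + 4000)
    for m in models:
        pre = _mean_signal(traces, m, lambda s, _: s[s.trial_idx < cfg.switch_trial])
        post = _mean_signal(traces, m, lambda s, _: s[s.trial_idx >= cfg.switch_trial])
        result[m]["predicted_value"] = sign(post - pre)

    return pd.DataFrame(result).T


def _repeat_switch_means(trace: pd.DataFrame, session: SessionLog,
                         model: str) -> tuple[float, float]:
    """Mean signal on trials whose previous same-stimulus trial had the same
    (repeat) vs the other (switch) choice; contralateral choices only."""
    col, event = SIGNAL_COLUMNS[model], SIGNAL_EVENT[model]
    df = session.to_frame()
    ev = trace[trace.event == event].set_index("trial_idx")
    last_choice: dict[float, str] = {}
    rep_vals, swi_vals = [], []
    for _, row in df.iterrows():
        stim = row.p_high
        prev = last_choice.get(stim)
        if prev is not None and row.choice == CONTRA_SIDE and row.trial_idx in ev.index:
            v = ev.loc[row.trial_idx, col]
            (rep_vals if row.choice == prev else swi_vals).append(v)
        last_choice[stim] = row.choice
    rep = float(np.mean(rep_vals)) if rep_vals else np.nan
    swi = float(np.mean(swi_vals)) if swi_vals else np.nan
    return rep, swi


def save_traces(traces, path_prefix: str | Path, params: AgentParams) -> None:
    """Write per-agent transition traces as CSV plus a JSON parameter file."""
    path_prefix = Path(path_prefix)
    for i, (trace, session) in enumerate(traces):
        trace.to_csv(f"{path_prefix}_agent{i}_trace.csv", index=False)
        session.to_csv(f"{path_prefix}_agent{i}_trials.csv", config_sidecar=False)
    Path(f"{path_prefix}_params.json").write_text(params.to_json())
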