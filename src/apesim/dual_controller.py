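"""Dual value-based / value-free controller network of habit formation.

A two-state, two-action network in which an actor-critic system learning
from reward prediction errors (the value-based controller) acts in parallel
with a tail-of-striatum-like system learning from action prediction errors
(the value-free controller). On each trial a sensory state vector ``s``
drives both weight matrices; their outputs plus per-action uniform noise
are summed and the maximal component is the action taken:

    A_total = W_actor s + W_tail s + noise,     a = argmax(A_total)

Reward follows the identity contingency (state 1 -> action 1, state 2 ->
action 2). The RPE is ``r - W_critic s``; the APE is ``1 - p_a[a]`` where
``p_a`` low-pass filters (time constant tau_tail) the binarised output of
the tail controller. Three-factor rules update the actor and tail weights
with their respective errors; the critic uses a two-factor rule; the actor
additionally relaxes toward its steady-state value of 1 with time constant
tau_decay, which transfers control to the value-free pathway over training.

One simulation time unit corresponds to one trial for all leaky dynamics
(predicted-action filter, actor decay, performance readout), integrated by
forward Euler with dt = 1; ``steps_per_trial`` exposes finer integration of
the purely relaxational terms if desired.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Literal

import numpy as np
import pandas as pd

EXPERIMENT_KINDS = ("learning", "lesion", "psychometric", "stimulation",
                    "value_free_only", "value_based_only")


@dataclass
class NetworkParams:
    alpha: float = 0.04            # RPE (actor/critic) learning rate
    beta: float = 0.02             # APE (tail) learning rate
    tau_tail: float = 100.0        # predicted-action filter time constant
    tau_decay: float = 100.0       # actor relaxation time constant
    perf_tau: float = 10.0         # performance readout filter
    perf_init: float = 0.5
    n_trials: int = 100
    steps_per_trial: int = 1       # Euler sub-steps for the leaky terms
    lesion: Literal["none", "tail", "actor"] = "none"
    lesion_time: int | None = None
    stimulation: Literal["none", "double_ape_contra"] = "none"
    contra_state: int = 1          # state index whose trials are stimulated
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tau_tail", "tau_decay", "perf_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("alpha", "beta"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class NetworkState:
    W_actor: np.ndarray = field(default_factory=lambda: np.ones((2, 2)))
    W_tail: np.ndarray = field(default_factory=lambda: np.ones((2, 2)))
    W_critic: np.ndarray = field(default_factory=lambda: np.zeros(2))
    p_a: np.ndarray = field(default_factory=lambda: np.zeros(2))
    clock: int = 0


def reward_rule(s: np.ndarray, a: int) -> float:
    """r = 1 when the action index matches the (dominant) state index."""
    s = np.asarray(s, dtype=float)
    return 1.0 if a == int(np.argmax(s)) else 0.0


def forward(s: np.ndarray, state: NetworkState,
            rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Compute total action drive and pick the maximal action.

    Noise is drawn independently per action component from U(0, 1); exact
    ties (measure zero) break toward the lower index.
    """
    s = np.asarray(s, dtype=float)
    if s.shape != (2,) or np.any(s < 0):
        raise ValueError("state must be a length-2 non-negative vector")
    a_actor = state.W_actor @ s
    a_tail = state.W_tail @ s
    noise = rng.uniform(0.0, 1.0, size=2)
    a_total = a_actor + a_tail + noise
    return a_total, int(np.argmax(a_total))


def compute_network_ape(a: int, s: np.ndarray, state: NetworkState,
                        params: NetworkParams) -> float:
    """APE of the taken action, then advance the predicted-action filter.

    The tail controller's instantaneous output is binarised (1 at its argmax
    drive, 0 elsewhere) and low-pass filtered into the predicted action
    ``p_a``; the APE is ``1 - p_a[a]`` evaluated *before* the filter step so
    a first-ever action yields an APE of exactly 1.
    """
    s = np.asarray(s, dtype=float)
    a_tail = state.W_tail @ s
    binary = np.zeros(2)
    binary[int(np.argmax(a_tail))] = 1.0
    delta_ape = 1.0 - state.p_a[a]
    dt = 1.0 / params.steps_per_trial
    for _ in range(params.steps_per_trial):
        state.p_a = state.p_a + dt * (-state.p_a + binary) / params.tau_tail
    return float(delta_ape)


def update_network(state: NetworkState, s: np.ndarray, a: int, r: float,
                   delta_ape: float, params: NetworkParams,
                   tail_plastic: bool = True, actor_plastic: bool = True) -> float:
    """Apply the three-factor (actor, tail) and two-factor (critic) updates
    plus actor decay and non-negativity clipping. Returns delta_RPE."""
    s = np.asarray(s, dtype=float)
    a_vec = np.zeros(2)
    a_vec[a] = 1.0
    delta_rpe = r - float(state.W_critic @ s)
    if tail_plastic:
        state.W_tail = state.W_tail + params.beta * delta_ape * np.outer(a_vec, s)
    if actor_plastic:
        state.W_actor = state.W_actor + params.alpha * delta_rpe * np.outer(a_vec, s)
        state.W_critic = state.W_critic + params.alpha * delta_rpe * s
        dt = 1.0 / params.steps_per_trial
        for _ in range(params.steps_per_trial):
            state.W_actor = state.W_actor + dt * (1.0 - state.W_actor) / params.tau_decay
    state.W_actor = np.clip(state.W_actor, 0.0, None)
    state.W_tail = np.clip(state.W_tail, 0.0, None)
    state.W_critic = np.clip(state.W_critic, 0.0, None)
    return float(delta_rpe)


class DualControllerNetwork:
    """One simulated agent: state, parameters and the per-trial loop."""

    def __init__(self, params: NetworkParams, rng: np.random.Generator | None = None):
        self.params = params
        self.state = NetworkState()
        self.rng = rng if rng is not None else np.random.default_rng(params.seed)
        self.perf = params.perf_init
        self._tail_plastic = True
        self._actor_plastic = True

    def clamp(self, which: str) -> None:
        """Zero and freeze one controller ('tail' or 'actor')."""
        if which == "tail":
            self.state.W_tail = np.zeros((2, 2))
            self._tail_plastic = False
        elif which == "actor":
            self.state.W_actor = np.zeros((2, 2))
            self.state.W_critic = np.zeros(2)
            self._actor_plastic = False
        else:
            raise ValueError(f"unknown controller {which!r}")

    def step(self, s: np.ndarray) -> dict:
        p = self.params
        st = self.state
        a_total, a = forward(s, st, self.rng)
        r = reward_rule(s, a)
        delta_ape = compute_network_ape(a, s, st, p)
        if p.stimulation == "double_ape_contra" and int(np.argmax(s)) == p.contra_state:
            delta_ape = 2.0 * delta_ape
        delta_rpe = update_network(st, s, a, r, delta_ape, p,
                                   tail_plastic=self._tail_plastic,
                                   actor_plastic=self._actor_plastic)
        self.perf = self.perf + (r - self.perf) / p.perf_tau
        st.clock += 1
        return {
            "trial": st.clock - 1,
            "s": int(np.argmax(s)),
            "s1": float(np.asarray(s, dtype=float)[1]),
            "a": a,
            "r": r,
            "delta_rpe": delta_rpe,
            "delta_ape": delta_ape,
            "performance": self.perf,
            "w_actor_00": st.W_actor[0, 0], "w_actor_01": st.W_actor[0, 1],
            "w_actor_10": st.W_actor[1, 0], "w_actor_11": st.W_actor[1, 1],
            "w_tail_00": st.W_tail[0, 0], "w_tail_01": st.W_tail[0, 1],
            "w_tail_10": st.W_tail[1, 0], "w_tail_11": st.W_tail[1, 1],
            "w_critic_0": st.W_critic[0], "w_critic_1": st.W_critic[1],
        }

    def run(self, n_trials: int | None = None, difficulty: float | None = None,
            difficulty_levels: np.ndarray | None = None) -> pd.DataFrame:
        """Run trials with random one-hot or graded states.

        With ``difficulty`` d fixed, the state is (1-d, d) on every trial;
        with ``difficulty_levels`` a level is drawn uniformly per trial
        (the psychometric stimulus protocol); otherwise states alternate
        randomly between the two one-hot inputs.
        """
        n = n_trials if n_trials is not None else self.params.n_trials
        if n < 1:
            raise ValueError("n_trials must be >= 1")
        rows = []
        for i in range(n):
            if self.params.lesion != "none" and self.params.lesion_time is not None \
                    and self.state.clock == self.params.lesion_time:
                self.clamp(self.params.lesion)
            if difficulty is not None:
                s = np.array([1.0 - difficulty, difficulty])
            elif difficulty_levels is not None:
                d = float(self.rng.choice(difficulty_levels))
                s = np.array([1.0 - d, d])
            else:
                idx = int(self.rng.integers(0, 2))
                s = np.zeros(2)
                s[idx] = 1.0
            rows.append(self.step(s))
        return pd.DataFrame(rows)


def run_experiment(kind: str, params: NetworkParams | None = None,
                   n_agents: int = 1, seed: int = 0,
                   difficulties: np.ndarray | None = None) -> pd.DataFrame:
    """Run one of the named experiment protocols over a cohort of agents.

    ``learning`` runs the full model; ``value_free_only`` /
    ``value_based_only`` clamp the other controller at zero from trial 0;
    ``lesion`` zeroes and freezes the named controller at ``lesion_time``;
    ``stimulation`` doubles the APE on contralateral-stimulus trials;
    ``psychometric`` sweeps the difficulty d with states (1-d, d) and
    reports choice proportions. Results concatenate per-agent trial rows
    (an ``agent`` column distinguishes them).
    """
    if kind not in EXPERIMENT_KINDS:
        raise ValueError(f"unknown experiment kind {kind!r}")
    params = params or NetworkParams()

    if kind == "psychometric":
        difficulties = difficulties if difficulties is not None \
            else np.linspace(0.0, 1.0, 11)
        rows = []
        for i in range(n_agents):
            for d in difficulties:
                net = DualControllerNetwork(params, np.random.default_rng(seed + i))
                df = net.run(params.n_trials, difficulty=float(d))
                rows.append({
                    "agent": i, "difficulty": float(d),
                    "prop_action_1": float((df.a == 1).mean()),
                    "mean_performance": float(df.performance.mean()),
                })
        return pd.DataFrame(rows)

    frames = []
    for i in range(n_agents):
        p = params if kind != "stimulation" else replace(params,
                                                         stimulation="double_ape_contra")
        net = DualControllerNetwork(p, np.random.default_rng(seed + i))
        if kind == "value_free_only":
            net.clamp("actor")
        elif kind == "value_based_only":
            net.clamp("tail")
        df = net.run(p.n_trials)
        df["agent"] = i
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def trials_to_criterion(perf: np.ndarray, criterion: float = 0.75,
                        sustained: bool = False) -> int:
    """Trials until the filtered performance reaches the criterion.

    With ``sustained=False`` (default) this is the first crossing. With
    ``sustained=True`` it is the trial from which performance reaches and
    *stays at* criterion for the rest of the run — the usual behavioural
    notion of criterion attainment, robust to transient crossings followed
    by regression. Returns one past the end if never attained.
    """
    p = np.asarray(perf)
    if sustained:
        below = np.nonzero(p < criterion)[0]
        if len(below) == 0:
            return 0
        return int(below[-1]) + 1 if below[-1] + 1 < len(p) else len(p)
    idx = np.nonzero(p >= criterion)[0]
    return int(idx[0]) if len(idx) else len(p)


def post_lesion_performance(df: pd.DataFrame, lesion_time: int,
                            n_after: int = 10, column: str = "performance") -> float:
    """Mean performance over the ``n_after`` trials following the lesion.

    Uses the low-pass-filtered performance readout by default; pass
    ``column="r"`` for the raw per-trial reward instead.
    """
    window = df[(df.trial >= lesion_time) & (df.trial < lesion_time + n_after)]
    return float(window[column].mean())
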