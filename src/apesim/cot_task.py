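"""Cloud-of-tones (COT) two-alternative choice task simulator.

The COT task is a self-initiated auditory discrimination: the animal pokes a
centre port, hears a 500 ms stream of 30 ms pure tones drawn from a low
(5-10 kHz) or high (20-40 kHz) octave, and reports whether the stream was
mostly low or mostly high by poking a left or right port. A correct choice
delivers a small water reward. The simulator reproduces the trial structure
as a semi-Markov environment (continuous event times, no frame clock) and
all task variants used in the photometry experiments: psychometric stimulus
sets, silence probes, a mid-session state change to a white-noise cue,
unexpected large rewards and omissions, a predicted-value change of one
port, and the sound-on-return variant.

Conventions: the recorded hemisphere is taken to be the left one, so the
*contralateral* side is ``right`` and the contralateral cue is the
high-octave stimulus. All event times are seconds from session start.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

SIDES = ("left", "right")
#: side contralateral to the (left) recording hemisphere
CONTRA_SIDE = "right"

REWARD_UL_STANDARD = 2.0
REWARD_UL_LARGE = 6.0

VARIANTS = (
    "standard",
    "psychometric",
    "silence",
    "state_change",
    "outcome_value",
    "predicted_value",
    "sound_on_return",
)


# ---------------------------------------------------------------------------
# tone clouds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToneCloudSpec:
    """Parameters of one tone-cloud stimulus.

    Each 10 ms slot of the 100 Hz stream independently contains a tone from
    the high octave with probability ``p_high`` and a tone from the low
    octave with probability ``1 - p_high``; both may sound simultaneously.
    """

    p_high: float = 0.5
    n_slots: int = 50
    low_octave: tuple[float, float] = (5_000.0, 10_000.0)
    high_octave: tuple[float, float] = (20_000.0, 40_000.0)
    n_freqs_per_octave: int = 16
    amplitude_db: tuple[float, float] = (60.0, 80.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_high <= 1.0:
            raise ValueError(f"p_high must lie in [0, 1], got {self.p_high}")
        if self.n_slots < 1:
            raise ValueError("n_slots must be >= 1")
        if self.n_freqs_per_octave < 1:
            raise ValueError("n_freqs_per_octave must be >= 1")


@dataclass(frozen=True)
class ToneCloud:
    """A sampled stimulus: per-slot frequency sets plus overall amplitude."""

    slots: tuple[frozenset, ...]
    has_high: np.ndarray
    has_low: np.ndarray
    amplitude_db: float
    spec: ToneCloudSpec


def _octave_freqs(octave: tuple[float, float], n: int) -> np.ndarray:
    lo, hi = octave
    # clip guards the endpoints against log/exp round-off
    return np.clip(np.logspace(math.log10(lo), math.log10(hi), n), lo, hi)


def sample_tone_cloud(spec: ToneCloudSpec, seed: int | np.random.Generator) -> ToneCloud:
    """Draw one tone cloud.

    Per slot the high/low draws are independent Bernoulli trials, so a slot
    may contain zero, one or two tones; a present tone's frequency is one of
    ``n_freqs_per_octave`` logarithmically spaced frequencies within its
    octave. The overall amplitude is uniform on ``amplitude_db``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    high_freqs = _octave_freqs(spec.high_octave, spec.n_freqs_per_octave)
    low_freqs = _octave_freqs(spec.low_octave, spec.n_freqs_per_octave)

    has_high = rng.random(spec.n_slots) < spec.p_high
    has_low = rng.random(spec.n_slots) < (1.0 - spec.p_high)
    hi_pick = rng.integers(0, spec.n_freqs_per_octave, size=spec.n_slots)
    lo_pick = rng.integers(0, spec.n_freqs_per_octave, size=spec.n_slots)

    slots = []
    for i in range(spec.n_slots):
        tones = set()
        if has_high[i]:
            tones.add(float(high_freqs[hi_pick[i]]))
        if has_low[i]:
            tones.add(float(low_freqs[lo_pick[i]]))
        slots.append(frozenset(tones))

    amp = float(rng.uniform(*spec.amplitude_db))
    return ToneCloud(tuple(slots), has_high, has_low, amp, spec)


# ---------------------------------------------------------------------------
# trial records and task configuration
# ---------------------------------------------------------------------------

@dataclass
class TrialRecord:
    trial_idx: int
    session_idx: int
    p_high: float
    correct_side: str
    choice: str          # "left", "right" or "none"
    rewarded: bool
    reward_ul: float     # 0, 2 or 6
    t_trial_start: float
    t_cue_on: float
    t_center_out: float
    t_side_in: float
    t_outcome: float
    inter_trial_interval: float
    flags: frozenset = field(default_factory=frozenset)

    def event_times(self) -> list[float]:
        return [self.t_trial_start, self.t_cue_on, self.t_center_out,
                self.t_side_in, self.t_outcome]


@dataclass
class DwellConfig:
    """Medians/spreads (log-normal) of the unconstrained dwell periods.

    The centre hold is uniform on the configured 100-300 ms window; movement
    and return durations are log-normal with the stated medians (the 0.68 s
    movement median matches the observed mean choice-movement duration).
    """

    movement_median_s: float = 0.68
    movement_sigma: float = 0.35
    return_median_s: float = 1.5
    return_sigma: float = 0.4
    outcome_dwell_s: float = 0.5


@dataclass
class TaskConfig:
    variant: str = "standard"
    stimulus_set: Sequence[float] | None = None
    switch_trial: int | None = None
    hold_time: tuple[float, float] = (0.1, 0.3)
    cue_duration: float = 0.5
    antibias_enabled: bool = False
    antibias_window: int = 10
    antibias_gain: float = 1.0
    silence_prob: float = 0.2     # fraction of contra-cue trials probed in the silence variant
    opto_prob: float = 0.0        # fraction of trials flagged opto_stim
    big_reward_side: str = CONTRA_SIDE   # port upgraded in the predicted_value variant
    dwell: DwellConfig = field(default_factory=DwellConfig)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.stimulus_set is None:
            if self.variant == "psychometric":
                self.stimulus_set = tuple(np.linspace(0.0, 1.0, 7))
            else:
                self.stimulus_set = (0.98, 0.02)
        self.stimulus_set = tuple(float(p) for p in self.stimulus_set)
        if self.variant == "psychometric":
            if len(self.stimulus_set) != 7:
                raise ValueError("psychometric variant requires exactly 7 stimulus levels")
            diffs = np.diff(sorted(self.stimulus_set))
            if not np.allclose(diffs, diffs[0]):
                raise ValueError("psychometric stimulus levels must be equally spaced")
        if self.switch_trial is None:
            self.switch_trial = 150 if self.variant == "state_change" else 100

    def to_json(self) -> str:
        d = asdict(self)
        d["stimulus_set"] = list(self.stimulus_set)
        return json.dumps(d, indent=2)


class SessionLog:
    """Ordered collection of trial records with CSV round-trip support."""

    def __init__(self, trials: list[TrialRecord], config: TaskConfig | None = None):
        self.trials = trials
        self.config = config

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            d = asdict(t)
            d["flags"] = ";".join(sorted(t.flags))
            rows.append(d)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path, config_sidecar: bool = True) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if config_sidecar and self.config is not None:
            path.with_suffix(".config.json").write_text(self.config.to_json())

    @classmethod
    def from_csv(cls, path: str | Path) -> "SessionLog":
        df = pd.read_csv(path, keep_default_na=False)
        trials = []
        for _, row in df.iterrows():
            d = row.to_dict()
            raw = d.pop("flags", "")
            flags = frozenset(tok for tok in str(raw).split(";") if tok)
            trials.append(TrialRecord(
                trial_idx=int(d["trial_idx"]),
                session_idx=int(d["session_idx"]),
                p_high=float(d["p_high"]),
                correct_side=str(d["correct_side"]),
                choice=str(d["choice"]),
                rewarded=bool(d["rewarded"]) if not isinstance(d["rewarded"], str)
                else d["rewarded"] == "True",
                reward_ul=float(d["reward_ul"]),
                t_trial_start=float(d["t_trial_start"]),
                t_cue_on=float(d["t_cue_on"]),
                t_center_out=float(d["t_center_out"]),
                t_side_in=float(d["t_side_in"]),
                t_outcome=float(d["t_outcome"]),
                inter_trial_interval=float(d["inter_trial_interval"]),
                flags=flags,
            ))
        return cls(trials)


# ---------------------------------------------------------------------------
# session engine
# ---------------------------------------------------------------------------

def correct_side_for(p_high: float) -> str:
    """Mostly-high stimuli are rewarded contralaterally (right)."""
    return CONTRA_SIDE if p_high > 0.5 else ("left" if p_high < 0.5 else CONTRA_SIDE)


def _antibias_target_prob_left(history: list[TrialRecord], window: int, gain: float) -> float:
    """P(target = left) after the anti-bias adjustment.

    The protocol inspects the last ``window`` trials, measures the choice
    bias on *error* trials only, weights it by the error rate and shifts the
    target-port probability against the bias, clipped to [0.1, 0.9]. With no
    recent errors it stays disengaged at 0.5.
    """
    recent = history[-window:]
    if not recent:
        return 0.5
    errors = [t for t in recent if t.choice != "none" and not t.rewarded
              and t.reward_ul == 0.0 and t.choice != t.correct_side]
    if not errors:
        return 0.5
    frac_right = np.mean([t.choice == "right" for t in errors])
    bias_right = frac_right - 0.5              # >0: errors made by going right
    error_rate = len(errors) / len(recent)
    return float(np.clip(0.5 + gain * 2.0 * bias_right * error_rate, 0.1, 0.9))


def _draw_stimulus(config: TaskConfig, history: list[TrialRecord],
                   rng: np.random.Generator) -> float:
    levels = np.asarray(config.stimulus_set)
    if config.antibias_enabled:
        p_left = _antibias_target_prob_left(history, config.antibias_window,
                                            config.antibias_gain)
        left_levels = levels[levels < 0.5]
        right_levels = levels[levels >= 0.5]
        if len(left_levels) and len(right_levels) and rng.random() < p_left:
            return float(rng.choice(left_levels))
        elif len(right_levels):
            return float(rng.choice(right_levels))
    return float(rng.choice(levels))


def _apply_outcome(config: TaskConfig, trial_idx: int, choice: str, correct: str,
                   rng: np.random.Generator) -> tuple[bool, float, set[str]]:
    """Reward contingency for each variant: (rewarded, reward_ul, extra flags)."""
    flags: set[str] = set()
    if choice != correct:
        return False, 0.0, flags
    ul = REWARD_UL_STANDARD
    if config.variant == "outcome_value":
        u = rng.random()
        if u < 0.1:
            flags.add("large_reward")
            ul = REWARD_UL_LARGE
        elif u < 0.2:
            flags.add("omission")
            return False, 0.0, flags
    elif config.variant == "predicted_value" and trial_idx >= config.switch_trial \
            and choice == config.big_reward_side:
        ul = REWARD_UL_LARGE
    return True, ul, flags


def run_session(config: TaskConfig,
                policy: Callable[[float | None, list[TrialRecord]], str],
                n_trials: int,
                seed: int | np.random.Generator) -> SessionLog:
    """Simulate one session under an arbitrary choice policy.

    ``policy(stimulus, history) -> side`` receives the trial's high-tone
    probability (``None`` on silence-probe trials) and the list of completed
    trials, and returns ``"left"`` or ``"right"``. Event times are continuous
    seconds; dwell periods follow :class:`DwellConfig`.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    trials: list[TrialRecord] = []
    t = 0.0
    for i in range(n_trials):
        p_high = _draw_stimulus(config, trials, rng)
        correct = correct_side_for(p_high)
        flags: set[str] = set()

        if config.opto_prob > 0 and rng.random() < config.opto_prob:
            flags.add("opto_stim")
        if config.variant == "state_change" and i >= config.switch_trial \
                and correct == CONTRA_SIDE:
            flags.add("white_noise_cue")
        silent = (config.variant == "silence" and correct == CONTRA_SIDE
                  and rng.random() < config.silence_prob)
        if silent:
            flags.add("silence")
        if config.variant == "sound_on_return":
            flags.add("sound_on_return")

        stim_for_policy = None if silent else p_high
        choice = policy(stim_for_policy, trials)
        if choice not in ("left", "right", "none"):
            raise ValueError(f"policy returned invalid choice {choice!r}")

        rewarded, reward_ul, extra = _apply_outcome(config, i, choice, correct, rng)
        flags |= extra

        dw = config.dwell
        t_start = t
        t_cue_on = t_start + rng.uniform(0.0, 0.05)
        hold = rng.uniform(*config.hold_time)
        t_center_out = t_cue_on + hold + 1e-4
        movement = rng.lognormal(math.log(dw.movement_median_s), dw.movement_sigma)
        t_side_in = t_center_out + movement
        t_outcome = t_side_in + 0.05
        return_dwell = rng.lognormal(math.log(dw.return_median_s), dw.return_sigma)
        iti = dw.outcome_dwell_s + return_dwell
        t = t_outcome + iti

        trials.append(TrialRecord(
            trial_idx=i, session_idx=0, p_high=p_high, correct_side=correct,
            choice=choice, rewarded=rewarded, reward_ul=reward_ul,
            t_trial_start=t_start, t_cue_on=t_cue_on, t_center_out=t_center_out,
            t_side_in=t_side_in, t_outcome=t_outcome,
            inter_trial_interval=iti, flags=frozenset(flags),
        ))
    return SessionLog(trials, config)


# ---------------------------------------------------------------------------
# reference policies
# ---------------------------------------------------------------------------

def always_correct_policy(stimulus: float | None, history: list[TrialRecord]) -> str:
    if stimulus is None:
        return "left"
    return correct_side_for(stimulus)


def make_random_policy(seed: int, p_right: float = 0.5):
    rng = np.random.default_rng(seed)

    def policy(stimulus, history):
        return "right" if rng.random() < p_right else "left"

    return policy
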