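"""Ground-truth synthetic data generators.

Everything the analysis modules consume can be generated here with known
ground truth: raw photometry sessions (event kernels convolved with event
trains, plus double-exponential bleaching, a shared motion artifact with
per-channel gains, white noise, and optional dual-carrier modulation),
behavioural learning cohorts following a modified Weibull curve, and fully
linked datasets (trial log + photometry + kinematics) with planted effect
sizes, so that every downstream estimate has a known expected value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from apesim.behavior_stats import weibull_curve
from apesim.cot_task import CONTRA_SIDE, SessionLog, TaskConfig
from apesim.photometry import CARRIER_FREQS, PhotometrySession
from apesim.semi_markov_agent import AgentParams, simulate_agent_session


@dataclass
class KernelShape:
    """Gamma-shaped response bump: amplitude, latency to onset, width."""

    amplitude: float = 1.0
    latency_s: float = 0.05
    width_s: float = 0.3
    shape: float = 2.0

    def evaluate(self, rate: float, duration_s: float = 2.5) -> np.ndarray:
        t = np.arange(0.0, duration_s, 1.0 / rate)
        tau = np.clip(t - self.latency_s, 0.0, None)
        scale = self.width_s / self.shape
        k = tau ** (self.shape - 1) * np.exp(-tau / scale)
        peak = k.max()
        if peak > 0:
            k = k / peak
        return self.amplitude * k


@dataclass
class SynthConfig:
    sampling_rate: float = 100.0
    session_length_s: float = 300.0
    kernels: dict[str, KernelShape] = field(default_factory=lambda: {
        "cue": KernelShape(amplitude=1.0, latency_s=0.05, width_s=0.25),
        "choice": KernelShape(amplitude=1.5, latency_s=0.1, width_s=0.4),
        "outcome": KernelShape(amplitude=0.8, latency_s=0.05, width_s=0.3),
    })
    bleach_amplitudes: tuple[float, float] = (2.0, 1.0)
    bleach_taus_s: tuple[float, float] = (600.0, 5000.0)
    offset: float = 10.0
    motion_sd: float = 0.3
    motion_cutoff_hz: float = 2.0
    motion_gain_signal: float = 1.0
    motion_gain_background: float = 0.8
    noise_sd: float = 0.05
    modulated: bool = False
    carrier_freqs: tuple[float, float] = CARRIER_FREQS
    seed: int = 0

    def __post_init__(self) -> None:
        min_rate = 2500.0 if self.modulated else 10.0
        if self.sampling_rate < min_rate:
            raise ValueError(
                f"sampling_rate must be >= {min_rate} Hz"
                f"{' when modulation is enabled' if self.modulated else ''}")


@dataclass
class GroundTruth:
    """Everything needed to predict downstream results without re-running."""

    kernels: dict[str, np.ndarray]
    event_times: dict[str, np.ndarray]
    artifact: np.ndarray
    bleach_signal: np.ndarray
    bleach_background: np.ndarray
    transient_amplitudes: dict[str, np.ndarray] = field(default_factory=dict)
    weibull_params: dict | None = None
    planted_coefficients: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        d = {
            "kernels": {k: v.tolist() for k, v in self.kernels.items()},
            "event_times": {k: np.asarray(v).tolist()
                            for k, v in self.event_times.items()},
            "transient_amplitudes": {k: np.asarray(v).tolist()
                                     for k, v in self.transient_amplitudes.items()},
            "weibull_params": self.weibull_params,
            "planted_coefficients": self.planted_coefficients,
        }
        Path(path).write_text(json.dumps(d))


def _bandlimited_noise(n: int, rate: float, cutoff_hz: float, sd: float,
                       rng: np.random.Generator) -> np.ndarray:
    from scipy import signal as sps
    x = rng.standard_normal(n)
    if cutoff_hz < rate / 2:
        sos = sps.butter(2, cutoff_hz, btype="low", fs=rate, output="sos")
        x = sps.sosfiltfilt(sos, x)
    s = x.std()
    return sd * x / s if s > 0 else x


def generate_photometry(events: dict[str, np.ndarray], config: SynthConfig,
                        amplitudes: dict[str, np.ndarray] | None = None
                        ) -> tuple[PhotometrySession, GroundTruth]:
    """Synthesise a two-channel photometry session from known components.

    The signal channel is the sum of event-kernel convolutions (optionally
    with per-event amplitudes, e.g. model APE magnitudes), a
    double-exponential bleaching decay, a shared band-limited motion
    artifact (different gain per channel), an offset and white noise. The
    background channel carries its own bleaching, the same artifact and
    noise, but no event signal — emulating an isosbestic channel. With
    ``config.modulated`` the two channels are returned amplitude-modulated
    onto the two sinusoidal carriers (summed into the signal attribute).
    """
    rng = np.random.default_rng(config.seed)
    rate = config.sampling_rate
    n = int(round(config.session_length_s * rate))
    t = np.arange(n) / rate

    clean = np.zeros(n)
    kern_arrays: dict[str, np.ndarray] = {}
    amps_used: dict[str, np.ndarray] = {}
    for name, times in events.items():
        times = np.asarray(times, dtype=float)
        if len(times) and (times.min() < 0 or times.max() > config.session_length_s):
            raise ValueError(f"event {name!r} outside session span")
        shape = config.kernels.get(name)
        if shape is None:
            continue
        k = shape.evaluate(rate)
        kern_arrays[name] = k
        amp = np.ones(len(times)) if amplitudes is None or name not in amplitudes \
            else np.asarray(amplitudes[name], dtype=float)
        amps_used[name] = amp
        train = np.zeros(n)
        idx = np.round(times * rate).astype(int)
        ok = (idx >= 0) & (idx < n)
        np.add.at(train, idx[ok], amp[ok])
        clean += np.convolve(train, k)[:n]

    a1, a2 = config.bleach_amplitudes
    t1, t2 = config.bleach_taus_s
    bleach_s = a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2)
    bleach_b = 0.8 * a1 * np.exp(-t / (1.1 * t1)) + 0.9 * a2 * np.exp(-t / t2)
    artifact = _bandlimited_noise(n, rate, config.motion_cutoff_hz,
                                  config.motion_sd, rng)

    signal = (config.offset + bleach_s + clean
              + config.motion_gain_signal * artifact
              + config.noise_sd * rng.standard_normal(n))
    background = (config.offset + bleach_b
                  + config.motion_gain_background * artifact
                  + config.noise_sd * rng.standard_normal(n))

    if config.modulated:
        f_sig, f_bg = config.carrier_freqs
        modulated = (signal * np.sin(2 * np.pi * f_sig * t)
                     + background * np.sin(2 * np.pi * f_bg * t))
        session = PhotometrySession(rate, modulated, np.zeros_like(modulated),
                                    {k: np.asarray(v, dtype=float)
                                     for k, v in events.items()})
    else:
        session = PhotometrySession(rate, signal, background,
                                    {k: np.asarray(v, dtype=float)
                                     for k, v in events.items()})
    truth = GroundTruth(kernels=kern_arrays,
                        event_times={k: np.asarray(v, dtype=float)
                                     for k, v in events.items()},
                        artifact=artifact, bleach_signal=bleach_s,
                        bleach_background=bleach_b,
                        transient_amplitudes=amps_used)
    return session, truth


def generate_cohort(n_mice: int, weibull_params: dict, n_trials: int,
                    seed: int = 0) -> tuple[pd.DataFrame, GroundTruth]:
    """Bernoulli learning cohort following a modified Weibull curve.

    ``weibull_params`` holds a (amplitude above 50, %), l (scale, trials)
    and s (shape). Returns one row per trial per mouse with the binary
    outcome and the generating probability.
    """
    rng = np.random.default_rng(seed)
    a, l, s = weibull_params["a"], weibull_params["l"], weibull_params["s"]
    t = np.arange(1, n_trials + 1, dtype=float)
    p = np.clip(weibull_curve(t, a, l, s) / 100.0, 0.0, 1.0)
    frames = []
    for m in range(n_mice):
        correct = rng.random(n_trials) < p
        frames.append(pd.DataFrame({
            "mouse": m, "trial_idx": np.arange(n_trials),
            "correct": correct.astype(int), "p_correct": p,
        }))
    truth = GroundTruth(kernels={}, event_times={}, artifact=np.empty(0),
                        bleach_signal=np.empty(0), bleach_background=np.empty(0),
                        weibull_params=dict(weibull_params))
    return pd.concat(frames, ignore_index=True), truth


def generate_kinematics(n_trials: int, seed: int = 0,
                        speed_coef: float = 0.0, trend_coef: float = -0.3,
                        noise_sd: float = 0.1) -> pd.DataFrame:
    """Per-trial kinematic covariates with a planted dopamine model.

    Dopamine = speed_coef * speed + trend_coef * log(trial) + noise; speed
    and turn angle are mildly correlated, as nose-tracked kinematics are.
    """
    rng = np.random.default_rng(seed)
    speed = rng.lognormal(np.log(20.0), 0.3, n_trials)        # cm/s
    turn = 30 + 0.5 * (speed - 20) + rng.normal(0, 10, n_trials)   # degrees
    trial = np.arange(1, n_trials + 1, dtype=float)
    dopamine = (speed_coef * speed + trend_coef * np.log(trial)
                + rng.normal(0, noise_sd, n_trials))
    return pd.DataFrame({"trial_idx": np.arange(n_trials), "speed": speed,
                         "turn_angle": turn, "dopamine": dopamine})


def generate_trajectories(responses: np.ndarray, seed: int = 0,
                          coupling: float = -1.0, n_points: int = 12,
                          base_noise: float = 0.5) -> list[np.ndarray]:
    """Choice-port trajectories whose trial-to-trial similarity depends on
    dopamine: jitter around a canonical arc scales with
    ``exp(coupling * response)``, so larger responses (negative coupling)
    yield more repeatable movements."""
    rng = np.random.default_rng(seed)
    s = np.linspace(0, 1, n_points)
    canonical = np.column_stack([10 * s, 5 * np.sin(np.pi * s)])
    out = []
    for r in np.asarray(responses, dtype=float):
        sd = base_noise * float(np.exp(coupling * r))
        out.append(canonical + rng.normal(0, sd, canonical.shape))
    return out


def generate_linked_dataset(config: TaskConfig | None = None,
                            params: AgentParams | None = None,
                            n_trials: int = 300, seed: int = 0,
                            synth: SynthConfig | None = None,
                            ape_scale: float = 1.5):
    """One coherent dataset from agent simulation to raw photometry.

    The semi-Markov agent produces a trial log and per-transition APE
    magnitudes; those magnitudes become the choice-locked transient
    amplitudes of a synthetic photometry session (cue and outcome transients
    have fixed unit amplitude), and kinematics with planted coefficients are
    attached per trial. Returns (session log, photometry session, ground
    truth, kinematics table).
    """
    config = config or TaskConfig("standard")
    params = params or AgentParams()
    rng = np.random.default_rng(seed)
    trace, log = simulate_agent_session(config, params, n_trials, rng)
    trial_df = log.to_frame()
    duration = float(trial_df["t_outcome"].iloc[-1] + 5.0)
    synth = synth or SynthConfig(session_length_s=duration, seed=seed + 1)
    if synth.session_length_s < duration:
        synth = SynthConfig(**{**asdict_shallow(synth),
                               "session_length_s": duration})

    choice_rows = trace[trace.event == "choice"]
    events = {
        "cue": trial_df["t_cue_on"].to_numpy(),
        "choice": trial_df["t_center_out"].to_numpy(),
        "outcome": trial_df["t_outcome"].to_numpy(),
    }
    amplitudes = {"choice": ape_scale * choice_rows["delta_ape"].to_numpy()}
    session, truth = generate_photometry(events, synth, amplitudes=amplitudes)
    truth.planted_coefficients["ape_scale"] = ape_scale
    kin = generate_kinematics(n_trials, seed=seed + 2)
    return log, session, truth, kin


def asdict_shallow(cfg: SynthConfig) -> dict:
    d = asdict(cfg)
    d["kernels"] = cfg.kernels       # keep KernelShape objects
    for k, v in list(d["kernels"].items()):
        if isinstance(v, dict):
            d["kernels"][k] = KernelShape(**v)
    return d
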