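# apesim

Models and analyses of **value-free dopamine teaching signals** in the
striatum. Dopamine in the tail of striatum (TS) behaves like an **action
prediction error (APE)** — the difference between the action taken and how
strongly that action was already predicted from the current stimulus —
rather than the canonical reward prediction error (RPE) carried by ventral
striatal dopamine. `apesim` implements the computational machinery needed
to study that idea end-to-end on synthetic data with known ground truth:

- **`apesim.cot_task`** — the cloud-of-tones two-alternative auditory
  choice task as a semi-Markov environment, with all photometry-era
  variants (psychometric stimulus sets, outcome-value surprises,
  predicted-value change, state change to a white-noise cue, silence
  probes, sound-on-return) and the anti-bias training protocol.
- **`apesim.semi_markov_agent`** — an actor–critic agent over trial-stage
  states with dwell-time-scaled average-reward RPE,

      δ_k = r_{k+1} − ρ_k·d_k + V(s_{k+1}) − V(s_k),   signal = max(0, δ_k + ψ),

  plus a value-free stimulus–action learner emitting rectified APEs
  (`δ_APE = a − A(s)` for the taken action; `A(s) ← A(s) + ε·δ_APE`), and
  novelty, salience and movement comparison signals — the five candidate
  models of what TS dopamine could encode.
- **`apesim.dual_controller`** — a two-state/two-action network combining a
  value-based actor–critic (learning rate α = 0.04, actor weights decaying
  to 1 with τ = 100) with a value-free "tail" controller (APE rate
  β = 0.02, predicted-action filter τ = 100): habit formation as transfer
  of control, with lesion, psychometric and APE-doubling stimulation
  protocols.
- **`apesim.photometry`** — dual-carrier lock-in demodulation, the full
  dF/F preprocessing chain (median + 10 Hz low-pass denoising, 0.001 Hz
  bleaching correction, isosbestic regression-based motion correction,
  baseline division, z-scoring), event-locked response extraction, and the
  event-kernel linear regression with per-regressor explained variance.
- **`apesim.behavior_stats`** — modified Weibull learning curves
  (`50 + a(1 − 2^(−(t/l)^s))`), the shuffle-null optogenetic bias test,
  dopamine-history and repeat/switch (65th-percentile) regressions, the
  discrete Fréchet trajectory-similarity analysis, and the residual trend
  regression.
- **`apesim.synthetic_data`** — generators for everything above: raw
  photometry with known kernels, bleaching, shared motion artifacts and
  noise; Weibull learning cohorts; fully linked datasets with planted
  effect sizes.

See `docs/methods.md` for the models, defaults and design choices.

## Worked example

Habit formation in the dual-controller network — the value-free controller
cannot learn alone, but paired with the value-based one it consolidates the
mapping and keeps performance from regressing:

```python
import numpy as np
from apesim.dual_controller import NetworkParams, run_experiment, trials_to_criterion

combined = run_experiment("learning", NetworkParams(n_trials=300), n_agents=12, seed=0)
value_based = run_experiment("value_based_only", NetworkParams(n_trials=300), n_agents=12, seed=0)
for t in (10, 50, 100, 200, 299):
    print(f"trial {t:3d}  combined {combined.groupby('trial').performance.mean().iloc[t]:.3f}"
          f"  value-based {value_based.groupby('trial').performance.mean().iloc[t]:.3f}")
```

```
trial  10  combined 0.487  value-based 0.510
trial  50  combined 0.831  value-based 0.800
trial 100  combined 0.990  value-based 0.885
trial 200  combined 1.000  value-based 0.886
trial 299  combined 1.000  value-based 0.858
```

Early learning is identical (both purely RPE-driven); from ~trial 50 the
tail controller's stimulus–action associations boost the combined model to
ceiling while the value-based model's decaying actor plateaus lower and
keeps dipping. Median *sustained* trials-to-0.75-criterion over the 12
agents: combined 39.5, value-based alone 261.5.

The semi-Markov agent's choice-locked APE decays as the stimulus–action
association forms — the signature that distinguishes it from reward-driven
signals:

```python
from apesim.cot_task import TaskConfig, CONTRA_SIDE
from apesim.semi_markov_agent import AgentParams, simulate_learning

traces = simulate_learning(TaskConfig("standard"), AgentParams(), 600, 20, seed=0)
```

Mean choice-locked APE on correct contralateral trials: **0.940** in the
first decile of training, **0.190** in the last.

A command-line interface mirrors the library:

```bash
ape task simulate --variant standard --n-trials 5000 --seed 1 --out session.csv
ape network run --kind lesion --lesion tail --lesion-time 1000 --n-trials 1100 --seed 3
ape synth photometry --seed 0 --out-prefix demo
ape photometry preprocess demo_trace.csv --out processed.csv
ape stats bias-test trials.csv --shuffles 1000
```

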