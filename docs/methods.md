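# Methods

This note documents the models and procedures implemented in `apesim`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data tests do and do not establish about real recordings.

## The task environment (`cot_task`)

The cloud-of-tones (COT) task is simulated as a semi-Markov environment:
trials are self-initiated, event times are continuous seconds from session
start, and nothing is quantised to a frame clock. A trial is centre poke →
tone cloud (500 ms, 100 Hz stream of 30 ms tones; each 10 ms slot carries a
high-octave tone with probability `p_high` and, independently, a low-octave
tone with probability `1 − p_high`; 16 log-spaced frequencies per octave,
5–10 and 20–40 kHz; overall amplitude uniform in 60–80 dB) → side-port
choice → outcome. A correct choice delivers 2 µl; variants inject 6 µl
surprises and omissions (probability 0.1 each), upgrade one port to 6 µl
mid-session (predicted value, default switch at trial 100), replace the
contralateral cue with white noise (state change, default switch at trial
150), omit the cue (silence probes), or move it to the return period.
The contralateral convention is fixed: recording in the left hemisphere,
so "contra" = right port and the high-octave cue.

Dwell periods beyond the mandated 100–300 ms centre hold are not constrained
by the experimental description, so they are configurable log-normals:
movement median 0.68 s (the reported mean choice-movement duration), return
median 1.5 s. These produce realistic event spacing for the kernel
regression without asserting unpublished values.

The anti-bias controller samples the last 10 trials, measures the choice
bias on error trials, weights it by the error rate, and shifts the
target-port probability against the bias (`0.5 + k·2·bias·error_rate`,
clipped to [0.1, 0.9], gain `k = 1`). It therefore engages progressively as
the subject becomes biased and disengages when errors disappear. The
target-side frequency it produces is autocorrelated in 10-trial blocks, so
its sampling error around 0.5 is larger than the iid binomial value — the
tests account for that.

## The semi-Markov agent (`semi_markov_agent`)

States are the within-trial stages — Start, a cue state (high, low, white
noise or silence), an action state per (sound, action) pair, and Outcome —
and the agent updates only at state transitions, carrying the dwell time
`d` spent in the departed state. The reward prediction error at transition
`k` is the average-reward, dwell-scaled form

    δ_k = r_{k+1} − ρ_k·d_k + V(s_{k+1}) − V(s_k)

with ρ the average reward per unit time over the trailing 500 transitions
(a growing window before that; 0 for a fresh agent). The broadcast
dopamine-like signal is the rectified `max(0, δ + ψ)` with baseline
ψ = 0.2. Critic and actor update as `V ← V + αδ`, `m ← m + βδ` with
α = β = 0.005; the policy is a softmax over the actor strengths of the two
side choices (inverse temperature 5.0; 0.5 for the previous-choice
analysis, where exploratory behaviour is needed to populate both repeat and
switch histories).

The value-free learner keeps stimulus–action strengths `A(s)` and emits an
action prediction error at the time of choice: the one-hot action minus
`A(s)`, rectified so only the taken action's positive component survives
(dips are never emitted), followed by `A(s) ← A(s) + ε·δ_APE` with ε = 0.01
(0.001 in the predicted-value simulation, where a value-free controller
should update slowly). After `k` identical pairings from naivety the APE is
exactly `(1 − ε)^(k−1)` — the suite checks this to machine precision.

Candidate comparison signals: novelty `N(s) = exp(−γ·I(s))` with visit
count `I` and γ = 0.01 (the decaying-exponential reading of the novelty
model; the sign/placement is exposed in code for anyone wanting the
alternative), salience `L = V/μ + N` with μ = 0.5, and a pure movement
signal (the one-hot action vector). Reward magnitudes scale with volume:
0 (omission), 1 (2 µl), 3 (6 µl).

In this module the `A(s)` learner is observational — the softmax uses actor
strengths only — because here the model's job is to generate photometry
predictions; the choice-biasing role of the value-free pathway lives in the
dual-controller network.

Two measurement choices matter for the manipulation analyses:

- **State change**: the cue-value drop at the switch is only visible once
  the critic has learned the cue's value. With α = 0.005 that takes several
  hundred trials, and the animals in the corresponding experiment had prior
  training sessions. The model simulation therefore pre-trains the agent
  (switch at trial 600 of a 650-trial run) rather than switching a naive
  agent at trial 150.
- **Outcome-value invariance**: large rewards and omissions are assigned
  randomly, so the choice-locked APE of those trials differs from standard
  trials only by sampling noise; the comparison first residualises the APE
  on 50-trial bins to remove the learning trend both groups share, which
  makes the estimator's noise floor far smaller than 1 % of the signal.

Each agent owns one RNG (seeded `seed + agent_index`); runs are
bit-reproducible.

## The dual-controller network (`dual_controller`)

A two-state/two-action network: a value-based actor–critic updated by RPE
(`δ_RPE = r − W_critic·s`; rates α = 0.04) in parallel with a value-free
"tail" controller updated by APE. Action drive is
`A_total = W_actor·s + W_tail·s + noise` with independent per-action noise
uniform on [0, 1]; the action is the argmax (lower index on measure-zero
ties). Reward follows the identity contingency. The predicted action `p_a`
low-pass filters the binarised tail output (time constant τ_tail = 100);
`δ_APE = 1 − p_a[a]`, read out *before* the filter step so a first-ever
action has APE exactly 1. Three-factor updates (`W ← W + rate·δ·a sᵀ`, tail
rate β = 0.02) plus a two-factor critic update; the actor relaxes towards
its steady state of 1 with τ_decay = 100, which is what transfers control
to the tail over training; all weights are clipped at zero. Performance is
the reward low-pass filtered with τ = 10 from 0.5.

**Time semantics.** The source description mixes "trials", "timesteps" and
absolute inactivation times without a conversion. All leaky terms here use
one time unit per trial, integrated by forward Euler with dt = 1
(`steps_per_trial` exposes finer integration). With τ = 100 in trial units
the model shows the documented rise-then-decay of the actor weights and the
transfer of control; if the filters instead relaxed fully within each trial
(τ = 100 against 1000 sub-trial steps) no transfer occurs. Inactivation
times 30/100/1000 are trials under this convention, and "performance after
lesion" is the mean of the filtered readout over the 10 trials following
the lesion.

**Trials to criterion.** Early learning of the combined and value-based-only
models is identical — by construction both are driven purely by RPE until
the tail has associations to express — so first-crossing comparisons of a
0.75 criterion are dominated by ties. Criterion attainment is therefore
defined as *sustained* attainment (the trial from which performance stays at
or above criterion): the value-based-only model repeatedly regresses below
criterion because its actor weights decay, while the combined model, whose
tail consolidates the learned mapping, does not. `trials_to_criterion`
defaults to first crossing and takes `sustained=True` for this definition.

**Long-horizon value-free behaviour.** At the original 100-trial scale the
value-free-only model stays at chance. Run ten times longer its update rule
(reinforce whatever is taken, more strongly when unpredicted) crystallises
an *arbitrary* state→action habit: per-agent terminal performance becomes
bimodal at 0/1 with symmetric probabilities, so the cohort mean stays at
chance (0.5) but with binomial-over-agents spread rather than per-trial
spread. This is a genuine property of the stated equations, not a numerical
artifact; it is the same mechanism that lets the tail take over the correct
mapping when paired with the value-based controller.

**Stimulation.** Doubling δ_APE on contralateral-stimulus trials is read
out on a psychometric protocol (graded states `(1−d, d)`, 7 levels):
on easy trials ceiling performance masks any bias, so the contralateral
choice bias is measured on intermediate-difficulty trials (0.2 < d < 0.8),
where it grows across the session relative to a matched unstimulated run.

## Photometry (`photometry`)

Demodulation is quadrature lock-in per carrier (211/531 Hz): multiply by
sine and cosine references, low-pass at 20 Hz (chosen below the carrier
spacing), magnitude scaled so a pure sinusoid of amplitude A returns A.
Preprocessing order: median filter (width 5) → 10 Hz Butterworth low-pass
(order 2, forward-backward for zero phase) → 0.001 Hz high-pass on both
channels (implemented as subtraction of the complementary low-pass, which
is numerically stable at Wn ≈ 10⁻⁵) → linear regression of the signal on
the background channel with the fitted component subtracted (motion
correction) → division by the slow baseline (0.001 Hz low-pass of the
denoised, *pre*-high-pass signal channel by default; a switch selects the
post-high-pass variant) → z-score. Degenerate (effectively constant)
traces z-score to zeros with a logged warning.

The kernel regression predicts the processed signal at each sample as an
intercept plus per-event kernels over windows of −0.5/+1.5 s (choice
movement), 0/+1 s (cue, outcome) and −0.2/+1.5 s (return), solved by OLS
(least-norm on rank-deficient designs, with a warning). Event times are
rounded to the nearest sample. Per-regressor explained variance removes the
fitted contribution of one regressor from the prediction *without
refitting* and reports `(v_full − v_partial)/v_full × 100`; because the
partial prediction can underperform the intercept, values above 100 are
possible and are not clipped. "Trimming" restricts scoring to the union of
kernel windows around events.

## Behavioural statistics (`behavior_stats`)

**Weibull learning curves.** `performance = 50 + a(1 − 2^(−(t/l)^s))`
(chance at trial 0 by construction), fitted by bounded least squares with
5 multi-starts over log-spaced scales. Parameter recovery and bootstrap
intervals fit the *raw binary* outcomes (×100): fitting a trailing
rolling-window performance instead shifts and smooths the curve and biases
the shape parameter upward. The maximum learning rate is the maximum of the
fitted curve's derivative on a dense grid (for shapes ≤ 1 the analytic
maximum sits at zero trials, so a grid over the observed range is the
robust choice); maximum performance is the maximum of 200-trial binned
medians.

**Shuffle bias test.** Per trial type, the observed bias is the stimulated
minus unstimulated chosen-side proportion. The null re-labels a random
subset of the type's trials (of the stimulated count) as pseudo-stimulated
and rebuilds the session bias — a label permutation, exactly exchangeable
under the null. A null built by subsampling *unstimulated trials only*
understates the observed statistic's variance and measured a type-I error
of ~0.15 at α = 0.05; the permutation form measures ~0.05, which is the
calibration this package requires of itself.

**Choice-history analyses.** The repeat-or-switch logistic regression uses
previous-trial dopamine and the current trial's log uncertainty
(`−log(2|p_high − 0.5| + 10⁻³)` — the uncertainty transform is this
package's choice, as no numerical definition was given), on correct trials
plus all ambiguous-stimulus trials; separation falls back to an L2
penalised fit, flagged. The per-lag dopamine-history regression predicts
response size on correct contralateral trials from whether the same side
was chosen for the same stimulus k trials back. Note the negative lag-1
coefficient of an APE-like signal expresses through the *accumulated*
stimulus–action association, so sessions must be long enough (and the
policy exploratory enough) for the association to tilt during them.

**Trajectory similarity.** Discrete Fréchet distance via the standard
coupling recurrence (memoised, evaluated iteratively; Euclidean ground
metric). Continuous Fréchet is out of scope. The test suite checks it
exactly against an exhaustive enumeration of monotone couplings.

**Residual trend regression.** Dopamine response is first regressed on
speed and turn angle; the residuals are regressed on log trial number; a
three-predictor fit provides the variance decomposition (per-predictor drop
in R² when its contribution is removed, without refitting).

## Synthetic data (`synthetic_data`)

Photometry sessions are built from gamma-shaped event kernels (amplitude,
latency, width — the shapes are parametric choices, since only kernel
plots, not parameters, are available), a double-exponential bleaching
decay, a band-limited (2 Hz) motion artifact shared across channels with
different gains — matching the isosbestic-correction rationale — white
noise per channel, and optional dual-carrier modulation (which requires a
≥ 2.5 kHz clock). The background channel carries bleach + artifact + noise
but no event signal. Cohorts are Bernoulli trials following a Weibull
curve; linked datasets inject the agent's per-trial APE magnitudes as
choice-locked transient amplitudes and attach kinematics and trajectories
with planted coefficients.

What this establishes — and what it does not: the generators share the
*structure* assumed by the analyses (linear superposition of kernels,
additive shared artifact, Bernoulli choices). Passing recovery tests shows
the pipeline is correct and calibrated under that structure; it does not
show that real dLight recordings satisfy it (nonlinear sensor dynamics,
hemodynamic contamination, non-stationary artifact gains and pose-dependent
movement signals are all outside the generator).

## Problem sizes used by the test suite

Cohorts of 100 agents are used where cohort means are asserted
(value-free chance level, APE learning decay with an exponential fit to the
cohort mean, state-change directions); 600–1500 trials per agent depending
on how slowly the relevant association accumulates; 12 paired seeds for the
combined-vs-value-based comparison, 20 for lesions, 30 for stimulation;
1000 null sessions × 200 shuffles for the type-I calibration; 5000-trial
cohorts for Weibull recovery; 200 random 6-point pairs against the
brute-force Fréchet oracle. These sizes make every assertion's noise floor
comfortably smaller than the effect it checks.

## Known limitations

- The agent's state space is the task graph; it cannot represent
  within-state time beyond the dwell scalar, so fine-grained ramping
  dynamics are outside the model.
- The dual-controller time-unit convention is a documented choice among
  irreconcilable readings; absolute trial counts (e.g. trials to
  criterion) should be read as model-relative, not behavioural,
  predictions.
- The value-free-only model's long-horizon habit crystallisation makes its
  cohort mean a higher-variance estimate of chance than per-trial
  binomial intuition suggests.
- Plain logistic psychometric fits are provided as plumbing only;
  cross-validated fitting and plotting are out of scope.
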