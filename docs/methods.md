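# Methods

`huntswitch` implements a behavioral-computational pipeline for a
pursuit–evasion switching task: a player shares a circular 2D arena with a
computer agent and, cued trial by trial, either hunts a fleeing prey or
escapes a chasing predator.  The package simulates the task, models how
the player generates movement, fits those models to trajectories in moving
windows, decodes the behavioral condition from the fitted parameters, and
quantifies how the decoded "condition-specific state" reorganizes after a
switch cue.  Everything runs on synthetic cohorts; no behavioral
recordings are required.

## Task simulator (`arena_sim`)

Positions are measured in screen-height units; one frame is 16 ms; the
player moves at most 0.006 units/frame.  The scripted agent re-evaluates
30 candidate positions every frame, equally spaced on a circle of radius
equal to its current speed, and takes the candidate minimizing

    cost(c) = ± d(c, player) + w · d(c, center) + wall ramp,

with the `+` sign for the predator (chase) and `−` for the prey (flee),
`w = 0.5`, and a quadratic ramp that switches on in the outer 15% of the
radius so the agent is not pinned against the wall.  Costs are quantized
at 1e-12 before the argmin so exact geometric ties resolve to the lowest
candidate index (candidate 0 points along +x); this makes the greedy step
bit-reproducible.  The cost sign on the player-distance term is
configurable (`cost_sign_paper_literal`) because the task description
states it both ways; the default implements the behaviorally coherent
flee/chase convention.

Sessions follow the trial protocol: 121 trials per run by default, a
switch/stay cue with 0.5 switch probability from the second trial on, main
stages drawn uniformly from 2–10 s and terminated early on capture
(distance < 0.02), respawning only after captures (agent: isotropic
Gaussian, SD = radius/4, rejected into the arena; player: uniform radius ×
uniform angle), a pre-encounter stage (player alone, uniform 0–10 s) with
probability 0.4 after capture-terminated trials, and random predator
boosts (onset 0.5/s, ×1.8 for 12 frames; prey never boost).  A staircase
tracks success per condition in blocks of 4 trials and moves the agent
speed by 0.0005 units/frame toward a 50% player success rate, clipped to
[0.002, 0.012].  Arena radius (0.5), capture radius, boost parameters,
staircase step and clip range are not fixed by the task description and
are package defaults, all configurable.

The staircase can only equilibrate a player that is actually competitive.
A scripted greedy player (straight pursuit; wall-following flight)
converges to ~0.5 success in a 200-trial closed loop.  The generative
softmax player below is far weaker — at the reported precision values its
per-action value differences are of order one, so its movement drifts only
slowly toward the target — and its success rates sit well below 0.5 even
at the easiest agent speed.  Success-rate-based checks therefore use the
scripted player; model-based analyses do not depend on success rates.

## Generative movement models (`movement_models`)

Movement is discretized into 128 directions plus a null action (joystick
modality; 8+1 for keyboard).  An observed per-frame displacement shorter
than 0.25 × speed counts as the null action; otherwise it snaps to the
nearest direction, ties to the lower index.

All models predict the agent's position and value each action `a` by the
squared distance between its landing point and that prediction,

    y_pred(t) = y(t) + y'(t)·θ + y''(t)·θ²/2,
    Q(a) = −d²(landing, y_pred)   (hunt)   or   +d²   (escape),
    p(a) = exp(τ·Q(a)) / Σ_{a'} exp(τ·Q(a')),

computed with max-subtraction.  The displayed choice rule in the source
text omits the exponential in the numerator; the standard softmax is the
only reading that yields probabilities and matches the described role of
τ, so that is what is implemented.

* **M1 (reactive):** y_pred = y(t); decisions every frame; free parameter τ.
* **M2 (fixed predictive):** per-frame differences y'(t) = y(t) − y(t−1),
  y''(t) = y'(t) − y'(t−1), horizon θ fixed at 1; decisions every frame;
  free parameter τ.
* **M3 (variable timescale):** lagged differences at lag round(θ),
  decisions every round(θ) frames; between decisions the planned action
  repeats with probability μ, else an action is drawn uniformly (including
  the planned one and the null).  Free parameters θ ∈ (0, 30],
  τ ∈ [−1000, 1000], μ ∈ [0, 1].

θ is treated as continuous where it is a prediction horizon and rounded to
an integer (≥ 1) wherever it indexes frames.  At a trial's start, missing
lags degrade gracefully: acceleration is zeroed when only one lag fits,
velocity too when none does.  Whether M1/M2 carry the momentum term is not
specified in the source; they are implemented without it (µ enters only
M3), which fixes their free-parameter counts at 1 for the BIC.

## Window fitting and model comparison (`model_fitting`)

Trials are segmented into 30-frame (500 ms) windows stepping by 15 frames
(240 ms; the nearest integer-frame realization of a 250 ms step), starting
at the first frame with a non-null action.  Windows are fitted
independently, giving a parameter time course.

The M3 likelihood identifies the latent planned action at a planning frame
with the action observed there (no marginalization is specified in the
source; this is the standard tractable choice).  Planning frames are
anchored at the trial's movement onset, not at each window's start — the
windows step by 15 frames, which is generally not a multiple of θ, and
anchoring at onset keeps the assumed planning grid aligned with the
process that generated the data.  Intermediate frames score
μ·1[obs = planned] + (1 − μ)/|A|.  All 30 frames are scorable, so the BIC
sample size is 30 and BIC = 2·NLL + k·ln 30.

Given an integer θ the likelihood separates: μ has a closed-form MLE from
the match counts on intermediate frames, and the planning-frame
log-likelihood is concave in τ (an exponential-family property), solved by
bounded scalar optimization.  The fitter therefore profiles over integer
θ = 1…30 with exact inner maximization and then polishes (θ, τ) jointly in
the profiled bin with L-BFGS-B, the horizon continuous and the lag fixed.
This profile search dominates a multi-start quasi-Newton over all three
parameters — it cannot land in a worse local optimum than any start of
such a scheme inside the same bins — and is deterministic, so repeated
fits are bit-identical.  Because the θ = 1 profile point evaluates exactly
the M2 objective, the fitted M3 likelihood is never worse than M2's
(tested per window).

Model evidence per subject is approximated as −BIC/2 summed over windows.
Random-effects Bayesian model selection places a Dirichlet(1) prior on
population model frequencies, estimates the posterior by variational
Bayes, computes exceedance probabilities by Monte-Carlo over the posterior
Dirichlet (10⁵ seeded draws), and protects them with the Bayes omnibus
risk — the posterior probability of the equal-frequency null obtained by
comparing the variational free energy against the null's exact evidence —
via PXP = EP·(1 − BOR) + BOR/M.  No installed package provides this
procedure, so it is implemented here and validated on symmetric and
strong-evidence configurations.

## Condition decoding and C_p (`state_decoding`)

The three M3 parameters are averaged over a trial's windows to one feature
vector per trial.  Per subject, a linear support-vector machine (C = 1,
features z-scored on the training fold only) is evaluated by
leave-one-trial-out cross-validation, with a sigmoid (Platt) calibration
fitted on a 3-fold split inside each training fold to obtain posterior
probabilities.  The hinge loss uses class-balanced weights: removing one
trial tilts the training class balance against the held-out label, which
biases a leave-one-out estimate a few points below chance under label
permutation; balancing removes that bias (the permutation null then
centres at 50%) without affecting the intact-label accuracy.

The condition-specific state of a window or trial is the decoder's
task-appropriate posterior, C_p = P(hunt | features) on hunt trials and
1 − P(hunt) on escape trials; 0.5 is an undifferentiated state.
Window-level C_p uses the fold trained with that window's trial left out,
so no quantity is ever scored by a decoder that saw it.  The permutation
null shuffles labels within subject and re-runs the full LOTO loop with an
uncalibrated SVM (only the argmax matters for accuracy).

## Trajectory metrics (`behavior_metrics`)

* **Thigmotaxis:** fraction of frames with ‖x‖ > R/√2, the circle
  enclosing half the arena's area; equality counts as inside.
* **Linearity:** mean cosine between the actual step and the ideal
  direction — toward the prey when hunting, directly away from the
  predator when escaping; null frames are skipped, all-null trials are
  undefined.
* **Movement variability:** mean absolute frame-to-frame heading change in
  degrees, headings defined only on moving frames and chains broken by
  pauses.  A second variant counts direction changes per second, capped at
  59 to match the count-based display scale; the degrees-per-frame
  definition is primary.  A flag excludes predator-boost frames.
* **Success rates:** per-subject proportions under arbitrary trial
  stratifications (condition, switch/stay).

All four are rotation invariant (tested to 1e-9).

## Switching statistics (`switching_analysis`)

For a switch trial, the transition magnitude is
`initial C_p(current) − (1 − final C_p(previous))`: how far the state
moved toward the new task beyond where the previous trial left it, once
the previous trial's final state is re-expressed on the current trial's
axis.  Time-to-criterion is the time from the first window to the first
window with C_p ≥ 0.6, censored when never reached; the pipeline passes
frame-accurate window times (0.24 s steps).  "Initial C_p" is the first
window's value (the source does not specify a multi-window initial
average).

Suppression load is probed by a linear mixed model of the current trial's
initial C_p on the previous trial's final C_p over switch trials (random
intercepts for subject, a variance component for run when several runs
exist, age/sex as covariates when present); censored time-to-criterion
trials are excluded from its time variant.  Success is related to
trial-mean C_p by a mixed-effects logistic regression (variational-Bayes
binomial mixed GLM, random intercept per subject).  Singular or separated
fits fall back, flagged, to cluster-robust OLS / logistic fits.  The
mixed-model engines are statsmodels; only the transition/criterion
statistics are bespoke.

## Synthetic cohorts (`cohort_generator`)

Subjects are simulated players whose movement is generated by M3 with
condition-specific parameters.  The condition means are the reported group
values — joystick modality: θ 15.5 (hunt) / 11.4 (escape), τ 322.0 / 49.6,
μ 0.68 / 0.74; keyboard modality: θ 15.6 / 10.9, τ 383.8 / 29.3,
μ 0.95 / 0.95.  The joystick modality is the default.  Between-subject
spread is a truncated normal with SD = 15% of each mean (the true
dispersion is not reported; this stand-in is configurable and documented
as such), truncated to the parameter bounds.  Subjects play full sessions
against the scripted agent with the staircase on; the default synthetic
trial length is 2–4 s (2 s in the study-scale checks) to keep the fitting
desk-scale, with the full 2–10 s protocol available.  Datasets are fully
reproducible from (config, master seed), carry a ground-truth manifest,
and ground truth reaches the analysis only in explicit recovery tests.

## What the synthetic cohort does and does not show

The generator reproduces the statistical structure the analysis assumes —
condition-specific M3 parameters, the trial protocol, agent behavior — so
green tests demonstrate that the pipeline recovers planted structure
(parameter recovery r ≥ 0.8 at 60 trials/subject; decoding accuracy at or
above the reported 88.7%; permutation null at 50 ± 2%; PXP(M3) = 1 on
M3-generated cohorts).  They do not show that human movement obeys M3, and
two deliberate limitations matter:

* The M3 policy at the reported parameter means is a much weaker
  hunter/escaper than a human, so absolute success rates, trial-outcome
  base rates, and capture-linked quantities (e.g., the pre-encounter
  composite rate) differ from the human task even though the protocol
  logic is identical.
* Group movement-variability direction: in the joystick parameter set the
  momentum μ is *lower* in hunt (0.68) than escape (0.74) — the source
  itself notes this ordering is inconsistent between its two experiments.
  In the generative model the (1 − μ) random-action rate dominates
  per-frame heading changes, so a cohort simulated at those means shows
  *hunt* as the more variable condition, opposite to the human direction.
  With the keyboard set (μ matched at 0.95) the τ ordering drives the
  prediction and escape is the more variable condition, as in the human
  data.  The corresponding default-cohort acceptance check is left
  failing rather than redefined; the keyboard-set check passes.

## Numerical choices

Likelihood probabilities are floored at 1e-12 only in the mixture branch
(the softmax branch is computed in log space and cannot underflow).  τ
optimization tolerance 1e-4 on the argument, 1e-6 relative on the
polished objective.  Exceedance probabilities use 10⁵ Dirichlet draws
(Monte-Carlo SE ≤ 0.2%).  All randomness flows from
`numpy.random.Generator` seeds; sessions, cohorts, fits and BMS results
are bit-reproducible given a seed.  Problem sizes used by the study-scale
checks — 5 subjects × 60 two-second trials for decoding (≈ 1,600 windows),
20 subjects × ≈ 70–100 windows for model selection, 100 label
permutations — were chosen as the smallest cohorts at which the pipeline's
estimates stabilize.
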