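# huntswitch

Behavioral-computational analysis of switching between hunting and
escaping in a 2D pursuit–evasion task.

A player shares a circular arena with a computer agent and is cued, trial
by trial, to either **hunt** (chase and capture a fleeing prey) or
**escape** (evade a pursuing predator).  A 1-s boundary-color cue between
trials signals whether the upcoming condition switches or stays.  The
scientific question this pipeline serves: is the *movement generation
process* itself condition-specific, and how is it re-coordinated after a
switch?

The package provides, end to end:

1. **Task simulator** — scripted greedy agent (30-candidate cost
   minimization), trial/session protocol with switch cues, respawning,
   predator speed boosts, and a difficulty staircase holding player
   success near 50% (`arena_sim`).
2. **Generative movement models** — three nested models of the player.
   All predict the agent's position
   `y_pred(t) = y(t) + y′(t)·θ + y″(t)·θ²/2`, value each discretized
   action by `Q(a) = ∓ d²(landing, y_pred)` (− hunt, + escape) and choose
   through a softmax `p(a) ∝ exp(τ·Q(a))`.  M1 is reactive
   (`y_pred = y(t)`), M2 predicts with per-frame derivatives and θ = 1,
   M3 plans every θ frames with lag-θ derivatives and repeats its plan
   with momentum probability μ between decisions (`movement_models`).
3. **Windowed fitting and model comparison** — maximum likelihood per
   500-ms window (30 frames, 15-frame step), BIC = 2·NLL + k·ln n, and
   random-effects Bayesian model selection (variational Dirichlet,
   exceedance and protected exceedance probabilities)
   (`model_fitting`).
4. **State decoding** — leave-one-trial-out linear SVM with Platt
   calibration on the trial-averaged (θ, τ, μ), yielding the
   condition-specific state `C_p` (task-appropriate posterior; 0.5 =
   undifferentiated) per window and trial (`state_decoding`).
5. **Trajectory metrics** — thigmotaxis, movement linearity, movement
   variability, success rates (`behavior_metrics`).
6. **Switching statistics** — transition magnitude
   `initial C_p − (1 − previous final C_p)`, suppression-load and
   success ~ C_p mixed-effects regressions, time to reach C_p ≥ 0.6
   (`switching_analysis`).
7. **Synthetic cohorts** — simulated subjects whose movement is generated
   by M3 with the reported condition-specific parameter means, so the
   whole pipeline runs and is tested without any external data
   (`cohort_generator`).

## Worked example

```python
import numpy as np
import huntswitch as hs

# a small synthetic cohort: 3 subjects x 20 two-second joystick trials
cfg = hs.CohortConfig(n_subjects=3, trials_per_subject=20,
                      trial_duration_s=(2.0, 2.0), master_seed=7)
cohort = hs.generate_cohort(cfg)

# fit the variable-timescale model in 500-ms windows
fits = hs.fit_sessions(cohort.sessions, ("M3",))
feats = hs.trial_features(fits)
print(feats.groupby("condition")[["theta", "tau", "mu"]].mean().round(2))

# decode hunt vs. escape per subject, leave-one-trial-out
accs = [hs.fit_decoder_loto(g).accuracy for _, g in feats.groupby("subject")]
print("mean LOTO accuracy:", round(float(np.mean(accs)), 3))
```

prints

```
           theta     tau    mu
condition
escape     11.36   70.64  0.62
hunt       17.92  414.69  0.58
mean LOTO accuracy: 0.983
```

The fitted planning timescale θ is longer and the precision τ far higher
in hunt than escape — the condition-specific parameter structure planted
by the generator (hunt θ = 15.5, τ = 322; escape θ = 11.4, τ = 49.6, plus
15% between-subject spread) is recovered, and the two movement-generation
states are almost perfectly separable from three parameters per trial.
The worked transition example: a hunt trial that ends 24% escape / 76%
hunt followed by an escape trial that starts at 60% escape is a
`hs.transition_magnitude(0.76, 0.60)` = **0.36** (36%) transition toward
the new task.

A thin CLI mirrors the stages:

```bash
huntswitch cohort --seed 0 --out logs/
huntswitch fit --in logs/ --models M3 --out fits.csv
huntswitch decode --fits fits.csv --out cp.csv
huntswitch metrics --in logs/ --out metrics.csv
huntswitch analyze --cp cp.csv --trials logs/trials.csv --out results.json
```

## Layout

```
src/huntswitch/        arena_sim, movement_models, model_fitting,
                       state_decoding, behavior_metrics,
                       switching_analysis, cohort_generator, cli
tests/                 pytest suite (unit, property, end-to-end)
docs/methods.md        model equations, fitting details, design choices,
                       known limitations of the synthetic cohort
scripts/acceptance.py  headline-number reproduction
```
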