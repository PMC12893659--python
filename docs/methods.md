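# Methods

## The model

`doadapt` simulates trial-by-trial visuomotor adaptation as a switched
discrete-time state-space system built around a *disturbance observer* —
a recurrent internal model of constant perturbations, the construct the
internal model principle of control theory says any error-driven process
must contain if it is to drive a persistent disturbance out of its
measurement.

One trial is one state update. The plant is trivial: the motor command
computed at the end of trial *k* becomes the hand angle on trial *k*+1,
`x(k+1) = u(k)`. This idealizes a healthy participant whose inverse model
of the arm is well calibrated; no within-trial (online) correction is
modeled. On trials with a visible cursor the experiment places the cursor
at

    y = r + α (x − r) + d

where `r` is the target angle, `d` the imposed rotation and `α ∈ [0,1]`
the *hand angle-gain*: `α = 1` is a standard visuomotor rotation, `α = 0`
a full error clamp (the cursor ignores the hand), intermediate values a
*graded* error clamp. The participant measures only the visual error
`e = r − y`. All angles are plain degrees with no wraparound.

Three controller modules contribute to `u`:

* **Error feedback** `u_s = K e` — single-trial learning; `K` is the
  error sensitivity.
* **Disturbance observer** — scalar state `w0`, output
  `w_hat = w0 + G e`, motor contribution `u_im = ψ(e) w_hat` with
  `ψ(e) = ψ∘ / (1 + b_w |e|)`. The state update
  `w0' = F w0 + F G e + G (u − u_f)` uses an efference copy of the
  expressed command. With `G = 1 − F` the output obeys the exact
  cancellation

      w_hat(j+1) = F w_hat(j) + G (−d − r_f)

  whatever command was expressed: the observer is agnostic to the task
  (it learns identically on Learn and Ignore trials), and for `r_f = 0`
  it telescopes to the closed form `w_hat(j) = −d (1 − F^j)`. The
  eigenvalue `S = F + G ψ∘` equals 1 exactly when `ψ∘ = 1`; then the
  internal model principle is satisfied and the steady-state error is
  zero. `ψ∘ < 1` models incomplete learning.
* **Feedforward system** — fast state
  `x_f' = A_f x_f + (1 − A_f) L(u_im) u_im` with
  `L(u_im) = L∘ / (1 + b_f |u_im|)`, and slow state
  `r_f' = r_f + L_f x_f` (learning transfer), producing
  `u_f = r + r_f`. It never sees the visual error directly; it is
  trained by the observer's sustained output — a cascade architecture.

**Trial modalities and phase switches.** Which module is *expressed*
depends on the instruction: on `LEARN` trials
`u = u_f + u_s + u_im (+ r_aim)`; on `IGNORE` trials (cursor visible,
"move the hand to the target") `u = u_f + x_f` while the observer updates
silently; on no-cursor trials there is no error — the observer state is
held (`w0' = F_n w0`, `F_n = 1` by default; set `F_n < 1` to enable
forgetting), `x_f` decays at `A_fn`, `r_f` is held, and the command is
either `u_f + x_f` (`NO_CURSOR_HAND`) or the remembered last-cursor-trial
signals `u_f + u_s(j) + u_im(j)` (`NO_CURSOR_CURSOR`, for rapid
cursor/no-cursor alternation). `ZERO_CLAMP` is computed identically to
`NO_CURSOR_HAND`, adopting the view that zero-error-clamp behavior is
feedforward-driven; a *non-zero* error clamp is not a separate mode but
`IGNORE` with `α = 0` and `d` equal to the clamp angle. A cursor-trial
counter `j` (a staircase in `k`) tracks how many trials carried an error.
The explicit re-aiming offset `r_aim` is an additive protocol input on
any mode (builders resolve `r_aim = −γ d`); it is part of `u`, hence of
the efference copy, and cancels out of the observer update.

## Parameters

| Parameter | Meaning | Default | Units |
|---|---|---|---|
| `K` | error-feedback sensitivity | 0.25 | – |
| `F` | observer learning rate (0.7 fast reaching; 0.9 saccades / two-rate behaviors) | 0.7 | – |
| `psi0` | asymptotic learning proportion | 1.0 | – |
| `b_w` | observer saturation strength | 0.001 | /deg |
| `A_f` | feedforward learning rate | 0.9 | – |
| `A_fn` | feedforward retention on no-cursor trials | 0.95 | – |
| `L0` | feedforward sensitivity to `u_im` | 1.1 | – |
| `b_f` | feedforward saturation strength | 0.01 | /deg |
| `L_f` | learning-transfer rate (≪ 1 for timescale separation) | 1e-4 | – |
| `F_n` | observer retention on no-cursor trials | 1.0 | – |

`G = 1 − F` is derived, never free. Invariants are enforced at
construction (`K, F ∈ (0,1)`, `psi0, A_fn, F_n ∈ (0,1]`, `A_f ∈ [0,1)`,
saturations ≥ 0). Per-experiment presets (one per simulated study row,
e.g. `"Ignore-N (CCW)"` with `psi0 = 0.8` for the direction-dependent
incomplete learning) ship as JSON; entries the source simulations mark as
irrelevant are filled with the nominal value, except a starred transfer
rate, which is set to 0 so "plays no role" holds exactly.

## Closed forms and numerics

With `r_f` frozen at 0 (short-experiment regime — the long-term drift of
`r_f` toward `−d` is exercised only by simulation), the Learn-loop fixed
point is

    e_ss = −d (1 − ψ∘) / [(1 − ψ∘) + α (K + ψ∘)],
    x_ss − r = (K + ψ∘)/(1 − ψ∘) · e_ss   (limit −d/α when ψ∘ = 1),
    w_hat_ss = e_ss + (x_ss − r).

`α = 0` with `ψ∘ = 1` has no finite fixed point (full clamp with
complete learning) and is reported as a clamp condition. With `b_w > 0`
the fixed point is found by damped fixed-point iteration (damping 0.5,
tolerance 1e-10); `b_f` does not enter because `x_f` is not expressed on
Learn trials. Steady state in tests means an absolute per-trial change
below 1e-9 or a 2000-trial cap; simulated endpoints match the closed
forms to 1e-6. Engine order of evaluation follows the cursor-trial
update list literally; in particular `L` consumes the `u_im` computed on
the same trial. Remembered signals before any cursor trial are defined
as 0 with a logged warning.

## Protocols

Builders reproduce the printed designs with targets normalized to
`r = 90°`: graded-clamp experiments (40 baseline + 100 rotation trials —
160 when `α = 0.4` — + 40 no-cursor, or 40/120/40 with washout),
spontaneous recovery (80 Learn at −45° + 5 at +45° + 20 veridical
washout), evoked recovery (80/4/3/2/20), counter-perturbation savings
(80/5/80), re-aiming and error-sensitivity savings (configurable
learn/washout/relearn, defaults 80/20/80, since the replicated studies'
counts are not printed), error clamp, cursor/no-cursor alternation, and
a learn-then-no-cursor aftereffect template. The rotation sign
convention of the graded-clamp study (−15° for `α ∈ {1.0, 0.6}`, +15°
for `α ∈ {0.8, 0.4}`) is the builder default. Baseline and washout are
Learn trials with `d = 0`, `α = 1`. The multi-target randomization,
inter-cycle breaks and movement-time gating of the human experiments are
not modeled; the four α-cycles are independent single-cycle protocols.
Protocols serialize to a versioned JSON schema (YAML accepted on input)
with exact round-tripping.

## Synthetic cohorts

The generator emulates the statistical structure the analysis pipeline
assumes: Gaussian motor-execution noise added to the hand angle *before*
cursor placement (so it propagates into `y`, `e` and every state
update), and optional per-participant multiplicative parameter jitter.
Noise enters at a single site (execution) to keep the generative model
identifiable. Default `motor_sd = 2°`, a conventional magnitude for
reach-direction variability; participant seeds are `master_seed + index`
with numpy's PCG64 for cross-platform determinism. Aggregation follows
the behavioral pipeline: per-participant baseline bias correction (mean
over the last 20 baseline trials) before the cohort mean and SE. What
the generator does **not** emulate: reaction/movement times, target
randomization, online corrections, outlier trials, or heavy-tailed /
autocorrelated noise — so passing recovery tests demonstrate estimator
correctness under the package's own noise model, not robustness to real
data artifacts.

Parameter recovery (`recover_observer_params`) exploits the model's
exact innovation form: each trial's command is a deterministic function
of the errors the participant actually observed, so one-step-ahead
prediction driven by the observed deviations leaves independent
motor-noise residuals. The conditional sum of squares is evaluated by
dense grid search (steps of 0.01 in `K`, `F`, `psi0`), with no iterative
optimizer. It consumes the *uncorrected* cohort mean
(`CohortTrace.raw_mean_dev`): bias correction subtracts a noisy constant
that a conditional predictor would misread as a systematic error offset.

## Design choices where the design was open

* `r_aim` participates in the efference copy (it is part of `u`); this
  keeps the observer's cancellation exact under re-aiming.
* The saccadic variant's sensitivity `ψ` uses the current-trial error
  (the reach engine indexes it by cursor trial; with one update per trial
  the two readings coincide).
* The two-rate variant is a reference implementation with four free
  parameters; none are pinned.
* Reduced-model initial conditions for equivalence checks use the change
  of variables `e(0) = r − x(0) − d`, `w_hat(0) = w0(0) + G e(0)`.
* Aftereffect/asymptote readout defaults to the mean of the last 10
  phase trials.

## Problem sizes used by the test and acceptance runs

Steady-state checks run 2000 Learn trials (3000 in the saturated case);
the closed-form observer oracle uses 100 random stable parameter draws
of 60 trials; the equivalence suite 25 draws of 200 trials;
boundedness is probed over 1e5 trials; recovery uses an n = 30,
`motor_sd = 2°` cohort on the 180-trial Learn protocol with the dense
default grids. The whole suite runs in a few seconds on one core.

## Known limitations

* Single adaptation field: no dual (CW + CCW or multi-target)
  adaptation; the direction-dependent `ψ∘` asymmetry is encoded as
  presets only, with no mechanism.
* The arm is a unit delay; torque-level dynamics and online feedback are
  out of scope.
* Parameters are constants (no adaptation laws); savings via error
  sensitivity is expressed as an explicit per-phase override of `K`.
* The long-term behavior of `r_f` (full offloading of the observer) has
  no closed-form analysis here; it is only simulated.
* The recovery estimator assumes the linear (`b_w = 0`) Learn loop with
  `α = 1`; it is not intended for clamp or no-cursor phases.
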