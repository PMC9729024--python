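# Methods

This note records the model conventions, parameter choices and known
limitations of the `birddog` toolkit. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from external data.

## Coordinate and task conventions

All computation is strictly 2-D in image coordinates: origin top-left, x
rightward, y downward, pixels. Videos are assumed oriented head-up, so
"above" means "smaller y". `preprocess.resize_policy` encodes the upstream
geometry contract for pose estimation: inputs with height ≥ 1000 px are
scaled to one third, shorter inputs to one half, and the frame is rotated
(0/90/180/270° clockwise) to put the head up.

The six task landmarks are the shoulder, elbow and wrist of the lifted arm,
the knee and ankle of the contralateral lifted leg, and one hip. The trunk
length `t` is the mean shoulder–hip distance over frames where both points
are present. Which shoulder–hip pair defines `t` is genuinely open; the
default is the pair ipsilateral to the lifted arm (the supporting-leg side,
which faces the camera in a lateral recording and is tracked most reliably),
with `trunk="mean"` averaging both sides. `t` is computed *after* denoising,
since index computation follows denoising in the pipeline order.

## Denoising

Three stages per landmark, x and y independently:

1. **Visibility gate.** Samples with visibility strictly below 0.5 are
   discarded. The simulator draws normal visibility in [0.9, 1.0] and
   dropout visibility in [0.1, 0.4], so the gate's behaviour at the
   threshold is testable.
2. **EWM outlier rejection, 5 passes.** Per pass, the exponentially weighted
   moving average (EMA) and standard deviation (EWMSD, σ) are computed over
   the surviving samples and a sample is discarded when |x − EMA| > m·σ with
   m = 1 by default. Conventions (the weighting itself is delegated to
   pandas `ewm`): span parameterization α = 2/(span+1) with span = video FPS
   (rounded); causal weighting including the current sample, renormalized
   over available history (`adjust=True`); missing samples skipped, never
   imputed mid-pass (`ignore_na=True`); unbiased EWMSD; samples with
   undefined or zero σ are never flagged (the first valid sample has no σ;
   a constant history gives σ = 0 and `0 > 0` is false). A pass that flags
   nothing ends the loop early with an identical result.
3. **Linear interpolation** over frame index; leading/trailing gaps are
   filled with the nearest valid value, since one-sided linear extrapolation
   is undefined. A landmark axis with fewer than two survivors is an error.

Two properties of the 1σ rule are worth knowing. First, it is *aggressive*:
on a white-noise-dominated series each pass flags roughly P(|z| ≳ 1.06) ≈ 29 %
of samples, so five passes smooth heavily. This is faithful to the reference
procedure, but it means genuinely jittery body motion is partially absorbed:
absolute post-denoise SPB magnitudes are smaller than the magnitudes of the
underlying motion, while cross-trial ordering is preserved (the evaluation
stage z-scores indices, so linear attenuation cancels). Second, the procedure
is **not idempotent**: a second application keeps flagging and re-smoothing
(it changes much less than the first — the tests assert a < 20 % ratio — but
not nothing). Exact idempotence only holds on series the first application
leaves untouched.

A pure linear ramp is flagged only inside the EWM warm-up (about the first
two to three windows), never in steady state, where the deviation-to-σ ratio
tends to √(1−α) ≈ 0.95 < 1 independent of slope.

The outlier test is per-axis, not a 2-D distance, and ">" is strict; both
points are unstated in the source procedure and are recorded here as the
implementation's reading.

## Indices

* **SPB3 normalization.** The hull area is divided by t² (and by n). The
  source formulation is silent about the normalization, but only a
  dimensionless quantity is comparable across camera distances and body
  sizes, and only t² is consistent with the reference magnitudes for this
  index being roughly the square of the SPB1-scale quantities. Degenerate
  hulls (collinear or < 3 distinct points) contribute zero area, not an
  error.
* **AG1 reference direction.** θ is measured against the horizontal unit
  vector pointing from the trunk toward the extended limb (sign taken from
  the mean x-offset of the limb midpoint from its proximal joint), so a
  perfectly extended horizontal limb scores 0. Angles are unsigned in
  [0, 180]: raising a limb above horizontal scores like drooping it — AG1's
  designed-in blind spot, asserted in the tests. Note one subtlety: because
  the two limbs point in opposite directions, a small camera tilt moves the
  two unsigned angles in opposite ways and their *sum* is first-order
  tilt-invariant; AG1's tilt sensitivity appears once a limb folds through
  horizontal (the non-invariance test rotates by 45°).
* **AG2/AG3 angle construction.** φ¹ is the angle between the extension of
  the hip→shoulder ray beyond the shoulder and the shoulder→elbow vector, so
  perfect trunk-aligned extension gives 0 (not 180); φ² mirrors it at the
  hip; φ³/φ⁴ are the elbow/knee flexion angles between each proximal segment
  extended and the distal segment. φ¹ (φ²) is clamped to 0 when the elbow
  (knee) is strictly above — smaller y than — the shoulder (hip); φ³/φ⁴ are
  never clamped. AG2 is the mean and AG3 the max of Φ = φ¹+φ²+φ³+φ⁴, both
  over the same set of valid frames.
* **Degenerate frames.** Frames with a zero-length segment yield undefined
  angles; they are excluded from means and maxima with a warning, and a
  report with more than 10 % excluded frames is marked `reliable=False`.
  An index whose angles are undefined in *every* frame raises.
* **Per-frame, not per-second.** d is displacement per frame interval, as
  defined; reports record the FPS so cross-FPS comparisons can be rescaled
  by the caller. Duration is n/fps capped at the 60 s task maximum.

Exact invariances (asserted to 1e−9): all six indices are
translation-invariant; all six are invariant to uniform scaling (through the
t and t² normalizations); SPB1–3 and AG2/AG3 are rotation-invariant as long
as no φ clamp changes state, while AG1 is not. SPB2 ≥ 4·SPB1 and AG3 ≥ AG2
hold algebraically (max ≥ mean).

## Evaluation

OLS with intercept (statsmodels behind `fit_ols`), standard errors from the
unbiased residual variance, two-sided t-tests. AIC uses the full Gaussian
log-likelihood with the residual variance counted as a parameter,
AIC = n·log(2π·RSS/n) + n + 2(k+2) for k predictors; the `aic_includes_scale`
flag switches to the convention without the variance parameter (a constant
offset — selection is unaffected). Backward stepwise selection greedily
removes the predictor whose removal lowers AIC the most and stops when no
removal lowers it; ties break by predictor name order for reproducibility.
The greedy path is cross-checked in the tests against exhaustive subset
enumeration: the greedy AIC can exceed the exhaustive optimum only as a
documented path artifact, never below it.

Predictors and response are z-scored (ddof = 1) before fitting by default, so
coefficients are standardized effect sizes — the scale on which reported
coefficients of this index family are plausible; raw-scale fitting is a flag
away. Records with missing ratings are dropped listwise with a logged count.

A caveat inherited from AIC itself: a pure-noise predictor survives backward
selection with probability P(χ²₁ > 2) ≈ 16 %. Selection "cleanliness" over
replicates is therefore bounded near 84 % per noise candidate; the test suite
asserts and documents this honestly rather than tuning around it.

## Synthetic data

The generator emulates a lateral, head-up recording of the task as a pose
estimator would report it: near-static shoulder and hip (trunk length 100 px
by default), the arm extended toward −x and the leg toward +x, both drooping
`droop_deg` below horizontal with `bend_deg` of additional elbow/knee
flexion (segment lengths 0.6/0.5/0.9/0.8 t).

**Body sway** is smooth and band-limited in reality, so the default process
is a 0.5 Hz random-phase sinusoid per keypoint and axis plus a small white
component, scaled so the per-frame RMS displacement is `sway_amplitude`
trunk lengths; the shoulder/hip jitter is one tenth of the limb amplitude. A
mean-reverting Gaussian walk (reversion 0.1/frame) is available as
`sway_process="gaussian_walk_reverting"`, but its innovations are white —
spectrally identical to estimator jitter — so the reference denoiser
correctly absorbs most of it; it is not a useful model of sway that should
*survive* denoising, which is why it is not the default. **Estimator
corruption** is modelled separately: per-frame visibility dropout
(probability 0.02 by default) and isotropic position spikes (probability
0.01, 50 px).

Defaults (30 FPS, 60 s, sway 0.002, droop 13°, bend 24°) describe an
adult-like trial: on the clean trajectory they yield SPB1 ≈ 0.0027,
AG1 ≈ 40°, AG2 ≈ 74° (computed by the acceptance script's reference-trial
entry), magnitudes in the range reported for adult cohorts on this task.
Cohort simulations draw per-trial parameters uniformly (tests use sway
0.001–0.006, droop 5–25°, bend 10–30°, duration 6–14 s — durations kept
short to bound runtime) and generate clinician ratings as a linear model on
the *clean* trajectory's z-scored indices plus Gaussian noise, clipped to
the 1–7 rating scale, so regression ground truth is exact.

What the generator does **not** model: anatomical constraints between
segments, pendulum-like coordinated limb drops, floor contact ending a
trial, estimator biases that correlate across landmarks, or rater
disagreement. Passing tests therefore demonstrate correctness of the
computational pipeline and recoverability under plausible noise, not
clinical validity on real recordings.

## Problem sizes

The test suite runs moderate sizes chosen as reasonable desk-scale defaults:
oracle comparisons on 50 trajectories up to 500 frames, denoising recovery
over 100 replicates, selection/duration cohort experiments with 50
replicates of 60-trial cohorts; the acceptance script uses 30-replicate
cohort experiments and 20 oracle trajectories. All randomness flows from a
single seed (`--seed` for the script; fixed seeds in tests).
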