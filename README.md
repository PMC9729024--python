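# birddog

Quantitative postural-control assessment from 2-D body-keypoint videos of the
**bird-dog** (one-arm-one-leg) balance task.

Occupational therapists rate how well a client holds the bird-dog posture —
kneeling on all fours, then lifting one arm and the contralateral leg to
horizontal for up to 60 s. The conventional score, hold duration, saturates
(most adults reach the 60 s cap), so it cannot discriminate between a rock-solid
hold and a wobbly one. Markerless pose estimators (MediaPipe Pose, OpenPose,
AlphaPose) turn an ordinary video into per-frame landmark coordinates; this
package turns those coordinates into fine-grained, clinically interpretable
indices and tests how well they predict clinician ratings.

## What it computes

Let $p_i^k$ be the image position of extended-limb keypoint
$k \in \{1{:}\text{elbow},\,2{:}\text{wrist},\,3{:}\text{knee},\,4{:}\text{ankle}\}$
at frame $i$ of $n$, and let $t$ be the trunk length (mean shoulder–hip
distance). With normalized steps
$d_i^k = \lVert p_{i+1}^k - p_i^k\rVert / t$ and $D_i = \sum_k d_i^k$:

**Static postural balance**

- $\mathrm{SPB1} = \frac{1}{4}\sum_k \frac{1}{n-1}\sum_i d_i^k$ — mean limb step;
- $\mathrm{SPB2} = \max_i D_i$ — largest combined step;
- $\mathrm{SPB3} = \frac{1}{n\,t^2}\sum_k \mathrm{area}(\mathrm{hull}_k)$ —
  excursion (convex-hull) area of each keypoint's visited positions.

**Antigravity** (degrees; lower is better)

- $\mathrm{AG1} = \frac{1}{n}\sum_i (\theta_i^1 + \theta_i^2)$, where
  $\theta^1$ ($\theta^2$) is the unsigned angle between the image horizontal
  and the ray from the shoulder (hip) to the midpoint of elbow and wrist
  (knee and ankle);
- $\mathrm{AG2} = \frac{1}{n}\sum_i \Phi_i$ and $\mathrm{AG3} = \max_i \Phi_i$,
  where $\Phi_i = \varphi_i^1+\varphi_i^2+\varphi_i^3+\varphi_i^4$ combines the
  angle of each proximal segment against the extended trunk line (clamped to 0
  when the elbow/knee is *above* the shoulder/hip) with the elbow/knee flexion
  angles. Unlike AG1, these are camera-tilt-invariant and penalize "tricky"
  bent-limb postures.

Before any index is computed, trajectories are denoised the way the reference
procedure prescribes: samples with visibility < 0.5 are dropped, then five
passes of an exponentially weighted outlier rejection (span = video FPS) drop
samples further than one EWM standard deviation from the EWM mean, and the
gaps are filled by linear interpolation.

An evaluation module relates indices to clinician ratings (1–7 scale) via OLS
with backward stepwise AIC selection, including the comparison of
"selected indices + duration" against the conventional "duration only" model.
A synthetic-data module generates bird-dog trials (segment geometry, smooth
sway, visibility dropout, position spikes) with known ground truth, so the
whole pipeline is testable without any video data.

## Worked example

Simulate a 10 s trial (15° droop, 20° flexion, default sway and estimator
noise), then score it:

```sh
$ birddog simulate --seed 42 --duration 10 --droop 15 --bend 20 --out demo
wrote demo/trial.keypoints.csv and demo/trial.truth.json

$ birddog score --input demo/trial.keypoints.csv --side left_arm_right_leg --out demo-out
INFO birddog.preprocess: denoise: 82 samples below visibility threshold, 2887 flagged by the EWM rule
trial.keypoints: spb1=0.0011537, spb2=0.010378, spb3=9.3425e-06, ag1=41.931, ag2=70.157, ag3=71.852, duration_s=10
```

Reading the numbers: the limbs moved on average 0.12 % of a trunk length per
frame (SPB1), with a worst combined step of ~1 % (SPB2) and a tiny excursion
footprint (SPB3). The limb axes averaged ~21° below horizontal per limb
(AG1 ≈ 42° for two limbs), and the summed segment angles (AG2 ≈ 70°) reflect
the 15° droop plus 20° flexion at both the arm and the leg. `demo/trial.truth.json`
holds the generating parameters and the noise-free indices for comparison.

The same operations are available as a library:

```python
from birddog import Side, read_keypoints, score_trial

traj = read_keypoints("demo/trial.keypoints.csv")
report = score_trial(traj, Side.LEFT_ARM_RIGHT_LEG)
print(report.spb1, report.ag2)
```

For cohort-level analysis, write one row per trial
(`trial_id,cohort,clinician_score,spb1,...,ag3,duration_s`) and run
`birddog evaluate --trials trials.csv --out out/` to get the stepwise-selected
model and the duration-model comparison (JSON + a formatted table).

## Scope

The package starts from keypoint trajectories (CSV/JSON; a name map for
MediaPipe's landmark vocabulary is included). Running a pose estimator on
video is out of scope — `birddog.preprocess.resize_policy` documents the
geometry contract (resize rule and head-up rotation) expected of whoever
produces the keypoints. See `docs/methods.md` for the model details, parameter
choices and known limitations.
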