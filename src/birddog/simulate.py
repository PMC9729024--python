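"""Synthetic bird-dog trials and cohorts with known ground truth.

The generator emulates what a pose estimator would report for a lateral,
head-up video of the one-arm-one-leg balance task: a near-static shoulder
and hip, an arm extended horizontally away from the trunk (toward negative
image x) and the contralateral leg extended the other way, both drooping
``droop_deg`` below horizontal with an additional ``bend_deg`` of elbow/knee
flexion.  Real body sway is smooth and band-limited, so the default sway
model is a low-frequency oscillation (independent random-phase sinusoids per
keypoint and axis, 0.5 Hz by default, plus a small white component); a
discrete mean-reverting Gaussian walk (reversion rate 0.1 per frame) is
available as an alternative, though its white per-frame innovations look
like estimator jitter to the denoiser and are largely smoothed away.  Either
process is scaled so the per-frame RMS displacement is about
``sway_amplitude`` trunk lengths; the shoulder/hip jitter is one tenth of
that.  Estimator failures are
modelled separately: per-frame visibility dropout (visibility drawn in
[0.1, 0.4] instead of [0.9, 1.0], cleanly separated by the 0.5 threshold)
and sporadic large position spikes.  The clean trajectory (body motion
without estimator corruption) is returned alongside the noisy one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .errors import ValidationError, ZeroVarianceError
from .indices import IndexReport, compute_index_report
from .keypoints import KeypointTrajectory, Side, resolve_task_keypoints, task_landmark_names
from .pipeline import score_trial
from .preprocess import DenoiseParams

logger = logging.getLogger(__name__)

#: Mean-reversion rate of the sway walk, per frame.
SWAY_REVERSION = 0.1
#: Shoulder/hip jitter amplitude relative to the limb sway amplitude.
TRUNK_JITTER_FRACTION = 0.1
#: Limb segment lengths as fractions of the trunk length.
SEGMENT_FRACTIONS = {"upper_arm": 0.6, "forearm": 0.5, "thigh": 0.9, "shank": 0.8}


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of one simulated trial.

    Defaults describe a typical adult-like trial: 30 FPS for the full 60 s
    cap, a 100 px trunk, sway of 0.2 % of the trunk length per frame
    (yielding SPB1 near the adult reference magnitude), a 13 deg droop with
    24 deg of flexion (AG2 near its adult reference magnitude), 2 % dropout
    and 1 % spike rates.
    """

    fps: float = 30.0
    duration_s: float = 60.0
    trunk_length_px: float = 100.0
    sway_amplitude: float = 0.002
    sway_process: str = "sinusoid_plus_noise"
    sway_frequency_hz: float = 0.5
    droop_deg: float = 13.0
    bend_deg: float = 24.0
    dropout_prob: float = 0.02
    outlier_prob: float = 0.01
    outlier_magnitude: float = 50.0
    side: Side = Side.LEFT_ARM_RIGHT_LEG
    image_size: tuple[int, int] = (1280, 720)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.duration_s <= 60:
            raise ValidationError("duration_s must lie in (0, 60]")
        if self.fps <= 0 or self.trunk_length_px <= 0:
            raise ValidationError("fps and trunk_length_px must be positive")
        for p in ("dropout_prob", "outlier_prob"):
            if not 0 <= getattr(self, p) <= 1:
                raise ValidationError(f"{p} must lie in [0, 1]")
        if self.sway_amplitude < 0 or self.outlier_magnitude < 0:
            raise ValidationError("amplitudes must be non-negative")
        if self.sway_process not in ("gaussian_walk_reverting", "sinusoid_plus_noise"):
            raise ValidationError(f"unknown sway_process {self.sway_process!r}")


@dataclass(eq=False)
class SimulatedTrial:
    """A noisy trajectory, its clean (body-motion only) twin, and the truth."""

    trajectory: KeypointTrajectory
    clean_trajectory: KeypointTrajectory
    true_params: SimulationParams


def _mean_reverting_walk(rng: np.random.Generator, n: int, shape: tuple, step_sd: float) -> np.ndarray:
    """AR(1) walk s_{i+1} = (1 - kappa) s_i + step_sd * z_i, started at 0.

    The unit innovations are drawn even when step_sd is 0, so trials with
    different amplitudes but the same seed share a sample path (monotonicity
    of the indices in the amplitude then holds path-wise).
    """
    z = rng.standard_normal((n,) + shape)
    out = np.zeros((n,) + shape)
    for i in range(1, n):
        out[i] = (1 - SWAY_REVERSION) * out[i - 1] + step_sd * z[i]
    return out


def _sinusoid(rng: np.random.Generator, n: int, shape: tuple, amp: float, fps: float, freq: float) -> np.ndarray:
    phase = rng.uniform(0, 2 * np.pi, shape)
    noise = rng.standard_normal((n,) + shape)
    # amplitude chosen so the per-frame RMS displacement matches `amp`
    a = amp * fps / (np.sqrt(2.0) * np.pi * freq) if freq > 0 else 0.0
    tt = np.arange(n).reshape((n,) + (1,) * len(shape))
    return a * np.sin(2 * np.pi * freq * tt / fps + phase) + 0.1 * amp * noise


def simulate_trial(params: SimulationParams | None = None, **overrides) -> SimulatedTrial:
    """Generate one trial; bit-reproducible from ``params.seed``."""
    params = replace(params or SimulationParams(), **overrides)
    rng = np.random.default_rng(params.seed)
    n = max(2, round(params.duration_s * params.fps))
    t = params.trunk_length_px
    w, h = params.image_size

    hip0 = np.array([0.55 * w, 0.6 * h])
    shoulder0 = hip0 + np.array([-t, 0.0])
    d = np.radians(params.droop_deg)
    db = np.radians(params.droop_deg + params.bend_deg)
    ua, fa = SEGMENT_FRACTIONS["upper_arm"] * t, SEGMENT_FRACTIONS["forearm"] * t
    th, sh = SEGMENT_FRACTIONS["thigh"] * t, SEGMENT_FRACTIONS["shank"] * t
    # head-up image coordinates: y grows downward, droop means larger y
    elbow0 = shoulder0 + ua * np.array([-np.cos(d), np.sin(d)])
    wrist0 = elbow0 + fa * np.array([-np.cos(db), np.sin(db)])
    knee0 = hip0 + th * np.array([np.cos(d), np.sin(d)])
    ankle0 = knee0 + sh * np.array([np.cos(db), np.sin(db)])

    names = task_landmark_names(params.side)
    order = ("shoulder", "hip", "elbow", "wrist", "knee", "ankle")
    base = {"shoulder": shoulder0, "hip": hip0, "elbow": elbow0,
            "wrist": wrist0, "knee": knee0, "ankle": ankle0}

    sway_sd = params.sway_amplitude * t
    if params.sway_process == "gaussian_walk_reverting":
        limb_sway = _mean_reverting_walk(rng, n, (4, 2), sway_sd)
        trunk_sway = _mean_reverting_walk(rng, n, (2, 2), TRUNK_JITTER_FRACTION * sway_sd)
    else:
        limb_sway = _sinusoid(rng, n, (4, 2), sway_sd, params.fps, params.sway_frequency_hz)
        trunk_sway = _sinusoid(rng, n, (2, 2), TRUNK_JITTER_FRACTION * sway_sd,
                               params.fps, params.sway_frequency_hz)

    clean = np.empty((n, 6, 2))
    for j, role in enumerate(order):
        clean[:, j, :] = base[role]
    clean[:, :2, :] += trunk_sway
    clean[:, 2:, :] += limb_sway

    # estimator corruption: additive spikes + visibility dropout
    noisy = clean.copy()
    spikes = rng.random((n, 6)) < params.outlier_prob
    angles = rng.uniform(0, 2 * np.pi, (n, 6))
    offsets = params.outlier_magnitude * np.stack([np.cos(angles), np.sin(angles)], axis=-1)
    noisy += np.where(spikes[..., None], offsets, 0.0)

    vis = 0.9 + rng.uniform(0, 0.1, (n, 6))
    dropout = rng.random((n, 6)) < params.dropout_prob
    vis = np.where(dropout, 0.1 + rng.uniform(0, 0.3, (n, 6)), vis)

    landmark_names = tuple(names[role] for role in order)
    make = lambda coords, visibility: KeypointTrajectory(
        fps=params.fps, landmarks=landmark_names, coords=coords,
        visibility=visibility, image_size=params.image_size,
    )
    return SimulatedTrial(
        trajectory=make(noisy, vis),
        clean_trajectory=make(clean, np.ones((n, 6))),
        true_params=params,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreModel:
    """Clinician-score generator: linear model on z-scored true indices.

    ``score = intercept + sum_j coefficients[j] * z(index_j) + N(0, noise_sd)``
    clipped to the 1–7 rating scale.  ``duration_s`` may appear among the
    coefficient keys alongside the six indices.
    """

    coefficients: Mapping[str, float]
    intercept: float = 4.0
    noise_sd: float = 0.5


@dataclass(eq=False)
class TrialRecord:
    """One cohort row: pipeline-computed indices plus the simulated rating."""

    trial_id: str
    cohort: str
    clinician_score: float
    indices: IndexReport


def simulate_cohort(
    n_trials: int,
    param_ranges: Mapping[str, tuple[float, float]] | None = None,
    score_model: ScoreModel | None = None,
    seed: int = 0,
    base_params: SimulationParams | None = None,
    cohort: str = "synthetic",
    denoise_params: DenoiseParams | None = None,
) -> list[TrialRecord]:
    """Simulate ``n_trials`` trials and score them with a known linear model.

    Per-trial parameters are drawn uniformly from ``param_ranges`` (keys are
    :class:`SimulationParams` field names).  Indices entering each record go
    through the real pipeline (denoise -> resolve -> indices) on the noisy
    trajectory; the clinician score is generated from the *clean* trajectory's
    indices, z-scored across the cohort, so the regression ground truth is
    exactly the score model's coefficients.
    """
    if n_trials == 0:
        return []
    param_ranges = dict(param_ranges or {})
    score_model = score_model or ScoreModel(coefficients={"spb1": -1.0})
    base_params = base_params or SimulationParams()
    rng = np.random.default_rng(seed)

    reports: list[IndexReport] = []
    clean_reports: list[IndexReport] = []
    for i in range(n_trials):
        draws = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in param_ranges.items()}
        params = replace(base_params, seed=int(rng.integers(2**31)), **draws)
        trial = simulate_trial(params)
        reports.append(score_trial(trial.trajectory, params.side, denoise_params=denoise_params))
        clean_task = resolve_task_keypoints(trial.clean_trajectory, params.side)
        clean_reports.append(compute_index_report(clean_task, fps=params.fps))

    score = np.full(n_trials, float(score_model.intercept))
    for name, beta in score_model.coefficients.items():
        vals = np.array([getattr(r, name) for r in clean_reports])
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ZeroVarianceError(
                f"score-model variable {name!r} is constant across the cohort"
            )
        score = score + beta * (vals - vals.mean()) / sd
    score = score + score_model.noise_sd * rng.standard_normal(n_trials)
    score = np.clip(score, 1.0, 7.0)

    return [
        TrialRecord(trial_id=f"{cohort}-{i:04d}", cohort=cohort,
                    clinician_score=float(score[i]), indices=reports[i])
        for i in range(n_trials)
    ]
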