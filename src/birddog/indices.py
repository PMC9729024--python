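"""The six pose-evaluation indices for the bird-dog balance task.

Static postural balance (SPB) indices quantify how still the extended limbs
are held.  With p_i^k the position of limb keypoint k (1 elbow, 2 wrist,
3 knee, 4 ankle) at frame i, n the number of frames and t the trunk length:

    d_i^k = ||p_{i+1}^k - p_i^k|| / t        (trunk-normalized step, i = 1..n-1)
    D_i   = sum_k d_i^k
    SPB1  = (1/4) sum_k (1/(n-1)) sum_i d_i^k     (mean step)
    SPB2  = max_i D_i                             (largest combined step)
    SPB3  = (1/n) sum_k area(hull_k) / t^2        (excursion hull area)

where hull_k is the convex hull of keypoint k's visited positions (collinear
or repeated point sets contribute zero area).  The t^2 normalization of SPB3
makes it dimensionless like SPB1/SPB2.

Antigravity (AG) indices quantify limb droop, in degrees; lower is better.
AG1 measures, per frame, the unsigned angle theta^1 between the image
horizontal and the ray from the shoulder to the midpoint of elbow and wrist
(theta^2 analogously hip -> midpoint of knee and ankle), then averages
theta^1 + theta^2 over frames.  It cannot tell "above horizontal" from
"below" and assumes a level camera.  AG2/AG3 instead use four intersegment
angles per frame:

    phi^1: trunk line extended beyond the shoulder vs. shoulder->elbow,
           clamped to 0 whenever the elbow is above the shoulder;
    phi^2: trunk line extended beyond the hip vs. hip->knee, clamped to 0
           whenever the knee is above the hip;
    phi^3: shoulder->elbow extended vs. elbow->wrist (unclamped);
    phi^4: hip->knee extended vs. knee->ankle (unclamped);
    Phi_i = phi^1 + phi^2 + phi^3 + phi^4
    AG2 = mean_i Phi_i,   AG3 = max_i Phi_i.

All angles are unsigned and lie in [0, 180] degrees ("above" means smaller
image y in a head-up video).  Frames with degenerate geometry (coincident
keypoints) are excluded from the means and maxima with a warning; a report
is marked unreliable when more than 10 % of frames are excluded.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .errors import UndefinedAngleError, ValidationError
from .keypoints import MAX_TRIAL_SECONDS, Side, TaskKeypoints

logger = logging.getLogger(__name__)

#: Fraction of excluded (degenerate) frames above which a report is flagged.
UNRELIABLE_EXCLUSION_FRACTION = 0.10


@dataclass(eq=False)
class MovingDistanceSequence:
    """Trunk-normalized inter-frame displacements of the four limb keypoints.

    ``d`` has shape (n-1, 4) with columns in k order (elbow, wrist, knee,
    ankle); ``D`` is the per-frame sum across keypoints.
    """

    d: np.ndarray
    keypoint_names: tuple[str, ...] = ("elbow", "wrist", "knee", "ankle")

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[1] != 4:
            raise ValidationError(f"d must have shape (n-1, 4), got {self.d.shape}")
        if (self.d < 0).any() or not np.isfinite(self.d).all():
            raise ValidationError("displacements must be finite and non-negative")

    @property
    def D(self) -> np.ndarray:
        return self.d.sum(axis=1)

    @property
    def n_frames(self) -> int:
        return self.d.shape[0] + 1


@dataclass(eq=False)
class AngleSeries:
    """Per-frame limb angles in degrees; NaN marks degenerate frames."""

    theta1: np.ndarray
    theta2: np.ndarray
    phi1: np.ndarray
    phi2: np.ndarray
    phi3: np.ndarray
    phi4: np.ndarray

    @property
    def Phi(self) -> np.ndarray:
        return self.phi1 + self.phi2 + self.phi3 + self.phi4


@dataclass
class IndexReport:
    """The six scalar indices plus trial duration for one trial."""

    side: Side
    spb1: float
    spb2: float
    spb3: float
    ag1: float
    ag2: float
    ag3: float
    duration_s: float
    fps: float
    n_frames: int
    excluded_ag1_frames: int = 0
    excluded_ag23_frames: int = 0
    reliable: bool = True

    CSV_HEADER = ("side", "spb1", "spb2", "spb3", "ag1", "ag2", "ag3", "duration_s")

    def to_dict(self) -> dict:
        return {
            "side": Side(self.side).value,
            "spb1": self.spb1, "spb2": self.spb2, "spb3": self.spb3,
            "ag1": self.ag1, "ag2": self.ag2, "ag3": self.ag3,
            "duration_s": self.duration_s, "fps": self.fps, "n_frames": self.n_frames,
            "excluded_ag1_frames": self.excluded_ag1_frames,
            "excluded_ag23_frames": self.excluded_ag23_frames,
            "reliable": self.reliable,
        }

    def csv_row(self) -> list:
        return [Side(self.side).value] + [getattr(self, k) for k in self.CSV_HEADER[1:]]

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(_round_floats(self.to_dict()), indent=2, sort_keys=True) + "\n")


def _round_floats(obj, ndigits: int = 12):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# SPB family
# ---------------------------------------------------------------------------

def moving_distances(task: TaskKeypoints) -> MovingDistanceSequence:
    """Per-keypoint inter-frame step lengths divided by the trunk length."""
    pts = task.limb_points()  # (n, 4, 2)
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=2) / task.trunk_length_t
    return MovingDistanceSequence(d=steps)


def spb1(md: MovingDistanceSequence) -> float:
    """Mean normalized step over frames and keypoints."""
    return float(md.d.mean())


def spb2(md: MovingDistanceSequence) -> float:
    """Largest combined (four-keypoint) normalized step."""
    return float(md.D.max())


def _hull_area(points: np.ndarray) -> float:
    """Convex-hull area of a 2-D point set; 0 for degenerate sets."""
    pts = np.unique(points, axis=0)
    if pts.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # .volume is the area in 2-D
    except QhullError:
        return 0.0  # collinear


def spb3(task: TaskKeypoints) -> float:
    """Summed excursion-hull area of the four keypoints, per frame, per t^2."""
    pts = task.limb_points()
    total = sum(_hull_area(pts[:, k, :]) for k in range(4))
    return total / (task.trunk_length_t ** 2 * task.n_frames)


# ---------------------------------------------------------------------------
# AG family
# ---------------------------------------------------------------------------

def _unsigned_angle(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Unsigned angle in degrees between row-vector series, NaN where degenerate."""
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    dot = np.einsum("ij,ij->i", u, v)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where((nu > 0) & (nv > 0), dot / (nu * nv), np.nan)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def _outward_horizontal(limb_mid: np.ndarray, joint: np.ndarray) -> np.ndarray:
    """Unit horizontal reference pointing from the trunk toward the limb."""
    mean_dx = np.nanmean(limb_mid[:, 0] - joint[:, 0])
    sx = -1.0 if mean_dx < 0 else 1.0
    return np.array([sx, 0.0])


def ag1_angles(task: TaskKeypoints) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame theta^1 (arm) and theta^2 (leg) against the image horizontal.

    The horizontal reference points away from the trunk toward the extended
    limb, so a perfectly horizontal limb scores 0.  Angles are unsigned: a
    limb raised above horizontal scores the same as one drooping below (a
    known blind spot of AG1 that AG2/AG3 repair).
    """
    mid_arm = 0.5 * (task.elbow + task.wrist)
    mid_leg = 0.5 * (task.knee + task.ankle)
    u_arm = np.broadcast_to(_outward_horizontal(mid_arm, task.shoulder), (task.n_frames, 2))
    u_leg = np.broadcast_to(_outward_horizontal(mid_leg, task.hip), (task.n_frames, 2))
    theta1 = _unsigned_angle(mid_arm - task.shoulder, u_arm)
    theta2 = _unsigned_angle(mid_leg - task.hip, u_leg)
    return theta1, theta2


def ag23_angles(task: TaskKeypoints) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame phi^1..phi^4 intersegment angles (degrees, [0, 180])."""
    trunk_up = task.shoulder - task.hip  # hip -> shoulder direction
    phi1 = _unsigned_angle(trunk_up, task.elbow - task.shoulder)
    phi2 = _unsigned_angle(-trunk_up, task.knee - task.hip)
    phi3 = _unsigned_angle(task.elbow - task.shoulder, task.wrist - task.elbow)
    phi4 = _unsigned_angle(task.knee - task.hip, task.ankle - task.knee)
    # "above" = strictly smaller image y in a head-up video
    phi1 = np.where(task.elbow[:, 1] < task.shoulder[:, 1], 0.0, phi1)
    phi2 = np.where(task.knee[:, 1] < task.hip[:, 1], 0.0, phi2)
    return phi1, phi2, phi3, phi4


def angle_series(task: TaskKeypoints) -> AngleSeries:
    theta1, theta2 = ag1_angles(task)
    phi1, phi2, phi3, phi4 = ag23_angles(task)
    return AngleSeries(theta1=theta1, theta2=theta2, phi1=phi1, phi2=phi2, phi3=phi3, phi4=phi4)


def _valid_mean(values: np.ndarray, what: str) -> tuple[float, int]:
    ok = np.isfinite(values)
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"{what}: {n_bad} frame(s) with degenerate geometry excluded", stacklevel=3)
    if not ok.any():
        raise UndefinedAngleError(f"{what} undefined in every frame")
    return float(values[ok].mean()), n_bad


def ag1(task: TaskKeypoints) -> float:
    """Mean over frames of theta^1 + theta^2 (degrees)."""
    theta1, theta2 = ag1_angles(task)
    value, _ = _valid_mean(theta1 + theta2, "AG1")
    return value


def ag2(task: TaskKeypoints) -> float:
    """Mean over frames of Phi = phi^1 + phi^2 + phi^3 + phi^4 (degrees)."""
    value, _ = _valid_mean(angle_series(task).Phi, "AG2")
    return value


def ag3(task: TaskKeypoints) -> float:
    """Maximum over frames of Phi (degrees); degenerate frames excluded."""
    Phi = angle_series(task).Phi
    ok = np.isfinite(Phi)
    if not ok.any():
        raise UndefinedAngleError("AG3 undefined in every frame")
    return float(Phi[ok].max())


def compute_index_report(task: TaskKeypoints, fps: float) -> IndexReport:
    """All six indices plus duration for one (already denoised) trial."""
    md = moving_distances(task)
    theta1, theta2 = ag1_angles(task)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ag1_value, _ = _valid_mean(theta1 + theta2, "AG1")
        Phi = angle_series(task).Phi
        ag2_value, _ = _valid_mean(Phi, "AG2")
    n = task.n_frames
    n_bad_ag1 = int(np.sum(~np.isfinite(theta1 + theta2)))
    n_bad_ag23 = int(np.sum(~np.isfinite(Phi)))
    if max(n_bad_ag1, n_bad_ag23) > 0:
        logger.warning("index report: %d AG1 and %d AG2/AG3 frames excluded as degenerate",
                       n_bad_ag1, n_bad_ag23)
    report = IndexReport(
        side=task.side,
        spb1=spb1(md), spb2=spb2(md), spb3=spb3(task),
        ag1=ag1_value, ag2=ag2_value, ag3=float(np.nanmax(Phi)),
        duration_s=min(n / fps, MAX_TRIAL_SECONDS),
        fps=fps, n_frames=n,
        excluded_ag1_frames=n_bad_ag1, excluded_ag23_frames=n_bad_ag23,
        reliable=max(n_bad_ag1, n_bad_ag23) <= UNRELIABLE_EXCLUSION_FRACTION * n,
    )
    return report


def frame_series(task: TaskKeypoints) -> pd.DataFrame:
    """Per-frame diagnostic table: d^k, D, theta and phi series.

    The displacement columns are undefined for the first frame (NaN there);
    all other columns have one value per frame.
    """
    n = task.n_frames
    md = moving_distances(task)
    ang = angle_series(task)
    data = {"frame": np.arange(n)}
    for j, nm in enumerate(md.keypoint_names):
        col = np.full(n, np.nan)
        col[1:] = md.d[:, j]
        data[f"d_{nm}"] = col
    D = np.full(n, np.nan)
    D[1:] = md.D
    data["D"] = D
    data.update(theta1=ang.theta1, theta2=ang.theta2,
                phi1=ang.phi1, phi2=ang.phi2, phi3=ang.phi3, phi4=ang.phi4, Phi=ang.Phi)
    return pd.DataFrame(data)
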