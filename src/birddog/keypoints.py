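"""Containers and I/O for 2-D body-keypoint trajectories.

Coordinates live in image space: origin at the top-left corner, x grows to the
right, y grows downward, units are pixels.  Videos are assumed to be oriented
head-up, so "above" always means "smaller y".  A trajectory stores one (x, y)
pair and one visibility value in [0, 1] per frame and landmark; missing
markers are NaN coordinates (the state a trajectory is in after outlier
removal and before interpolation).

The bird-dog (one-arm-one-leg balance) task involves six landmarks per trial:
the shoulder, elbow and wrist of the lifted arm, the knee and ankle of the
lifted (contralateral) leg, and a hip used both as the trunk anchor and as
the proximal joint of the leg angles.  :func:`resolve_task_keypoints` selects
those series and computes the trunk length ``t`` — the mean shoulder–hip
distance — which normalizes all pixel-scale quantities.
"""

from __future__ import annotations

import csv
import enum
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import (
    AmbiguousRecordError,
    InsufficientDataError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Canonical landmark vocabulary used throughout the package.
CANONICAL_LANDMARKS = (
    "shoulder_l", "shoulder_r",
    "elbow_l", "elbow_r",
    "wrist_l", "wrist_r",
    "hip_l", "hip_r",
    "knee_l", "knee_r",
    "ankle_l", "ankle_r",
)

#: Mapping from the 33-point MediaPipe Pose naming to the canonical vocabulary
#: (only the twelve task-relevant body landmarks; pass as ``name_map`` to
#: :func:`read_keypoints` when ingesting MediaPipe exports).
MEDIAPIPE_NAME_MAP = {
    "left_shoulder": "shoulder_l", "right_shoulder": "shoulder_r",
    "left_elbow": "elbow_l", "right_elbow": "elbow_r",
    "left_wrist": "wrist_l", "right_wrist": "wrist_r",
    "left_hip": "hip_l", "right_hip": "hip_r",
    "left_knee": "knee_l", "right_knee": "knee_r",
    "left_ankle": "ankle_l", "right_ankle": "ankle_r",
}

#: Maximum scored trial duration in seconds (task protocol cap).
MAX_TRIAL_SECONDS = 60.0


class Side(str, enum.Enum):
    """Which diagonal pair of limbs is lifted."""

    LEFT_ARM_RIGHT_LEG = "left_arm_right_leg"
    RIGHT_ARM_LEFT_LEG = "right_arm_left_leg"

    @property
    def arm(self) -> str:
        return "l" if self is Side.LEFT_ARM_RIGHT_LEG else "r"

    @property
    def leg(self) -> str:
        return "r" if self is Side.LEFT_ARM_RIGHT_LEG else "l"


def task_landmark_names(side: Side) -> dict[str, str]:
    """Canonical landmark name for each task role on the given side.

    The hip is the one ipsilateral to the lifted arm (the supporting-leg
    side, typically the camera-facing side in a lateral recording).
    """
    side = Side(side)
    return {
        "shoulder": f"shoulder_{side.arm}",
        "elbow": f"elbow_{side.arm}",
        "wrist": f"wrist_{side.arm}",
        "hip": f"hip_{side.arm}",
        "knee": f"knee_{side.leg}",
        "ankle": f"ankle_{side.leg}",
    }


@dataclass(eq=False)
class KeypointTrajectory:
    """Per-frame (x, y, visibility) samples for a fixed landmark set.

    Parameters
    ----------
    fps
        Video frame rate, > 0.
    landmarks
        Ordered landmark names; coords/visibility columns follow this order.
    coords
        Array of shape ``(n_frames, n_landmarks, 2)``; NaN marks a missing
        sample.
    visibility
        Array of shape ``(n_frames, n_landmarks)`` with values in [0, 1]
        (NaN where the estimator reported none; treated as fully visible).
    image_size
        Optional ``(width, height)`` of the source video in pixels.
    """

    fps: float
    landmarks: tuple[str, ...]
    coords: np.ndarray
    visibility: np.ndarray
    image_size: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.landmarks = tuple(self.landmarks)
        self.coords = np.asarray(self.coords, dtype=float)
        self.visibility = np.asarray(self.visibility, dtype=float)
        if self.fps <= 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValidationError(
                f"coords must have shape (n_frames, n_landmarks, 2), got {self.coords.shape}"
            )
        n, m = self.coords.shape[:2]
        if n < 2:
            raise ValidationError(f"a trajectory needs at least 2 frames, got {n}")
        if m != len(self.landmarks):
            raise ValidationError("coords landmark axis does not match landmark names")
        if self.visibility.shape != (n, m):
            raise ValidationError(
                f"visibility must have shape {(n, m)}, got {self.visibility.shape}"
            )
        vis = self.visibility[np.isfinite(self.visibility)]
        if vis.size and (vis.min() < 0 or vis.max() > 1):
            raise ValidationError("visibility values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def index(self, name: str) -> int:
        try:
            return self.landmarks.index(name)
        except ValueError:
            raise KeyError(f"landmark {name!r} not present in trajectory") from None

    def get(self, name: str) -> np.ndarray:
        """(n_frames, 2) coordinate view of one landmark."""
        return self.coords[:, self.index(name), :]

    def visibility_of(self, name: str) -> np.ndarray:
        return self.visibility[:, self.index(name)]

    def copy(self) -> "KeypointTrajectory":
        return replace(self, coords=self.coords.copy(), visibility=self.visibility.copy())


@dataclass(eq=False)
class TaskKeypoints:
    """The six per-frame series of one bird-dog trial plus the trunk length.

    ``k_index`` fixes the conventional numbering of the extended-limb
    keypoints: 1 elbow, 2 wrist, 3 knee, 4 ankle.
    """

    side: Side
    shoulder: np.ndarray
    hip: np.ndarray
    elbow: np.ndarray
    wrist: np.ndarray
    knee: np.ndarray
    ankle: np.ndarray
    trunk_length_t: float

    k_index: Mapping[int, str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.k_index is None:
            self.k_index = {1: "elbow", 2: "wrist", 3: "knee", 4: "ankle"}
        if not self.trunk_length_t > 0:
            raise ValidationError(
                f"trunk_length_t must be positive, got {self.trunk_length_t}"
            )
        n = self.shoulder.shape[0]
        for role in ("hip", "elbow", "wrist", "knee", "ankle"):
            arr = getattr(self, role)
            if arr.shape != (n, 2):
                raise ValidationError(f"series {role!r} has shape {arr.shape}, expected {(n, 2)}")

    @property
    def n_frames(self) -> int:
        return self.shoulder.shape[0]

    def limb_points(self) -> np.ndarray:
        """(n_frames, 4, 2) stack of the extended-limb keypoints in k order."""
        return np.stack([getattr(self, self.k_index[k]) for k in (1, 2, 3, 4)], axis=1)

    def transformed(self, fn) -> "TaskKeypoints":
        """Apply ``fn`` (an (n,2)->(n,2) coordinate map) to every series.

        The trunk length is recomputed from the transformed shoulder/hip,
        so uniform scalings propagate into ``t``.
        """
        series = {r: fn(getattr(self, r)) for r in ("shoulder", "hip", "elbow", "wrist", "knee", "ankle")}
        t = float(np.mean(np.linalg.norm(series["shoulder"] - series["hip"], axis=1)))
        return TaskKeypoints(side=self.side, trunk_length_t=t, **series)


def trunk_length(
    traj: KeypointTrajectory, side: Side, mode: str = "ipsilateral"
) -> float:
    """Mean shoulder–hip distance over frames where both points are finite.

    ``mode='ipsilateral'`` uses the lifted-arm shoulder and same-side hip;
    ``mode='mean'`` averages the left and right shoulder–hip pair distances.
    """
    side = Side(side)
    if mode == "ipsilateral":
        pairs = [(f"shoulder_{side.arm}", f"hip_{side.arm}")]
    elif mode == "mean":
        pairs = [("shoulder_l", "hip_l"), ("shoulder_r", "hip_r")]
    else:
        raise ValueError(f"unknown trunk mode {mode!r}")
    means = []
    for sh_name, hip_name in pairs:
        sh, hip = traj.get(sh_name), traj.get(hip_name)
        ok = np.isfinite(sh).all(axis=1) & np.isfinite(hip).all(axis=1)
        if not ok.any():
            raise InsufficientDataError(
                f"no frame has both {sh_name!r} and {hip_name!r}; cannot compute trunk length"
            )
        means.append(float(np.mean(np.linalg.norm(sh[ok] - hip[ok], axis=1))))
    t = float(np.mean(means))
    if not t > 0:
        raise ValidationError("trunk length is zero: shoulder and hip coincide in every frame")
    return t


def resolve_task_keypoints(
    traj: KeypointTrajectory, side: Side, trunk: str = "ipsilateral"
) -> TaskKeypoints:
    """Select the six task series for ``side`` and compute the trunk length.

    Raises :class:`InsufficientDataError` when a required landmark is absent
    from the trajectory or missing (NaN) in more than 50 % of frames.
    """
    side = Side(side)
    names = task_landmark_names(side)
    absent = [nm for nm in names.values() if nm not in traj.landmarks]
    if trunk == "mean":
        absent += [nm for nm in ("shoulder_l", "shoulder_r", "hip_l", "hip_r")
                   if nm not in traj.landmarks and nm not in absent]
    if absent:
        raise InsufficientDataError(f"required landmarks missing from trajectory: {sorted(set(absent))}")
    too_sparse = []
    series = {}
    for role, nm in names.items():
        arr = traj.get(nm)
        frac_missing = float(np.mean(~np.isfinite(arr).all(axis=1)))
        if frac_missing > 0.5:
            too_sparse.append(f"{nm} ({frac_missing:.0%} missing)")
        series[role] = arr
    if too_sparse:
        raise InsufficientDataError(f"landmarks missing in more than half the frames: {too_sparse}")
    t = trunk_length(traj, side, mode=trunk)
    return TaskKeypoints(side=side, trunk_length_t=t, **series)


def duration_seconds(traj: KeypointTrajectory) -> float:
    """Trial duration ``n_frames / fps``, capped at the 60 s task maximum."""
    return min(traj.n_frames / traj.fps, MAX_TRIAL_SECONDS)


# ---------------------------------------------------------------------------
# I/O.  CSV dialect: optional leading "# key=value" metadata lines, then a
# header "frame,landmark,x,y,visibility" (visibility optional), frames
# 0-based.  JSON dialect: {"fps", "width", "height", "frames": [{"idx",
# "points": {"<landmark>": [x, y, visibility]}}]}.
# ---------------------------------------------------------------------------

def _finish(
    fps: float | None,
    image_size: tuple[int, int] | None,
    records: dict[tuple[int, str], tuple[float, float, float]],
    landmarks: list[str],
    source: str,
) -> KeypointTrajectory:
    if fps is None:
        raise ValidationError(
            f"{source}: fps not present in file metadata and not supplied by caller"
        )
    frames = sorted({f for f, _ in records})
    frame_pos = {f: i for i, f in enumerate(frames)}
    n, m = len(frames), len(landmarks)
    if n < 2:
        raise ValidationError(f"{source}: fewer than 2 frames")
    coords = np.full((n, m, 2), np.nan)
    vis = np.ones((n, m))
    col = {nm: j for j, nm in enumerate(landmarks)}
    for (f, nm), (x, y, v) in records.items():
        i, j = frame_pos[f], col[nm]
        coords[i, j] = (x, y)
        vis[i, j] = v
    return KeypointTrajectory(
        fps=float(fps), landmarks=tuple(landmarks), coords=coords,
        visibility=vis, image_size=image_size,
    )


def read_keypoints(
    path: str | Path,
    format: str | None = None,
    fps: float | None = None,
    image_size: tuple[int, int] | None = None,
    name_map: Mapping[str, str] | None = None,
) -> KeypointTrajectory:
    """Read a keypoint trajectory from CSV or JSON.

    ``format`` defaults to the file suffix.  ``fps``/``image_size`` supplied
    here override file metadata.  ``name_map`` renames estimator-specific
    landmark labels to the canonical vocabulary (e.g.
    :data:`MEDIAPIPE_NAME_MAP`); unlisted names pass through unchanged.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        return _read_csv(path, fps, image_size, name_map or {})
    if fmt == "json":
        return _read_json(path, fps, image_size, name_map or {})
    raise ValueError(f"unsupported keypoint format {fmt!r}")


def _read_csv(path, fps, image_size, name_map):
    meta: dict[str, float] = {}
    records: dict[tuple[int, str], tuple[float, float, float]] = {}
    landmarks: list[str] = []
    with open(path, newline="") as fh:
        header: list[str] | None = None
        has_vis = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    try:
                        meta[key.strip()] = float(val)
                    except ValueError:
                        pass
                continue
            parts = next(csv.reader([line]))
            if header is None:
                header = [p.strip() for p in parts]
                required = {"frame", "landmark", "x", "y"}
                if not required.issubset(header):
                    raise ParseError(
                        f"{path} line {lineno}: header must contain {sorted(required)}, got {header}"
                    )
                has_vis = "visibility" in header
                idx = {nm: header.index(nm) for nm in header}
                continue
            try:
                frame = int(parts[idx["frame"]])
                name = name_map.get(parts[idx["landmark"]], parts[idx["landmark"]])
                x = float(parts[idx["x"]])
                y = float(parts[idx["y"]])
                v = float(parts[idx["visibility"]]) if has_vis and parts[idx["visibility"]] != "" else 1.0
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path} line {lineno}: malformed row {line!r} ({exc})") from None
            key = (frame, name)
            if key in records:
                raise AmbiguousRecordError(
                    f"{path} line {lineno}: duplicate record for frame {frame}, landmark {name!r}"
                )
            if name not in landmarks:
                landmarks.append(name)
            records[key] = (x, y, v)
    if header is None:
        raise ParseError(f"{path}: empty file")
    fps = fps if fps is not None else meta.get("fps")
    if image_size is None and "width" in meta and "height" in meta:
        image_size = (int(meta["width"]), int(meta["height"]))
    return _finish(fps, image_size, records, landmarks, str(path))


def _read_json(path, fps, image_size, name_map):
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from None
    fps = fps if fps is not None else payload.get("fps")
    if image_size is None and "width" in payload and "height" in payload:
        image_size = (int(payload["width"]), int(payload["height"]))
    records: dict[tuple[int, str], tuple[float, float, float]] = {}
    landmarks: list[str] = []
    for entry in payload.get("frames", []):
        try:
            frame = int(entry["idx"])
            points = entry["points"]
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: malformed frame entry {entry!r} ({exc})") from None
        for raw_name, vals in points.items():
            name = name_map.get(raw_name, raw_name)
            if len(vals) not in (2, 3):
                raise ParseError(f"{path}: point {raw_name!r} at frame {frame} must be [x, y(, visibility)]")
            x, y = float(vals[0]), float(vals[1])
            v = float(vals[2]) if len(vals) == 3 else 1.0
            key = (frame, name)
            if key in records:
                raise AmbiguousRecordError(f"{path}: duplicate record for frame {frame}, landmark {name!r}")
            if name not in landmarks:
                landmarks.append(name)
            records[key] = (x, y, v)
    return _finish(fps, image_size, records, landmarks, str(path))


def write_keypoints(traj: KeypointTrajectory, path: str | Path, format: str | None = None) -> None:
    """Write a trajectory; round-trips bit-exactly through :func:`read_keypoints`."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            fh.write(f"# fps={traj.fps!r}\n")
            if traj.image_size is not None:
                fh.write(f"# width={traj.image_size[0]}\n# height={traj.image_size[1]}\n")
            writer = csv.writer(fh)
            writer.writerow(["frame", "landmark", "x", "y", "visibility"])
            for i in range(traj.n_frames):
                for j, nm in enumerate(traj.landmarks):
                    x, y = traj.coords[i, j]
                    v = traj.visibility[i, j]
                    writer.writerow([i, nm, repr(float(x)), repr(float(y)), repr(float(v))])
    elif fmt == "json":
        payload: dict = {"fps": traj.fps}
        if traj.image_size is not None:
            payload["width"], payload["height"] = int(traj.image_size[0]), int(traj.image_size[1])
        payload["frames"] = [
            {
                "idx": i,
                "points": {
                    nm: [float(traj.coords[i, j, 0]), float(traj.coords[i, j, 1]),
                         float(traj.visibility[i, j])]
                    for j, nm in enumerate(traj.landmarks)
                },
            }
            for i in range(traj.n_frames)
        ]
        Path(path).write_text(json.dumps(payload, allow_nan=True))
    else:
        raise ValueError(f"unsupported keypoint format {fmt!r}")
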