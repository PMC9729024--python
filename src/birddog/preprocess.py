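"""Video-geometry policy and keypoint denoising.

Denoising follows a three-stage recipe.  (1) Samples whose visibility is
strictly below 0.5 are discarded.  (2) For each landmark and coordinate axis
independently, an exponentially weighted moving average (EMA) and standard
deviation (EWMSD, sigma) are computed with span equal to the video FPS, and a
sample is discarded when it lies more than ``sigma_multiplier * sigma`` from
the EMA; this pass is repeated five times, each pass re-estimating the
statistics on the surviving samples only.  (3) Discarded samples are filled
by linear interpolation over frame index (constant extension at the ends).

Conventions (see docs/methods.md for rationale): the exponential weighting is
causal and span-parameterized (alpha = 2 / (span + 1)) with weights
renormalized over the available history; missing samples are skipped, never
imputed mid-pass; samples with undefined or zero sigma are never flagged; the
outlier test uses a strict ">" and per-axis deviations, not 2-D distances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CannotInterpolateError, ValidationError
from .keypoints import KeypointTrajectory

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DenoiseParams:
    """Tunable parameters of the denoising procedure.

    ``window`` is the EWM span in frames; ``None`` means "use the video FPS,
    rounded".  ``sigma_multiplier`` scales the rejection threshold (1.0
    reproduces the reference procedure).
    """

    visibility_threshold: float = 0.5
    window: int | None = None
    n_iterations: int = 5
    sigma_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.visibility_threshold <= 1.0:
            raise ValidationError("visibility_threshold must lie in [0, 1]")
        if self.window is not None and self.window < 2:
            raise ValidationError("window must be at least 2 frames")
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be at least 1")
        if not self.sigma_multiplier > 0:
            raise ValidationError("sigma_multiplier must be positive")

    def resolved_window(self, fps: float) -> int:
        return self.window if self.window is not None else max(2, round(fps))


@dataclass(frozen=True)
class GeometryPolicy:
    """Resize/rotation contract for whoever runs the pose estimator upstream.

    Tall inputs (height >= 1000 px) are scaled to one third, shorter ones to
    one half; the rotation (clockwise degrees) turns the participant's head
    upward so that image "up" matches anatomical "up".
    """

    input_size: tuple[int, int]
    scale_factor: float
    rotation: int

    @property
    def output_size(self) -> tuple[int, int]:
        w, h = self.input_size
        if self.rotation in (90, 270):
            w, h = h, w
        return (round(w * self.scale_factor), round(h * self.scale_factor))


_ROTATION_FOR_HEAD = {"up": 0, "left": 90, "down": 180, "right": 270}


def resize_policy(height: float, width: float, head_direction: str = "up") -> GeometryPolicy:
    """Geometry policy for a raw video of the given size.

    ``head_direction`` is where the participant's head points in the raw
    frames; the returned clockwise rotation turns it upward.
    """
    if height <= 0 or width <= 0:
        raise ValidationError(f"video dimensions must be positive, got {width}x{height}")
    if head_direction not in _ROTATION_FOR_HEAD:
        raise ValidationError(f"head_direction must be one of {sorted(_ROTATION_FOR_HEAD)}")
    scale = 1.0 / 3.0 if height >= 1000 else 0.5
    return GeometryPolicy(
        input_size=(int(width), int(height)),
        scale_factor=scale,
        rotation=_ROTATION_FOR_HEAD[head_direction],
    )


def flag_low_visibility(traj: KeypointTrajectory, params: DenoiseParams | None = None) -> np.ndarray:
    """Boolean (n_frames, n_landmarks) mask, True where visibility < threshold.

    The comparison is strict, so a visibility of exactly 0.5 survives.
    NaN visibility (estimator reported none) is never flagged.
    """
    params = params or DenoiseParams()
    with np.errstate(invalid="ignore"):
        return traj.visibility < params.visibility_threshold


def _ewm_stats(df: pd.DataFrame, window: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    ewm = df.ewm(span=window, adjust=True, ignore_na=True, min_periods=1)
    return ewm.mean(), ewm.std(bias=False)


def _ewm_flag_frame(df: pd.DataFrame, window: int, multiplier: float) -> pd.DataFrame:
    """One rejection pass on a column-wise series table with NaN for missing."""
    ema, sd = _ewm_stats(df, window)
    dev = (df - ema).abs()
    with np.errstate(invalid="ignore"):
        return df.notna() & (sd > 0) & (dev > multiplier * sd)


def ewm_outlier_pass(series: np.ndarray, params: DenoiseParams, window: int | None = None) -> np.ndarray:
    """One EMA/EWMSD rejection pass over a scalar series with NaN gaps.

    Returns the augmented missing mask (True = missing/outlier); entries that
    were already missing stay missing.  A series shorter than the window is
    returned unchanged with a warning.
    """
    x = np.asarray(series, dtype=float)
    window = window if window is not None else params.window
    if window is None:
        raise ValidationError("ewm_outlier_pass needs an explicit window when params.window is None")
    missing = ~np.isfinite(x)
    if x.size < window:
        warnings.warn(
            f"series of length {x.size} is shorter than the EWM window {window}; pass skipped",
            stacklevel=2,
        )
        return missing
    frame = pd.DataFrame({"x": np.where(missing, np.nan, x)})
    new = _ewm_flag_frame(frame, window, params.sigma_multiplier)["x"].to_numpy()
    return missing | new


def interpolate_missing(x: np.ndarray, label: str = "series") -> np.ndarray:
    """Linear interpolation over frame index; constant extension at the ends."""
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(x)
    if ok.all():
        return x.copy()
    if ok.sum() < 2:
        raise CannotInterpolateError(
            f"{label}: only {int(ok.sum())} valid sample(s) survive; cannot interpolate"
        )
    idx = np.arange(x.size)
    return np.interp(idx, idx[ok], x[ok])


def denoise(traj: KeypointTrajectory, params: DenoiseParams | None = None) -> KeypointTrajectory:
    """Full denoising pipeline; returns a trajectory with finite coordinates.

    Visibility thresholding runs once, the EWM rejection pass
    ``params.n_iterations`` times (a pass that flags nothing ends the loop
    early with an identical result), interpolation last.  x and y of each
    landmark are processed independently.
    """
    params = params or DenoiseParams()
    window = params.resolved_window(traj.fps)
    n, m = traj.coords.shape[:2]

    columns = {}
    low_vis = flag_low_visibility(traj, params)
    for j, nm in enumerate(traj.landmarks):
        for a, axis in enumerate("xy"):
            col = traj.coords[:, j, a].astype(float).copy()
            col[low_vis[:, j]] = np.nan
            columns[(nm, axis)] = col
    df = pd.DataFrame(columns)
    n_thresholded = int(df.isna().to_numpy().sum())

    if n < window:
        warnings.warn(
            f"trajectory of {n} frames is shorter than the EWM window {window}; "
            "outlier passes skipped, interpolation only",
            stacklevel=2,
        )
    else:
        for _ in range(params.n_iterations):
            flags = _ewm_flag_frame(df, window, params.sigma_multiplier)
            if not flags.to_numpy().any():
                break
            df = df.mask(flags)

    n_flagged = int(df.isna().to_numpy().sum()) - n_thresholded
    logger.info(
        "denoise: %d samples below visibility threshold, %d flagged by the EWM rule",
        n_thresholded, n_flagged,
    )

    coords = np.empty_like(traj.coords)
    for j, nm in enumerate(traj.landmarks):
        for a, axis in enumerate("xy"):
            coords[:, j, a] = interpolate_missing(df[(nm, axis)].to_numpy(), label=f"{nm}.{axis}")
    out = traj.copy()
    out.coords = coords
    return out
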