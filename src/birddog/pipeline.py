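"""High-level glue: trajectory in, index report out."""

from __future__ import annotations

from .indices import IndexReport, compute_index_report
from .keypoints import KeypointTrajectory, Side, resolve_task_keypoints
from .preprocess import DenoiseParams, denoise


def score_trial(
    traj: KeypointTrajectory,
    side: Side,
    denoise_params: DenoiseParams | None = None,
    apply_denoise: bool = True,
    trunk: str = "ipsilateral",
) -> IndexReport:
    """Denoise a trajectory, resolve the task landmarks and compute indices.

    ``apply_denoise=False`` skips denoising (diagnostics on raw estimator
    output); the trunk length is then taken from the raw coordinates.
    """
    if apply_denoise:
        traj = denoise(traj, denoise_params)
    task = resolve_task_keypoints(traj, side, trunk=trunk)
    return compute_index_report(task, fps=traj.fps)
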