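import numpy as np
import pytest

from birddog import (
    KeypointTrajectory,
    Side,
    SimulationParams,
    TaskKeypoints,
    simulate_trial,
)


@pytest.fixture
def static_params():
    """Ideal static posture: perfectly horizontal limbs, no motion, no noise."""
    return SimulationParams(
        duration_s=4.0, sway_amplitude=0.0, droop_deg=0.0, bend_deg=0.0,
        dropout_prob=0.0, outlier_prob=0.0, seed=0,
    )


@pytest.fixture
def static_trial(static_params):
    return simulate_trial(static_params)


@pytest.fixture
def default_trial():
    return simulate_trial(SimulationParams(duration_s=8.0, seed=42))


def make_trajectory(coords_by_name, fps=30.0, visibility=None):
    """Build a trajectory from {landmark: (n, 2) array-like}."""
    names = tuple(coords_by_name)
    coords = np.stack([np.asarray(coords_by_name[nm], dtype=float) for nm in names], axis=1)
    n = coords.shape[0]
    vis = np.ones((n, len(names))) if visibility is None else np.asarray(visibility, dtype=float)
    return KeypointTrajectory(fps=fps, landmarks=names, coords=coords, visibility=vis)


def make_task(shoulder, hip, elbow, wrist, knee, ankle, side=Side.LEFT_ARM_RIGHT_LEG, t=None):
    """Build TaskKeypoints directly from per-frame arrays (t from shoulder-hip)."""
    arrs = {k: np.asarray(v, dtype=float) for k, v in
            dict(shoulder=shoulder, hip=hip, elbow=elbow, wrist=wrist, knee=knee, ankle=ankle).items()}
    if t is None:
        t = float(np.mean(np.linalg.norm(arrs["shoulder"] - arrs["hip"], axis=1)))
    return TaskKeypoints(side=side, trunk_length_t=t, **arrs)


@pytest.fixture
def ideal_task():
    """Two frames of the perfect posture: limbs on the extended trunk line."""
    n = 5
    rep = lambda p: np.tile(np.asarray(p, dtype=float), (n, 1))
    return make_task(
        shoulder=rep((100.0, 200.0)), hip=rep((200.0, 200.0)),
        elbow=rep((40.0, 200.0)), wrist=rep((-10.0, 200.0)),
        knee=rep((290.0, 200.0)), ankle=rep((370.0, 200.0)),
    )
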