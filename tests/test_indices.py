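import numpy as np
import pytest

from birddog import (
    MovingDistanceSequence,
    SimulationParams,
    Side,
    UndefinedAngleError,
    ag1,
    ag1_angles,
    ag2,
    ag23_angles,
    ag3,
    compute_index_report,
    moving_distances,
    resolve_task_keypoints,
    simulate_trial,
    spb1,
    spb2,
    spb3,
)

from ._oracles import ag_direct, spb1_direct, spb2_direct, spb3_direct
from .conftest import make_task


def tile(p, n=2):
    return np.tile(np.asarray(p, dtype=float), (n, 1))


def random_task(seed, n=120):
    trial = simulate_trial(SimulationParams(
        duration_s=n / 30.0, sway_amplitude=0.004, droop_deg=12.0, bend_deg=18.0,
        dropout_prob=0.0, outlier_prob=0.0, seed=seed))
    return resolve_task_keypoints(trial.clean_trajectory, trial.true_params.side)


class TestMovingDistances:
    def test_static_posture_gives_zeros(self, ideal_task):
        md = moving_distances(ideal_task)
        assert (md.d == 0).all() and (md.D == 0).all()
        assert md.d.shape == (ideal_task.n_frames - 1, 4)

    def test_single_step_normalized_by_trunk(self):
        elbow = np.array([[0.0, 0.0], [3.0, 0.0]])
        task = make_task(
            shoulder=tile((0, 0)), hip=tile((0, 10)), elbow=elbow,
            wrist=tile((5, 5)), knee=tile((6, 6)), ankle=tile((7, 7)),
        )
        md = moving_distances(task)
        np.testing.assert_allclose(md.d, [[0.3, 0.0, 0.0, 0.0]])
        assert md.D[0] == pytest.approx(0.3)

    def test_unit_diagonal_steps(self):
        wrist = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
        task = make_task(
            shoulder=tile((0, 0), 3), hip=tile((0, 1), 3), elbow=tile((2, 2), 3),
            wrist=wrist, knee=tile((3, 3), 3), ankle=tile((4, 4), 3),
        )
        np.testing.assert_allclose(moving_distances(task).d[:, 1], [1.0, 1.0])

    def test_combined_sequence_conserves_sum(self, default_trial):
        task = resolve_task_keypoints(default_trial.clean_trajectory, Side.LEFT_ARM_RIGHT_LEG)
        md = moving_distances(task)
        np.testing.assert_allclose(md.D, md.d.sum(axis=1), atol=0)


class TestSPB:
    def test_constant_step_means(self):
        d = np.full((10, 4), 0.1)
        md = MovingDistanceSequence(d=d)
        assert spb1(md) == pytest.approx(0.1)
        assert spb2(md) == pytest.approx(0.4)

    def test_spb2_catches_single_jump(self):
        d = np.zeros((10, 4))
        d[4, 2] = 0.5
        assert spb2(MovingDistanceSequence(d=d)) == pytest.approx(0.5)

    def test_spb3_square_excursion(self):
        """Each keypoint tracing the corners of a t-sided square over 4 frames
        gives hull area t^2 per keypoint: (4 * 1) / n = 1."""
        t = 10.0
        square = np.array([[0, 0], [t, 0], [t, t], [0, t]], dtype=float)
        task = make_task(
            shoulder=tile((0, 0), 4), hip=tile((0, t), 4),
            elbow=square, wrist=square + 50, knee=square + 100, ankle=square + 150,
        )
        assert spb3(task) == pytest.approx(1.0)

    def test_spb3_collinear_oscillation_is_zero(self):
        line = np.array([[0.0, 0.0], [5.0, 0.0], [2.5, 0.0], [7.0, 0.0]])
        task = make_task(
            shoulder=tile((0, 0), 4), hip=tile((0, 10), 4),
            elbow=line, wrist=line + 20, knee=line + 40, ankle=line + 60,
        )
        assert spb3(task) == 0.0

    def test_spb2_at_least_four_spb1(self):
        for seed in range(5):
            md = moving_distances(random_task(seed))
            assert spb2(md) >= 4 * spb1(md) - 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_direct_summation_oracles(self, seed):
        task = random_task(seed)
        md = moving_distances(task)
        pts, t = task.limb_points(), task.trunk_length_t
        assert spb1(md) == pytest.approx(spb1_direct(pts, t), abs=1e-9)
        assert spb2(md) == pytest.approx(spb2_direct(pts, t), abs=1e-9)
        assert spb3(task) == pytest.approx(spb3_direct(pts, t), abs=1e-9)


class TestAG1:
    def test_horizontal_limbs_score_zero(self, ideal_task):
        theta1, theta2 = ag1_angles(ideal_task)
        assert (theta1 == 0).all() and (theta2 == 0).all()
        assert ag1(ideal_task) == 0.0

    def test_droop_angle_measured_from_horizontal(self):
        # arm midpoint 45 deg below horizontal, leg 30 deg below
        task = make_task(
            shoulder=tile((100, 100)), hip=tile((200, 100)),
            elbow=tile((100 - 40, 100 + 40)), wrist=tile((100 - 40, 100 + 40)),
            knee=tile((200 + 2 * np.cos(np.radians(30)), 100 + 2 * np.sin(np.radians(30)))),
            ankle=tile((200 + 2 * np.cos(np.radians(30)), 100 + 2 * np.sin(np.radians(30)))),
        )
        theta1, theta2 = ag1_angles(task)
        assert theta1[0] == pytest.approx(45.0)
        assert theta2[0] == pytest.approx(30.0)
        assert ag1(task) == pytest.approx(75.0)

    def test_raised_limb_scores_as_if_drooping(self):
        """Unsigned angles: 30 deg above horizontal scores like 30 below (the
        design blind spot of AG1 that motivates AG2/AG3)."""
        above = make_task(
            shoulder=tile((100, 100)), hip=tile((200, 100)),
            elbow=tile((100 - 40, 100 - 23.09)), wrist=tile((100 - 40, 100 - 23.09)),
            knee=tile((280, 100)), ankle=tile((280, 100)),
        )
        theta1, _ = ag1_angles(above)
        assert theta1[0] == pytest.approx(30.0, abs=0.01)

    def test_coincident_midpoint_excluded_with_warning(self):
        task = make_task(
            shoulder=tile((0, 0), 3), hip=tile((0, 100), 3),
            elbow=np.array([[0.0, 0.0], [-10.0, 0.0], [-10.0, 0.0]]),
            wrist=np.array([[0.0, 0.0], [-30.0, 0.0], [-30.0, 0.0]]),
            knee=tile((50, 100), 3), ankle=tile((90, 100), 3),
        )
        with pytest.warns(UserWarning, match="degenerate"):
            value = ag1(task)
        assert value == pytest.approx(0.0)


class TestAG23:
    def test_ideal_posture_all_phi_zero(self, ideal_task):
        for phi in ag23_angles(ideal_task):
            assert (phi == 0).all()
        assert ag2(ideal_task) == 0.0
        assert ag3(ideal_task) == 0.0

    def test_elbow_above_shoulder_clamps_phi1(self):
        task = make_task(
            shoulder=tile((100, 100)), hip=tile((200, 100)),
            elbow=tile((60, 20)),  # well above the shoulder
            wrist=tile((20, 20)),
            knee=tile((280, 100)), ankle=tile((360, 100)),
        )
        phi1, phi2, phi3, phi4 = ag23_angles(task)
        assert (phi1 == 0).all()
        assert phi2[0] == pytest.approx(0.0)

    def test_droop_and_bend_decompose(self):
        """Shoulder->elbow 30 deg below the extended trunk line and a further
        40 deg of forearm flexion give phi1 = 30, phi3 = 40."""
        sh = np.array([100.0, 100.0])
        u30 = np.array([-np.cos(np.radians(30)), np.sin(np.radians(30))])
        u70 = np.array([-np.cos(np.radians(70)), np.sin(np.radians(70))])
        elbow = sh + 40 * u30
        wrist = elbow + 35 * u70
        task = make_task(
            shoulder=tile(sh), hip=tile((200, 100)),
            elbow=tile(elbow), wrist=tile(wrist),
            knee=tile((280, 100)), ankle=tile((360, 100)),
        )
        phi1, phi2, phi3, phi4 = ag23_angles(task)
        assert phi1[0] == pytest.approx(30.0)
        assert phi3[0] == pytest.approx(40.0)
        assert phi2[0] == pytest.approx(0.0) and phi4[0] == pytest.approx(0.0)

    def test_mean_and_max_of_alternating_phi(self):
        u20 = np.array([np.cos(np.radians(20)), np.sin(np.radians(20))])
        u40 = np.array([np.cos(np.radians(40)), np.sin(np.radians(40))])
        hip = np.array([200.0, 100.0])
        knee = np.stack([hip + 80 * u20, hip + 80 * u40, hip + 80 * u20, hip + 80 * u40])
        ankle = knee + (knee - hip)
        task = make_task(
            shoulder=tile((100, 100), 4), hip=tile(hip, 4),
            elbow=tile((60, 100), 4), wrist=tile((20, 100), 4),
            knee=knee, ankle=ankle,
        )
        # Phi alternates 20, 40 (phi2 only): AG2 = 30, AG3 = 40
        assert ag2(task) == pytest.approx(30.0)
        assert ag3(task) == pytest.approx(40.0)

    def test_ag3_never_below_ag2(self):
        for seed in range(5):
            task = random_task(seed)
            assert ag3(task) >= ag2(task) - 1e-12

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_direct_frame_loop_oracle(self, seed):
        task = random_task(seed, n=90)
        got = (ag1(task), ag2(task), ag3(task))
        expected = ag_direct(task.shoulder, task.hip, task.elbow, task.wrist, task.knee, task.ankle)
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_all_frames_degenerate_raises(self):
        task = make_task(
            shoulder=tile((0, 0)), hip=tile((0, 100)),
            elbow=tile((0, 0)), wrist=tile((0, 0)),
            knee=tile((0, 100)), ankle=tile((0, 100)),
        )
        with pytest.raises(UndefinedAngleError):
            with pytest.warns(UserWarning):
                ag2(task)


class TestInvariances:
    @pytest.fixture
    def task(self):
        # droop deep enough that modest rotations leave every phi clamp
        # inactive (elbow/knee stay clearly below shoulder/hip)
        trial = simulate_trial(SimulationParams(
            duration_s=100 / 30.0, sway_amplitude=0.002, droop_deg=20.0, bend_deg=18.0,
            dropout_prob=0.0, outlier_prob=0.0, seed=9))
        return resolve_task_keypoints(trial.clean_trajectory, trial.true_params.side)

    @staticmethod
    def indices_of(task):
        md = moving_distances(task)
        return np.array([spb1(md), spb2(md), spb3(task), ag1(task), ag2(task), ag3(task)])

    def test_translation_invariance_of_all_six(self, task):
        base = self.indices_of(task)
        shifted = task.transformed(lambda p: p + np.array([314.0, -27.0]))
        np.testing.assert_allclose(self.indices_of(shifted), base, atol=1e-9)

    def test_scale_invariance_of_all_six(self, task):
        base = self.indices_of(task)
        scaled = task.transformed(lambda p: 3.7 * p)
        np.testing.assert_allclose(self.indices_of(scaled), base, atol=1e-9)

    def test_rotation_invariance_of_spb_and_ag23(self, task):
        """A modest rotation (clamp states unchanged: droop keeps the limbs
        below their proximal joints) preserves SPB1-3 and AG2/AG3."""
        base = self.indices_of(task)
        a = np.radians(8.0)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        center = task.hip.mean(axis=0)
        rotated = task.transformed(lambda p: (p - center) @ R.T + center)
        got = self.indices_of(rotated)
        np.testing.assert_allclose(got[:3], base[:3], atol=1e-9)
        np.testing.assert_allclose(got[4:], base[4:], atol=1e-9)

    def test_ag1_is_not_rotation_invariant(self, task):
        """AG1 references the image horizontal.  A rotation that folds one
        limb through horizontal breaks the two-limb cancellation of the
        unsigned angles, so AG1 moves while AG2/AG3 stay put."""
        base = self.indices_of(task)[3]
        a = np.radians(45.0)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        center = task.hip.mean(axis=0)
        rotated = task.transformed(lambda p: (p - center) @ R.T + center)
        assert abs(ag1(rotated) - base) > 5.0


class TestReport:
    def test_static_ideal_posture_is_all_zeros(self, static_trial):
        task = resolve_task_keypoints(static_trial.clean_trajectory, Side.LEFT_ARM_RIGHT_LEG)
        report = compute_index_report(task, fps=30.0)
        assert (report.spb1, report.spb2, report.spb3) == (0.0, 0.0, 0.0)
        assert (report.ag1, report.ag2, report.ag3) == (0.0, 0.0, 0.0)
        assert report.duration_s == pytest.approx(4.0)
        assert report.reliable

    def test_duration_capped_at_sixty_seconds(self):
        n = 2000
        task = make_task(
            shoulder=tile((100, 100), n), hip=tile((200, 100), n),
            elbow=tile((60, 100), n), wrist=tile((20, 100), n),
            knee=tile((280, 100), n), ankle=tile((360, 100), n),
        )
        assert compute_index_report(task, fps=30.0).duration_s == 60.0

    def test_many_degenerate_frames_mark_report_unreliable(self):
        n = 20
        elbow = np.tile([60.0, 100.0], (n, 1))
        elbow[: n // 2] = [100.0, 100.0]  # coincides with the shoulder
        task = make_task(
            shoulder=tile((100, 100), n), hip=tile((200, 100), n),
            elbow=elbow, wrist=tile((20, 100), n),
            knee=tile((280, 100), n), ankle=tile((360, 100), n),
        )
        report = compute_index_report(task, fps=30.0)
        assert not report.reliable
        assert report.excluded_ag23_frames == n // 2

    def test_report_round_trips_through_json(self, tmp_path, static_trial):
        task = resolve_task_keypoints(static_trial.clean_trajectory, Side.LEFT_ARM_RIGHT_LEG)
        report = compute_index_report(task, fps=30.0)
        path = tmp_path / "r.json"
        report.write_json(path)
        import json

        payload = json.loads(path.read_text())
        assert payload["side"] == "left_arm_right_leg"
        assert payload["spb1"] == 0.0 and payload["ag3"] == 0.0
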