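"""Simulator correctness: trajectories, forward kinematics, projection, noise."""

import numpy as np
import pytest

from gaitkin import (CameraConfig, FourierTrajectory, GaitModelParams,
                     MarkerSeries, NoiseModel, TRACKED_SUBSET, corrupt,
                     default_camera, default_noise, forward_kinematics,
                     generate_trajectories, project, simulate_study)
from gaitkin.errors import ConfigError, DataError
from gaitkin.kinematics import JointAngleSeries


class TestTrajectories:
    def test_periodic_to_machine_precision(self, short_params):
        angles = generate_trajectories(short_params, fps=120.0)
        period = int(round(120.0 / short_params.cadence))
        np.testing.assert_allclose(angles.data[:-period], angles.data[period:],
                                   atol=1e-9)

    def test_right_is_left_shifted_half_period(self, short_params):
        angles = generate_trajectories(short_params, fps=120.0)
        half = int(round(0.5 * 120.0 / short_params.cadence))
        np.testing.assert_allclose(angles.data[:-half, 1, :],
                                   angles.data[half:, 0, :], atol=1e-9)

    def test_zero_amplitudes_give_constant_means(self):
        flat = FourierTrajectory(5.0, (0.0,), (0.0,))
        params = GaitModelParams(duration=2.0, hip_traj=flat, knee_traj=flat,
                                 ankle_traj=flat)
        angles = generate_trajectories(params, fps=30.0)
        np.testing.assert_allclose(angles.data, 5.0, atol=1e-12)

    def test_no_harmonics_anywhere_is_degenerate(self):
        empty = FourierTrajectory(5.0, (), ())
        with pytest.raises(ConfigError, match="degenerate"):
            GaitModelParams(hip_traj=empty, knee_traj=empty, ankle_traj=empty)

    def test_gait_like_ranges(self):
        angles = generate_trajectories(GaitModelParams(duration=5.0), fps=120.0)
        hip = angles.data[:, 0, 0]
        knee = angles.data[:, 0, 1]
        ankle = angles.data[:, 0, 2]
        assert -15 < hip.min() < 0 and 25 < hip.max() < 40
        assert 0 <= knee.min() < 15 and 55 < knee.max() < 70
        assert -20 < ankle.min() < -8 and 5 < ankle.max() < 18


class TestForwardKinematics:
    def _angles(self, hip=0.0, knee=0.0, ankle=0.0, n=4):
        data = np.zeros((n, 2, 3))
        data[:, :, 0], data[:, :, 1], data[:, :, 2] = hip, knee, ankle
        return JointAngleSeries(fps=30.0, times=np.arange(n) / 30.0, data=data)

    def test_neutral_pose_geometry(self):
        p = GaitModelParams()
        mk = forward_kinematics(self._angles(), p)
        col = {n: i for i, n in enumerate(TRACKED_SUBSET)}
        hip = mk.positions[0, col["left_hip"]]
        knee = mk.positions[0, col["left_knee"]]
        ankle = mk.positions[0, col["left_ankle"]]
        toe = mk.positions[0, col["left_foot_index"]]
        assert knee[0] == pytest.approx(hip[0]) and ankle[0] == pytest.approx(hip[0])
        assert hip[1] - knee[1] == pytest.approx(p.thigh)
        assert knee[1] - ankle[1] == pytest.approx(p.shank)
        assert toe[0] - ankle[0] == pytest.approx(p.foot)  # horizontal foot
        assert toe[1] == pytest.approx(ankle[1])

    def test_bent_knee_matches_two_link_chain_oracle(self):
        p = GaitModelParams()
        mk = forward_kinematics(self._angles(knee=30.0), p)
        col = {n: i for i, n in enumerate(TRACKED_SUBSET)}
        # independent 2-link chain: thigh vertical down, shank rotated 30 deg
        hip = np.array([0.0, p.hip_height])
        knee = hip + p.thigh * np.array([np.cos(-np.pi / 2), np.sin(-np.pi / 2)])
        phi_shank = -np.pi / 2 - np.radians(30.0)
        ankle = knee + p.shank * np.array([np.cos(phi_shank), np.sin(phi_shank)])
        np.testing.assert_allclose(mk.positions[0, col["left_ankle"], :2], ankle,
                                   atol=1e-12)

    def test_sides_differ_only_in_z_sign(self):
        p = GaitModelParams()
        mk = forward_kinematics(self._angles(hip=12.0, knee=25.0, ankle=-5.0), p)
        col = {n: i for i, n in enumerate(TRACKED_SUBSET)}
        for part in ("hip", "knee", "ankle", "heel", "foot_index"):
            left = mk.positions[0, col[f"left_{part}"]]
            right = mk.positions[0, col[f"right_{part}"]]
            np.testing.assert_allclose(left[:2], right[:2], atol=1e-12)
            assert left[2] == pytest.approx(-right[2])


def _segment_markers(phi_deg, length=0.4):
    """Two-marker series: a sagittal segment at elevation phi."""
    d = length * np.array([np.cos(np.radians(phi_deg)),
                           np.sin(np.radians(phi_deg)), 0.0])
    pos = np.stack([np.stack([np.array([0.0, 1.0, 0.0]),
                              np.array([0.0, 1.0, 0.0]) + d])] * 3)
    return MarkerSeries(fps=30.0, times=np.arange(3) / 30.0, positions=pos,
                        names=("left_hip", "left_knee"))


def _projected_segment_angle(pose):
    i = pose.index("left_hip")
    j = pose.index("left_knee")
    du = pose.points[0, j, 0] - pose.points[0, i, 0]
    dv = pose.points[0, j, 1] - pose.points[0, i, 1]
    return np.degrees(np.arctan2(-dv, du))  # pixel y points down


class TestProjection:
    def test_lateral_orthographic_is_affine(self, lateral_clean):
        params, angles, markers, cam, pose = lateral_clean
        # pixel coordinates are an affine image of world (anterior, up)
        col = list(markers.names).index("left_knee")
        k = pose.index("left_knee")
        wx = markers.positions[::4, col, 0][:pose.n_frames]
        px = pose.points[:, k, 0]
        np.testing.assert_allclose(px - px[0], cam.ortho_scale * (wx - wx[0]),
                                   atol=1e-9)

    @pytest.mark.parametrize("alpha", [0.0, 30.0, 45.0, 60.0])
    def test_foreshortening_closed_form(self, alpha):
        for phi in range(-80, 81, 10):
            cam = CameraConfig(azimuth=90.0 - alpha, model="orthographic")
            pose = project(_segment_markers(phi), cam)
            expected = np.degrees(np.arctan2(
                np.sin(np.radians(phi)),
                np.cos(np.radians(phi)) * np.cos(np.radians(alpha))))
            assert _projected_segment_angle(pose) == pytest.approx(expected,
                                                                   abs=0.2)

    def test_pinhole_size_halves_with_doubled_distance(self):
        mk = _segment_markers(0.0)
        near = project(mk, CameraConfig(distance=3.0))
        far = project(mk, CameraConfig(distance=6.0))
        size_near = abs(near.points[0, near.index("left_knee"), 0]
                        - near.points[0, near.index("left_hip"), 0])
        size_far = abs(far.points[0, far.index("left_knee"), 0]
                       - far.points[0, far.index("left_hip"), 0])
        assert size_near / size_far == pytest.approx(2.0, rel=0.01)

    def test_point_behind_camera_rejected(self):
        mk = _segment_markers(0.0)
        mk.positions[:, :, 0] += 10.0  # beyond a front-facing camera
        with pytest.raises(DataError, match="behind"):
            project(mk, CameraConfig(azimuth=0.0))

    def test_untracked_landmarks_marked_missing(self, lateral_clean):
        *_, pose = lateral_clean
        assert pose.missing[:, pose.index("nose")].all()
        assert not pose.missing[:, pose.index("left_knee")].any()


class TestCorrupt:
    def test_zero_noise_is_identity(self, lateral_clean):
        *_, cam, pose = lateral_clean
        clean = NoiseModel(pixel_sigma_near=0.0, pixel_sigma_far=0.0,
                           dropout_prob_far=0.0)
        out = corrupt(pose, clean, cam)
        np.testing.assert_array_equal(out.points[~out.missing],
                                      pose.points[~pose.missing])

    def test_far_side_jitter_exceeds_near(self, lateral_clean):
        params, angles, markers, cam, _ = lateral_clean
        long_params = GaitModelParams(duration=60.0)
        long_angles = generate_trajectories(long_params, fps=120.0)
        mk = forward_kinematics(long_angles, long_params)
        pose = project(mk, cam)
        noise = NoiseModel(pixel_sigma_near=1.0, pixel_sigma_far=3.0,
                           dropout_prob_far=0.0, seed=42)
        noisy = corrupt(pose, noise, cam)
        resid = noisy.points - pose.points
        sd_near = np.nanstd(resid[:, pose.index("left_knee"), 0])
        sd_far = np.nanstd(resid[:, pose.index("right_knee"), 0])
        assert sd_far > sd_near

    def test_same_seed_bit_identical(self, lateral_clean):
        *_, cam, pose = lateral_clean
        noise = default_noise("P3", seed=7)
        a = corrupt(pose, noise, cam)
        b = corrupt(pose, noise, cam)
        np.testing.assert_array_equal(a.points, b.points)
        np.testing.assert_array_equal(a.missing, b.missing)


class TestSimulateStudy:
    def test_file_counts_and_frame_counts(self, tmp_path):
        positions = {lab: default_camera(lab) for lab in ("P1", "P3")}
        manifest = simulate_study(tmp_path / "s", cohort_n=2, positions=positions,
                                  duration=60.0, seed=3)
        assert len(manifest["subjects"]) == 2
        pose_files = sorted((tmp_path / "s" / "pose").glob("*.csv"))
        ref_files = sorted((tmp_path / "s" / "ref").glob("*_markers.csv"))
        assert len(pose_files) == 4 and len(ref_files) == 2
        import pandas as pd
        assert len(pd.read_csv(pose_files[0])) == 1800  # 60 s at 30 fps

    def test_identical_seeds_byte_identical(self, tmp_path):
        for d in ("a", "b"):
            simulate_study(tmp_path / d, cohort_n=1, duration=5.0, seed=9,
                           positions={"P3": default_camera("P3")})
        fa = (tmp_path / "a" / "pose" / "S01_P3.csv").read_bytes()
        fb = (tmp_path / "b" / "pose" / "S01_P3.csv").read_bytes()
        assert fa == fb
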