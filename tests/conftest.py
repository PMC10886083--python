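import numpy as np
import pytest

from gaitkin import (BLAZEPOSE_33, TRACKED_SUBSET, BodyFrameSeries,
                     CameraConfig, GaitModelParams, PoseSeries, TrialMetadata,
                     forward_kinematics, generate_trajectories, project,
                     to_body_frame)


def make_pose(n=5, fps=30.0, seed=0, visibility=False) -> PoseSeries:
    """A plausible upright pose in image coordinates (y down, walking +x)."""
    rng = np.random.default_rng(seed)
    points = np.zeros((n, 33, 2))
    base_y = {"shoulder": 300.0, "hip": 600.0, "knee": 800.0, "ankle": 1000.0,
              "heel": 1030.0, "foot_index": 1020.0}
    for j, name in enumerate(BLAZEPOSE_33):
        y = 200.0
        for part, py in base_y.items():
            if name.endswith(part):
                y = py
        x = 500.0 + (30.0 if name.endswith("foot_index") else 0.0)
        points[:, j, 0] = x + rng.normal(0, 2, n)
        points[:, j, 1] = y + rng.normal(0, 2, n)
    vis = np.full((n, 33), 0.95) if visibility else None
    return PoseSeries(fps=fps, times=np.arange(n) / fps, points=points,
                      missing=np.zeros((n, 33), bool), visibility=vis,
                      meta=TrialMetadata(subject_id="T01", camera_position="P3"))


def make_body(trace, landmark="left_knee", fps=30.0, missing=None) -> BodyFrameSeries:
    """Body-frame series with one landmark's x following `trace`."""
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    joints = np.zeros((n, 12, 2))
    base = {"shoulder": 1.4, "hip": 0.9, "knee": 0.5, "ankle": 0.1,
            "heel": 0.05, "foot_index": 0.05}
    for j, name in enumerate(TRACKED_SUBSET):
        part = name.split("_", 1)[1]
        joints[:, j, 0] = 0.2 if part == "foot_index" else 0.0
        joints[:, j, 1] = base[part]
    k = TRACKED_SUBSET.index(landmark)
    joints[:, k, 0] = trace
    miss = np.zeros((n, 12), bool)
    if missing is not None:
        miss[np.asarray(missing, dtype=int), k] = True
        joints[miss] = np.nan
    return BodyFrameSeries(fps=fps, times=np.arange(n) / fps, joints=joints,
                           missing=miss)


@pytest.fixture(scope="session")
def short_params():
    return GaitModelParams(duration=10.0, cadence=1.0)


@pytest.fixture(scope="session")
def lateral_clean(short_params):
    """Noise-free lateral orthographic observation of a 10 s gait."""
    angles = generate_trajectories(short_params, fps=120.0)
    markers = forward_kinematics(angles, short_params)
    cam = CameraConfig(azimuth=90.0, model="orthographic", fps=30.0)
    pose = project(markers, cam)
    return short_params, angles, markers, cam, pose


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """Scaled-down cohort study: 10 subjects x 5 positions x 60 s."""
    from gaitkin import simulate_study
    out = tmp_path_factory.mktemp("study")
    simulate_study(out, cohort_n=10, duration=60.0, seed=20)
    return out


@pytest.fixture(scope="session")
def study_summary(study_dir):
    from gaitkin import PipelineConfig, run_pipeline
    return run_pipeline(PipelineConfig(study_dir=str(study_dir)))
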