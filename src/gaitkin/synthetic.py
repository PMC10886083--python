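"""Synthetic treadmill gait with paired reference and camera observations.

This module generates everything the pipeline consumes, with known ground
truth, emulating the validation-study design it is built to analyse:

* quasi-periodic sagittal hip/knee/ankle trajectories at a self-selected
  cadence (~1 cycle/s), parameterized as truncated Fourier series over
  cycle phase, for ~1 min trials (~50-60 gait cycles);
* a planar forward-kinematic link chain (trunk fixed vertical in the
  treadmill frame, thigh-shank-foot per side, right leg half a cycle out
  of phase) giving 3D joint-center "marker" positions at 120 fps;
* a camera model (pinhole or orthographic) placed 3 m away at 0.8 m
  height at configurable azimuths around the subject, sampling at 30 fps;
* a landmark noise model with side-dependent Gaussian pixel jitter,
  inflated noise and dropouts for the camera-far leg while the legs
  overlap in projection — the mechanism behind the far-side accuracy loss
  seen when one leg occludes the other during crossover.

The camera-position labels P1..P5 map to azimuths around the lateral
(side-on) view: P1/P2 front-diagonal, P3 purely lateral, P4/P5 rear.
The default azimuths deviate moderately from lateral (see
:data:`STUDY_AZIMUTHS`): a raw geometric projection has no learned pose
prior and therefore foreshortens off-axis segments far more than a
trained landmark detector does in practice, so strongly oblique default
views would leave the simulated observations outside the operating
regime of the real system. Steeper geometries remain available through
:class:`CameraConfig`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError, DataError
from .events import GaitEvents
from .io import (BLAZEPOSE_33, TRACKED_SUBSET, MarkerSeries, PoseSeries,
                 TrialMetadata, write_marker_csv, write_pose_csv)
from .kinematics import JOINTS, SIDES, JointAngleSeries

__all__ = ["FourierTrajectory", "GaitModelParams", "CameraConfig", "NoiseModel",
           "generate_trajectories", "forward_kinematics", "project", "corrupt",
           "ground_truth_events", "simulate_study", "STUDY_AZIMUTHS",
           "default_camera", "default_noise", "default_params_sampler"]


@dataclass(frozen=True)
class FourierTrajectory:
    """Periodic angle trajectory theta(p) over cycle phase p in [0, 1).

    theta(p) = mean + sum_k amps[k] * cos(2*pi*(k+1)*p + phases[k]), degrees.
    """

    mean: float
    amps: tuple[float, ...]
    phases: tuple[float, ...]

    def __call__(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        out = np.full_like(p, self.mean)
        for k, (a, ph) in enumerate(zip(self.amps, self.phases)):
            out = out + a * np.cos(2.0 * np.pi * (k + 1) * p + ph)
        return out

    def scaled(self, amp_scale: float = 1.0, mean_shift: float = 0.0) -> "FourierTrajectory":
        return FourierTrajectory(self.mean + mean_shift,
                                 tuple(a * amp_scale for a in self.amps),
                                 self.phases)


# Default gait-like trajectories (3 harmonics), phase 0 ~ ipsilateral heel
# strike. Ranges: hip ~ -10..+30 deg, knee ~ 0..65 deg, ankle ~ -15..+12 deg.
DEFAULT_HIP = FourierTrajectory(10.0, (19.0, 4.0, 1.2), (0.25, 2.30, 1.00))
DEFAULT_KNEE = FourierTrajectory(22.0, (25.0, 12.0, 3.0), (-4.52, -2.76, -1.01))
DEFAULT_ANKLE = FourierTrajectory(-2.0, (7.0, 7.5, 2.0), (2.80, 0.20, -1.40))


@dataclass(frozen=True)
class GaitModelParams:
    """Segment geometry and gait trajectory parameters (lengths in m)."""

    trunk: float = 0.50
    thigh: float = 0.41
    shank: float = 0.42
    foot: float = 0.24
    heel_offset: float = 0.07
    pelvis_half_width: float = 0.12
    hip_height: float = 0.90
    cadence: float = 1.0          # gait cycles per second
    duration: float = 60.0        # seconds
    phase_offset_right: float = 0.5
    hip_traj: FourierTrajectory = DEFAULT_HIP
    knee_traj: FourierTrajectory = DEFAULT_KNEE
    ankle_traj: FourierTrajectory = DEFAULT_ANKLE
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("trunk", "thigh", "shank", "foot", "heel_offset",
                     "pelvis_half_width", "hip_height"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"segment length {name} must be positive")
        if self.cadence <= 0 or self.duration <= 0:
            raise ConfigError("cadence and duration must be positive")
        if all(len(t.amps) == 0 for t in (self.hip_traj, self.knee_traj, self.ankle_traj)):
            raise ConfigError("degenerate gait: no harmonics in any joint trajectory")


@dataclass(frozen=True)
class CameraConfig:
    """A camera around the subject.

    ``azimuth`` is measured in the ground plane from the subject's
    anterior direction toward the camera side: 90 deg is a pure lateral
    view, smaller values front-diagonal, larger values rear-diagonal.
    ``side`` is the side of the subject the camera stands on.
    """

    azimuth: float = 90.0
    distance: float = 3.0
    height: float = 0.8
    fps: float = 30.0
    resolution: tuple[int, int] = (1080, 2340)  # width, height (portrait phone)
    model: str = "pinhole"
    side: str = "left"
    focal_px: float = 1500.0
    ortho_scale: float = 600.0    # pixels per metre

    def __post_init__(self) -> None:
        if self.distance <= 0 or self.fps <= 0:
            raise ConfigError("camera distance and fps must be positive")
        if self.model not in ("pinhole", "orthographic"):
            raise ConfigError("camera model must be 'pinhole' or 'orthographic'")
        if self.side not in SIDES:
            raise ConfigError("camera side must be 'left' or 'right'")


@dataclass(frozen=True)
class NoiseModel:
    """Side-dependent Gaussian landmark jitter with crossover occlusion.

    ``pixel_sigma_near``/``pixel_sigma_far`` are jitter SDs (pixels) for
    the camera-near and camera-far side; during frames where the
    projected ankle/toe horizontal separation falls below
    ``overlap_threshold_px`` the far-side sigma is multiplied by
    ``occlusion_boost`` and far-side landmarks drop out with probability
    ``dropout_prob_far``. ``landmark_scales`` multiplies the sigma of
    individual landmarks (e.g. noisier toes than hips).
    """

    pixel_sigma_near: float = 2.0
    pixel_sigma_far: float = 3.2
    occlusion_boost: float = 3.0
    dropout_prob_far: float = 0.1
    overlap_threshold_px: float = 40.0
    landmark_scales: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_sigma_near < 0 or self.pixel_sigma_far < 0:
            raise ConfigError("sigmas must be >= 0")
        if not 0 <= self.dropout_prob_far <= 1:
            raise ConfigError("dropout_prob_far must be in [0, 1]")
        if self.occlusion_boost < 1:
            raise ConfigError("occlusion_boost must be >= 1")


#: Declared P1..P5 -> azimuth mapping (degrees; 90 = lateral).
STUDY_AZIMUTHS = {"P1": 70.0, "P2": 80.0, "P3": 90.0, "P4": 100.0, "P5": 110.0}


def default_camera(label: str, side: str = "left", model: str = "pinhole") -> CameraConfig:
    """Study-geometry camera for a position label (3 m, 0.8 m, 30 fps)."""
    if label not in STUDY_AZIMUTHS:
        raise ConfigError(f"unknown camera position {label!r}")
    return CameraConfig(azimuth=STUDY_AZIMUTHS[label], side=side, model=model)


# Per-position landmark jitter defaults (pixels, camera-near side).
# Proximal landmarks (shoulder/hip/knee) are detected best at the front
# diagonal P2; foot landmarks (ankle/heel/toe) best at the lateral P3 and
# degrade sharply behind the subject (P5), where crossover occlusion of
# the far foot is most damaging.
_POSITION_NOISE = {
    #        prox_sigma  foot_sigma  dropout_far
    "P1": (3.5, 5.0, 0.10),
    "P2": (1.2, 4.0, 0.10),
    "P3": (3.0, 1.2, 0.10),
    "P4": (4.5, 6.0, 0.20),
    "P5": (5.5, 8.0, 0.30),
}
_FOOT_LANDMARKS = ("left_ankle", "right_ankle", "left_heel", "right_heel",
                   "left_foot_index", "right_foot_index")


def default_noise(label: str, seed: int = 0) -> NoiseModel:
    """Study-condition noise model for a camera position label."""
    prox, foot, dropout = _POSITION_NOISE[label]
    scales = {name: foot / prox for name in _FOOT_LANDMARKS}
    return NoiseModel(pixel_sigma_near=prox, pixel_sigma_far=1.6 * prox,
                      occlusion_boost=3.0, dropout_prob_far=dropout,
                      landmark_scales=scales, seed=seed)


# ---------------------------------------------------------------------------
# Trajectory generation and forward kinematics
# ---------------------------------------------------------------------------

def generate_trajectories(params: GaitModelParams, fps: float = 120.0) -> JointAngleSeries:
    """Ground-truth joint angles for both sides at the reference frame rate."""
    n = int(round(params.duration * fps))
    times = np.arange(n) / fps
    data = np.empty((n, 2, 3))
    for s, side in enumerate(SIDES):
        off = 0.0 if side == "left" else params.phase_offset_right
        p = np.mod(params.cadence * times + off, 1.0)
        data[:, s, 0] = params.hip_traj(p)
        data[:, s, 1] = params.knee_traj(p)
        data[:, s, 2] = params.ankle_traj(p)
    meta = TrialMetadata(camera_position="REF", duration=params.duration)
    return JointAngleSeries(fps=fps, times=times, data=data, source="mocap", meta=meta)


def forward_kinematics(angles: JointAngleSeries, params: GaitModelParams) -> MarkerSeries:
    """Place 3D joint-center positions from joint-angle trajectories.

    The trunk is fixed vertical at the origin (treadmill frame: no net
    translation); segment directions chain exactly per the conventions of
    :mod:`gaitkin.kinematics`, so recomputing angles from a lateral
    projection recovers the inputs.
    """
    n = angles.n_frames
    pos = np.empty((n, len(TRACKED_SUBSET), 3))
    col = {name: i for i, name in enumerate(TRACKED_SUBSET)}
    for s, side in enumerate(SIDES):
        z = params.pelvis_half_width * (1.0 if side == "left" else -1.0)
        th_hip = np.radians(angles.data[:, s, 0])
        th_knee = np.radians(angles.data[:, s, 1])
        th_ankle = np.radians(angles.data[:, s, 2])
        phi_thigh = -np.pi / 2 + th_hip
        phi_shank = phi_thigh - th_knee
        phi_foot = th_ankle + phi_shank + np.pi / 2

        hip = np.column_stack([np.zeros(n), np.full(n, params.hip_height)])
        shoulder = hip + [0.0, params.trunk]
        knee = hip + params.thigh * np.column_stack([np.cos(phi_thigh), np.sin(phi_thigh)])
        ankle = knee + params.shank * np.column_stack([np.cos(phi_shank), np.sin(phi_shank)])
        foot_dir = np.column_stack([np.cos(phi_foot), np.sin(phi_foot)])
        toe = ankle + params.foot * foot_dir
        heel = ankle - params.heel_offset * foot_dir

        for name, xy in (("shoulder", shoulder), ("hip", hip), ("knee", knee),
                         ("ankle", ankle), ("heel", heel), ("foot_index", toe)):
            j = col[f"{side}_{name}"]
            pos[:, j, :2] = xy
            pos[:, j, 2] = z
    meta = replace(angles.meta)
    return MarkerSeries(fps=angles.fps, times=angles.times.copy(), positions=pos,
                        names=TRACKED_SUBSET, meta=meta)


def _heel_strike_phase(params: GaitModelParams, what: str = "heel") -> float:
    """Cycle phase of max anterior heel excursion (or min toe excursion)."""
    p = np.linspace(0.0, 1.0, 4096, endpoint=False)
    angs = np.stack([params.hip_traj(p), params.knee_traj(p), params.ankle_traj(p)], axis=1)
    dummy = JointAngleSeries(fps=1.0, times=np.arange(len(p), dtype=float),
                             data=np.stack([angs, angs], axis=1))
    mk = forward_kinematics(dummy, params)
    if what == "heel":
        sig = mk.positions[:, list(TRACKED_SUBSET).index("left_heel"), 0]
        return float(p[np.argmax(sig)])
    sig = mk.positions[:, list(TRACKED_SUBSET).index("left_foot_index"), 0]
    return float(p[np.argmin(sig)])


def ground_truth_events(params: GaitModelParams, fps: float) -> GaitEvents:
    """Exact heel-strike/toe-off frame indices implied by the gait model.

    Events are the frames nearest the phase of extreme anterior heel
    (toe) excursion of the analytic forward-kinematic model.
    """
    n = int(round(params.duration * fps))
    p_hs = _heel_strike_phase(params, "heel")
    p_to = _heel_strike_phase(params, "toe")
    ev = GaitEvents(method="simulator-ground-truth")
    for side in SIDES:
        off = 0.0 if side == "left" else params.phase_offset_right
        out = {}
        for name, p_event in (("hs", p_hs), ("to", p_to)):
            ks = np.arange(-1, int(np.ceil(params.duration * params.cadence)) + 2)
            t = (p_event - off + ks) / params.cadence
            frames = np.round(t * fps).astype(int)
            frames = frames[(frames >= 0) & (frames < n)]
            out[name] = np.unique(frames)
        ev.heel_strikes[side] = out["hs"]
        ev.toe_offs[side] = out["to"]
    return ev


# ---------------------------------------------------------------------------
# Camera projection and landmark corruption
# ---------------------------------------------------------------------------

def _camera_basis(camera: CameraConfig):
    th = np.radians(camera.azimuth)
    lateral = 1.0 if camera.side == "left" else -1.0
    cam_pos = np.array([camera.distance * np.cos(th), camera.height,
                        lateral * camera.distance * np.sin(th)])
    fwd = -np.array([np.cos(th), 0.0, lateral * np.sin(th)])  # horizontal axis
    right = np.cross(fwd, np.array([0.0, 1.0, 0.0]))
    right /= np.linalg.norm(right)
    up = np.cross(right, fwd)
    return cam_pos, right, up, fwd


def project(markers: MarkerSeries, camera: CameraConfig,
            meta: TrialMetadata | None = None) -> PoseSeries:
    """Project 3D landmarks to noise-free pixel coordinates at camera fps.

    Marker positions are linearly interpolated onto the camera's time
    grid first; pixel y points down (image convention). Landmarks outside
    the tracked subset are emitted as missing. Pinhole projection raises
    :class:`DataError` for points at or behind the camera plane.
    """
    t0, t1 = markers.times[0], markers.times[-1]
    n_new = int(np.floor((t1 - t0) * camera.fps + 1e-9)) + 1
    times = t0 + np.arange(n_new) / camera.fps
    flat = markers.positions.reshape(markers.n_frames, -1)
    interp = np.empty((n_new, flat.shape[1]))
    for c in range(flat.shape[1]):
        interp[:, c] = np.interp(times, markers.times, flat[:, c])
    world = interp.reshape(n_new, len(markers.names), 3)

    cam_pos, right, up, fwd = _camera_basis(camera)
    cx, cy = camera.resolution[0] / 2.0, camera.resolution[1] / 2.0
    rel = world - cam_pos
    u_comp = rel @ right
    v_comp = rel @ up
    if camera.model == "orthographic":
        u = cx + camera.ortho_scale * (world @ right)
        v = cy - camera.ortho_scale * (world @ up)
    else:
        depth = rel @ fwd
        if np.any(depth <= 1e-6):
            raise DataError("landmark at or behind the camera plane")
        u = cx + camera.focal_px * u_comp / depth
        v = cy - camera.focal_px * v_comp / depth

    points = np.full((n_new, 33, 2), np.nan)
    missing = np.ones((n_new, 33), dtype=bool)
    for j, name in enumerate(markers.names):
        k = BLAZEPOSE_33.index(name)
        points[:, k, 0] = u[:, j]
        points[:, k, 1] = v[:, j]
        missing[:, k] = False
    if meta is None:
        meta = replace(markers.meta, camera_position="P3", camera_side=camera.side)
    return PoseSeries(fps=camera.fps, times=times, points=points, missing=missing,
                      meta=meta)


def corrupt(series: PoseSeries, noise: NoiseModel, camera: CameraConfig) -> PoseSeries:
    """Add side-dependent landmark jitter and crossover occlusion dropouts.

    Deterministic for a given ``noise.seed``. With all sigmas and the
    dropout probability zero the series is returned unchanged (copy).
    """
    rng = np.random.default_rng(noise.seed)
    points = series.points.copy()
    missing = series.missing.copy()
    n = series.n_frames
    far_side = "right" if camera.side == "left" else "left"

    # overlap: horizontal pixel separation of the feet below threshold
    la = points[:, BLAZEPOSE_33.index("left_ankle"), 0]
    ra = points[:, BLAZEPOSE_33.index("right_ankle"), 0]
    lt = points[:, BLAZEPOSE_33.index("left_foot_index"), 0]
    rt = points[:, BLAZEPOSE_33.index("right_foot_index"), 0]
    with np.errstate(invalid="ignore"):
        sep = np.fmin(np.abs(la - ra), np.abs(lt - rt))
    overlap = sep < noise.overlap_threshold_px

    jitter = rng.standard_normal((n, 33, 2))
    dropout_draw = rng.random((n, 33))
    for name in TRACKED_SUBSET:
        k = BLAZEPOSE_33.index(name)
        far = name.startswith(far_side)
        sigma = noise.pixel_sigma_far if far else noise.pixel_sigma_near
        sigma = sigma * noise.landmark_scales.get(name, 1.0)
        sig = np.full(n, sigma)
        if far:
            sig[overlap] *= noise.occlusion_boost
        points[:, k, :] += sig[:, None] * jitter[:, k, :]
        if far and noise.dropout_prob_far > 0:
            drop = overlap & (dropout_draw[:, k] < noise.dropout_prob_far)
            points[drop, k, :] = np.nan
            missing[drop, k] = True
    return PoseSeries(fps=series.fps, times=series.times.copy(), points=points,
                      missing=missing, visibility=None, schema=series.schema,
                      meta=series.meta)


# ---------------------------------------------------------------------------
# Study simulation
# ---------------------------------------------------------------------------

def default_params_sampler(rng: np.random.Generator,
                           duration: float = 60.0) -> GaitModelParams:
    """Draw per-subject gait parameters: cadence, stature and style jitter."""
    scale = rng.normal(1.0, 0.03)
    return GaitModelParams(
        thigh=0.41 * scale, shank=0.42 * scale, foot=0.24 * scale,
        trunk=0.50 * scale, hip_height=0.90 * scale,
        cadence=float(rng.uniform(0.85, 1.15)),
        duration=duration,
        hip_traj=DEFAULT_HIP.scaled(rng.normal(1.0, 0.08), rng.normal(0.0, 1.5)),
        knee_traj=DEFAULT_KNEE.scaled(rng.normal(1.0, 0.08), rng.normal(0.0, 1.5)),
        ankle_traj=DEFAULT_ANKLE.scaled(rng.normal(1.0, 0.08), rng.normal(0.0, 1.0)),
    )


def simulate_study(out_dir: str | Path, cohort_n: int = 10,
                   positions: dict[str, CameraConfig] | None = None,
                   params_sampler=default_params_sampler,
                   noise_sampler=default_noise,
                   duration: float = 60.0, ref_fps: float = 120.0,
                   seed: int = 0) -> dict:
    """Write a full paired synthetic study to ``out_dir``.

    Per subject: one 120 fps reference marker CSV (+ ground-truth angles
    and events) and one corrupted 30 fps pose CSV per camera position,
    each with a JSON metadata sidecar. Returns the manifest (also written
    as ``manifest.json``). Fully reproducible from ``seed``.
    """
    out_dir = Path(out_dir)
    (out_dir / "ref").mkdir(parents=True, exist_ok=True)
    (out_dir / "pose").mkdir(parents=True, exist_ok=True)
    if positions is None:
        positions = {label: default_camera(label) for label in STUDY_AZIMUTHS}

    master = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "cohort_n": cohort_n, "duration": duration,
                      "ref_fps": ref_fps,
                      "positions": {k: dataclasses.asdict(v) for k, v in positions.items()},
                      "subjects": []}
    for i in range(cohort_n):
        sid = f"S{i + 1:02d}"
        sub_rng = np.random.default_rng(master.integers(2**31))
        params = params_sampler(sub_rng, duration=duration)
        angles = generate_trajectories(params, fps=ref_fps)
        angles.meta.subject_id = sid
        markers = forward_kinematics(angles, params)
        truth = ground_truth_events(params, fps=positions[next(iter(positions))].fps)

        ref_csv = out_dir / "ref" / f"{sid}_markers.csv"
        write_marker_csv(markers, ref_csv)
        markers.meta.duration = duration
        markers.meta.to_json(ref_csv.with_suffix(".json"))
        angles.to_frame().to_csv(out_dir / "ref" / f"{sid}_angles.csv", index=False)
        (out_dir / "ref" / f"{sid}_events.json").write_text(json.dumps(
            {side: {"heel_strikes": truth.heel_strikes[side].tolist(),
                    "toe_offs": truth.toe_offs[side].tolist()} for side in SIDES},
            indent=2) + "\n")

        entry = {"subject_id": sid, "cadence": params.cadence,
                 "ref_markers": str(ref_csv.relative_to(out_dir)), "pose": {}}
        for label, cam in positions.items():
            meta = TrialMetadata(subject_id=sid, camera_position=label,
                                 camera_side=cam.side, duration=duration)
            clean = project(markers, cam, meta=meta)
            noise = noise_sampler(label, seed=int(sub_rng.integers(2**31)))
            noisy = corrupt(clean, noise, cam)
            pose_csv = out_dir / "pose" / f"{sid}_{label}.csv"
            write_pose_csv(noisy, pose_csv)
            meta.to_json(pose_csv.with_suffix(".json"))
            entry["pose"][label] = str(pose_csv.relative_to(out_dir))
        manifest["subjects"].append(entry)

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
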