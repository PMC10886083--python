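"""Reading, validating and writing landmark / marker time series.

The pipeline consumes per-frame 2D pose landmarks exported as CSV by a
33-keypoint human-pose-estimation model (BlazePose layout), and reference
marker trajectories from an optical motion-capture system (CSV or TRC).
Both are mapped into a common *body frame* — y up, the subject's anterior
direction +x — which is the substrate for all kinematic computation.

Pixel coordinates follow the standard video convention (origin top-left,
y down); the body-frame conversion flips axes based on anatomical
plausibility checks (shoulders above hips, toes anterior of heels), so it
is robust to camera side and mirrored footage and is idempotent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, SchemaError

#: The 33 landmark names of the BlazePose full-body topology, in model order.
BLAZEPOSE_33: tuple[str, ...] = (
    "nose",
    "left_eye_inner", "left_eye", "left_eye_outer",
    "right_eye_inner", "right_eye", "right_eye_outer",
    "left_ear", "right_ear",
    "mouth_left", "mouth_right",
    "left_shoulder", "right_shoulder",
    "left_elbow", "right_elbow",
    "left_wrist", "right_wrist",
    "left_pinky", "right_pinky",
    "left_index", "right_index",
    "left_thumb", "right_thumb",
    "left_hip", "right_hip",
    "left_knee", "right_knee",
    "left_ankle", "right_ankle",
    "left_heel", "right_heel",
    "left_foot_index", "right_foot_index",
)

#: Lower-extremity subset used for sagittal gait analysis (6 per side).
#: ``foot_index`` is the toe landmark.
TRACKED_SUBSET: tuple[str, ...] = (
    "left_shoulder", "right_shoulder",
    "left_hip", "right_hip",
    "left_knee", "right_knee",
    "left_ankle", "right_ankle",
    "left_heel", "right_heel",
    "left_foot_index", "right_foot_index",
)

SIDES = ("left", "right")


@dataclass(frozen=True)
class LandmarkSchema:
    """Declared landmark vocabulary of a pose file.

    Parameters
    ----------
    names
        Ordered landmark labels; must be 33 unique names.
    tracked_subset
        The 12 labels (6 per side) entering gait analysis.
    """

    names: tuple[str, ...] = BLAZEPOSE_33
    tracked_subset: tuple[str, ...] = TRACKED_SUBSET

    def __post_init__(self) -> None:
        if len(self.names) != 33 or len(set(self.names)) != 33:
            raise SchemaError(f"schema must have 33 unique landmark names, got {len(self.names)}")
        missing = [n for n in self.tracked_subset if n not in self.names]
        if missing:
            raise SchemaError(f"tracked_subset not contained in names: {missing}")
        if len(self.tracked_subset) != 12:
            raise SchemaError("tracked_subset must have 12 landmarks (6 per side)")


DEFAULT_SCHEMA = LandmarkSchema()


@dataclass
class TrialMetadata:
    """Identity and acquisition context of one recorded trial."""

    subject_id: str = ""
    camera_position: str = "REF"  # P1..P5 for camera streams, REF for mocap
    camera_side: str = "left"
    treadmill: bool = True
    duration: float = 0.0

    def __post_init__(self) -> None:
        allowed = {"P1", "P2", "P3", "P4", "P5", "REF"}
        if self.camera_position not in allowed:
            raise SchemaError(f"camera_position must be one of {sorted(allowed)}")
        if self.camera_side not in SIDES:
            raise SchemaError("camera_side must be 'left' or 'right'")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TrialMetadata":
        return cls(**json.loads(Path(path).read_text()))


def _check_times(times: np.ndarray, fps: float) -> None:
    if len(times) > 1:
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise DataError("time stamps must be strictly increasing")
        if np.any(np.abs(dt - 1.0 / fps) > 0.1 / fps):
            raise DataError("inter-frame intervals deviate >10% from 1/fps")


@dataclass
class PoseSeries:
    """One camera's 2D landmark trajectories for a trial.

    ``points`` has shape (n_frames, n_landmarks, 2) in pixel coordinates
    (origin top-left, y down); missing detections are NaN and flagged in
    ``missing`` — they are never silently dropped.
    """

    fps: float
    times: np.ndarray
    points: np.ndarray
    missing: np.ndarray
    visibility: np.ndarray | None = None
    schema: LandmarkSchema = field(default_factory=LandmarkSchema)
    meta: TrialMetadata = field(default_factory=TrialMetadata)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        n = len(self.times)
        if self.points.shape != (n, len(self.schema.names), 2):
            raise SchemaError(
                f"points shape {self.points.shape} does not match "
                f"({n}, {len(self.schema.names)}, 2)"
            )
        if self.missing.shape != self.points.shape[:2]:
            raise SchemaError("missing mask shape mismatch")
        _check_times(self.times, self.fps)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def index(self, name: str) -> int:
        return self.schema.names.index(name)


@dataclass
class MarkerSeries:
    """Reference motion-capture trajectories: per-frame 3D marker positions.

    World convention of this package: x anterior, y up, z toward the
    subject's left; units metres.
    """

    fps: float
    times: np.ndarray
    positions: np.ndarray  # (n_frames, n_markers, 3)
    names: tuple[str, ...]
    meta: TrialMetadata = field(default_factory=TrialMetadata)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.times)
        if self.positions.shape != (n, len(self.names), 3):
            raise SchemaError("positions shape does not match names/times")
        _check_times(self.times, self.fps)

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass
class BodyFrameSeries:
    """Tracked-subset 2D coordinates in a y-up, anterior-positive-x frame."""

    fps: float
    times: np.ndarray
    joints: np.ndarray  # (n_frames, 12, 2)
    names: tuple[str, ...] = TRACKED_SUBSET
    missing: np.ndarray | None = None
    meta: TrialMetadata = field(default_factory=TrialMetadata)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.joints = np.asarray(self.joints, dtype=float)
        if self.missing is None:
            self.missing = ~np.isfinite(self.joints).all(axis=2)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.joints.shape != (len(self.times), len(self.names), 2):
            raise SchemaError("joints shape does not match names/times")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def get(self, name: str) -> np.ndarray:
        """Return the (n_frames, 2) trajectory of one landmark."""
        return self.joints[:, self.names.index(name), :]


# ---------------------------------------------------------------------------
# CSV pose format: frame,time,<name>_x,<name>_y[,<name>_z][,<name>_vis]
# ---------------------------------------------------------------------------

def write_pose_csv(series: PoseSeries, path: str | Path) -> Path:
    """Write a :class:`PoseSeries` to the long-header landmark CSV."""
    if series.n_frames == 0:
        raise DataError("refusing to write a PoseSeries with zero frames")
    path = Path(path)
    cols: dict[str, np.ndarray] = {
        "frame": np.arange(series.n_frames),
        "time": series.times,
    }
    for j, name in enumerate(series.schema.names):
        cols[f"{name}_x"] = series.points[:, j, 0]
        cols[f"{name}_y"] = series.points[:, j, 1]
        if series.visibility is not None:
            cols[f"{name}_vis"] = series.visibility[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")
    return path


def read_pose_csv(path: str | Path, schema: LandmarkSchema = DEFAULT_SCHEMA,
                  meta: TrialMetadata | None = None) -> PoseSeries:
    """Read a landmark CSV into a validated :class:`PoseSeries`.

    Unparseable coordinate cells become NaN and are flagged missing.
    Raises :class:`SchemaError` naming any absent mandatory landmark
    columns, and :class:`DataError` on an empty file.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError(f"empty pose CSV: {path}") from None
    if df.empty:
        raise DataError(f"pose CSV has no data rows: {path}")

    absent = [name for name in schema.names
              if f"{name}_x" not in df.columns or f"{name}_y" not in df.columns]
    if absent:
        raise SchemaError(f"pose CSV missing landmark columns: {absent}")
    if "time" not in df.columns:
        raise SchemaError("pose CSV missing mandatory 'time' column")

    n = len(df)
    times = pd.to_numeric(df["time"], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(times)):
        raise DataError("unparseable values in 'time' column")
    points = np.empty((n, 33, 2))
    vis = None
    if all(f"{name}_vis" in df.columns for name in schema.names):
        vis = np.empty((n, 33))
    for j, name in enumerate(schema.names):
        points[:, j, 0] = pd.to_numeric(df[f"{name}_x"], errors="coerce")
        points[:, j, 1] = pd.to_numeric(df[f"{name}_y"], errors="coerce")
        if vis is not None:
            vis[:, j] = pd.to_numeric(df[f"{name}_vis"], errors="coerce")
    missing = ~np.isfinite(points).all(axis=2)

    if n > 1:
        fps = 1.0 / float(np.median(np.diff(times)))
        if abs(fps - round(fps)) < 0.01:  # absorb timestamp round-off
            fps = float(round(fps))
    else:
        fps = 1.0
    if meta is None:
        sidecar = path.with_suffix(".json")
        meta = TrialMetadata.from_json(sidecar) if sidecar.exists() else TrialMetadata()
    return PoseSeries(fps=fps, times=times, points=points, missing=missing,
                      visibility=vis, schema=schema, meta=meta)


# ---------------------------------------------------------------------------
# Marker formats: simple wide CSV and the standard TRC text format
# ---------------------------------------------------------------------------

def write_marker_csv(series: MarkerSeries, path: str | Path) -> Path:
    path = Path(path)
    cols: dict[str, np.ndarray] = {
        "frame": np.arange(series.n_frames),
        "time": series.times,
    }
    for j, name in enumerate(series.names):
        for k, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = series.positions[:, j, k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")
    return path


def _read_marker_csv(path: Path, meta: TrialMetadata | None) -> MarkerSeries:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise SchemaError("marker CSV missing 'time' column")
    names = []
    for c in df.columns:
        if c.endswith("_x"):
            stem = c[:-2]
            if f"{stem}_y" in df.columns and f"{stem}_z" in df.columns:
                names.append(stem)
    if not names:
        raise SchemaError("marker CSV contains no <name>_x/_y/_z triplets")
    n = len(df)
    pos = np.empty((n, len(names), 3))
    for j, name in enumerate(names):
        for k, ax in enumerate("xyz"):
            pos[:, j, k] = pd.to_numeric(df[f"{name}_{ax}"], errors="coerce")
    times = df["time"].to_numpy(dtype=float)
    fps = 1.0 / float(np.median(np.diff(times))) if n > 1 else 1.0
    return MarkerSeries(fps=fps, times=times, positions=pos, names=tuple(names),
                        meta=meta or TrialMetadata())


def _read_trc(path: Path, meta: TrialMetadata | None) -> MarkerSeries:
    lines = path.read_text().splitlines()
    if len(lines) < 5:
        raise SchemaError(f"TRC file too short: {path}")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    hdr = dict(zip(header_keys, header_vals))
    try:
        fps = float(hdr["DataRate"])
        n_markers = int(hdr["NumMarkers"])
    except (KeyError, ValueError) as exc:
        raise SchemaError(f"malformed TRC header in {path}: {exc}") from None
    marker_line = lines[3].split("\t")
    names = tuple(m for m in marker_line[2:] if m.strip())
    if len(names) != n_markers:
        raise SchemaError(
            f"TRC declares {n_markers} markers but names row lists {len(names)}")

    rows = []
    times = []
    for lineno, line in enumerate(lines[5:], start=6):
        if not line.strip():
            continue
        fields = line.split("\t")
        expected = 2 + 3 * n_markers
        if len(fields) < expected:
            raise SchemaError(f"TRC row at line {lineno} truncated "
                              f"({len(fields)} fields, expected {expected})")
        times.append(float(fields[1]))
        rows.append([float(v) if v.strip() else np.nan for v in fields[2:expected]])
    if not rows:
        raise DataError(f"TRC file has no data rows: {path}")
    pos = np.asarray(rows).reshape(len(rows), n_markers, 3)
    return MarkerSeries(fps=fps, times=np.asarray(times), positions=pos,
                        names=names, meta=meta or TrialMetadata())


def read_marker_series(path: str | Path, dialect: str = "csv",
                       meta: TrialMetadata | None = None) -> MarkerSeries:
    """Read marker trajectories from ``csv`` or ``trc`` files."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if dialect == "csv":
        return _read_marker_csv(path, meta)
    if dialect == "trc":
        return _read_trc(path, meta)
    raise ConfigError(f"unknown marker dialect {dialect!r}; use 'csv' or 'trc'")


def write_trc(series: MarkerSeries, path: str | Path) -> Path:
    """Write a minimal standards-conforming TRC file."""
    path = Path(path)
    n, m = series.n_frames, len(series.names)
    out = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{series.fps:g}\t{series.fps:g}\t{n}\t{m}\tm\t{series.fps:g}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(series.names) + "\t\t",
        "\t\t" + "\t".join(f"X{j+1}\tY{j+1}\tZ{j+1}" for j in range(m)),
    ]
    for i in range(n):
        vals = "\t".join(f"{v:.9g}" for v in series.positions[i].ravel())
        out.append(f"{i+1}\t{series.times[i]:.9g}\t{vals}")
    path.write_text("\n".join(out) + "\n")
    return path


# ---------------------------------------------------------------------------
# Body-frame conversion
# ---------------------------------------------------------------------------

def _orient(joints: np.ndarray, names: Sequence[str], missing: np.ndarray) -> np.ndarray:
    """Flip axes so +y is up and +x is anterior; idempotent by construction."""
    joints = joints.copy()
    idx = {n: i for i, n in enumerate(names)}

    def mean_diff(a: str, b: str, axis: int) -> float:
        d = joints[:, idx[a], axis] - joints[:, idx[b], axis]
        return float(np.nanmean(d))

    up = 0.5 * (mean_diff("left_shoulder", "left_hip", 1)
                + mean_diff("right_shoulder", "right_hip", 1))
    if up < 0:  # image convention: smaller y is higher
        joints[:, :, 1] *= -1.0
    fwd = 0.5 * (mean_diff("left_foot_index", "left_heel", 0)
                 + mean_diff("right_foot_index", "right_heel", 0))
    if fwd < 0:
        joints[:, :, 0] *= -1.0
    return joints


def to_body_frame(series: PoseSeries | MarkerSeries | BodyFrameSeries,
                  schema: LandmarkSchema = DEFAULT_SCHEMA) -> BodyFrameSeries:
    """Map a series into the canonical body frame (y up, anterior +x).

    Marker series are first projected onto the sagittal (x-y) plane of the
    lab frame. Landmarks missing in more than half the frames raise
    :class:`DataError`.
    """
    tracked = schema.tracked_subset
    if isinstance(series, BodyFrameSeries):
        joints, missing = series.joints, series.missing
        fps, times, meta = series.fps, series.times, series.meta
        names = series.names
    elif isinstance(series, MarkerSeries):
        absent = [n for n in tracked if n not in series.names]
        if absent:
            raise SchemaError(f"marker series lacks tracked landmarks: {absent}")
        cols = [series.names.index(n) for n in tracked]
        joints = series.positions[:, cols, :2]  # sagittal-plane projection
        missing = ~np.isfinite(joints).all(axis=2)
        fps, times, meta, names = series.fps, series.times, series.meta, tracked
    else:
        cols = [series.index(n) for n in tracked]
        joints = series.points[:, cols, :]
        missing = series.missing[:, cols]
        fps, times, meta, names = series.fps, series.times, series.meta, tracked

    frac_missing = missing.mean(axis=0)
    bad = [names[i] for i in np.flatnonzero(frac_missing > 0.5)]
    if bad:
        raise DataError(f"landmarks missing in >50% of frames: {bad}")

    oriented = _orient(joints, names, missing)
    return BodyFrameSeries(fps=fps, times=times.copy(), joints=oriented,
                           names=tuple(names), missing=missing.copy(), meta=meta)
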