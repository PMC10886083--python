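"""Sagittal-plane segment orientations and lower-extremity joint angles.

Four body segments are modelled per side as directed 2D vectors in the
body frame (y up, anterior +x):

====== ======================= =========================
name    direction               neutral-standing angle
====== ======================= =========================
trunk   shoulder -> hip          -90 deg (pointing down)
thigh   hip -> knee              -90 deg
shank   knee -> ankle            -90 deg
foot    ankle -> toe               0 deg (horizontal)
====== ======================= =========================

The segment angle phi is the quadrant-correct arctangent of the segment
vector, ``phi = atan2(dy, dx)`` in degrees, in (-180, 180]. Joint angles
are differences of adjacent segment angles:

    theta_hip   = phi_thigh - phi_trunk
    theta_knee  = phi_thigh - phi_shank
    theta_ankle = phi_foot  - phi_shank - 90 deg

With the directions above, quiet standing yields 0 deg at all three
joints, and hip flexion, knee flexion and ankle dorsiflexion are
positive. A plain one-argument arctangent would be ambiguous by 180 deg
whenever a segment crosses the vertical; the two-argument form is used
throughout. Angle traces are unwrapped so no physical inter-frame jump
appears as a +-360 deg artifact.

The heel landmark is deliberately excluded here — it drives event
detection only; the foot segment runs ankle -> toe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .io import BodyFrameSeries, TrialMetadata

__all__ = ["JOINTS", "SIDES", "SEGMENTS", "JointAngleSeries", "segment_angle",
           "hip_angle", "knee_angle", "ankle_angle", "compute_joint_angles",
           "wrap_degrees"]

JOINTS = ("hip", "knee", "ankle")
SIDES = ("left", "right")

#: segment name -> (origin landmark suffix, tip landmark suffix)
SEGMENTS = {
    "trunk": ("shoulder", "hip"),
    "thigh": ("hip", "knee"),
    "shank": ("knee", "ankle"),
    "foot": ("ankle", "foot_index"),
}


def wrap_degrees(a):
    """Wrap angles to the half-open interval (-180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def segment_angle(origin, tip):
    """Quadrant-correct orientation of the segment origin->tip, degrees.

    Accepts single points or (n, 2) stacks. Zero-length segments raise
    :class:`DataError` identifying the offending frame.
    """
    origin = np.asarray(origin, dtype=float)
    tip = np.asarray(tip, dtype=float)
    d = tip - origin
    dx, dy = d[..., 0], d[..., 1]
    zero = (dx == 0) & (dy == 0)
    if np.any(zero):
        frames = np.flatnonzero(np.atleast_1d(zero))
        raise DataError(f"zero-length segment at frame(s) {frames[:5].tolist()}")
    ang = np.degrees(np.arctan2(dy, dx))
    return ang if ang.ndim else float(ang)


def hip_angle(phi_thigh, phi_trunk):
    """theta_hip = phi_thigh - phi_trunk, wrapped to (-180, 180]."""
    return wrap_degrees(np.asarray(phi_thigh) - np.asarray(phi_trunk))


def knee_angle(phi_thigh, phi_shank):
    """theta_knee = phi_thigh - phi_shank, wrapped to (-180, 180]."""
    return wrap_degrees(np.asarray(phi_thigh) - np.asarray(phi_shank))


def ankle_angle(phi_foot, phi_shank):
    """theta_ankle = phi_foot - phi_shank - 90 deg, wrapped to (-180, 180]."""
    return wrap_degrees(np.asarray(phi_foot) - np.asarray(phi_shank) - 90.0)


@dataclass
class JointAngleSeries:
    """Hip/knee/ankle angle traces in degrees, both sides.

    ``data`` has shape (n_frames, 2, 3): axis 1 indexes :data:`SIDES`,
    axis 2 indexes :data:`JOINTS`. ``source`` records which measurement
    system produced the angles ('hpe' or 'mocap').
    """

    fps: float
    times: np.ndarray
    data: np.ndarray
    source: str = "hpe"
    meta: TrialMetadata = field(default_factory=TrialMetadata)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.times), 2, 3):
            raise DataError(f"angle data shape {self.data.shape} != (n, 2, 3)")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def trace(self, joint: str, side: str) -> np.ndarray:
        """Return one (n_frames,) angle trace."""
        return self.data[:, SIDES.index(side), JOINTS.index(joint)]

    def to_frame(self):
        """Long-format DataFrame: time, side, hip, knee, ankle."""
        import pandas as pd
        parts = []
        for s, side in enumerate(SIDES):
            parts.append(pd.DataFrame({
                "time": self.times, "side": side,
                **{j: self.data[:, s, k] for k, j in enumerate(JOINTS)},
            }))
        return pd.concat(parts, ignore_index=True)


def _unwrap_with_nan(a: np.ndarray) -> np.ndarray:
    """np.unwrap that tolerates NaN runs (unwraps the finite subsequence)."""
    out = a.copy()
    finite = np.isfinite(a)
    if finite.sum() >= 2:
        out[finite] = np.unwrap(a[finite], period=360.0)
    return out


def compute_joint_angles(series: BodyFrameSeries) -> JointAngleSeries:
    """Compute per-frame hip/knee/ankle angles for both sides.

    Expects a preprocessed body-frame series (gaps filled); frames with
    remaining missing landmarks yield NaN angles at the affected joints.
    """
    n = series.n_frames
    data = np.full((n, 2, 3), np.nan)
    for s, side in enumerate(SIDES):
        phi = {}
        for seg, (o_suf, t_suf) in SEGMENTS.items():
            origin = series.get(f"{side}_{o_suf}")
            tip = series.get(f"{side}_{t_suf}")
            d = tip - origin
            valid = np.isfinite(d).all(axis=1)
            zero = valid & (d[:, 0] == 0) & (d[:, 1] == 0)
            if np.any(zero):
                raise DataError(
                    f"zero-length {side} {seg} segment at frame "
                    f"{int(np.flatnonzero(zero)[0])}")
            ang = np.full(n, np.nan)
            ang[valid] = np.degrees(np.arctan2(d[valid, 1], d[valid, 0]))
            phi[seg] = ang
        data[:, s, 0] = _unwrap_with_nan(hip_angle(phi["thigh"], phi["trunk"]))
        data[:, s, 1] = _unwrap_with_nan(knee_angle(phi["thigh"], phi["shank"]))
        data[:, s, 2] = _unwrap_with_nan(ankle_angle(phi["foot"], phi["shank"]))
    return JointAngleSeries(fps=series.fps, times=series.times.copy(), data=data,
                            source="mocap" if series.meta.camera_position == "REF" else "hpe",
                            meta=series.meta)
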