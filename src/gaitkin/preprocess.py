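"""Smoothing, gap filling, resampling and event-based temporal alignment.

Pose landmarks from video carry frame-to-frame jitter; a centered moving
average with a truncated (shrinking) window at the edges suppresses it
without changing trace length. Short detection dropouts are filled by
linear interpolation; long gaps stay flagged so downstream consumers can
mask them. The reference motion-capture stream (120 fps) is brought to
the camera frame rate (30 fps) by linear interpolation onto the target
timestamps, and the two streams are aligned at a common heel-strike frame.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError
from .io import BodyFrameSeries

__all__ = ["FilterConfig", "moving_average", "gap_fill", "resample",
           "align_at_heel_strike"]


@dataclass(frozen=True)
class FilterConfig:
    """Smoothing/gap-fill parameters.

    window
        Odd number of frames of the centered moving average. The default,
        5 frames at 30 fps (~0.17 s), attenuates landmark jitter while
        leaving gait-band content (< 6 Hz) essentially untouched.
    max_gap
        Longest interior run of missing frames that is linearly
        interpolated; longer gaps remain flagged.
    """

    window: int = 5
    max_gap: int = 10

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ConfigError(f"moving-average window must be odd and >=1, got {self.window}")
        if self.max_gap < 0:
            raise ConfigError("max_gap must be >= 0")


def _moving_average_1d(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated windows at the edges.

    NaNs are excluded from the local mean (window shrinks around them);
    samples that are NaN on input stay NaN on output.
    """
    if window == 1:
        return x.copy()
    finite = np.isfinite(x)
    vals = np.where(finite, x, 0.0)
    kernel = np.ones(window)
    half = (window - 1) // 2
    # full convolution sliced at the window centers: robust to traces
    # shorter than the window (mode="same" would return window-length output)
    sums = np.convolve(vals, kernel, mode="full")[half:half + len(x)]
    counts = np.convolve(finite.astype(float), kernel, mode="full")[half:half + len(x)]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[~finite] = np.nan
    return out


def moving_average(series: BodyFrameSeries, config: FilterConfig = FilterConfig()) -> BodyFrameSeries:
    """Smooth every coordinate trace with a centered moving average."""
    joints = np.empty_like(series.joints)
    for j in range(series.joints.shape[1]):
        for k in range(2):
            joints[:, j, k] = _moving_average_1d(series.joints[:, j, k], config.window)
    return BodyFrameSeries(fps=series.fps, times=series.times.copy(), joints=joints,
                           names=series.names, missing=series.missing.copy(),
                           meta=series.meta)


def _fill_1d(x: np.ndarray, flagged: np.ndarray, max_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Fill runs of flagged samples; returns (filled values, remaining flags)."""
    x = x.copy()
    flags = flagged.copy()
    n = len(x)
    good = np.flatnonzero(~flags)
    if len(good) == 0:
        raise DataError("all samples missing")
    # leading / trailing gaps: hold nearest observed value
    if good[0] > 0:
        x[:good[0]] = x[good[0]]
        flags[:good[0]] = False
    if good[-1] < n - 1:
        x[good[-1] + 1:] = x[good[-1]]
        flags[good[-1] + 1:] = False
    # interior gaps: linear interpolation if short enough
    i = good[0]
    while i < good[-1]:
        if flags[i]:
            j = i
            while flags[j]:
                j += 1
            gap = j - i
            if gap <= max_gap:
                left, right = i - 1, j
                frac = np.arange(1, gap + 1) / (gap + 1)
                x[i:j] = x[left] + frac * (x[right] - x[left])
                flags[i:j] = False
            i = j
        else:
            i += 1
    return x, flags


def gap_fill(series: BodyFrameSeries, config: FilterConfig = FilterConfig()) -> BodyFrameSeries:
    """Interpolate flagged gaps of length <= ``max_gap``; keep longer ones flagged.

    Leading and trailing gaps are held at the nearest observed value.
    Non-gap samples are passed through bit-identically.
    """
    joints = series.joints.copy()
    missing = series.missing.copy()
    for j, name in enumerate(series.names):
        flags = missing[:, j] | ~np.isfinite(joints[:, j]).all(axis=1)
        if not flags.any():
            continue
        try:
            for k in range(2):
                joints[:, j, k], newflags = _fill_1d(joints[:, j, k], flags, config.max_gap)
        except DataError:
            raise DataError(f"landmark {name!r} is missing in every frame") from None
        missing[:, j] = newflags
        joints[missing[:, j], j, :] = np.nan
    return BodyFrameSeries(fps=series.fps, times=series.times.copy(), joints=joints,
                           names=series.names, missing=missing, meta=series.meta)


def resample(series, target_fps: float):
    """Linearly interpolate a series onto timestamps ``t0 + k/target_fps``.

    Works on :class:`BodyFrameSeries` and on
    :class:`~gaitkin.kinematics.JointAngleSeries` (anything with ``times``
    plus a per-frame array attribute). The first timestamp is preserved;
    the new grid spans the original time range.
    """
    if target_fps <= 0:
        raise ConfigError("target_fps must be positive")
    if target_fps > series.fps * 4:
        import warnings
        warnings.warn(f"upsampling {series.fps} -> {target_fps} fps exceeds design intent",
                      stacklevel=2)
    t0, t1 = series.times[0], series.times[-1]
    n_new = int(np.floor((t1 - t0) * target_fps + 1e-9)) + 1
    new_times = t0 + np.arange(n_new) / target_fps

    def interp_stack(arr: np.ndarray) -> np.ndarray:
        flat = arr.reshape(arr.shape[0], -1)
        out = np.empty((n_new, flat.shape[1]))
        for c in range(flat.shape[1]):
            out[:, c] = np.interp(new_times, series.times, flat[:, c])
        return out.reshape((n_new,) + arr.shape[1:])

    if isinstance(series, BodyFrameSeries):
        joints = interp_stack(series.joints)
        miss = interp_stack(series.missing.astype(float)) > 1e-9
        return BodyFrameSeries(fps=target_fps, times=new_times, joints=joints,
                               names=series.names, missing=miss, meta=series.meta)

    from .kinematics import JointAngleSeries
    if isinstance(series, JointAngleSeries):
        data = interp_stack(series.data)
        return JointAngleSeries(fps=target_fps, times=new_times, data=data,
                                source=series.source, meta=series.meta)
    raise ConfigError(f"cannot resample object of type {type(series).__name__}")


def _crop(series, start: int, length: int):
    out = copy.copy(series)
    out.times = series.times[start:start + length] - series.times[start]
    for attr in ("joints", "missing", "data", "points", "visibility"):
        arr = getattr(series, attr, None)
        if arr is not None:
            setattr(out, attr, arr[start:start + length])
    return out


def align_at_heel_strike(a, b, event_a: int, event_b: int):
    """Crop two equal-fps series so given heel-strike frames land at index 0.

    Both outputs are truncated to the shorter remaining length, giving a
    frame-by-frame comparable pair.
    """
    if abs(a.fps - b.fps) > 1e-3 * max(a.fps, b.fps):
        raise DataError(f"cannot align series at different fps ({a.fps} vs {b.fps})")
    for name, ev, s in (("a", event_a, a), ("b", event_b, b)):
        if not (0 <= ev < len(s.times)):
            raise DataError(f"event index {ev} out of range for series {name} "
                            f"({len(s.times)} frames)")
    length = min(len(a.times) - event_a, len(b.times) - event_b)
    return _crop(a, event_a, length), _crop(b, event_b, length)
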