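"""Gait-event detection, cycle segmentation and time normalization.

On a treadmill the body has no net translation, so foot contact and
lift-off can be read from the anterior excursion of the foot relative to
the pelvis: heel strike occurs at local maxima of ``heel.x - hip.x``
(the heel is at its most anterior point at initial contact) and toe-off
at local minima of ``toe.x - hip.x`` (the toe trails furthest at
lift-off). This is the standard kinematic convention for treadmill
walking and uses only landmarks the pipeline already tracks.

Robustness rules: candidate peaks must be separated by at least half the
median cycle period, and exactly one toe-off is kept between consecutive
heel strikes (the most extreme candidate), which enforces the
heel-strike/toe-off alternation invariant by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import DataError, InsufficientCyclesError
from .io import BodyFrameSeries
from .kinematics import JOINTS, SIDES, JointAngleSeries

__all__ = ["GaitEvents", "NormalizedCycle", "detect_events", "segment_cycles",
           "cycle_slices", "time_normalize", "cycle_ensembles"]

#: Grid of the time-normalized gait cycle: 0..100% inclusive.
CYCLE_GRID = np.linspace(0.0, 100.0, 101)


@dataclass
class GaitEvents:
    """Heel-strike and toe-off frame indices per side."""

    heel_strikes: dict[str, np.ndarray] = field(default_factory=dict)
    toe_offs: dict[str, np.ndarray] = field(default_factory=dict)
    method: str = "anterior-excursion-extrema"

    def validate(self) -> None:
        for side, hs in self.heel_strikes.items():
            if np.any(np.diff(hs) <= 0):
                raise DataError(f"{side} heel strikes not strictly increasing")
            to = self.toe_offs.get(side, np.array([], dtype=int))
            if np.any(np.diff(to) <= 0):
                raise DataError(f"{side} toe-offs not strictly increasing")
            for a, b in zip(hs[:-1], hs[1:]):
                n_inside = int(np.sum((to > a) & (to < b)))
                if n_inside != 1:
                    raise DataError(
                        f"{side}: {n_inside} toe-offs between heel strikes {a} and {b}")


@dataclass
class NormalizedCycle:
    """Ensemble of cycles interpolated onto the 101-point percent grid."""

    grid: np.ndarray
    curves: np.ndarray  # (n_cycles, 101)
    mean: np.ndarray
    sd: np.ndarray      # population SD; NaN where n_cycles < 2
    n_cycles: int


def _detection_signal(series: BodyFrameSeries, side: str, landmark: str) -> np.ndarray:
    x = series.get(f"{side}_{landmark}")[:, 0] - series.get(f"{side}_hip")[:, 0]
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise DataError(f"no usable {side} {landmark} trajectory")
    if not finite.all():  # bridge residual gaps for detection only
        idx = np.arange(len(x))
        x = np.interp(idx, idx[finite], x[finite])
    return x


def _periodic_peaks(x: np.ndarray, min_separation_frac: float) -> np.ndarray:
    span = np.ptp(x)
    if span <= 1e-12:
        raise InsufficientCyclesError("insufficient cycles: signal has no extrema")
    first, _ = find_peaks(x, prominence=0.2 * span)
    if len(first) >= 2:
        period = float(np.median(np.diff(first)))
        dist = max(1, int(round(min_separation_frac * period)))
        peaks, _ = find_peaks(x, prominence=0.2 * span, distance=dist)
    else:
        peaks = first
    if len(peaks) < 2:
        raise InsufficientCyclesError(
            f"insufficient cycles: {len(peaks)} heel strikes detected")
    return peaks


def detect_events(series: BodyFrameSeries, side: str,
                  min_separation_frac: float = 0.5) -> GaitEvents:
    """Detect heel strikes and toe-offs for one side.

    Raises :class:`InsufficientCyclesError` when fewer than two heel
    strikes are found (e.g. a standing trial).
    """
    if side not in SIDES:
        raise DataError(f"side must be one of {SIDES}")
    heel = _detection_signal(series, side, "heel")
    hs = _periodic_peaks(heel, min_separation_frac)

    toe = _detection_signal(series, side, "foot_index")
    toe_offs = []
    for a, b in zip(hs[:-1], hs[1:]):
        seg = toe[a + 1:b]
        if len(seg):
            toe_offs.append(a + 1 + int(np.argmin(seg)))
    ev = GaitEvents(heel_strikes={side: np.asarray(hs, dtype=int)},
                    toe_offs={side: np.asarray(toe_offs, dtype=int)})
    ev.validate()
    return ev


def detect_events_both(series: BodyFrameSeries,
                       min_separation_frac: float = 0.5) -> GaitEvents:
    """Detect events for both sides into a single :class:`GaitEvents`."""
    merged = GaitEvents()
    for side in SIDES:
        ev = detect_events(series, side, min_separation_frac)
        merged.heel_strikes[side] = ev.heel_strikes[side]
        merged.toe_offs[side] = ev.toe_offs[side]
    return merged


def cycle_slices(events: GaitEvents, side: str,
                 bounds: tuple[float, float] = (0.5, 1.5)) -> list[slice]:
    """Per-cycle slices between consecutive heel strikes.

    Cycles shorter than ``bounds[0]`` or longer than ``bounds[1]`` times
    the median cycle length are excluded (guards against missed or
    spurious events).
    """
    hs = events.heel_strikes.get(side)
    if hs is None or len(hs) < 2:
        raise InsufficientCyclesError(f"need >=2 heel strikes on side {side!r}")
    lengths = np.diff(hs)
    med = float(np.median(lengths))
    keep = (lengths >= bounds[0] * med) & (lengths <= bounds[1] * med)
    return [slice(int(a), int(b) + 1)
            for a, b, k in zip(hs[:-1], hs[1:], keep) if k]


def segment_cycles(angles: JointAngleSeries, events: GaitEvents, side: str,
                   bounds: tuple[float, float] = (0.5, 1.5)) -> dict[str, list[np.ndarray]]:
    """Split each joint's angle trace into per-cycle segments."""
    slices = cycle_slices(events, side, bounds)
    return {joint: [angles.trace(joint, side)[sl] for sl in slices]
            for joint in JOINTS}


def time_normalize(cycles: list[np.ndarray]) -> NormalizedCycle:
    """Interpolate each cycle onto the 0-100% grid; ensemble mean and SD."""
    if not cycles:
        raise DataError("cannot normalize an empty cycle list")
    curves = np.empty((len(cycles), len(CYCLE_GRID)))
    for i, c in enumerate(cycles):
        c = np.asarray(c, dtype=float)
        if len(c) < 2:
            raise DataError(f"cycle {i} has fewer than 2 samples")
        p = np.linspace(0.0, 100.0, len(c))
        curves[i] = np.interp(CYCLE_GRID, p, c)
    mean = curves.mean(axis=0)
    # population SD: a descriptive ensemble spread, invariant under
    # duplicating the cycle list (unlike the n-1 estimator)
    sd = curves.std(axis=0, ddof=0) if len(cycles) >= 2 else np.full_like(mean, np.nan)
    return NormalizedCycle(grid=CYCLE_GRID.copy(), curves=curves, mean=mean,
                           sd=sd, n_cycles=len(cycles))


def cycle_ensembles(angles: JointAngleSeries, events: GaitEvents,
                    bounds: tuple[float, float] = (0.5, 1.5),
                    ) -> dict[tuple[str, str], NormalizedCycle]:
    """Normalized-cycle ensembles keyed by (joint, side)."""
    out = {}
    for side in SIDES:
        if side not in events.heel_strikes:
            continue
        per_joint = segment_cycles(angles, events, side, bounds)
        for joint, cyc in per_joint.items():
            out[(joint, side)] = time_normalize(cyc)
    return out
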