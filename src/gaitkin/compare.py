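"""Agreement statistics between pose-estimated and reference joint angles.

Two frame-aligned angle traces (M: motion capture, H: pose estimation)
are compared with the mean absolute error

    MAE = (1/N) * sum_i |M_i - H_i|        [degrees]

and the sample Pearson correlation

    rho(M, H) = cov(M, H) / (sigma_M * sigma_H).

Metrics are computed over the full aligned trial (all frames, typically
~50 cycles); a per-cycle variant is available. Cohort summaries average
per-subject results within each joint x side x camera-position cell
(mean +- sample SD across subjects) and a one-way repeated-measures
ANOVA tests the camera-position effect within subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .kinematics import JOINTS, SIDES, JointAngleSeries

__all__ = ["mae", "pearson", "compare_trial", "summarize_cohort",
           "position_effect_test", "ComparisonResult", "CohortSummary",
           "POSITIONS"]

POSITIONS = ("P1", "P2", "P3", "P4", "P5")


def mae(m, h) -> float:
    """Mean absolute error between two equal-length traces, in degrees."""
    m = np.asarray(m, dtype=float)
    h = np.asarray(h, dtype=float)
    if m.shape != h.shape:
        raise DataError(f"length mismatch: {m.shape} vs {h.shape}")
    if m.size == 0:
        raise DataError("empty traces")
    return float(np.mean(np.abs(m - h)))


def pearson(m, h) -> float:
    """Sample Pearson correlation coefficient of two traces.

    A zero-variance trace makes the correlation undefined and raises
    :class:`DataError` rather than silently returning 0.
    """
    m = np.asarray(m, dtype=float)
    h = np.asarray(h, dtype=float)
    if m.shape != h.shape:
        raise DataError(f"length mismatch: {m.shape} vs {h.shape}")
    if m.size < 3:
        raise DataError("need at least 3 samples for a correlation")
    if np.std(m) == 0 or np.std(h) == 0:
        raise DataError("correlation undefined: zero variance in a trace")
    mc, hc = m - m.mean(), h - h.mean()
    return float(np.dot(mc, hc) / np.sqrt(np.dot(mc, mc) * np.dot(hc, hc)))


@dataclass
class ComparisonResult:
    """Per-trial agreement: MAE and rho for each joint x side.

    ``table`` is indexed by (joint, side) with columns mae, rho, n_frames.
    """

    subject_id: str
    position: str
    table: pd.DataFrame

    def cell(self, joint: str, side: str) -> pd.Series:
        return self.table.loc[(joint, side)]


def compare_trial(mocap_angles: JointAngleSeries, hpe_angles: JointAngleSeries,
                  events=None, per_cycle: bool = False) -> ComparisonResult:
    """Compare two aligned, equal-fps angle series per joint and side.

    Both inputs must already be at the same frame rate and aligned at a
    common heel strike (see :mod:`gaitkin.preprocess`). Frames where
    either trace is NaN (unfilled landmark dropouts) are excluded; the
    per-cell ``n_frames`` counts the frames actually compared.

    With ``per_cycle=True`` the metrics are computed per gait cycle
    (cycles from ``events``) and averaged.
    """
    if abs(mocap_angles.fps - hpe_angles.fps) > 1e-3 * mocap_angles.fps:
        raise DataError("series must share a frame rate; resample first")
    n = min(mocap_angles.n_frames, hpe_angles.n_frames)
    rows = []
    for joint in JOINTS:
        for side in SIDES:
            m = mocap_angles.trace(joint, side)[:n]
            h = hpe_angles.trace(joint, side)[:n]
            ok = np.isfinite(m) & np.isfinite(h)
            if ok.sum() < 3:
                raise DataError(f"too few comparable frames for {side} {joint}")
            if per_cycle and events is not None:
                from .events import cycle_slices
                maes, rhos = [], []
                for sl in cycle_slices(events, side):
                    mm, hh = m[sl], h[sl]
                    good = np.isfinite(mm) & np.isfinite(hh)
                    if good.sum() >= 3:
                        maes.append(mae(mm[good], hh[good]))
                        rhos.append(pearson(mm[good], hh[good]))
                rows.append((joint, side, float(np.mean(maes)),
                             float(np.mean(rhos)), int(ok.sum())))
            else:
                rows.append((joint, side, mae(m[ok], h[ok]),
                             pearson(m[ok], h[ok]), int(ok.sum())))
    table = pd.DataFrame(rows, columns=["joint", "side", "mae", "rho", "n_frames"])
    table = table.set_index(["joint", "side"])
    return ComparisonResult(subject_id=hpe_angles.meta.subject_id,
                            position=hpe_angles.meta.camera_position,
                            table=table)


@dataclass
class CohortSummary:
    """Across-subject aggregation of trial comparisons.

    ``mae_mean``/``mae_sd``/``rho_mean``/``rho_sd`` are DataFrames indexed
    by (joint, side) with one column per camera position. ``best_position``
    gives, per (joint, side), the position with minimal mean MAE and the
    one with maximal mean rho. ``p_position`` holds the repeated-measures
    ANOVA p-value of the position effect on MAE per (joint, side).
    """

    mae_mean: pd.DataFrame
    mae_sd: pd.DataFrame
    rho_mean: pd.DataFrame
    rho_sd: pd.DataFrame
    best_position: pd.DataFrame
    p_position: pd.Series | None = None
    n_subjects: int = 0
    long: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


def _long_table(results: list[ComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for (joint, side), cell in r.table.iterrows():
            rows.append((r.subject_id, r.position, joint, side,
                         cell["mae"], cell["rho"]))
    return pd.DataFrame(rows, columns=["subject", "position", "joint", "side",
                                       "mae", "rho"])


def summarize_cohort(results: list[ComparisonResult],
                     with_p: bool = True) -> CohortSummary:
    """Aggregate per-trial results across subjects (mean +- sample SD).

    Cells with fewer than two subjects get an undefined (NaN) SD. The
    best camera position per joint x side is identified by minimal mean
    MAE and maximal mean rho.
    """
    if not results:
        raise DataError("no comparison results to summarize")
    long = _long_table(results)
    positions = [p for p in POSITIONS if p in set(long["position"])]
    g = long.groupby(["joint", "side", "position"])

    def pivot(stat: pd.Series) -> pd.DataFrame:
        df = stat.unstack("position")
        idx = pd.MultiIndex.from_product([JOINTS, SIDES], names=["joint", "side"])
        return df.reindex(index=idx, columns=positions)

    mae_mean = pivot(g["mae"].mean())
    mae_sd = pivot(g["mae"].std(ddof=1))
    rho_mean = pivot(g["rho"].mean())
    rho_sd = pivot(g["rho"].std(ddof=1))

    best = pd.DataFrame({
        "min_mae": mae_mean.idxmin(axis=1),
        "max_rho": rho_mean.idxmax(axis=1),
    })

    p_pos = None
    if with_p and len(positions) >= 2:
        pvals = {}
        for (joint, side), sub in long.groupby(["joint", "side"]):
            grid = sub.pivot_table(index="subject", columns="position",
                                   values="mae")
            if grid.shape[0] >= 2 and not grid.isna().any().any():
                pvals[(joint, side)] = position_effect_test(grid.to_numpy())
            else:
                pvals[(joint, side)] = np.nan
        p_pos = pd.Series(pvals, name="p_position")

    return CohortSummary(mae_mean=mae_mean, mae_sd=mae_sd, rho_mean=rho_mean,
                         rho_sd=rho_sd, best_position=best, p_position=p_pos,
                         n_subjects=long["subject"].nunique(), long=long)


def position_effect_test(values: np.ndarray) -> float:
    """One-way repeated-measures ANOVA p-value for a subjects x conditions grid.

    ``values[i, j]`` is subject i's score under condition (camera
    position) j; the grid must be complete. Returns the p-value of the
    condition main effect, F((k-1), (k-1)(n-1)). A grid with zero
    between-condition variation returns the boundary p = 1 (F = 0).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise DataError("need a complete (>=2 subjects) x (>=2 conditions) grid")
    if np.any(~np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))
        raise DataError(f"incomplete grid: missing cells at {bad.tolist()}")
    n, k = values.shape
    grand = values.mean()
    cond_means = values.mean(axis=0)
    subj_means = values.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    resid = values - cond_means[None, :] - subj_means[:, None] + grand
    ss_err = np.sum(resid ** 2)
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    if ss_cond <= 1e-300:
        return 1.0
    if ss_err <= 1e-300:
        return 0.0
    f_stat = (ss_cond / df_cond) / (ss_err / df_err)
    return float(stats.f.sf(f_stat, df_cond, df_err))
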