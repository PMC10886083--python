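"""End-to-end workflow: simulate/load -> preprocess -> angles -> events ->
align -> compare -> cohort summary.

The pipeline mirrors a two-system validation workflow: a reference
marker stream (120 fps) and one pose stream per camera position (30 fps)
per subject. Each pose stream is gap-filled and smoothed, joint angles
are computed for both streams, the reference is resampled to the camera
frame rate, both are aligned at their first detected left heel strike,
and per-trial MAE / Pearson rho are aggregated across subjects.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import events as ev
from . import preprocess as pp
from .compare import ComparisonResult, CohortSummary, compare_trial, summarize_cohort
from .errors import ConfigError, DataError
from .io import read_marker_series, read_pose_csv, to_body_frame
from .kinematics import JOINTS, SIDES, JointAngleSeries, compute_joint_angles

log = logging.getLogger("gaitkin")

__all__ = ["PipelineConfig", "run_pipeline", "process_pose_stream",
           "process_reference", "analyze_trial_pair"]


@dataclass
class PipelineConfig:
    """Validated configuration for the full workflow."""

    window: int = 5
    max_gap: int = 10
    target_fps: float = 30.0
    min_separation_frac: float = 0.5
    cycle_bounds: tuple[float, float] = (0.5, 1.5)
    per_cycle: bool = False
    smooth_reference: bool = False
    seed: int = 0
    study_dir: str = ""
    out_dir: str = ""
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        pp.FilterConfig(window=self.window, max_gap=self.max_gap)  # validates
        if self.target_fps <= 0:
            raise ConfigError("target_fps must be positive")
        if not (0 < self.min_separation_frac < 1):
            raise ConfigError("min_separation_frac must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        flat: dict = {}
        for key, val in d.items():
            if key in ("preprocess", "events", "compare", "io") and isinstance(val, dict):
                for k2, v2 in val.items():
                    flat[k2] = v2
            else:
                flat[key] = val
        unknown = set(flat) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "cycle_bounds" in flat:
            flat["cycle_bounds"] = tuple(flat["cycle_bounds"])
        return cls(**flat)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(d)


def process_pose_stream(path: str | Path, config: PipelineConfig) -> tuple[JointAngleSeries, ev.GaitEvents]:
    """Pose CSV -> body frame -> gap fill -> smooth -> angles + events."""
    fc = pp.FilterConfig(window=config.window, max_gap=config.max_gap)
    series = read_pose_csv(path)
    body = to_body_frame(series)
    body = pp.gap_fill(body, fc)
    body = pp.moving_average(body, fc)
    angles = compute_joint_angles(body)
    gait_events = ev.detect_events_both(body, config.min_separation_frac)
    return angles, gait_events


def process_reference(path: str | Path, config: PipelineConfig,
                      dialect: str = "csv") -> tuple[JointAngleSeries, ev.GaitEvents]:
    """Marker file -> sagittal body frame -> angles -> resample to target fps."""
    markers = read_marker_series(path, dialect=dialect)
    body = to_body_frame(markers)
    if config.smooth_reference:
        body = pp.moving_average(body, pp.FilterConfig(window=config.window,
                                                       max_gap=config.max_gap))
    angles = compute_joint_angles(body)
    angles = pp.resample(angles, config.target_fps)
    body30 = pp.resample(body, config.target_fps)
    gait_events = ev.detect_events_both(body30, config.min_separation_frac)
    return angles, gait_events


def analyze_trial_pair(ref_angles: JointAngleSeries, ref_events: ev.GaitEvents,
                       hpe_angles: JointAngleSeries, hpe_events: ev.GaitEvents,
                       config: PipelineConfig) -> ComparisonResult:
    """Align the two streams at their first left heel strike and compare."""
    hs_ref = int(ref_events.heel_strikes["left"][0])
    hs_hpe = int(hpe_events.heel_strikes["left"][0])
    a, b = pp.align_at_heel_strike(ref_angles, hpe_angles, hs_ref, hs_hpe)
    shifted = ev.GaitEvents(
        heel_strikes={s: hpe_events.heel_strikes[s] - hs_hpe for s in SIDES},
        toe_offs={s: hpe_events.toe_offs[s] - hs_hpe for s in SIDES})
    return compare_trial(a, b, events=shifted, per_cycle=config.per_cycle)


def run_pipeline(config: PipelineConfig) -> CohortSummary:
    """Run the full workflow over a simulated/recorded study directory.

    Expects the layout written by :func:`gaitkin.synthetic.simulate_study`
    (a ``manifest.json`` listing per-subject reference and pose files).
    Writes per-trial JSON results, MAE/rho summary CSVs and
    normalized-cycle CSVs to ``config.out_dir`` when set.
    """
    study_dir = Path(config.study_dir)
    manifest_path = study_dir / "manifest.json"
    if not manifest_path.exists():
        raise DataError(f"no manifest.json in {study_dir}")
    manifest = json.loads(manifest_path.read_text())

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    results: list[ComparisonResult] = []
    for entry in manifest["subjects"]:
        sid = entry["subject_id"]
        log.info("subject %s: reference %s", sid, entry["ref_markers"])
        try:
            ref_angles, ref_events = process_reference(
                study_dir / entry["ref_markers"], config)
        except DataError as exc:
            raise DataError(f"[reference, subject {sid}] {exc}") from exc
        for label, rel in entry["pose"].items():
            log.info("subject %s position %s: %s", sid, label, rel)
            try:
                hpe_angles, hpe_events = process_pose_stream(study_dir / rel, config)
                res = analyze_trial_pair(ref_angles, ref_events,
                                         hpe_angles, hpe_events, config)
            except DataError as exc:
                raise DataError(f"[compare, subject {sid}, {label}] {exc}") from exc
            results.append(res)
            if out_dir:
                rec = {"subject": sid, "position": label,
                       "metrics": {f"{j}_{s}": {
                           "mae": float(res.table.loc[(j, s), "mae"]),
                           "rho": float(res.table.loc[(j, s), "rho"]),
                           "n_frames": int(res.table.loc[(j, s), "n_frames"])}
                           for j in JOINTS for s in SIDES},
                       "params": {"window": config.window, "max_gap": config.max_gap,
                                  "target_fps": config.target_fps,
                                  "events_method": hpe_events.method}}
                (out_dir / f"trial_{sid}_{label}.json").write_text(
                    json.dumps(rec, indent=2) + "\n")

    summary = summarize_cohort(results)
    if out_dir:
        write_summary_tables(summary, out_dir)
    return summary


def write_summary_tables(summary: CohortSummary, out_dir: str | Path) -> None:
    """Emit MAE and rho tables (rows joint x side, columns positions)."""
    out_dir = Path(out_dir)
    for metric, mean_df, sd_df in (("mae", summary.mae_mean, summary.mae_sd),
                                   ("rho", summary.rho_mean, summary.rho_sd)):
        cells = mean_df.copy().astype(object)
        for idx in cells.index:
            for col in cells.columns:
                m, s = mean_df.loc[idx, col], sd_df.loc[idx, col]
                cells.loc[idx, col] = (f"{m:.2f} ± {s:.2f}"
                                       if np.isfinite(m) else "")
        if metric == "mae" and summary.p_position is not None:
            cells["p"] = [f"{summary.p_position.get(idx, np.nan):.4g}"
                          for idx in cells.index]
        cells.to_csv(out_dir / f"summary_{metric}.csv")
    summary.best_position.to_csv(out_dir / "best_positions.csv")
    summary.long.to_csv(out_dir / "per_trial_metrics.csv", index=False)


def export_cycles(angles: JointAngleSeries, gait_events: ev.GaitEvents,
                  path: str | Path) -> Path:
    """Write normalized-cycle mean/SD curves: percent,side,joint,mean,sd."""
    rows = []
    for (joint, side), nc in ev.cycle_ensembles(angles, gait_events).items():
        for g, m, s in zip(nc.grid, nc.mean, nc.sd):
            rows.append((g, side, joint, m, s))
    df = pd.DataFrame(rows, columns=["percent", "side", "joint", "mean", "sd"])
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6g")
    return path
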