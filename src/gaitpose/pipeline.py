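"""End-to-end trial and study runners.

``run_trial`` executes read -> preprocess -> event detection -> parameter
computation for one trial directory (OpenPose per-frame JSON) and writes
the per-trial outcome row and the detected events. ``run_study`` collects
per-trial results for a full cohort, builds the six-level condition table
and writes the statistical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .config import PipelineConfig, config_to_dict
from .errors import IncompleteParticipantError
from .gait_events import detect_events
from .gait_params import SpatiotemporalResult, summarize_trial
from .pose_io import CalibrationScale, read_openpose_sequence
from .preprocess import preprocess_pipeline
from .simulate import CONDITIONS
from .study_stats import analyze_cohort, render_report, select_best_condition
from .trajectory import KeypointTrajectorySet

log = logging.getLogger(__name__)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def process_trajectory(
    traj: KeypointTrajectorySet, cfg: PipelineConfig
) -> tuple[SpatiotemporalResult, object, list[int]]:
    """Preprocess an in-memory trajectory set and compute its outcomes."""
    ppm = cfg.pixels_per_meter or traj.meta.get(
        "pixels_per_meter", cfg.camera.pixels_per_meter
    )
    scale = CalibrationScale(pixels_per_meter=ppm)
    traj_m, swap_frames = preprocess_pipeline(traj, scale, cfg.preprocess)
    seq = detect_events(traj_m, cfg=cfg.events)
    result = summarize_trial(traj_m, seq)
    return result, seq, swap_frames


def run_trial(
    input_dir: str | Path,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    meta: dict | None = None,
) -> SpatiotemporalResult:
    """Process one trial directory of OpenPose frame files."""
    cfg = cfg or PipelineConfig()
    traj = read_openpose_sequence(
        input_dir, frame_rate=cfg.camera.frame_rate, meta=meta
    )
    traj.meta.setdefault("pixels_per_meter", cfg.camera.pixels_per_meter)
    result, seq, swap_frames = process_trajectory(traj, cfg)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        row = {**(meta or {}), **result.as_dict(),
               "n_strides_used": result.n_strides_used,
               "window_start_s": result.analysis_window[0],
               "window_end_s": result.analysis_window[1],
               "n_swap_frames": len(swap_frames),
               "config_hash": _config_hash(cfg)}
        pd.DataFrame([row]).to_csv(out_dir / "trial_result.csv", index=False)
        pd.DataFrame(
            [{"time_s": e.time, "side": e.side, "type": e.kind,
              "detector_signal_value": e.signal_value} for e in seq.events]
        ).to_csv(out_dir / "events.csv", index=False)
        log.info("trial %s: wrote results (config %s)", input_dir, _config_hash(cfg))
    return result


def run_study(
    results: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    strict: bool = False,
) -> "object":
    """Analyze a per-trial results table (participant, condition, outcomes).

    Incomplete participants are excluded with a warning, or rejected under
    ``strict``. Returns the :class:`~gaitpose.study_stats.StatReport`.
    """
    cfg = cfg or PipelineConfig()
    complete = results.groupby("participant")["condition"].apply(
        lambda s: set(s) >= set(CONDITIONS)
    )
    incomplete = complete.index[~complete].tolist()
    if incomplete:
        if strict:
            raise IncompleteParticipantError(
                f"incomplete participants under --strict: {incomplete}"
            )
        log.warning("excluding incomplete participants: %s", incomplete)
        results = results[~results["participant"].isin(incomplete)]
    report = analyze_cohort(
        results,
        alpha=cfg.stats.alpha,
        routing_override=cfg.stats.routing_override or None,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.pairwise_tidy().to_csv(out_dir / "pairwise.csv", index=False)
        report.mean_differences.to_csv(out_dir / "mean_differences.csv", index=False)
        report.winner_counts.to_csv(out_dir / "winner_counts.csv")
        with_best, _, _ = select_best_condition(results)
        (out_dir / "report.md").write_text(
            render_report(report, table_with_best=with_best)
        )
    return report
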