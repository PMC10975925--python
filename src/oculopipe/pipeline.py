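"""End-to-end orchestration: ingest -> kinematics -> blinks -> saccades ->
pupillometry -> classification, with per-trial fault isolation.

A failure in any stage degrades that trial to "Not marked" and never aborts
the session.  All analysis stages are deterministic; reruns on identical
inputs and config produce byte-identical output tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .blink_detect import BlinkRecord, detect_blinks
from .config import PipelineConfig
from .io_session import TrialRecord, read_session
from .ipast_classify import (TrialClassification, classify_trial,
                             session_stats, SessionStats)
from .kinematics import (VelocityTrace, apply_drift_offset, compute_velocity,
                         drift_reference, pixels_to_degrees)
from .pupillometry import eligible_trial, pupil_metrics, pupil_table
from .saccade_detect import (detect_saccades_trial, main_sequence_zscores,
                             saccade_table)

log = logging.getLogger(__name__)

__all__ = ["SessionResult", "analyze_session", "run_all"]


@dataclass
class SessionResult:
    saccades: pd.DataFrame
    blinks: pd.DataFrame
    thresholds: pd.DataFrame
    pupil: pd.DataFrame
    classifications: list[TrialClassification]
    trials_table: pd.DataFrame
    stats: SessionStats | None
    masez_meta: dict = field(default_factory=dict)
    drift_offsets: pd.DataFrame | None = None
    failed_trials: list[int] = field(default_factory=list)


def analyze_session(
    trials: list[TrialRecord],
    config: PipelineConfig | None = None,
    do_merge_pso: bool = True,
    do_classify: bool = True,
    do_pupil: bool = True,
) -> SessionResult:
    """Run the full analysis on parsed trials (pixel units in, tables out)."""
    cfg = config or PipelineConfig()
    tl = cfg.timeline
    w = cfg.smoothing.w_at(trials[0].trace.rate_hz) if trials else cfg.smoothing.w

    deg_trials: list[TrialRecord | None] = []
    vels: list[VelocityTrace | None] = []
    failed: list[int] = []
    for rec in trials:
        try:
            if rec.trace.units == "px":
                rec = TrialRecord(**{**rec.__dict__, "trace": pixels_to_degrees(
                    rec.trace, rec.geometry)})
            else:
                rec = TrialRecord(**{**rec.__dict__, "trace": rec.trace.copy()})
            vel = compute_velocity(rec.trace, w) if len(rec.trace) > 6 * w else None
            deg_trials.append(rec)
            vels.append(vel)
        except Exception:
            log.exception("trial %s failed unit conversion; Not marked", rec.trial_id)
            deg_trials.append(None)
            vels.append(None)
            failed.append(rec.trial_id)

    # drift re-referencing, pooled per segment
    drift_rows = []
    by_segment: dict[int, list[int]] = {}
    for i, rec in enumerate(deg_trials):
        if rec is not None and vels[i] is not None:
            by_segment.setdefault(rec.drift_segment_id, []).append(i)
    for seg, idxs in sorted(by_segment.items()):
        off = drift_reference(
            [deg_trials[i] for i in idxs], [vels[i] for i in idxs],
            epoch_ms=cfg.drift.epoch_ms, bin_deg=cfg.drift.bin_deg,
            span_deg=cfg.drift.span_deg, min_samples=cfg.drift.min_samples,
            speed_max_dps=cfg.drift.speed_max_dps, segment_id=seg,
        )
        for i in idxs:
            apply_drift_offset(deg_trials[i], off, vels[i])
        drift_rows.append({"segment_id": seg, "dx": off.dx, "dy": off.dy,
                           "n_samples_used": off.n_samples_used})

    all_sacc: list = []
    all_blinks: list[dict] = []
    thr_rows: list[dict] = []
    blinks_by_trial: dict[int, list[BlinkRecord]] = {}
    for rec, vel in zip(deg_trials, vels):
        if rec is None:
            continue
        try:
            _, blinks = detect_blinks(rec.trace.A, rec.trace.T,
                                      rec.trace.rate_hz, rec.trial_id, cfg.blink)
            blinks_by_trial[rec.trial_id] = blinks
            if vel is None:
                continue
            thr, events, reclassified = detect_saccades_trial(
                rec.trial_id, rec.trace.T, vel, rec.trace.rate_hz,
                fixation_epoch_ms=cfg.drift.epoch_ms, blinks=blinks,
                sacc_cfg=cfg.saccade,
                pso_cfg=cfg.pso if do_merge_pso else _NO_PSO,
                boom_cfg=cfg.boomerang, blinc_cfg=cfg.blincade,
            )
            thr_rows.append({"trial_id": thr.trial_id, "value": thr.value,
                             "noise_mean": thr.noise_mean, "noise_sd": thr.noise_sd,
                             "n_noise_samples": thr.n_noise_samples})
            all_sacc.extend(events)
            for r in reclassified:
                # the area-based pass usually already holds this blink; only
                # add a record when the reclassified pair is new
                if any(b.blink_start <= r["end_ms"] and b.blink_end >= r["start_ms"]
                       for b in blinks_by_trial[rec.trial_id]):
                    continue
                blinks_by_trial[rec.trial_id].append(BlinkRecord(
                    trial_id=rec.trial_id,
                    loss_start=r["start_ms"], loss_end=r["end_ms"],
                    blink_start=r["start_ms"], blink_end=r["end_ms"],
                    duration_ms=r["end_ms"] - r["start_ms"],
                    category="blink", partial=True, tail="low",
                ))
        except Exception:
            log.exception("trial %s failed detection; Not marked", rec.trial_id)
            failed.append(rec.trial_id)

    for tid, blist in blinks_by_trial.items():
        for b in blist:
            all_blinks.append({
                "trial_id": b.trial_id, "loss_start": b.loss_start,
                "loss_end": b.loss_end, "blink_start": b.blink_start,
                "blink_end": b.blink_end, "duration_ms": b.duration_ms,
                "category": b.category, "partial": b.partial, "tail": b.tail,
            })

    sacc_df = saccade_table(all_sacc)
    sacc_df, masez_meta = main_sequence_zscores(sacc_df, cfg.masez)
    blink_df = pd.DataFrame(
        all_blinks, columns=["trial_id", "loss_start", "loss_end", "blink_start",
                             "blink_end", "duration_ms", "category", "partial",
                             "tail"])
    thr_df = pd.DataFrame(thr_rows, columns=["trial_id", "value", "noise_mean",
                                             "noise_sd", "n_noise_samples"])

    pupil_rows = []
    classifications: list[TrialClassification] = []
    for rec in deg_trials:
        if rec is None:
            continue
        tid = rec.trial_id
        tsacc = sacc_df[sacc_df["trial_id"] == tid] if len(sacc_df) else sacc_df
        tblinks = blinks_by_trial.get(tid, [])
        if do_pupil:
            try:
                ok, reason = eligible_trial(rec, tsacc, tblinks, cfg.pupil, tl)
                pupil_rows.append(pupil_metrics(rec, ok, reason, cfg.pupil, tl))
            except Exception:
                log.exception("trial %s failed pupillometry", tid)
        if do_classify:
            try:
                if tid in failed:
                    raise RuntimeError("upstream failure")
                classifications.append(classify_trial(rec, tsacc, tblinks,
                                                      cfg.classify, tl))
            except Exception:
                classifications.append(TrialClassification(
                    tid, rec.condition, "Not marked", None, False))

    pupil_df = pupil_table(pupil_rows)
    trials_df = pd.DataFrame(
        [{"trial_id": c.trial_id, "condition": c.condition, "category": c.category,
          "first_viable_srt": c.first_viable_srt, "lapse_flag": c.lapse_flag}
         for c in classifications],
        columns=["trial_id", "condition", "category", "first_viable_srt",
                 "lapse_flag"])
    stats = session_stats(classifications) if classifications else None
    return SessionResult(
        saccades=sacc_df, blinks=blink_df, thresholds=thr_df, pupil=pupil_df,
        classifications=classifications, trials_table=trials_df, stats=stats,
        masez_meta=masez_meta,
        drift_offsets=pd.DataFrame(drift_rows, columns=["segment_id", "dx", "dy",
                                                        "n_samples_used"]),
        failed_trials=sorted(set(failed)),
    )


class _NoPso:
    """PSO config that never merges (gap test always fails)."""
    max_gap_ms = -1.0
    amp_min_deg = 0.0
    amp_max_deg = 0.0


_NO_PSO = _NoPso()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def run_all(
    session: str | Path | list[TrialRecord],
    config: PipelineConfig | None = None,
    outdir: str | Path = "results",
) -> SessionResult:
    """Run the whole pipeline and write the six output tables + manifest."""
    cfg = config or PipelineConfig()
    if isinstance(session, (str, Path)):
        trials = read_session(session, dialect=cfg.io.dialect,
                              max_interp_gap_ms=cfg.io.max_interp_gap_ms)
    else:
        trials = session
    result = analyze_session(trials, cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(result.saccades, outdir / "saccades.tsv")
    _write_tsv(result.blinks, outdir / "blinks.tsv")
    _write_tsv(result.thresholds, outdir / "thresholds.tsv")
    _write_tsv(result.pupil, outdir / "pupil.tsv")
    _write_tsv(result.trials_table, outdir / "trials.tsv")
    if result.stats is not None:
        with open(outdir / "session_stats.json", "w") as fh:
            json.dump({
                "n_trials": result.stats.n_trials,
                "counts": result.stats.counts,
                "error_rate": result.stats.error_rate,
                "error_ratio": result.stats.error_ratio,
                "non_compliance_rate": result.stats.non_compliance_rate,
                "fixation_break_rate": result.stats.fixation_break_rate,
                "anticipatory_rate": result.stats.anticipatory_rate,
            }, fh, indent=1, sort_keys=True)
    manifest = {
        "oculopipe_version": __version__,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "n_trials": len(trials),
        "n_failed_trials": len(result.failed_trials),
        "masez_meta": result.masez_meta,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return result
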