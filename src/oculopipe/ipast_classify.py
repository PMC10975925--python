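"""IPAST saccade-timing and trial classification, plus session statistics.

Saccade timing relative to STIM onset: anticipatory responses launch in
[-110, 89] ms (too early to be visually triggered -- a guess), express in
[90, 139] ms, regular in [140, 800] ms; responses after 800 ms are kept for
trial classification (up to 1000 ms) but dropped from latency metrics.

Each trial receives exactly one category.  The decision order runs from data
quality outward: eye loss, fixation attainment, fixation breaks, then the
first viable saccade's timing and direction, then the residual categories
(random saccade / no saccade).  Transient fixation breaks that recover before
FIX offset only set a lapse flag and defer to the subsequent behavior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blink_detect import BlinkRecord
from .config import ClassifyConfig, TimelineConfig
from .io_session import TrialRecord

__all__ = [
    "CATEGORIES",
    "TimingClass",
    "TrialClassification",
    "SessionStats",
    "classify_timing",
    "first_viable_saccade",
    "classify_trial",
    "session_stats",
]

# Category names exactly as reported in the trial-type table.
CATEGORIES = [
    "Not marked",
    "Correct Pro-Saccade",
    "Correct Anti-Saccade",
    "Pro-Saccade Direction Error",
    "Anti-Saccade Direction Error",
    "Anticipatory Correct Pro-Saccade",
    "Anticipatory Correct Anti-Saccade",
    "Anticipatory Pro-Saccade Direction Error",
    "Anticipatory Anti-Saccade Direction Error",
    "Fixation Break",
    "No Saccade",
    "Random Saccade",
    "Never Fixated",
    "Eye Loss",
]


@dataclass
class TimingClass:
    label: str  # fixation_break | anticipatory | express | regular | late
    srt_ms: float


@dataclass
class TrialClassification:
    trial_id: int
    condition: str | None
    category: str
    first_viable_srt: float | None
    lapse_flag: bool


@dataclass
class SessionStats:
    counts: dict  # condition -> {category: n}
    n_trials: int
    error_rate: float | None
    error_ratio: float | None
    non_compliance_rate: float | None
    fixation_break_rate: float | None
    anticipatory_rate: float | None


def classify_timing(srt_ms: float, cfg: ClassifyConfig | None = None) -> TimingClass:
    """Label an SRT by its window; boundaries are honored exactly."""
    cfg = cfg or ClassifyConfig()
    a0, a1 = cfg.anticipatory_ms
    e0, e1 = cfg.express_ms
    r0, r1 = cfg.regular_ms
    if srt_ms < a0:
        label = "fixation_break"
    elif srt_ms <= a1:
        label = "anticipatory"
    elif e0 <= srt_ms <= e1:
        label = "express"
    elif r0 <= srt_ms <= r1:
        label = "regular"
    elif r1 < srt_ms <= cfg.viable_ms[1]:
        label = "late"
    else:
        label = "late"
    return TimingClass(label=label, srt_ms=srt_ms)


def first_viable_saccade(
    saccades: pd.DataFrame,
    cfg: ClassifyConfig | None = None,
) -> pd.Series | None:
    """First movement (blincades included) that could answer the stimulus:
    amplitude >= 2 deg, launched within 2 deg of FIX, onset in [-110, 1000] ms."""
    cfg = cfg or ClassifyConfig()
    if len(saccades) == 0:
        return None
    df = saccades.sort_values("onset_ms", kind="stable")
    launch = np.hypot(df["start_x"], df["start_y"])
    m = (df["amplitude"] >= cfg.viable_amp_deg) \
        & (launch <= cfg.fix_radius_deg) \
        & (df["onset_ms"] >= cfg.viable_ms[0]) \
        & (df["onset_ms"] <= cfg.viable_ms[1])
    if not m.any():
        return None
    return df.loc[m].iloc[0]


def _direction_toward_stim(dx: float, stim_side: str) -> bool:
    return dx < 0 if stim_side == "left" else dx > 0


def _off_both_axes(dx: float, dy: float, tol_deg: float) -> bool:
    ang = abs(np.degrees(np.arctan2(dy, dx)))
    return min(ang, 180.0 - ang) > tol_deg


def _fixation_runs(inside: np.ndarray, analyzable: np.ndarray):
    """Runs of in-window samples over analyzable (non-loss) data."""
    use = inside & analyzable
    edges = np.diff(np.concatenate(([0], use.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def classify_trial(
    trial: TrialRecord,
    saccades: pd.DataFrame,
    blinks: list[BlinkRecord],
    cfg: ClassifyConfig | None = None,
    timeline: TimelineConfig | None = None,
) -> TrialClassification:
    """Assign the trial its single behavioral category."""
    cfg = cfg or ClassifyConfig()
    timeline = timeline or TimelineConfig()
    cid = trial.trial_id

    if trial.not_marked or trial.condition not in ("PRO", "ANTI") \
            or trial.stim_side not in ("left", "right"):
        return TrialClassification(cid, trial.condition, "Not marked", None, False)

    t = trial.trace.T
    fix_on, fix_off = timeline.fix_on_ms, timeline.fix_off_ms
    resp_end = cfg.viable_ms[1]

    # (1) Eye Loss over the FIX + response epochs
    m_epochs = (t >= fix_on) & (t <= resp_end)
    lost = (trial.trace.A == 0) | ~trial.trace.valid
    if m_epochs.any():
        frac = float(np.mean(lost[m_epochs]))
        if frac > cfg.eye_loss_frac:
            return TrialClassification(cid, trial.condition, "Eye Loss", None, False)

    # samples inside blink extents are not trusted for gaze-window analysis
    analyzable = ~lost
    for b in blinks:
        analyzable &= ~((t >= b.blink_start) & (t <= b.blink_end))

    dist = np.hypot(trial.trace.X, trial.trace.Y)
    inside = dist <= cfg.fix_radius_deg
    m_fix = (t >= fix_on) & (t <= fix_off)
    step = trial.trace.step_ms
    dwell_samples = int(round(cfg.fix_dwell_ms / step))

    # (2) Never Fixated: no continuous dwell inside the FIX window
    fix_idx = np.flatnonzero(m_fix)
    attained_at: int | None = None
    if len(fix_idx):
        runs = _fixation_runs(inside[fix_idx], analyzable[fix_idx])
        for s, e in runs:
            if e - s + 1 >= dwell_samples:
                attained_at = fix_idx[0] + s
                break
    if attained_at is None:
        return TrialClassification(cid, trial.condition, "Never Fixated", None, False)

    # (3) Fixation Break: left the window before FIX offset and never returned
    lapse = False
    after = fix_idx[fix_idx >= attained_at]
    outs = ~inside[after] & analyzable[after]
    if outs.any():
        first_out = int(np.flatnonzero(outs)[0])
        back = inside[after] & analyzable[after]
        if back[first_out:].any():
            lapse = True
        else:
            return TrialClassification(cid, trial.condition, "Fixation Break",
                                       None, False)

    # (4)-(7): first viable saccade
    v = first_viable_saccade(saccades, cfg)
    if v is None:
        return TrialClassification(cid, trial.condition, "No Saccade", None, lapse)
    srt = float(v["onset_ms"])
    dx = float(v["end_x"] - v["start_x"])
    dy = float(v["end_y"] - v["start_y"])

    if _off_both_axes(dx, dy, cfg.random_axis_off_deg):
        return TrialClassification(cid, trial.condition, "Random Saccade", srt, lapse)

    toward = _direction_toward_stim(dx, trial.stim_side)
    timing = classify_timing(srt, cfg)
    pro = trial.condition == "PRO"
    correct = toward if pro else not toward
    if timing.label == "anticipatory":
        if pro:
            cat = ("Anticipatory Correct Pro-Saccade" if correct
                   else "Anticipatory Pro-Saccade Direction Error")
        else:
            cat = ("Anticipatory Correct Anti-Saccade" if correct
                   else "Anticipatory Anti-Saccade Direction Error")
    elif timing.label in ("express", "regular", "late"):
        if pro:
            cat = "Correct Pro-Saccade" if correct else "Pro-Saccade Direction Error"
        else:
            cat = "Correct Anti-Saccade" if correct else "Anti-Saccade Direction Error"
    else:  # pre-anticipatory movement that slipped past the break logic
        return TrialClassification(cid, trial.condition, "Fixation Break", srt, lapse)
    return TrialClassification(cid, trial.condition, cat, srt, lapse)


def session_stats(classifications: list[TrialClassification]) -> SessionStats:
    """Per-condition category counts and the headline rate/ratio statistics.

    ``error_rate`` divides ANTI direction errors (post-stimulus window) by all
    ANTI trials; ``error_ratio`` divides them by correct + direction-error
    ANTI trials only.  Non-compliance pools no-saccade, random-saccade and
    never-fixated trials over all trials.
    """
    counts: dict[str, dict[str, int]] = {}
    for c in classifications:
        cond = c.condition if c.condition in ("PRO", "ANTI") else "UNKNOWN"
        counts.setdefault(cond, {k: 0 for k in CATEGORIES})
        counts[cond][c.category] += 1
    n = len(classifications)

    def _rate(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    anti = counts.get("ANTI", {k: 0 for k in CATEGORIES})
    anti_total = sum(anti.values())
    err = anti["Anti-Saccade Direction Error"]
    corr = anti["Correct Anti-Saccade"]
    all_counts = {k: sum(c.get(k, 0) for c in counts.values()) for k in CATEGORIES}
    non_comp = (all_counts["No Saccade"] + all_counts["Random Saccade"]
                + all_counts["Never Fixated"])
    antic = sum(all_counts[k] for k in CATEGORIES if k.startswith("Anticipatory"))
    return SessionStats(
        counts=counts,
        n_trials=n,
        error_rate=_rate(err, anti_total),
        error_ratio=_rate(err, corr + err),
        non_compliance_rate=_rate(non_comp, n),
        fixation_break_rate=_rate(all_counts["Fixation Break"], n),
        anticipatory_rate=_rate(antic, n),
    )
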