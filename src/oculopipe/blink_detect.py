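"""Blink detection from pupil-area dropout.

Video trackers lose the pupil during blinks (area falls to zero) and corrupt
it during partial occlusions (mascara, squinting).  Per trial the pipeline:

1. normalizes pupil area so its non-zero mean is 300 arbitrary units (A300);
2. removes the slow, non-linear area trend by modelling it on a copy with
   high-velocity / out-of-band samples interpolated away, heavily smoothing
   that copy, and subtracting it (re-centred on 300) -> Aflat;
3. detects data-loss intervals where Aflat leaves the 250-350 band;
4. refines each interval to the full blink extent by walking outward while
   the smoothed absolute area velocity stays above a per-trial dynamic
   threshold (the eyelid perturbs the area signal before and after the
   actual data loss);
5. categorizes each loss by its full duration (blink / dropout / other loss).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import BlinkConfig
from .kinematics import central_velocity, zero_phase_boxcar

__all__ = [
    "PupilAreaTrace",
    "BlinkRecord",
    "normalize_area",
    "flatten_area",
    "detect_loss",
    "refine_blink_extent",
    "categorize_loss",
    "detect_blinks",
]


@dataclass
class PupilAreaTrace:
    A300: np.ndarray
    Aflat: np.ndarray
    sVEL: np.ndarray
    saVEL: np.ndarray


@dataclass
class BlinkRecord:
    """One data-loss interval with its refined full-blink extent (ms)."""

    trial_id: int
    loss_start: float
    loss_end: float
    blink_start: float
    blink_end: float
    duration_ms: float
    category: str  # blink | dropout | other_loss
    partial: bool  # area excursion without the raw signal reaching zero
    tail: str = "low"  # which Aflat tail triggered detection: low | high


def _safe_boxcar(x: np.ndarray, w: int) -> np.ndarray:
    """Boxcar with the width clipped so short traces remain filterable."""
    if len(x) < 2:
        return x.astype(float)
    w_eff = min(w, max(1, (len(x) - 1) // 3))
    return zero_phase_boxcar(x, w_eff)


def normalize_area(A: np.ndarray) -> np.ndarray:
    """Scale pupil area so the mean of samples above 10 equals 300.

    Samples at or below 10 (loss or near-loss) are excluded from the mean but
    still scaled; a trial with no sample above 10 returns all zeros (the trial
    is flagged as eye loss downstream).
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("pupil area must be non-negative")
    mask = A > 10
    if not mask.any():
        return np.zeros_like(A)
    return A / A[mask].mean() * 300.0


def _interp_failed(x: np.ndarray, ok: np.ndarray) -> np.ndarray:
    """Replace failing samples by linear interpolation between flanking passes;
    failing stretches touching an edge are extended from the nearest pass."""
    if ok.all():
        return x.copy()
    if not ok.any():
        return np.full_like(x, 300.0)
    idx = np.arange(len(x))
    return np.interp(idx, idx[ok], x[ok])


def flatten_area(A300: np.ndarray, rate_hz: float = 500.0,
                 cfg: BlinkConfig | None = None) -> PupilAreaTrace:
    """Remove the low-frequency area trend so fixed thresholds apply.

    The trend model is re-centred on 300 after subtraction so that the 250/350
    loss thresholds remain meaningful on the flattened signal.
    """
    cfg = cfg or BlinkConfig()
    A300 = np.asarray(A300, dtype=float)
    if len(A300) < 3:
        flat = A300.copy()
        z = np.zeros_like(A300)
        return PupilAreaTrace(A300=A300, Aflat=flat, sVEL=z, saVEL=z)
    # area velocity in units per sample step; threshold scales with rate
    vel = central_velocity(A300, dt=1.0)
    sVEL = _safe_boxcar(vel, 3)
    saVEL = _safe_boxcar(np.abs(vel), 3)
    svel_thresh = cfg.svel_thresh * (500.0 / rate_hz)
    ok = (np.abs(sVEL) <= svel_thresh) & (A300 >= cfg.band_lo) & (A300 <= cfg.band_hi)
    repaired = _interp_failed(A300, ok)
    model = _safe_boxcar(repaired, cfg.model_w)
    Aflat = A300 - model + 300.0
    return PupilAreaTrace(A300=A300, Aflat=Aflat, sVEL=sVEL, saVEL=saVEL)


def detect_loss(Aflat: np.ndarray, rate_hz: float = 500.0,
                cfg: BlinkConfig | None = None) -> list[tuple[int, int, str]]:
    """Maximal runs where Aflat leaves [250, 350]; nearby runs merged.

    Returns (start_idx, end_idx_inclusive, tail) with tail 'low' if the run
    dipped below the band and 'high' if it only exceeded it (mascara case).
    """
    cfg = cfg or BlinkConfig()
    Aflat = np.asarray(Aflat, dtype=float)
    bad = (Aflat < cfg.loss_lo) | (Aflat > cfg.loss_hi)
    if not bad.any():
        return []
    edges = np.diff(np.concatenate(([0], bad.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    runs = list(zip(starts.tolist(), ends.tolist()))
    # merge runs separated by less than merge_gap_ms
    gap_samples = cfg.merge_gap_ms * rate_hz / 1000.0
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 < gap_samples:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        seg = Aflat[s:e + 1]
        tail = "low" if np.any(seg < cfg.loss_lo) else "high"
        out.append((s, e, tail))
    return out


def refine_blink_extent(
    A300: np.ndarray,
    loss_intervals: list[tuple[int, int]],
    which: int,
    rate_hz: float = 500.0,
    cfg: BlinkConfig | None = None,
    saVEL: np.ndarray | None = None,
) -> tuple[int, int]:
    """Expand one loss interval to the full blink extent.

    The smoothed absolute area velocity (saVEL) is compared against a dynamic
    per-trial threshold (mean + k*SD over samples at least ``quiet_gap_ms``
    away from any loss interval, floored); the extent walks outward from the
    loss bounds while saVEL stays above threshold, capped at ``walk_cap_ms``.
    """
    cfg = cfg or BlinkConfig()
    A300 = np.asarray(A300, dtype=float)
    n = len(A300)
    if saVEL is None:
        saVEL = _safe_boxcar(np.abs(central_velocity(A300, dt=1.0)), 3)
    s0, e0 = loss_intervals[which][0], loss_intervals[which][1]

    quiet = np.ones(n, dtype=bool)
    guard = int(round(cfg.quiet_gap_ms * rate_hz / 1000.0))
    for iv in loss_intervals:
        lo = max(0, iv[0] - guard)
        hi = min(n, iv[1] + 1 + guard)
        quiet[lo:hi] = False
    floor = cfg.savel_floor * (500.0 / rate_hz)
    if not quiet.any():
        warnings.warn("no quiescent samples for blink-extent threshold; "
                      "extent left at the loss interval", stacklevel=2)
        return s0, e0
    q = saVEL[quiet]
    thr = max(floor, float(q.mean() + cfg.k_sd * q.std()))

    cap = int(round(cfg.walk_cap_ms * rate_hz / 1000.0))
    b0 = s0
    while b0 > 0 and s0 - (b0 - 1) <= cap and saVEL[b0 - 1] > thr:
        b0 -= 1
    b1 = e0
    while b1 < n - 1 and (b1 + 1) - e0 <= cap and saVEL[b1 + 1] > thr:
        b1 += 1
    return b0, b1


def categorize_loss(duration_ms: float, cfg: BlinkConfig | None = None) -> str:
    """Duration-based taxonomy: short flickers are tracker dropouts, very long
    losses are some other interference; the stereotypical range is a blink."""
    cfg = cfg or BlinkConfig()
    if duration_ms < cfg.min_ms:
        return "dropout"
    if duration_ms > cfg.max_ms:
        return "other_loss"
    return "blink"


def detect_blinks(
    A: np.ndarray,
    T: np.ndarray,
    rate_hz: float,
    trial_id: int = 0,
    cfg: BlinkConfig | None = None,
) -> tuple[PupilAreaTrace, list[BlinkRecord]]:
    """Full per-trial blink pass on the raw area vector."""
    cfg = cfg or BlinkConfig()
    A = np.asarray(A, dtype=float)
    T = np.asarray(T, dtype=float)
    A300 = normalize_area(A)
    trace = flatten_area(A300, rate_hz, cfg)
    if not A300.any():
        return trace, []  # fully lost trial; classified Eye Loss downstream
    intervals = detect_loss(trace.Aflat, rate_hz, cfg)
    records: list[BlinkRecord] = []
    pairs = [(s, e) for s, e, _ in intervals]
    for k, (s, e, tail) in enumerate(intervals):
        b0, b1 = refine_blink_extent(A300, pairs, k, rate_hz, cfg, saVEL=trace.saVEL)
        duration = T[b1] - T[b0] + (T[1] - T[0] if len(T) > 1 else 0.0)
        partial = not np.any(A[s:e + 1] == 0)
        records.append(BlinkRecord(
            trial_id=trial_id,
            loss_start=float(T[s]), loss_end=float(T[e]),
            blink_start=float(T[b0]), blink_end=float(T[b1]),
            duration_ms=float(duration),
            category=categorize_loss(duration, cfg),
            partial=bool(partial), tail=tail,
        ))
    return trace, records
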