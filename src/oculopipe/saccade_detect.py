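"""Saccade detection and the saccade table.

Detection uses a per-trial dynamic speed threshold: the mean + 2.5 SD of the
fixation-epoch background noise (samples below a fixed 50 deg/s ceiling),
never less than 20 deg/s.  Speed must stay above threshold for 10 ms to count
as a saccade.

The raw events then go through three corrections specific to video-based
tracking:

* **PSO merging** -- the iris keeps wobbling after the eye stops ("slosh"),
  producing small supra-threshold lobes just after a saccade.  A following
  event that is close in time (< 40 ms), small (0.5-5 deg) and smaller than
  the main saccade is absorbed into it, which moves the recorded endpoint to
  where the oscillation settles and markedly improves endpoint accuracy (at
  the cost of overestimating duration).
* **Boomerang splitting** -- two opposed saccades fused into one
  supra-threshold event (speed never dips below threshold between them) are
  split at the deepest speed nadir between the two major speed peaks.
* **Blincade resolution** -- events overlapping data loss are tagged; the
  classic blink artifact (upward loss event immediately followed by a
  downward return landing near the start) is reclassified as a blink, and a
  genuine mid-saccade blink becomes a single "blincade" usable for behavior
  but not for kinematics.

Finally each saccade receives two main-sequence Z-scores (peak velocity
against amplitude and against duration, residuals of a low-flexibility cubic
spline fit on clean saccades); |Z| >= 3.29 (p < 0.001) flags fouled tracking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import LSQUnivariateSpline
from scipy.signal import find_peaks

from .blink_detect import BlinkRecord
from .config import (BlincadeConfig, BoomerangConfig, MainSequenceConfig,
                     PsoConfig, SaccadeConfig)
from .kinematics import VelocityTrace

__all__ = [
    "DetectionThreshold",
    "SaccadeRecord",
    "dynamic_threshold",
    "detect_candidates",
    "measure_event",
    "merge_pso",
    "split_boomerang",
    "resolve_blincades",
    "saccade_table",
    "main_sequence_zscores",
    "filter_by_masez",
    "detect_saccades_trial",
]


@dataclass
class DetectionThreshold:
    trial_id: int
    value: float
    noise_mean: float
    noise_sd: float
    n_noise_samples: int


@dataclass
class SaccadeRecord:
    trial_id: int
    onset_ms: float
    offset_ms: float
    start_x: float
    start_y: float
    end_x: float
    end_y: float
    amplitude: float
    angle: float
    duration_ms: float
    peak_velocity: float
    peak_acceleration: float
    pso_merged: bool = False
    pso_end_ms: float | None = None
    boomerang_half: str = "none"  # none | first | second
    boomerang_unsplit: bool = False  # met boomerang criteria but had no nadir
    blincade: bool = False
    interpolated: bool = False  # blincade trajectory linearly interpolated
    lapse_flag: bool = False
    masez_amp: float = np.nan
    masez_dur: float = np.nan
    onset_idx: int = field(default=-1, repr=False)
    offset_idx: int = field(default=-1, repr=False)
    # offset of the pre-slosh core (first threshold crossing); equals
    # offset_idx unless oscillation lobes were merged in
    core_offset_idx: int = field(default=-1, repr=False)


# ---------------------------------------------------------------------------
# threshold & raw candidates
# ---------------------------------------------------------------------------

def dynamic_threshold(
    speed: np.ndarray,
    T: np.ndarray,
    fixation_epoch_ms: tuple[float, float],
    trial_id: int = 0,
    cfg: SaccadeConfig | None = None,
) -> DetectionThreshold:
    """Noise-adaptive detection threshold for one trial.

    Over fixation-epoch samples with speed below the fixed 50 deg/s ceiling:
    ``max(20, mean + 2.5 * SD)``.  Too few qualifying samples -> floor of 20
    with a warning.
    """
    cfg = cfg or SaccadeConfig()
    speed = np.asarray(speed, dtype=float)
    T = np.asarray(T, dtype=float)
    m = (T >= fixation_epoch_ms[0]) & (T <= fixation_epoch_ms[1])
    q = speed[m & (speed < cfg.noise_ceiling_dps)]
    if len(q) < cfg.min_noise_samples:
        warnings.warn(
            f"trial {trial_id}: only {len(q)} noise samples for the dynamic "
            "threshold; falling back to the 20 deg/s floor", stacklevel=2,
        )
        return DetectionThreshold(trial_id, cfg.floor_dps,
                                  float(q.mean()) if len(q) else np.nan,
                                  float(q.std()) if len(q) else np.nan, len(q))
    mu, sd = float(q.mean()), float(q.std())
    return DetectionThreshold(trial_id, max(cfg.floor_dps, mu + cfg.k_sd * sd),
                              mu, sd, len(q))


def detect_candidates(
    speed: np.ndarray,
    threshold: float,
    rate_hz: float,
    min_dur_ms: float = 10.0,
) -> list[tuple[int, int]]:
    """Maximal supra-threshold runs lasting at least ``min_dur_ms``.

    Returns (onset_idx, offset_idx) pairs where the offset is the first
    sub-threshold sample after the run (clipped to the last sample).
    """
    speed = np.asarray(speed, dtype=float)
    above = speed > threshold
    if not above.any():
        return []
    edges = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    min_samples = int(np.ceil(min_dur_ms * rate_hz / 1000.0))
    out = []
    for s, e in zip(starts, ends):
        if e - s + 1 >= min_samples:
            out.append((int(s), int(min(e + 1, len(speed) - 1))))
    return out


def measure_event(
    trial_id: int,
    i0: int,
    i1: int,
    T: np.ndarray,
    vel: VelocityTrace,
    dt_s: float,
) -> SaccadeRecord:
    """Build a SaccadeRecord for samples [i0, i1] from the smoothed trace."""
    xs, ys = vel.xs, vel.ys
    dx = xs[i1] - xs[i0]
    dy = ys[i1] - ys[i0]
    seg = vel.speed[i0:i1 + 1]
    accel = np.gradient(seg, dt_s) if len(seg) >= 2 else np.zeros(1)
    return SaccadeRecord(
        trial_id=trial_id,
        onset_ms=float(T[i0]), offset_ms=float(T[i1]),
        start_x=float(xs[i0]), start_y=float(ys[i0]),
        end_x=float(xs[i1]), end_y=float(ys[i1]),
        amplitude=float(np.hypot(dx, dy)),
        angle=float(np.degrees(np.arctan2(dy, dx))),
        duration_ms=float(T[i1] - T[i0]),
        peak_velocity=float(seg.max()),
        peak_acceleration=float(accel.max()),
        onset_idx=i0, offset_idx=i1, core_offset_idx=i1,
    )


# ---------------------------------------------------------------------------
# PSO merging
# ---------------------------------------------------------------------------

def merge_pso(
    events: list[SaccadeRecord],
    T: np.ndarray,
    vel: VelocityTrace,
    dt_s: float,
    cfg: PsoConfig | None = None,
) -> list[SaccadeRecord]:
    """Absorb post-saccadic oscillation lobes into their parent saccades.

    A following event is merged iff the gap is < 40 ms, its amplitude lies in
    [0.5, 5] deg, and it is smaller than the main saccade.  Merging is applied
    left-to-right and iteratively, so a merged saccade can absorb a further
    oscillation lobe under the same rules.
    """
    cfg = cfg or PsoConfig()
    out: list[SaccadeRecord] = []
    i = 0
    while i < len(events):
        cur = events[i]
        j = i + 1
        while j < len(events):
            nxt = events[j]
            gap = nxt.onset_ms - cur.offset_ms
            if (gap < cfg.max_gap_ms
                    and cfg.amp_min_deg <= nxt.amplitude <= cfg.amp_max_deg
                    and nxt.amplitude < cur.amplitude):
                merged = measure_event(cur.trial_id, cur.onset_idx,
                                       nxt.offset_idx, T, vel, dt_s)
                merged.pso_merged = True
                merged.pso_end_ms = merged.offset_ms
                merged.lapse_flag = cur.lapse_flag
                merged.core_offset_idx = cur.core_offset_idx
                cur = merged
                j += 1
            else:
                break
        out.append(cur)
        i = j
    return out


# ---------------------------------------------------------------------------
# boomerang splitting
# ---------------------------------------------------------------------------

def _angdiff(a: float, b: float) -> float:
    """Absolute angular difference in degrees, in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def split_boomerang(
    event: SaccadeRecord,
    T: np.ndarray,
    vel: VelocityTrace,
    dt_s: float,
    rate_hz: float,
    task_axes_deg: tuple[float, float] = (0.0, 180.0),
    cfg: BoomerangConfig | None = None,
) -> list[SaccadeRecord]:
    """Split a fused pair of opposed saccades at an interior speed nadir.

    Criteria: (i) initial and final 10 ms displacement directions differ by
    more than 135 deg, (ii) both align within 45 deg of the two opposed task
    locations, (iii) the trajectory is metrically abnormal (path length
    > 1.5x the net amplitude, or duration > 1.5x the nominal main-sequence
    duration for that amplitude).  The split point is the deepest local speed
    nadir strictly between the two largest speed peaks; with no interior
    nadir the event is only flagged.
    """
    cfg = cfg or BoomerangConfig()
    i0, i1 = event.onset_idx, event.offset_idx
    # geometry and timing are judged on the pre-slosh core of the event:
    # absorbed oscillation lobes reverse the final-direction probe and
    # inflate the duration, which would masquerade as a boomerang
    j1 = event.core_offset_idx if event.core_offset_idx >= 0 else i1
    probe = max(1, int(round(cfg.probe_ms * rate_hz / 1000.0)))
    if j1 - i0 < 2 * probe:
        return [event]
    xs, ys = vel.xs, vel.ys
    a_init = np.degrees(np.arctan2(ys[i0 + probe] - ys[i0], xs[i0 + probe] - xs[i0]))
    a_final = np.degrees(np.arctan2(ys[j1] - ys[j1 - probe], xs[j1] - xs[j1 - probe]))
    if _angdiff(a_init, a_final) <= cfg.angle_min_deg:
        return [event]
    for a in (a_init, a_final):
        if min(_angdiff(a, task_axes_deg[0]), _angdiff(a, task_axes_deg[1])) > cfg.axis_tol_deg:
            return [event]
    core_amp = float(np.hypot(xs[j1] - xs[i0], ys[j1] - ys[i0]))
    path = float(np.sum(np.hypot(np.diff(xs[i0:j1 + 1]), np.diff(ys[i0:j1 + 1]))))
    pred_dur = cfg.dur_slope_ms_per_deg * core_amp + cfg.dur_intercept_ms
    abnormal = (core_amp > 0 and path > cfg.path_ratio * core_amp) \
        or (T[j1] - T[i0]) > cfg.dur_ratio * pred_dur
    if not abnormal:
        return [event]

    # deepest local nadir strictly between the two largest speed peaks;
    # a prominence floor keeps sample noise on a lobe's crown from posing
    # as a second peak
    seg = vel.speed[i0:j1 + 1]
    peaks, _ = find_peaks(seg, prominence=0.1 * float(seg.max()))
    if len(peaks) < 2:
        return [replace(event, boomerang_unsplit=True)]
    top2 = peaks[np.argsort(seg[peaks])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    if hi - lo < 2:
        return [replace(event, boomerang_unsplit=True)]
    mid = lo + 1 + int(np.argmin(seg[lo + 1:hi]))
    m = i0 + mid
    first = measure_event(event.trial_id, i0, m, T, vel, dt_s)
    second = measure_event(event.trial_id, m, i1, T, vel, dt_s)
    first.boomerang_half = "first"
    second.boomerang_half = "second"
    first.lapse_flag = second.lapse_flag = event.lapse_flag
    second.pso_merged = event.pso_merged
    second.pso_end_ms = event.pso_end_ms
    second.core_offset_idx = j1
    return [first, second]


# ---------------------------------------------------------------------------
# blincades
# ---------------------------------------------------------------------------

def resolve_blincades(
    events: list[SaccadeRecord],
    blinks: list[BlinkRecord],
    cfg: BlincadeConfig | None = None,
) -> tuple[list[SaccadeRecord], list[dict]]:
    """Tag loss-overlapping events; fold blink artifacts back into blinks.

    An event overlapping a refined blink extent is a blincade.  The pattern
    (upward blincade immediately followed, within 40 ms, by a downward event):
    net start-to-final displacement < 2 deg -> both removed and recorded as a
    blink; otherwise combined into one blincade whose trajectory is treated
    as linearly interpolated start-to-end.
    """
    cfg = cfg or BlincadeConfig()
    which_blink: dict[int, int] = {}
    for k, ev in enumerate(events):
        for bi, b in enumerate(blinks):
            if ev.onset_ms <= b.blink_end and ev.offset_ms >= b.blink_start:
                ev.blincade = True
                which_blink[k] = bi
                break
    out: list[SaccadeRecord] = []
    reclassified: list[dict] = []
    i = 0
    while i < len(events):
        ev = events[i]
        nxt = events[i + 1] if i + 1 < len(events) else None
        up = ev.end_y - ev.start_y
        # "immediately followed": within the PSO time constant, or the two
        # events bracket the same data loss (the gap then IS the loss)
        adjacent = nxt is not None and (
            nxt.onset_ms - ev.offset_ms < cfg.max_gap_ms
            or which_blink.get(i) == which_blink.get(i + 1, -2)
        )
        if (ev.blincade and up > 0 and adjacent
                and (nxt.end_y - nxt.start_y) < 0):
            net = float(np.hypot(nxt.end_x - ev.start_x, nxt.end_y - ev.start_y))
            if net < cfg.blink_radius_deg:
                reclassified.append({
                    "trial_id": ev.trial_id,
                    "start_ms": ev.onset_ms,
                    "end_ms": nxt.offset_ms,
                    "net_displacement_deg": net,
                })
                i += 2
                continue
            combined = SaccadeRecord(
                trial_id=ev.trial_id,
                onset_ms=ev.onset_ms, offset_ms=nxt.offset_ms,
                start_x=ev.start_x, start_y=ev.start_y,
                end_x=nxt.end_x, end_y=nxt.end_y,
                amplitude=net,
                angle=float(np.degrees(np.arctan2(nxt.end_y - ev.start_y,
                                                  nxt.end_x - ev.start_x))),
                duration_ms=nxt.offset_ms - ev.onset_ms,
                peak_velocity=max(ev.peak_velocity, nxt.peak_velocity),
                peak_acceleration=max(ev.peak_acceleration, nxt.peak_acceleration),
                blincade=True, interpolated=True,
                lapse_flag=ev.lapse_flag or nxt.lapse_flag,
                onset_idx=ev.onset_idx, offset_idx=nxt.offset_idx,
            )
            out.append(combined)
            i += 2
            continue
        out.append(ev)
        i += 1
    return out, reclassified


# ---------------------------------------------------------------------------
# main-sequence Z-scores
# ---------------------------------------------------------------------------

_RECORD_COLUMNS = [
    "trial_id", "onset_ms", "offset_ms", "start_x", "start_y", "end_x", "end_y",
    "amplitude", "angle", "duration_ms", "peak_velocity", "peak_acceleration",
    "pso_merged", "pso_end_ms", "boomerang_half", "boomerang_unsplit",
    "blincade", "interpolated", "lapse_flag", "masez_amp", "masez_dur",
]


def saccade_table(records: list[SaccadeRecord]) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in _RECORD_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


def _fit_spline(x: np.ndarray, y: np.ndarray, n_knots: int):
    """Low-flexibility cubic least-squares spline (effective df = n_knots + 4)."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order].astype(float), y[order].astype(float)
    # strictly increasing abscissae for the spline routine
    eps = max(1e-9, 1e-9 * float(xs[-1] - xs[0] if xs[-1] > xs[0] else 1.0))
    for i in range(1, len(xs)):
        if xs[i] <= xs[i - 1]:
            xs[i] = xs[i - 1] + eps
    for k in range(n_knots, -1, -1):
        if k == 0:
            knots = np.array([])
        else:
            qs = np.linspace(0, 1, k + 2)[1:-1]
            knots = np.quantile(xs, qs)
            knots = knots[(knots > xs[0]) & (knots < xs[-1])]
        try:
            spl = LSQUnivariateSpline(xs, ys, t=knots, k=3)
            return spl, knots
        except Exception:
            continue
    raise RuntimeError("could not fit main-sequence spline")


def main_sequence_zscores(
    table: pd.DataFrame,
    cfg: MainSequenceConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Score every saccade against the block's main sequence.

    Two cross-sectional fits (peak velocity vs amplitude, and vs duration) are
    made on clean saccades only -- records with missing kinematics, boomerang
    halves, and blincades are excluded from the fit -- and every record,
    including the flagged ones, receives a residual Z-score from each fit.
    """
    cfg = cfg or MainSequenceConfig()
    table = table.copy()
    meta: dict = {"n_clean": 0, "fitted": False}
    if len(table) == 0:
        table["masez_amp"] = np.array([], dtype=float)
        table["masez_dur"] = np.array([], dtype=float)
        meta["reason"] = "empty table"
        return table, meta
    finite = np.isfinite(table["amplitude"]) & np.isfinite(table["peak_velocity"]) \
        & np.isfinite(table["duration_ms"])
    clean = finite & ~table["blincade"] & (table["boomerang_half"] == "none") \
        & ~table["boomerang_unsplit"]
    n_clean = int(clean.sum())
    meta["n_clean"] = n_clean
    if n_clean < cfg.min_clean:
        table["masez_amp"] = np.nan
        table["masez_dur"] = np.nan
        meta["reason"] = f"only {n_clean} clean saccades (< {cfg.min_clean})"
        return table, meta

    for xcol, zcol, key in (("amplitude", "masez_amp", "amp"),
                            ("duration_ms", "masez_dur", "dur")):
        x = table.loc[clean, xcol].to_numpy()
        y = table.loc[clean, "peak_velocity"].to_numpy()
        spl, knots = _fit_spline(x, y, cfg.n_knots)
        resid_clean = y - spl(x)
        sd = float(resid_clean.std(ddof=1))
        meta[f"knots_{key}"] = knots.tolist()
        meta[f"resid_sd_{key}"] = sd
        allx = table[xcol].to_numpy(dtype=float)
        resid_all = table["peak_velocity"].to_numpy(dtype=float) - spl(allx)
        table[zcol] = resid_all / sd if sd > 0 else 0.0
    meta["fitted"] = True
    return table, meta


def filter_by_masez(table: pd.DataFrame, zcrit: float | None = None) -> pd.DataFrame:
    """Retain saccades whose both main-sequence |Z| are below the cut-off
    (default: two-sided normal critical value for p < 0.001)."""
    if zcrit is None:
        zcrit = MainSequenceConfig().zcrit
    if np.isinf(zcrit):
        return table.copy()
    keep = (table["masez_amp"].abs() < zcrit) & (table["masez_dur"].abs() < zcrit)
    return table.loc[keep].copy()


# ---------------------------------------------------------------------------
# per-trial orchestration
# ---------------------------------------------------------------------------

def detect_saccades_trial(
    trial_id: int,
    T: np.ndarray,
    vel: VelocityTrace,
    rate_hz: float,
    fixation_epoch_ms: tuple[float, float],
    blinks: list[BlinkRecord] | None = None,
    sacc_cfg: SaccadeConfig | None = None,
    pso_cfg: PsoConfig | None = None,
    boom_cfg: BoomerangConfig | None = None,
    blinc_cfg: BlincadeConfig | None = None,
    task_axes_deg: tuple[float, float] = (0.0, 180.0),
) -> tuple[DetectionThreshold, list[SaccadeRecord], list[dict]]:
    """Threshold -> candidates -> PSO merge -> boomerang split -> blincades."""
    sacc_cfg = sacc_cfg or SaccadeConfig()
    dt_s = 1.0 / rate_hz
    thr = dynamic_threshold(vel.speed, T, fixation_epoch_ms, trial_id, sacc_cfg)
    cand = detect_candidates(vel.speed, thr.value, rate_hz, sacc_cfg.min_dur_ms)
    events = [measure_event(trial_id, i0, i1, T, vel, dt_s) for i0, i1 in cand]
    events = merge_pso(events, T, vel, dt_s, pso_cfg)
    split: list[SaccadeRecord] = []
    for ev in events:
        split.extend(split_boomerang(ev, T, vel, dt_s, rate_hz, task_axes_deg, boom_cfg))
    final, reclassified = resolve_blincades(split, blinks or [], blinc_cfg)
    return thr, final, reclassified
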