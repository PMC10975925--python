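"""IPAST pupillometry: the FIX-locked constriction/dilation response.

The fixation point's appearance drives a stereotyped pupil response --
constriction to a nadir followed by dilation before the predictable stimulus
onset.  Metrics use the raw pupil area (camera pixel counts) on trials where
the eyes stayed still and near the fixation point and data loss was short,
so that pupil-size changes are not confounded by gaze position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blink_detect import BlinkRecord
from .config import PupilConfig, TimelineConfig
from .io_session import TrialRecord
from .kinematics import central_velocity, zero_phase_boxcar
from .saccade_detect import SaccadeRecord

__all__ = ["PupilMetrics", "eligible_trial", "pupil_metrics", "pupil_table"]


@dataclass
class PupilMetrics:
    trial_id: int
    eligible: bool
    reason: str  # "ok" or the ineligibility/missing-data reason code
    baseline: float = np.nan  # mean area 150-200 ms post FIX
    min_size: float = np.nan
    max_constriction_time: float = np.nan  # ms from FIX onset
    final_size: float = np.nan  # mean area 150-200 ms pre STIM
    onset_latency: float = np.nan  # ms from FIX onset; NaN if never significant
    max_constriction_velocity: float = np.nan  # area units / s (signed)
    constriction_amount: float = np.nan  # baseline - min_size
    max_dilation_velocity: float = np.nan
    dilation_amount: float = np.nan  # final_size - min_size


def eligible_trial(
    trial: TrialRecord,
    saccades: list[SaccadeRecord] | pd.DataFrame,
    blinks: list[BlinkRecord],
    cfg: PupilConfig | None = None,
    timeline: TimelineConfig | None = None,
) -> tuple[bool, str]:
    """Stationary-eye gate for pupillometry over the FIX + GAP window.

    Requires no saccade above 2 deg, mean gaze within 2 deg of FIX, and less
    than 200 ms of total data loss in the window.
    """
    cfg = cfg or PupilConfig()
    timeline = timeline or TimelineConfig()
    w0, w1 = timeline.fix_on_ms, 0.0
    if isinstance(saccades, pd.DataFrame):
        amp = saccades["amplitude"].to_numpy(dtype=float)
        onset = saccades["onset_ms"].to_numpy(dtype=float)
    else:
        amp = np.array([s.amplitude for s in saccades])
        onset = np.array([s.onset_ms for s in saccades])
    if np.any((amp > cfg.max_sacc_deg) & (onset >= w0) & (onset <= w1)):
        return False, "saccade>2deg"
    t = trial.trace.T
    m = (t >= w0) & (t <= w1)
    ok = m & trial.trace.valid
    if not ok.any():
        return False, "loss>=200ms"
    gx = float(trial.trace.X[ok].mean())
    gy = float(trial.trace.Y[ok].mean())
    if np.hypot(gx, gy) > cfg.center_radius_deg:
        return False, "off_center"
    step = trial.trace.step_ms
    loss_ms = float(np.sum(m & ((trial.trace.A == 0) | ~trial.trace.valid))) * step
    if loss_ms >= cfg.max_loss_ms:
        return False, "loss>=200ms"
    return True, "ok"


def pupil_metrics(
    trial: TrialRecord,
    eligible: bool = True,
    reason: str = "ok",
    cfg: PupilConfig | None = None,
    timeline: TimelineConfig | None = None,
) -> PupilMetrics:
    """Compute the FIX-response metrics from the raw area vector.

    Baseline and final sizes are window means; the nadir is taken over the
    FIX epoch excluding loss samples (values are never fabricated across
    interpolation).  Response onset is the first sample of the earliest 20 ms
    window, after 200 ms post FIX, in which every sample deviates from
    baseline in the same direction by more than 1.96 baseline SDs.
    """
    cfg = cfg or PupilConfig()
    timeline = timeline or TimelineConfig()
    out = PupilMetrics(trial_id=trial.trial_id, eligible=eligible, reason=reason)
    if not eligible:
        return out
    t = trial.trace.T
    A = trial.trace.A
    fix_on = timeline.fix_on_ms
    good = trial.trace.valid & (A > 0)

    def window_mean(lo_ms: float, hi_ms: float, code: str) -> float | None:
        m = (t >= fix_on + lo_ms) & (t <= fix_on + hi_ms)
        if not m.any() or not good[m].all():
            out.eligible = False
            out.reason = code
            return None
        return float(A[m].mean())

    baseline = window_mean(*cfg.baseline_ms, code="loss_in_baseline")
    if baseline is None:
        return out
    final = window_mean(*cfg.final_ms, code="loss_in_final")
    if final is None:
        return out
    out.baseline, out.final_size = baseline, final

    epoch = (t >= fix_on) & (t <= 0.0)
    usable = epoch & good
    if not usable.any():
        out.eligible = False
        out.reason = "loss>=200ms"
        return out
    idx_usable = np.flatnonzero(usable)
    imin = idx_usable[np.argmin(A[idx_usable])]
    out.min_size = float(A[imin])
    out.max_constriction_time = float(t[imin] - fix_on)
    out.constriction_amount = out.baseline - out.min_size
    out.dilation_amount = out.final_size - out.min_size

    # response onset: sliding significance window
    bmask = (t >= fix_on + cfg.baseline_ms[0]) & (t <= fix_on + cfg.baseline_ms[1])
    bsd = float(A[bmask].std(ddof=1)) if bmask.sum() > 1 else 0.0
    thresh = cfg.sig_sd * bsd
    win = max(1, int(round(cfg.window_ms * trial.trace.rate_hz / 1000.0)))
    search = np.flatnonzero((t >= fix_on + cfg.onset_search_from_ms) & (t <= 0.0))
    onset_idx = None
    dev = A - out.baseline
    for i in search:
        j = i + win
        if j > len(t) or t[j - 1] > 0.0:
            break
        seg = dev[i:j]
        if not good[i:j].all():
            continue
        if np.all(seg > thresh) or np.all(seg < -thresh):
            onset_idx = i
            break
    if onset_idx is not None:
        out.onset_latency = float(t[onset_idx] - fix_on)

    # pupil velocity: 3-point smoothed derivative of raw area, in units/s
    dt_s = trial.trace.step_ms / 1000.0
    if len(A) > 7:
        velA = zero_phase_boxcar(central_velocity(A.astype(float), dt_s), 3)
        v0 = onset_idx if onset_idx is not None else (search[0] if len(search) else imin)
        if imin > v0:
            out.max_constriction_velocity = float(velA[v0:imin + 1].min())
        istim = int(np.searchsorted(t, 0.0, side="right")) - 1
        if istim > imin:
            out.max_dilation_velocity = float(velA[imin:istim + 1].max())
    return out


def pupil_table(metrics: list[PupilMetrics]) -> pd.DataFrame:
    cols = ["trial_id", "eligible", "reason", "baseline", "min_size",
            "max_constriction_time", "final_size", "onset_latency",
            "max_constriction_velocity", "constriction_amount",
            "max_dilation_velocity", "dilation_amount"]
    return pd.DataFrame([{c: getattr(m, c) for c in cols} for m in metrics],
                        columns=cols)
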