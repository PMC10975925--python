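"""Seeded synthetic eye-tracking sessions with ground truth.

The generator emulates the IPAST timeline (1000 ms ITI, 1000 ms FIX, 200 ms
gap, stimulus at +-10 deg, 3200 ms trials) and the signal phenomena the
pipeline is built to handle:

* saccades with raised-cosine velocity profiles obeying the main sequence
  ``Vp = V_inf * (1 - exp(-A / A0))`` (duration follows from the amplitude
  integral, D = 2A / Vp);
* post-saccadic oscillations: a damped sinusoid (default 20 Hz, 30 ms decay)
  superimposed near the end of each saccade, along the saccade direction for
  horizontal movements, with amplitude scaled by ``slosh_gain`` to emulate
  the wide inter-individual range of iris mobility;
* boomerang saccades: two opposed movements overlapped in time so the speed
  never falls below detection threshold between them;
* blinks: pupil-area ramp to zero (30 ms), a data-loss interval, a recovery
  ramp, optionally with the up/down gaze artifact video trackers produce as
  the eyelid sweeps the pupil image;
* the FIX-locked pupil response: constriction to a nadir then dilation
  before the predictable STIM onset, on top of a slow area drift.

A ``freeview`` mode produces unstructured saccade sequences with a wide
amplitude range (2-16 deg), used to probe the main-sequence fit.

Every injected event is returned in a ground-truth structure so detection
can be scored (greedy one-to-one onset matching).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import TimelineConfig
from .io_session import SampleTrace, ScreenGeometry, TrialRecord
from .kinematics import degrees_to_pixels

__all__ = [
    "GeneratorConfig",
    "TrialTruth",
    "SessionTruth",
    "simulate_session",
    "write_asc",
    "score_detection",
    "DetectionScore",
]

DEFAULT_GEOMETRY = ScreenGeometry(
    width_px=1280, height_px=1024, width_cm=33.8, height_cm=27.0, distance_cm=60.0
)


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic session."""

    task: str = "ipast"  # ipast | freeview
    rate_hz: float = 500.0
    n_trials: int = 100
    seed: int = 0
    # signal quality
    noise_sd_deg: float = 0.05
    pupil_noise_sd: float = 0.5  # area units
    # post-saccadic slosh
    slosh_gain: float = 0.5  # 0..1, scales the PSO displacement amplitude
    pso_freq_hz: float = 20.0
    pso_decay_ms: float = 30.0
    pso_base_amp_deg: float = 1.2  # displacement at slosh_gain = 1
    # blinks
    blink_rate_per_trial: float = 0.3
    blink_ramp_ms: float = 30.0
    blink_loss_ms: tuple[float, float] = (50.0, 150.0)
    blink_artifact_prob: float = 0.3
    blink_artifact_deg: float = 3.0
    # main-sequence kinematics
    vpeak_inf_dps: float = 500.0
    amp0_deg: float = 12.0
    detect_floor_dps: float = 20.0  # annotation point for scoreable onsets
    # IPAST behavior mix (probabilities of the rarer trial outcomes; the
    # remainder are correct/direction-error responses)
    p_fixation_break: float = 0.05
    p_no_saccade: float = 0.01
    p_random_saccade: float = 0.01
    p_never_fixated: float = 0.01
    p_eye_loss: float = 0.01
    p_anticipatory: float = 0.05
    p_direction_error_pro: float = 0.03
    p_direction_error_anti: float = 0.23
    boomerang_prob: float = 0.0  # among ANTI direction errors
    srt_range_ms: tuple[float, float] = (150.0, 400.0)
    anticipatory_srt_range_ms: tuple[float, float] = (-90.0, 60.0)
    endpoint_sd_deg: float = 0.3
    # pupil response (area units; times relative to FIX onset)
    pupil_baseline: float = 500.0
    pupil_constriction: float = 80.0
    pupil_nadir_ms: float = 600.0
    pupil_dilation: float = 40.0
    pupil_onset_ms: float = 300.0
    pupil_drift_amp: float = 5.0
    pupil_drift_period_ms: float = 5000.0
    # tracker drift (per-segment constant calibration offset)
    drift_segment_trials: int = 40
    drift_offset_sd_deg: float = 0.3
    timeline: TimelineConfig = field(default_factory=TimelineConfig)
    geometry: ScreenGeometry = field(default_factory=lambda: DEFAULT_GEOMETRY)

    def __post_init__(self) -> None:
        for name in ("blink_rate_per_trial",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("p_fixation_break", "p_no_saccade", "p_random_saccade",
                     "p_never_fixated", "p_eye_loss", "p_anticipatory",
                     "boomerang_prob", "p_direction_error_pro",
                     "p_direction_error_anti", "slosh_gain"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class TrialTruth:
    trial_id: int
    condition: str | None
    stim_side: str | None
    category: str
    srt_ms: float | None
    saccades: list[dict] = field(default_factory=list)
    blinks: list[dict] = field(default_factory=list)
    boomerang: bool = False
    pupil: dict | None = None


@dataclass
class SessionTruth:
    trials: list[TrialTruth]
    config: GeneratorConfig

    def all_saccades(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            for s in t.saccades:
                rows.append({"trial_id": t.trial_id, **s})
        return pd.DataFrame(rows)

    def all_blinks(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            for b in t.blinks:
                rows.append({"trial_id": t.trial_id, **b})
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        data = []
        for t in self.trials:
            data.append({
                "trial_id": t.trial_id, "condition": t.condition,
                "stim_side": t.stim_side, "category": t.category,
                "srt_ms": t.srt_ms, "saccades": t.saccades,
                "blinks": t.blinks, "boomerang": t.boomerang, "pupil": t.pupil,
            })
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


# ---------------------------------------------------------------------------
# kinematic primitives
# ---------------------------------------------------------------------------

def _main_sequence_peak(amp: float, vinf: float, a0: float) -> float:
    return vinf * (1.0 - np.exp(-amp / a0))


def _saccade_profile(t_ms: np.ndarray, onset_ms: float, dur_ms: float) -> np.ndarray:
    """Normalized raised-cosine displacement profile (0 before, 1 after)."""
    u = (t_ms - onset_ms) / dur_ms
    prof = np.clip(u, 0.0, 1.0)
    m = (u > 0) & (u < 1)
    prof = np.where(m, u - np.sin(2 * np.pi * np.clip(u, 0, 1)) / (2 * np.pi), prof)
    return prof


def _pso_wave(t_ms: np.ndarray, start_ms: float, amp_deg: float,
              freq_hz: float, decay_ms: float) -> np.ndarray:
    dtms = t_ms - start_ms
    m = dtms > 0
    w = np.zeros_like(t_ms, dtype=float)
    w[m] = amp_deg * np.exp(-dtms[m] / decay_ms) * np.sin(
        2 * np.pi * freq_hz * dtms[m] / 1000.0)
    return w


class _TrialBuilder:
    """Accumulates signal components for one trial on the sample grid."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        self.cfg = cfg
        tl = cfg.timeline
        step = 1000.0 / cfg.rate_hz
        n = int(round(tl.trial_ms / step))
        self.T = tl.trial_start_ms + step * np.arange(n)
        self.x = np.zeros(n)
        self.y = np.zeros(n)
        self.A = np.full(n, np.nan)  # filled by pupil_curve
        self.valid = np.ones(n, dtype=bool)
        self.rng = rng
        self.truth_saccades: list[dict] = []
        self.truth_blinks: list[dict] = []
        self._cum = np.zeros(2)  # settled gaze position after queued saccades

    def add_saccade(self, onset_ms: float, dxy: tuple[float, float],
                    slosh: bool = True) -> dict:
        cfg = self.cfg
        dx, dy = dxy
        amp = float(np.hypot(dx, dy))
        vp = _main_sequence_peak(amp, cfg.vpeak_inf_dps, cfg.amp0_deg)
        dur = max(3 * 1000.0 / cfg.rate_hz, 2000.0 * amp / vp)  # ms
        prof = _saccade_profile(self.T, onset_ms, dur)
        self.x += dx * prof
        self.y += dy * prof
        if slosh and cfg.slosh_gain > 0 and amp >= 1.0:
            a = cfg.slosh_gain * cfg.pso_base_amp_deg * min(1.0, amp / 8.0 + 0.5)
            ux, uy = dx / amp, dy / amp
            wave = _pso_wave(self.T, onset_ms + 0.8 * dur, a,
                             cfg.pso_freq_hz, cfg.pso_decay_ms)
            self.x += ux * wave
            self.y += uy * wave
        # a threshold detector can first see the movement where the noiseless
        # speed crosses the detection floor; annotate that time as the
        # scoreable onset (the raised cosine has zero takeoff slope, so the
        # profile start itself is unobservable at any finite threshold)
        u0 = np.arcsin(np.sqrt(min(1.0, cfg.detect_floor_dps / vp))) / np.pi
        rec = {
            "onset_ms": float(onset_ms + u0 * dur),
            "profile_start_ms": float(onset_ms),
            "offset_eye_ms": float(onset_ms + dur),
            "offset_signal_ms": float(onset_ms + 0.8 * dur + 2.5 * cfg.pso_decay_ms
                                      if slosh and cfg.slosh_gain > 0 else onset_ms + dur),
            "dx": float(dx), "dy": float(dy),
            "start_x": float(self._cum[0]), "start_y": float(self._cum[1]),
            "end_x": float(self._cum[0] + dx), "end_y": float(self._cum[1] + dy),
            "amplitude": amp, "peak_velocity": float(vp),
            "duration_ms": float(dur),
        }
        self._cum += (dx, dy)
        self.truth_saccades.append(rec)
        return rec

    def add_boomerang(self, onset_ms: float, dx1: float, dx2: float) -> None:
        """Two opposed saccades fused so the speed never falls sub-threshold.

        A purely horizontal reversal would pass through zero horizontal
        velocity; fused boomerangs in recordings follow a curved (looping)
        path whose vertical velocity carries the speed through the reversal,
        so both components get a same-signed upward fraction.
        """
        f = 0.3
        r1 = self.add_saccade(onset_ms, (dx1, f * abs(dx1)), slosh=False)
        onset2 = onset_ms + 0.6 * r1["duration_ms"]
        self.add_saccade(onset2, (dx2, f * abs(dx2)), slosh=True)

    def add_blink(self, start_ms: float, loss_ms: float, artifact: bool) -> None:
        cfg = self.cfg
        ramp = cfg.blink_ramp_ms
        t = self.T
        # area envelope: 1 -> 0 over the closing ramp, 0 during loss, 0 -> 1 over recovery
        env = np.ones_like(t)
        closing = (t >= start_ms) & (t < start_ms + ramp)
        env[closing] = 1.0 - (t[closing] - start_ms) / ramp
        lost = (t >= start_ms + ramp) & (t < start_ms + ramp + loss_ms)
        env[lost] = 0.0
        opening = (t >= start_ms + ramp + loss_ms) & (t < start_ms + 2 * ramp + loss_ms)
        env[opening] = (t[opening] - (start_ms + ramp + loss_ms)) / ramp
        self._blink_env = getattr(self, "_blink_env", np.ones_like(t))
        self._blink_env = np.minimum(self._blink_env, env)
        self.valid &= ~lost
        if artifact:
            # eyelid sweep: gaze pulled up while closing, released on opening
            up = cfg.blink_artifact_deg
            dy = np.zeros_like(t)
            dy[closing] = up * (t[closing] - start_ms) / ramp
            dy[lost] = up
            dy[opening] = up * (1.0 - (t[opening] - (start_ms + ramp + loss_ms)) / ramp)
            self.y += dy
        self.truth_blinks.append({
            "blink_start_ms": float(start_ms),
            "blink_end_ms": float(start_ms + 2 * ramp + loss_ms),
            "loss_start_ms": float(start_ms + ramp),
            "loss_end_ms": float(start_ms + ramp + loss_ms),
            "artifact": bool(artifact),
        })

    def pupil_curve(self, respond: bool = True) -> dict:
        """FIX-locked constriction/dilation on a slow drift; returns truth."""
        cfg = self.cfg
        tl = cfg.timeline
        t = self.T
        base = np.full_like(t, cfg.pupil_baseline)
        fix_on = tl.fix_on_ms
        if respond:
            t_on = fix_on + cfg.pupil_onset_ms
            t_nad = fix_on + cfg.pupil_nadir_ms
            c, d = cfg.pupil_constriction, cfg.pupil_dilation
            m1 = (t >= t_on) & (t < t_nad)
            base[m1] -= c / 2 * (1 - np.cos(np.pi * (t[m1] - t_on) / (t_nad - t_on)))
            # dilation launches promptly off the nadir (quarter-sine), as in
            # recorded pupil traces where re-dilation follows peak constriction
            # without a plateau
            m2 = (t >= t_nad) & (t < 0)
            base[m2] += -c + d * np.sin(np.pi / 2 * (t[m2] - t_nad) / (0 - t_nad))
            base[t >= 0] += -c + d
        phase = self.rng.uniform(0, 2 * np.pi)
        drift = cfg.pupil_drift_amp * np.sin(
            2 * np.pi * (t - t[0]) / cfg.pupil_drift_period_ms + phase)
        curve = base + drift
        # ground truth measured off the noiseless curve, mirroring the metric
        # definitions (window means, epoch nadir)
        def wmean(lo, hi):
            m = (t >= fix_on + lo) & (t <= fix_on + hi)
            return float(curve[m].mean())
        epoch = (t >= fix_on) & (t <= 0)
        imin = np.flatnonzero(epoch)[np.argmin(curve[epoch])]
        truth = {
            "baseline": wmean(150, 200),
            "min_size": float(curve[imin]),
            "nadir_ms": float(t[imin] - fix_on),
            "final_size": wmean(1150, 1200),
            "onset_ms": float(cfg.pupil_onset_ms) if respond else None,
        }
        # detectable onset: the earliest 20 ms window of the noiseless curve
        # whose every sample deviates from baseline by > 1.96 x the commanded
        # noise SD (the same significance rule the metrics apply); the
        # raised-cosine takeoff makes the profile start itself unobservable
        if respond:
            thr = 1.96 * cfg.pupil_noise_sd
            win = max(1, int(round(20.0 * cfg.rate_hz / 1000.0)))
            dev = curve - truth["baseline"]
            truth["onset_detectable_ms"] = None
            search = np.flatnonzero((t >= fix_on + 200.0) & (t <= 0))
            for i in search:
                seg = dev[i:i + win]
                if len(seg) == win and (np.all(seg > thr) or np.all(seg < -thr)):
                    truth["onset_detectable_ms"] = float(t[i] - fix_on)
                    break
        else:
            truth["onset_detectable_ms"] = None
        truth["constriction"] = truth["baseline"] - truth["min_size"]
        truth["dilation"] = truth["final_size"] - truth["min_size"]
        self._pupil_base = curve
        return truth

    def finish(self) -> SampleTrace:
        cfg = self.cfg
        rng = self.rng
        curve = getattr(self, "_pupil_base", np.full_like(self.T, cfg.pupil_baseline))
        env = getattr(self, "_blink_env", np.ones_like(self.T))
        A = np.maximum(0.0, curve * env + rng.normal(0, cfg.pupil_noise_sd, len(self.T)))
        A[env == 0] = 0.0
        x = self.x + rng.normal(0, cfg.noise_sd_deg, len(self.T))
        y = self.y + rng.normal(0, cfg.noise_sd_deg, len(self.T))
        x[~self.valid] = np.nan
        y[~self.valid] = np.nan
        return SampleTrace(self.T.copy(), x, y, A, self.valid.copy(),
                           cfg.rate_hz, units="deg")


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

def _plan_category(cfg: GeneratorConfig, rng: np.random.Generator,
                   condition: str) -> str:
    specials = [
        ("eye_loss", cfg.p_eye_loss),
        ("never_fixated", cfg.p_never_fixated),
        ("fixation_break", cfg.p_fixation_break),
        ("no_saccade", cfg.p_no_saccade),
        ("random", cfg.p_random_saccade),
        ("anticipatory", cfg.p_anticipatory),
    ]
    u = rng.uniform()
    acc = 0.0
    for name, p in specials:
        acc += p
        if u < acc:
            return name
    p_err = (cfg.p_direction_error_pro if condition == "PRO"
             else cfg.p_direction_error_anti)
    return "direction_error" if rng.uniform() < p_err else "correct"


_CATEGORY_NAME = {
    ("PRO", "correct", False): "Correct Pro-Saccade",
    ("PRO", "direction_error", False): "Pro-Saccade Direction Error",
    ("ANTI", "correct", False): "Correct Anti-Saccade",
    ("ANTI", "direction_error", False): "Anti-Saccade Direction Error",
    ("PRO", "correct", True): "Anticipatory Correct Pro-Saccade",
    ("PRO", "direction_error", True): "Anticipatory Pro-Saccade Direction Error",
    ("ANTI", "correct", True): "Anticipatory Correct Anti-Saccade",
    ("ANTI", "direction_error", True): "Anticipatory Anti-Saccade Direction Error",
}


def _simulate_ipast_trial(cfg: GeneratorConfig, rng: np.random.Generator,
                          trial_id: int) -> tuple[SampleTrace, TrialTruth, dict]:
    tl = cfg.timeline
    condition = "PRO" if rng.uniform() < 0.5 else "ANTI"
    side = "left" if rng.uniform() < 0.5 else "right"
    stim_x = -tl.stim_ecc_deg if side == "left" else tl.stim_ecc_deg
    plan = _plan_category(cfg, rng, condition)

    b = _TrialBuilder(cfg, rng)
    truth = TrialTruth(trial_id=trial_id, condition=condition, stim_side=side,
                       category="", srt_ms=None)
    pupil_ok = plan in ("correct", "direction_error", "no_saccade", "random")
    srt = None
    jitter = lambda: rng.normal(0.0, cfg.endpoint_sd_deg)

    if plan == "eye_loss":
        truth.category = "Eye Loss"
        # blank out most of the FIX + response epochs
        t = b.T
        lost = (t >= tl.fix_on_ms) & (t <= 900.0)
        b.valid &= ~lost
        b._blink_env = np.where(lost, 0.0, 1.0)
    elif plan == "never_fixated":
        truth.category = "Never Fixated"
        b.x += 6.0
        b.y += 4.0
    elif plan == "fixation_break":
        truth.category = "Fixation Break"
        t_break = rng.uniform(-900.0, -450.0)
        tgt = stim_x if rng.uniform() < 0.5 else -stim_x
        b.add_saccade(t_break, (tgt + jitter(), jitter()))
    elif plan == "no_saccade":
        truth.category = "No Saccade"
    elif plan == "random":
        truth.category = "Random Saccade"
        srt = rng.uniform(*cfg.srt_range_ms)
        b.add_saccade(srt, (jitter(), (8.0 if rng.uniform() < 0.5 else -8.0) + jitter()))
    else:
        anticipatory = plan == "anticipatory"
        if anticipatory:
            srt = rng.uniform(*cfg.anticipatory_srt_range_ms)
            err = rng.uniform() < 0.5
        else:
            srt = rng.uniform(*cfg.srt_range_ms)
            err = plan == "direction_error"
        correct_x = stim_x if condition == "PRO" else -stim_x
        first_x = -correct_x if err else correct_x
        boomerang = (err and not anticipatory and condition == "ANTI"
                     and rng.uniform() < cfg.boomerang_prob)
        if boomerang:
            b.add_boomerang(srt, first_x + jitter(), 2 * correct_x + jitter())
            truth.boomerang = True
        else:
            b.add_saccade(srt, (first_x + jitter(), jitter()))
            if err and not anticipatory:
                # corrective movement back toward the instructed location
                b.add_saccade(srt + rng.uniform(180, 260),
                              (2 * correct_x + jitter(), jitter()))
        truth.category = _CATEGORY_NAME[(condition, "direction_error" if err else "correct",
                                         anticipatory)]
    truth.srt_ms = srt

    ptruth = b.pupil_curve(respond=plan not in ("eye_loss", "never_fixated"))
    if pupil_ok:
        truth.pupil = ptruth

    # blinks, kept clear of the FIX/GAP and response windows
    if plan not in ("eye_loss",) and cfg.blink_rate_per_trial > 0:
        n_blinks = rng.poisson(cfg.blink_rate_per_trial)
        windows = [(-2100.0, -1600.0), (550.0, 750.0)]
        for k in range(min(n_blinks, len(windows))):
            w0, w1 = windows[k]
            start = rng.uniform(w0, w1)
            loss = rng.uniform(*cfg.blink_loss_ms)
            artifact = rng.uniform() < cfg.blink_artifact_prob
            b.add_blink(start, loss, artifact)

    truth.saccades = b.truth_saccades
    truth.blinks = b.truth_blinks
    events = {
        "trial_start": tl.trial_start_ms, "fix_on": tl.fix_on_ms,
        "fix_off": tl.fix_off_ms, "stim_on": 0.0, "trial_end": tl.trial_end_ms,
    }
    return b.finish(), truth, events


def _simulate_freeview_trial(cfg: GeneratorConfig, rng: np.random.Generator,
                             trial_id: int) -> tuple[SampleTrace, TrialTruth, dict]:
    """Unstructured saccade sequence with a wide amplitude range."""
    tl = cfg.timeline
    b = _TrialBuilder(cfg, rng)
    b.pupil_curve(respond=False)
    truth = TrialTruth(trial_id=trial_id, condition="PRO", stim_side="right",
                       category="FreeViewing", srt_ms=None)
    x_now = 0.0
    t_next = -100.0
    while t_next < 820.0:
        # natural viewing is dominated by small saccades; log-uniform
        # amplitudes emulate that while still covering the 2-16 deg range
        amp = float(np.exp(rng.uniform(np.log(2.0), np.log(16.0))))
        direction = 1.0 if x_now <= 0 else -1.0
        if abs(x_now + direction * amp) > 14.0:
            direction = -direction
        b.add_saccade(t_next, (direction * amp, rng.normal(0, 0.2)))
        x_now += direction * amp
        t_next += b.truth_saccades[-1]["duration_ms"] + rng.uniform(140.0, 220.0)
    truth.saccades = b.truth_saccades
    events = {
        "trial_start": tl.trial_start_ms, "fix_on": tl.fix_on_ms,
        "fix_off": tl.fix_off_ms, "stim_on": 0.0, "trial_end": tl.trial_end_ms,
    }
    return b.finish(), truth, events


def simulate_session(
    cfg: GeneratorConfig,
) -> tuple[list[TrialRecord], SessionTruth]:
    """Generate a full seeded session as pixel-unit TrialRecords plus truth.

    Output is deterministic for a given config (bit-identical across runs).
    """
    if cfg.timeline.trial_ms <= 0:
        raise ValueError("trial duration must be positive")
    rng = np.random.default_rng(cfg.seed)
    records: list[TrialRecord] = []
    truths: list[TrialTruth] = []
    seg_offsets: dict[int, tuple[float, float]] = {}
    for k in range(cfg.n_trials):
        if cfg.task == "ipast":
            trace, truth, events = _simulate_ipast_trial(cfg, rng, k)
        elif cfg.task == "freeview":
            trace, truth, events = _simulate_freeview_trial(cfg, rng, k)
        else:
            raise ValueError(f"unknown task {cfg.task!r}")
        seg = k // cfg.drift_segment_trials
        if seg not in seg_offsets:
            seg_offsets[seg] = (rng.normal(0, cfg.drift_offset_sd_deg),
                                rng.normal(0, cfg.drift_offset_sd_deg))
        ox, oy = seg_offsets[seg]
        # tracker calibration drift then degrees -> pixel conversion
        px, py = degrees_to_pixels(trace.X + ox, trace.Y + oy, cfg.geometry)
        trace.X, trace.Y, trace.units = px, py, "px"
        records.append(TrialRecord(
            trial_id=k, condition=truth.condition, stim_side=truth.stim_side,
            trace=trace, events=dict(events), geometry=cfg.geometry,
            drift_segment_id=seg,
        ))
        truths.append(truth)
    return records, SessionTruth(trials=truths, config=cfg)


def simulate_blincade_trial(
    cfg: GeneratorConfig,
    trial_id: int = 0,
    net_dx_deg: float = 0.0,
    seed: int = 0,
) -> TrialRecord:
    """One trial containing the classic blink artifact around data loss.

    Gaze is dragged upward as the eyelid sweeps the pupil image, tracking is
    lost, and the signal returns landing ``net_dx_deg`` to the right of the
    start.  Net ~0 emulates a plain blink mis-read as two saccades; a large
    net emulates a true mid-saccade blink (blincade).
    """
    tl = cfg.timeline
    rng = np.random.default_rng(seed)
    b = _TrialBuilder(cfg, rng)
    b.pupil_curve(respond=False)
    t = b.T
    start_ms, ramp, loss = 300.0, cfg.blink_ramp_ms, 80.0
    closing = (t >= start_ms) & (t < start_ms + ramp)
    lost = (t >= start_ms + ramp) & (t < start_ms + ramp + loss)
    opening = (t >= start_ms + ramp + loss) & (t < start_ms + 2 * ramp + loss)
    env = np.ones_like(t)
    env[closing] = 1.0 - (t[closing] - start_ms) / ramp
    env[lost] = 0.0
    env[opening] = (t[opening] - (start_ms + ramp + loss)) / ramp
    b._blink_env = env
    b.valid &= ~lost
    up = cfg.blink_artifact_deg
    dy = np.zeros_like(t)
    dy[closing] = up * (t[closing] - start_ms) / ramp
    dy[lost] = up
    dy[opening] = up * (1.0 - (t[opening] - (start_ms + ramp + loss)) / ramp)
    b.y += dy
    # the eye lands displaced horizontally once tracking resumes
    b.x += np.where(t >= start_ms + ramp + loss, net_dx_deg, 0.0)
    trace = b.finish()
    px, py = degrees_to_pixels(trace.X, trace.Y, cfg.geometry)
    trace.X, trace.Y, trace.units = px, py, "px"
    events = {"trial_start": tl.trial_start_ms, "fix_on": tl.fix_on_ms,
              "fix_off": tl.fix_off_ms, "stim_on": 0.0,
              "trial_end": tl.trial_end_ms}
    return TrialRecord(trial_id=trial_id, condition="PRO", stim_side="right",
                       trace=trace, events=events, geometry=cfg.geometry)


# ---------------------------------------------------------------------------
# ASC writer (so the reader is exercised end to end)
# ---------------------------------------------------------------------------

def write_asc(trials: list[TrialRecord], path: str | Path,
              inter_trial_gap_ms: float = 200.0) -> None:
    path = Path(path)
    lines: list[str] = ["** oculopipe synthetic session"]
    g = trials[0].geometry if trials else DEFAULT_GEOMETRY
    rate = trials[0].trace.rate_hz if trials else 500.0
    t_abs = 10000.0
    lines.append(
        f"MSG {t_abs:.0f} GEOMETRY width_px={g.width_px} height_px={g.height_px} "
        f"width_cm={g.width_cm} height_cm={g.height_cm} distance_cm={g.distance_cm}"
    )
    lines.append(f"MSG {t_abs:.0f} RATE {rate:.0f}")
    for rec in trials:
        tr = rec.trace
        base = t_abs - tr.T[0]
        lines.append(f"MSG {t_abs:.0f} DRIFT_SEGMENT {rec.drift_segment_id}")
        lines.append(f"MSG {base + tr.T[0]:.0f} TRIALID {rec.trial_id}")
        if rec.condition:
            lines.append(f"MSG {base + tr.T[0]:.0f} TRIAL_CONDITION {rec.condition}")
        if rec.stim_side:
            lines.append(f"MSG {base + tr.T[0]:.0f} STIM_SIDE {rec.stim_side}")
        for name, tag in (("fix_on", "FIX_ON"), ("fix_off", "FIX_OFF"),
                          ("stim_on", "STIM_ON")):
            if name in rec.events:
                lines.append(f"MSG {base + rec.events[name]:.0f} {tag}")
        for i in range(len(tr)):
            t = base + tr.T[i]
            if tr.valid[i] and np.isfinite(tr.X[i]):
                lines.append(f"{t:.0f}\t{tr.X[i]:.3f}\t{tr.Y[i]:.3f}\t{tr.A[i]:.2f}")
            else:
                lines.append(f"{t:.0f}\t.\t.\t0.0")
        lines.append(f"MSG {base + rec.events.get('trial_end', tr.T[-1]):.0f} TRIAL_END")
        t_abs = base + tr.T[-1] + inter_trial_gap_ms
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# detection scoring
# ---------------------------------------------------------------------------

@dataclass
class DetectionScore:
    n_true: int
    n_detected: int
    n_matched: int
    onset_errors_ms: np.ndarray
    matches: list[tuple[int, int]]  # (truth row, detected row)

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_true if self.n_true else np.nan

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else np.nan


def score_detection(
    detected: pd.DataFrame,
    truth: pd.DataFrame,
    tol_ms: float = 20.0,
    onset_col: str = "onset_ms",
    truth_onset_col: str = "onset_ms",
) -> DetectionScore:
    """Greedy one-to-one matching by onset proximity within ``tol_ms``.

    Both tables must carry a ``trial_id`` column; matching is within trial.
    """
    matches: list[tuple[int, int]] = []
    errors: list[float] = []
    used_det: set[int] = set()
    for tid, tgrp in truth.groupby("trial_id"):
        dgrp = detected[detected["trial_id"] == tid]
        cand = []
        for ti, trow in tgrp.iterrows():
            for di, drow in dgrp.iterrows():
                err = abs(drow[onset_col] - trow[truth_onset_col])
                if err <= tol_ms:
                    cand.append((err, ti, di))
        cand.sort(key=lambda c: c[0])
        used_t: set = set()
        for err, ti, di in cand:
            if ti in used_t or di in used_det:
                continue
            used_t.add(ti)
            used_det.add(di)
            matches.append((ti, di))
            errors.append(err)
    return DetectionScore(
        n_true=len(truth), n_detected=len(detected), n_matched=len(matches),
        onset_errors_ms=np.array(errors), matches=matches,
    )
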