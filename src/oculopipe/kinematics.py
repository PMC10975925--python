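"""Gaze kinematics: unit conversion, smoothing, velocity, drift re-referencing.

Position is smoothed with a zero-phase moving average (forward-backward
boxcar) before differentiation; instantaneous velocity uses a central
difference with one-sided differences at the ends; speed is the Euclidean
norm of the two smoothed velocity components.  Between-trial drift is removed
by subtracting the modal fixation position pooled over each drift segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import filtfilt

from .io_session import SampleTrace, ScreenGeometry, TrialRecord

__all__ = [
    "VelocityTrace",
    "DriftOffset",
    "pixels_to_degrees",
    "degrees_to_pixels",
    "zero_phase_boxcar",
    "central_velocity",
    "euclidean_speed",
    "compute_velocity",
    "drift_reference",
    "apply_drift_offset",
]


@dataclass
class VelocityTrace:
    """Smoothed per-sample kinematics of one trial (deg/s)."""

    velX: np.ndarray
    velY: np.ndarray
    speed: np.ndarray
    smoothing_w: int
    # smoothed positions the velocities were differentiated from; saccade
    # endpoints are read from these
    xs: np.ndarray | None = None
    ys: np.ndarray | None = None


@dataclass
class DriftOffset:
    """Constant re-referencing offset (degrees) for one drift segment."""

    segment_id: int
    dx: float
    dy: float
    n_samples_used: int


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

def pixels_to_degrees(trace: SampleTrace, geom: ScreenGeometry) -> SampleTrace:
    """Convert X/Y from screen pixels to degrees of visual angle.

    Origin at screen center, rightward and upward positive:
    ``deg = atan((px - center) * cm_per_px / distance) * 180 / pi``
    (screen pixel y grows downward, hence the sign flip on Y).
    """
    if trace.units != "px":
        raise ValueError(f"trace units are {trace.units!r}, expected 'px'")
    if geom.distance_cm <= 0:
        raise ValueError("viewing distance must be positive")
    cx = geom.width_px / 2.0
    cy = geom.height_px / 2.0
    x_deg = np.degrees(np.arctan((trace.X - cx) * geom.cm_per_px_x / geom.distance_cm))
    y_deg = -np.degrees(np.arctan((trace.Y - cy) * geom.cm_per_px_y / geom.distance_cm))
    out = trace.copy()
    out.X, out.Y, out.units = x_deg, y_deg, "deg"
    return out


def degrees_to_pixels(x_deg: np.ndarray, y_deg: np.ndarray,
                      geom: ScreenGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`pixels_to_degrees` (used by the simulator)."""
    cx = geom.width_px / 2.0
    cy = geom.height_px / 2.0
    px = cx + np.tan(np.radians(np.asarray(x_deg))) * geom.distance_cm / geom.cm_per_px_x
    py = cy - np.tan(np.radians(np.asarray(y_deg))) * geom.distance_cm / geom.cm_per_px_y
    return px, py


# ---------------------------------------------------------------------------
# smoothing & differentiation
# ---------------------------------------------------------------------------

def zero_phase_boxcar(x: np.ndarray, w: int) -> np.ndarray:
    """Forward-backward moving average of width ``w`` (unit DC gain, zero phase).

    Edges are handled by odd-reflection padding of length ``3*(w-1)``, so the
    input must be longer than that.
    """
    x = np.asarray(x, dtype=float)
    if w < 1:
        raise ValueError("smoothing width must be >= 1")
    if w == 1:
        return x.copy()
    padlen = 3 * (w - 1)
    if len(x) <= padlen:
        raise ValueError(
            f"input of length {len(x)} too short for width {w}; "
            f"need at least {padlen + 1} samples"
        )
    return filtfilt(np.ones(w) / w, [1.0], x, padlen=padlen)


def central_velocity(x: np.ndarray, dt: float) -> np.ndarray:
    """Central-difference velocity with 2-point differences at the ends."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples to differentiate")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return np.gradient(x, dt)


def euclidean_speed(velX: np.ndarray, velY: np.ndarray) -> np.ndarray:
    velX = np.asarray(velX, dtype=float)
    velY = np.asarray(velY, dtype=float)
    if velX.shape != velY.shape:
        raise ValueError("velocity components must have equal length")
    return np.hypot(velX, velY)


def _fill_invalid(x: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Bridge invalid/NaN stretches by linear interpolation (edge-held).

    Keeps the filter and derivative finite through data loss; the validity
    mask still marks those samples so no detection is trusted there alone.
    """
    good = valid & np.isfinite(x)
    if good.all():
        return x.astype(float)
    if not good.any():
        return np.zeros_like(x, dtype=float)
    idx = np.arange(len(x))
    return np.interp(idx, idx[good], x[good])


def compute_velocity(trace: SampleTrace, w: int) -> VelocityTrace:
    """Smooth positions, differentiate, and take the Euclidean speed."""
    dt = trace.step_ms / 1000.0
    x = _fill_invalid(trace.X, trace.valid)
    y = _fill_invalid(trace.Y, trace.valid)
    xs = zero_phase_boxcar(x, w)
    ys = zero_phase_boxcar(y, w)
    velX = central_velocity(xs, dt)
    velY = central_velocity(ys, dt)
    return VelocityTrace(velX=velX, velY=velY, speed=euclidean_speed(velX, velY),
                         smoothing_w=w, xs=xs, ys=ys)


# ---------------------------------------------------------------------------
# drift re-referencing
# ---------------------------------------------------------------------------

def _mode_1d(values: np.ndarray, bin_deg: float, span_deg: float) -> float:
    """Histogram mode: mean of samples in the fullest bin; ties -> bin nearest 0."""
    # edges built as +-k * bin so they are exactly sign-symmetric in floating
    # point; the nearest-zero tie-break is then deterministic
    k = int(round(span_deg / bin_deg))
    edges = bin_deg * np.arange(-k, k + 1)
    counts, _ = np.histogram(values, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    best = counts.max()
    cand = np.flatnonzero(counts == best)
    # deterministic tie-break: bin center nearest zero, then the more negative
    order = sorted(cand, key=lambda i: (abs(centers[i]), centers[i]))
    i = order[0]
    in_bin = (values >= edges[i]) & (values < edges[i + 1])
    if not in_bin.any():
        return float(centers[i])
    return float(values[in_bin].mean())


def drift_reference(
    trials: list[TrialRecord],
    velocities: list[VelocityTrace],
    epoch_ms: tuple[float, float] = (-700.0, -200.0),
    bin_deg: float = 0.1,
    span_deg: float = 5.0,
    min_samples: int = 100,
    speed_max_dps: float = 50.0,
    segment_id: int = 0,
) -> DriftOffset:
    """Modal fixation position pooled over one drift segment's trials.

    Fixation-epoch samples with speed below ``speed_max_dps`` qualify; the
    per-axis mode uses a ``bin_deg`` histogram over +-``span_deg``.  Too few
    qualifying samples -> offset (0, 0) with a warning.
    """
    xs, ys = [], []
    for rec, vel in zip(trials, velocities):
        t = rec.trace.T
        m = (t >= epoch_ms[0]) & (t <= epoch_ms[1]) & rec.trace.valid
        m &= vel.speed < speed_max_dps
        xs.append(rec.trace.X[m])
        ys.append(rec.trace.Y[m])
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    n = len(x)
    if n < min_samples:
        warnings.warn(
            f"drift segment {segment_id}: only {n} qualifying fixation samples; "
            "offset left at (0, 0)", stacklevel=2,
        )
        return DriftOffset(segment_id, 0.0, 0.0, n)
    dx = _mode_1d(x, bin_deg, span_deg)
    dy = _mode_1d(y, bin_deg, span_deg)
    if abs(dx) > 5.0 or abs(dy) > 5.0:
        warnings.warn(
            f"drift segment {segment_id}: offset ({dx:.2f}, {dy:.2f}) deg exceeds "
            "5 deg; likely calibration failure", stacklevel=2,
        )
    return DriftOffset(segment_id, dx, dy, n)


def apply_drift_offset(trial: TrialRecord, offset: DriftOffset,
                       vel: VelocityTrace | None = None) -> None:
    """Subtract the segment offset from the trial (and its smoothed positions)."""
    trial.trace.X = trial.trace.X - offset.dx
    trial.trace.Y = trial.trace.Y - offset.dy
    if vel is not None and vel.xs is not None:
        vel.xs = vel.xs - offset.dx
        vel.ys = vel.ys - offset.dy
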