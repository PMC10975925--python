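"""Session ingestion: parse gaze recordings into per-trial records.

Two dialects are accepted:

* ``asc`` -- EyeLink-style text export: whitespace-delimited sample rows
  (``<t> <x> <y> <area>``; missing gaze printed as ``.``) interleaved with
  ``MSG <t> <text>`` event rows.  Task events are recognized through a
  configurable regex map, since event-tag vocabularies are lab-specific.
* ``table`` -- a directory of per-trial TSV files (columns T, X, Y, A, valid)
  each with a JSON sidecar holding events, condition, stimulus side, geometry
  and sampling rate.

After parsing, timestamps are repaired to a strictly increasing uniform grid
(isolated gaps linearly interpolated, duplicates dropped), event stamps are
rounded to the sample step, and each trial is re-based so that STIM onset is
time zero.
"""

from __future__ import annotations

import json
import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ScreenGeometry",
    "SampleTrace",
    "TrialRecord",
    "DEFAULT_EVENT_MAP",
    "read_session",
    "write_session",
    "repair_timestamps",
    "round_events_to_rate",
]

REQUIRED_EVENTS = ("trial_start", "fix_on", "fix_off", "stim_on", "trial_end")

DEFAULT_EVENT_MAP: dict[str, str] = {
    "trial_start": r"TRIALID\s+(?P<trial_id>\d+)",
    "condition": r"TRIAL_CONDITION\s+(?P<condition>PRO|ANTI)",
    "stim_side": r"STIM_SIDE\s+(?P<side>left|right)",
    "fix_on": r"\bFIX_ON\b",
    "fix_off": r"\bFIX_OFF\b",
    "stim_on": r"\bSTIM_ON\b",
    "trial_end": r"\bTRIAL_END\b",
    "drift_segment": r"DRIFT_SEGMENT\s+(?P<segment>\d+)",
}

# EyeLink ASC housekeeping rows that carry no information we use.
_IGNORED_PREFIXES = (
    "**",
    "#",
    ";",
    "START",
    "END",
    "SFIX",
    "EFIX",
    "SSACC",
    "ESACC",
    "SBLINK",
    "EBLINK",
    "INPUT",
    "BUTTON",
    "PRESCALER",
    "VPRESCALER",
    "PUPIL",
    "EVENTS",
    "SAMPLES",
    "DISPLAY_COORDS",
)


@dataclass
class ScreenGeometry:
    """Monitor geometry needed for the pixel -> degrees-of-visual-angle map."""

    width_px: int
    height_px: int
    width_cm: float
    height_cm: float
    distance_cm: float

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_cm", "height_cm", "distance_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be strictly positive")
        ppcm_x = self.width_px / self.width_cm
        ppcm_y = self.height_px / self.height_cm
        if abs(ppcm_x - ppcm_y) > 0.10 * max(ppcm_x, ppcm_y):
            warnings.warn(
                "pixel density differs by more than 10% between axes "
                f"({ppcm_x:.2f} vs {ppcm_y:.2f} px/cm); check geometry",
                stacklevel=2,
            )

    @property
    def cm_per_px_x(self) -> float:
        return self.width_cm / self.width_px

    @property
    def cm_per_px_y(self) -> float:
        return self.height_cm / self.height_px

    def to_dict(self) -> dict:
        return {
            "width_px": self.width_px,
            "height_px": self.height_px,
            "width_cm": self.width_cm,
            "height_cm": self.height_cm,
            "distance_cm": self.distance_cm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenGeometry":
        return cls(**d)


@dataclass
class SampleTrace:
    """Aligned per-trial sample vectors.

    T is in milliseconds, X/Y in pixels before unit conversion and degrees of
    visual angle after, A is pupil area in camera-pixel counts (0 = loss).
    ``valid`` is False for samples that were missing in the recording or were
    filled in during timestamp repair.
    """

    T: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    A: np.ndarray
    valid: np.ndarray
    rate_hz: float
    units: str = "px"

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.T)
        if not all(len(v) == n for v in (self.X, self.Y, self.A, self.valid)):
            raise ValueError("SampleTrace vectors must have equal length")
        if np.any(self.A < 0):
            raise ValueError("pupil area must be non-negative")

    @property
    def step_ms(self) -> float:
        return 1000.0 / self.rate_hz

    def __len__(self) -> int:
        return len(self.T)

    def copy(self) -> "SampleTrace":
        return SampleTrace(
            self.T.copy(), self.X.copy(), self.Y.copy(), self.A.copy(),
            self.valid.copy(), self.rate_hz, self.units,
        )


@dataclass
class TrialRecord:
    """One trial: trace aligned to STIM onset (= 0 ms) plus task metadata."""

    trial_id: int
    condition: str | None  # "PRO" | "ANTI"
    stim_side: str | None  # "left" | "right"
    trace: SampleTrace
    events: dict[str, float]
    geometry: ScreenGeometry
    drift_segment_id: int = 0
    not_marked: bool = False
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# timestamp utilities
# ---------------------------------------------------------------------------

def round_events_to_rate(events: dict[str, float], rate_hz: float) -> dict[str, float]:
    """Round event stamps to multiples of the sample step; ties round down."""
    step = 1000.0 / rate_hz
    out = {}
    for name, t in events.items():
        q = t / step
        lo = math.floor(q)
        out[name] = step * (lo + 1 if q - lo > 0.5 else lo)
    return out


def repair_timestamps(trace: SampleTrace, max_interp_gap_ms: float = 100.0) -> SampleTrace:
    """Force T onto a strictly increasing uniform grid.

    Duplicated stamps are dropped (first kept).  Missing stamps are inserted;
    for gaps no longer than ``max_interp_gap_ms`` the corresponding X, Y and A
    are linearly interpolated (and flagged invalid), longer gaps are inserted
    as invalid samples with no fabricated gaze.
    """
    T = np.asarray(trace.T, dtype=float)
    if len(T) == 0:
        return trace.copy()
    if np.any(np.diff(T) < 0):
        raise ValueError("timestamps must be non-decreasing before repair")

    keep = np.concatenate(([True], np.diff(T) > 0))
    T, X, Y, A, V = (
        T[keep], trace.X[keep], trace.Y[keep], trace.A[keep], trace.valid[keep]
    )

    step = trace.step_ms
    n_new = int(round((T[-1] - T[0]) / step)) + 1
    newT = T[0] + step * np.arange(n_new)
    idx = np.round((T - T[0]) / step).astype(int)
    if len(np.unique(idx)) != len(idx):
        raise ValueError("timestamps are not aligned to the sampling grid")

    newX = np.full(n_new, np.nan)
    newY = np.full(n_new, np.nan)
    newA = np.zeros(n_new)
    newV = np.zeros(n_new, dtype=bool)
    newX[idx], newY[idx], newA[idx], newV[idx] = X, Y, A, V

    present = np.zeros(n_new, dtype=bool)
    present[idx] = True
    missing = ~present
    if np.any(missing):
        # interpolate only across short gaps
        gap_start = np.flatnonzero(missing & ~np.roll(missing, 1))
        gap_end = np.flatnonzero(missing & ~np.roll(missing, -1))
        for g0, g1 in zip(gap_start, gap_end):
            gap_ms = (g1 - g0 + 1) * step
            if g0 == 0 or g1 == n_new - 1 or gap_ms > max_interp_gap_ms:
                continue
            span = np.arange(g0, g1 + 1)
            for arr in (newX, newY, newA):
                arr[span] = np.interp(newT[span], [newT[g0 - 1], newT[g1 + 1]],
                                      [arr[g0 - 1], arr[g1 + 1]])
        # interpolated (and long-gap) samples stay invalid in the mask

    return SampleTrace(newT, newX, newY, newA, newV, trace.rate_hz, trace.units)


# ---------------------------------------------------------------------------
# ASC dialect
# ---------------------------------------------------------------------------

def _parse_float(tok: str) -> float:
    if tok in (".", "...", "nan", "NaN"):
        return np.nan
    return float(tok)


def _parse_asc(path: Path, event_map: dict[str, str]):
    """Return (samples DataFrame, list of (t, text) messages, header dict)."""
    times, xs, ys, areas = [], [], [], []
    messages: list[tuple[float, str]] = []
    header: dict[str, str] = {}
    msg_re = re.compile(r"^MSG\s+(\d+(?:\.\d+)?)\s+(.*)$")
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            m = msg_re.match(line)
            if m:
                messages.append((float(m.group(1)), m.group(2).strip()))
                continue
            first = line.split(None, 1)[0]
            if any(line.startswith(p) for p in _IGNORED_PREFIXES):
                continue
            try:
                t = float(first)
            except ValueError:
                raise ValueError(f"{path}: unparseable line {lineno}: {line!r}") from None
            toks = line.split()
            if len(toks) < 4:
                raise ValueError(f"{path}: sample line {lineno} has fewer than 4 fields")
            try:
                x, y, a = (_parse_float(toks[1]), _parse_float(toks[2]),
                           _parse_float(toks[3]))
            except ValueError:
                raise ValueError(f"{path}: unparseable line {lineno}: {line!r}") from None
            times.append(t)
            xs.append(x)
            ys.append(y)
            areas.append(0.0 if not np.isfinite(a) else a)
    df = pd.DataFrame({"T": times, "X": xs, "Y": ys, "A": areas})
    return df, messages, header


def _extract_geometry(messages) -> ScreenGeometry | None:
    pat = re.compile(r"GEOMETRY\s+(.*)")
    for _, text in messages:
        m = pat.match(text)
        if m:
            kv = dict(tok.split("=") for tok in m.group(1).split())
            return ScreenGeometry(
                width_px=int(kv["width_px"]), height_px=int(kv["height_px"]),
                width_cm=float(kv["width_cm"]), height_cm=float(kv["height_cm"]),
                distance_cm=float(kv["distance_cm"]),
            )
    return None


def _extract_rate(messages) -> float | None:
    pat = re.compile(r"RATE\s+(\d+(?:\.\d+)?)")
    for _, text in messages:
        m = pat.match(text)
        if m:
            return float(m.group(1))
    return None


def read_session(
    path: str | Path,
    dialect: str = "asc",
    geometry: ScreenGeometry | None = None,
    rate_hz: float | None = None,
    event_map: dict[str, str] | None = None,
    max_interp_gap_ms: float = 100.0,
) -> list[TrialRecord]:
    """Parse a recording into a list of TrialRecords in recording order.

    Trials missing a required event stamp are still emitted, flagged
    ``not_marked`` (they classify as "Not marked" downstream), with a warning.
    """
    path = Path(path)
    if dialect == "asc":
        return _read_asc_session(path, geometry, rate_hz, event_map, max_interp_gap_ms)
    if dialect == "table":
        return _read_table_session(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_asc_session(path, geometry, rate_hz, event_map, max_interp_gap_ms):
    if not path.exists():
        raise FileNotFoundError(path)
    emap = {k: re.compile(v) for k, v in (event_map or DEFAULT_EVENT_MAP).items()}
    samples, messages, _ = _parse_asc(path, emap)
    geometry = geometry or _extract_geometry(messages)
    rate_hz = rate_hz or _extract_rate(messages)
    if len(samples) == 0 and not messages:
        return []
    if geometry is None:
        raise ValueError(f"{path}: no screen geometry in file and none supplied")
    if rate_hz is None:
        # infer from median timestamp step
        if len(samples) < 2:
            raise ValueError(f"{path}: cannot infer sampling rate")
        rate_hz = 1000.0 / float(np.median(np.diff(samples["T"].to_numpy())))

    t0 = None
    if len(samples):
        t0 = float(samples["T"].iloc[0])
    if messages:
        t0 = min(t0, messages[0][0]) if t0 is not None else messages[0][0]
    if t0 is None:
        return []
    # paper-style re-basing: subtract the first stamp in the file
    samples = samples.assign(T=samples["T"] - t0)
    messages = [(t - t0, text) for t, text in messages]

    # group messages into trials
    trials: list[dict] = []
    current: dict | None = None
    drift_segment = 0
    for t, text in messages:
        m = emap["drift_segment"].search(text) if "drift_segment" in emap else None
        if m:
            drift_segment = int(m.group("segment"))
            continue
        m = emap["trial_start"].search(text)
        if m:
            if current is not None:
                trials.append(current)
            current = {
                "trial_id": int(m.group("trial_id")),
                "events": {"trial_start": t},
                "condition": None,
                "stim_side": None,
                "drift_segment": drift_segment,
            }
            continue
        if current is None:
            continue
        m = emap["condition"].search(text)
        if m:
            current["condition"] = m.group("condition")
            continue
        m = emap["stim_side"].search(text)
        if m:
            current["stim_side"] = m.group("side")
            continue
        for name in ("fix_on", "fix_off", "stim_on", "trial_end"):
            if emap[name].search(text):
                current["events"][name] = t
                break
    if current is not None:
        trials.append(current)

    T = samples["T"].to_numpy()
    records: list[TrialRecord] = []
    for tr in trials:
        events = round_events_to_rate(tr["events"], rate_hz)
        missing = [e for e in REQUIRED_EVENTS if e not in events]
        not_marked = bool(missing) or tr["condition"] is None or tr["stim_side"] is None
        if missing:
            log.warning("trial %s missing event stamp(s) %s; flagged Not marked",
                        tr["trial_id"], missing)
        lo = events.get("trial_start", 0.0)
        hi = events.get("trial_end", lo)
        sel = (T >= lo) & (T <= hi)
        sub = samples.loc[sel]
        valid = np.isfinite(sub["X"].to_numpy()) & np.isfinite(sub["Y"].to_numpy())
        trace = SampleTrace(sub["T"].to_numpy(), sub["X"].to_numpy(),
                            sub["Y"].to_numpy(), sub["A"].to_numpy(),
                            valid, rate_hz, units="px")
        if len(trace):
            trace = repair_timestamps(trace, max_interp_gap_ms)
        # align to STIM onset; fall back to trial start for unmarked trials
        if "stim_on" in events:
            t_zero = events["stim_on"]
        else:
            t_zero = lo  # leaves the trial unusable but representable
        trace.T = trace.T - t_zero
        events = {k: v - t_zero for k, v in events.items()}
        records.append(TrialRecord(
            trial_id=tr["trial_id"], condition=tr["condition"],
            stim_side=tr["stim_side"], trace=trace, events=events,
            geometry=geometry, drift_segment_id=tr["drift_segment"],
            not_marked=not_marked,
        ))
    return records


# ---------------------------------------------------------------------------
# table dialect (per-trial TSV + JSON sidecar)
# ---------------------------------------------------------------------------

def write_session(trials: list[TrialRecord], outdir: str | Path) -> None:
    """Write trials to the tabular dialect (one TSV + JSON sidecar each)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in trials:
        stem = outdir / f"trial_{rec.trial_id:04d}"
        df = pd.DataFrame({
            "T": rec.trace.T, "X": rec.trace.X, "Y": rec.trace.Y,
            "A": rec.trace.A, "valid": rec.trace.valid.astype(int),
        })
        df.to_csv(f"{stem}.tsv", sep="\t", index=False)
        meta = {
            "trial_id": rec.trial_id,
            "condition": rec.condition,
            "stim_side": rec.stim_side,
            "events": rec.events,
            "geometry": rec.geometry.to_dict(),
            "rate_hz": rec.trace.rate_hz,
            "units": rec.trace.units,
            "drift_segment_id": rec.drift_segment_id,
            "not_marked": rec.not_marked,
        }
        with open(f"{stem}.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)


def _read_table_session(path: Path) -> list[TrialRecord]:
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for tsv in sorted(path.glob("trial_*.tsv")):
        sidecar = tsv.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing sidecar for {tsv}")
        with open(sidecar) as fh:
            meta = json.load(fh)
        df = pd.read_csv(tsv, sep="\t", float_precision="round_trip")
        trace = SampleTrace(
            df["T"].to_numpy(), df["X"].to_numpy(), df["Y"].to_numpy(),
            df["A"].to_numpy(), df["valid"].to_numpy().astype(bool),
            meta["rate_hz"], units=meta.get("units", "px"),
        )
        records.append(TrialRecord(
            trial_id=meta["trial_id"], condition=meta["condition"],
            stim_side=meta["stim_side"], trace=trace,
            events={k: float(v) for k, v in meta["events"].items()},
            geometry=ScreenGeometry.from_dict(meta["geometry"]),
            drift_segment_id=meta.get("drift_segment_id", 0),
            not_marked=meta.get("not_marked", False),
        ))
    return records
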