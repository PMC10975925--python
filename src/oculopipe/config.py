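"""Pipeline configuration.

Every tunable the analysis stages use lives here, grouped by stage, with the
defaults the rest of the package documents.  Configs are plain dataclasses so
they serialize cleanly to/from YAML and reject unknown keys on load.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "TimelineConfig",
    "SmoothingConfig",
    "DriftConfig",
    "BlinkConfig",
    "SaccadeConfig",
    "PsoConfig",
    "BoomerangConfig",
    "BlincadeConfig",
    "MainSequenceConfig",
    "PupilConfig",
    "ClassifyConfig",
    "PipelineConfig",
]

# Two-sided standard normal critical value for p < 0.001 (the main-sequence
# outlier cut); kept as a literal so config does not import scipy.
Z_CRIT_P001 = 3.290526731491926


@dataclass
class TimelineConfig:
    """IPAST trial timeline: 1000 ms ITI, 1000 ms FIX, 200 ms gap, then STIM.

    All derived epochs are expressed in milliseconds relative to STIM onset.
    """

    iti_ms: float = 1000.0
    fix_ms: float = 1000.0
    gap_ms: float = 200.0
    trial_ms: float = 3200.0
    stim_ecc_deg: float = 10.0

    @property
    def fix_on_ms(self) -> float:
        return -(self.fix_ms + self.gap_ms)

    @property
    def fix_off_ms(self) -> float:
        return -self.gap_ms

    @property
    def trial_start_ms(self) -> float:
        return -(self.iti_ms + self.fix_ms + self.gap_ms)

    @property
    def trial_end_ms(self) -> float:
        return self.trial_ms - (self.iti_ms + self.fix_ms + self.gap_ms)


@dataclass
class SmoothingConfig:
    # Zero-phase boxcar half-width applied to X/Y position before
    # differentiation.  3 samples (6 ms at 500 Hz) keeps peak-velocity
    # attenuation of small saccades below ~2.5% while suppressing pixel noise;
    # wider windows visibly depress the main sequence at 2-3 deg amplitudes.
    w: int = 3

    def w_at(self, rate_hz: float) -> int:
        return max(1, int(round(self.w * rate_hz / 500.0)))


@dataclass
class DriftConfig:
    bin_deg: float = 0.1
    span_deg: float = 5.0
    # final 500 ms of the FIX period, relative to STIM onset
    epoch_ms: tuple[float, float] = (-700.0, -200.0)
    min_samples: int = 100
    speed_max_dps: float = 50.0
    warn_offset_deg: float = 5.0


@dataclass
class BlinkConfig:
    svel_thresh: float = 1000.0  # area units / sample step at 500 Hz
    band_lo: float = 200.0
    band_hi: float = 400.0
    loss_lo: float = 250.0
    loss_hi: float = 350.0
    model_w: int = 50
    merge_gap_ms: float = 20.0
    quiet_gap_ms: float = 50.0
    k_sd: float = 2.5
    savel_floor: float = 2.0  # area units / sample step at 500 Hz
    walk_cap_ms: float = 100.0
    min_ms: float = 50.0  # full-blink duration bounds
    max_ms: float = 500.0


@dataclass
class SaccadeConfig:
    floor_dps: float = 20.0
    k_sd: float = 2.5
    min_dur_ms: float = 10.0
    noise_ceiling_dps: float = 50.0
    min_noise_samples: int = 50


@dataclass
class PsoConfig:
    max_gap_ms: float = 40.0
    amp_min_deg: float = 0.5
    amp_max_deg: float = 5.0


@dataclass
class BoomerangConfig:
    angle_min_deg: float = 135.0
    axis_tol_deg: float = 45.0
    path_ratio: float = 1.5
    dur_ratio: float = 1.5
    # nominal amplitude->duration main-sequence model, D = slope*A + intercept.
    # Population-specific: the default linearizes the raised-cosine family
    # D = 2A / (V_inf (1 - exp(-A/A0))) with V_inf = 500 deg/s, A0 = 12 deg
    # over 2-15 deg; recalibrate for a different cohort or tracker.
    dur_slope_ms_per_deg: float = 2.4
    dur_intercept_ms: float = 47.0
    probe_ms: float = 10.0


@dataclass
class BlincadeConfig:
    max_gap_ms: float = 40.0
    blink_radius_deg: float = 2.0


@dataclass
class MainSequenceConfig:
    min_clean: int = 30
    n_knots: int = 4  # interior knots of the cubic fit -> effective df 8
    zcrit: float = Z_CRIT_P001


@dataclass
class PupilConfig:
    window_ms: float = 20.0
    sig_sd: float = 1.96
    center_radius_deg: float = 2.0
    max_loss_ms: float = 200.0
    max_sacc_deg: float = 2.0
    baseline_ms: tuple[float, float] = (150.0, 200.0)  # post FIX onset
    final_ms: tuple[float, float] = (1150.0, 1200.0)  # post FIX onset
    onset_search_from_ms: float = 200.0


@dataclass
class ClassifyConfig:
    fix_radius_deg: float = 2.0
    fix_dwell_ms: float = 200.0
    viable_amp_deg: float = 2.0
    anticipatory_ms: tuple[float, float] = (-110.0, 89.0)
    express_ms: tuple[float, float] = (90.0, 139.0)
    regular_ms: tuple[float, float] = (140.0, 800.0)
    viable_ms: tuple[float, float] = (-110.0, 1000.0)
    metrics_max_srt_ms: float = 800.0
    random_axis_off_deg: float = 45.0
    eye_loss_frac: float = 0.5


@dataclass
class IoConfig:
    dialect: str = "asc"
    max_interp_gap_ms: float = 100.0


@dataclass
class PipelineConfig:
    timeline: TimelineConfig = field(default_factory=TimelineConfig)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    drift: DriftConfig = field(default_factory=DriftConfig)
    blink: BlinkConfig = field(default_factory=BlinkConfig)
    saccade: SaccadeConfig = field(default_factory=SaccadeConfig)
    pso: PsoConfig = field(default_factory=PsoConfig)
    boomerang: BoomerangConfig = field(default_factory=BoomerangConfig)
    blincade: BlincadeConfig = field(default_factory=BlincadeConfig)
    masez: MainSequenceConfig = field(default_factory=MainSequenceConfig)
    pupil: PupilConfig = field(default_factory=PupilConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    io: IoConfig = field(default_factory=IoConfig)
    log_level: str = "INFO"

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        def _convert(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: _convert(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return _convert(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        return _dataclass_from_dict(cls, data, path="")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _dataclass_from_dict(cls: type, data: dict[str, Any], path: str) -> Any:
    if not isinstance(data, dict):
        raise TypeError(f"config section {path or cls.__name__!r} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise KeyError(
            f"unknown config key(s) {sorted(unknown)} in section {path or 'root'}"
        )
    kwargs: dict[str, Any] = {}
    for name, value in data.items():
        f = fields[name]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.type, str) and f.type.endswith("Config")
        ):
            sub_cls = f.default_factory() .__class__ if f.default_factory is not dataclasses.MISSING else None  # type: ignore[misc]
            kwargs[name] = _dataclass_from_dict(
                sub_cls, value, path=f"{path}.{name}" if path else name
            )
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)
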