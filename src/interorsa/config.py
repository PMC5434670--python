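"""Run configuration: every pipeline default in one validated place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Defaults mirror the standard protocol this pipeline implements:
    1 kHz ECG, 300 ms beat-to-beat artifact threshold, 241-tap FIR over
    0.12-0.40 Hz on a 10 Hz heart-period grid, 30-s epochs, and the
    age/BMI/anxiety/depression covariate set for the ANCOVA."""

    sampling_rate_hz: float = 1000.0
    artifact_threshold_ms: float = 300.0
    filter_taps: int = 241
    band_hz: tuple[float, float] = (0.12, 0.40)
    grid_rate_hz: float = 10.0
    epoch_s: float = 30.0
    min_peak_separation_ms: float = 300.0
    covariates: list[str] = field(
        default_factory=lambda: ["age", "bmi", "stai_trait", "stai_state", "bdi"]
    )
    alpha: float = 0.05
    bonferroni_family: int = 2
    mains_notch_hz: float | None = None  # disabled by default
    seed: int = 0

    def __post_init__(self) -> None:
        self.band_hz = tuple(self.band_hz)  # type: ignore[assignment]
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.artifact_threshold_ms <= 0:
            raise ValueError("artifact_threshold_ms must be positive")
        if self.filter_taps % 2 == 0 or self.filter_taps < 3:
            raise ValueError("filter_taps must be odd and >= 3")
        lo, hi = self.band_hz
        if not (0 < lo < hi < self.grid_rate_hz / 2):
            raise ValueError("band_hz must lie inside (0, Nyquist)")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_hz"] = list(self.band_hz)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
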