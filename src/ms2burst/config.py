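"""Pipeline configuration: a versioned, YAML-serializable parameter set.

The config round-trips losslessly through YAML and carries a content hash
so output artifacts can be traced to the exact parameters that produced
them (the hash changes iff any parameter changes).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PipelineConfig"]

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All tunable parameters of the end-to-end pipeline."""

    # sampling
    frame_interval: float = 16.8          # s; 12.8 for the finer preset
    channel_histone: int = 0
    channel_ms2: int = 1
    # optional centered crop: preset name ("square", "dorsoventral") or None
    crop: str | None = None
    # segmentation
    segmentation_method: int = 1
    segmentation: dict[str, Any] = field(default_factory=dict)
    # tracking
    max_disp: float | None = None         # px; default nucleus radius
    nucleus_radius: float = 9.0
    # spot quantification
    fit_window: int = 11
    # burst calling
    burst_threshold: float | None = None  # None = 10%-of-max auto rule
    min_len: int = 5
    end_frac: float = 0.55
    shift: int = 2
    smooth_window: int = 5
    # population metrics
    activity_fraction: float = 0.10
    shuffle_seed: int = 0
    # reconstitution
    half_life: float = 7.0                # min
    decay_model: str = "exponential"
    # simulation stage (optional): kwargs for FieldParams / TelegraphParams
    # or a variant preset name
    simulation: dict[str, Any] | None = None
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.segmentation_method not in (1, 2):
            raise ValueError("segmentation_method must be 1 or 2")
        if self.fit_window % 2 == 0 or self.fit_window < 3:
            raise ValueError("fit_window must be odd and >= 3")
        if not 0 < self.end_frac < 1:
            raise ValueError("end_frac must lie in (0, 1)")
        if not 0 < self.activity_fraction < 1:
            raise ValueError("activity_fraction must lie in (0, 1)")
        if self.min_len < 1 or self.shift < 0:
            raise ValueError("min_len >= 1 and shift >= 0 required")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd integer")
        if self.half_life <= 0:
            raise ValueError("half_life must be positive")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON form (first 12 hex digits)."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def with_overrides(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)
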