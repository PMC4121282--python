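"""Pipeline configuration: YAML-backed settings for every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .matching import MatchingConfig
from .registration import RegistrationConfig
from .segmentation import SegmentationConfig


@dataclass
class PipelineConfig:
    """All stage settings plus the evaluation threshold grid and seed.

    Defaults encode the documented constants (5 mm FWHM pre-smoothing, EM
    tolerance 1e-4 over at most 30 iterations) and the gap-filling choices of
    the individual modules.
    """

    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    matching: MatchingConfig = field(default_factory=MatchingConfig)
    thresholds: list[float] = field(default_factory=lambda: list(np.arange(0.0, 101.0, 1.0)))
    seed: int = 0

    def __post_init__(self) -> None:
        if any(t < 0 or t > 100 for t in self.thresholds):
            raise ConfigError("evaluation thresholds must lie in [0, 100]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["registration"].pop("mask", None)
        return d

    @staticmethod
    def from_dict(raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        try:
            reg = RegistrationConfig(**raw.pop("registration", {}))
            seg = SegmentationConfig(**raw.pop("segmentation", {}))
            match = MatchingConfig(**raw.pop("matching", {}))
            thresholds = [float(t) for t in raw.pop("thresholds", np.arange(0.0, 101.0, 1.0))]
            seed = int(raw.pop("seed", 0))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc
        if raw:
            raise ConfigError(f"unknown configuration keys: {sorted(raw)}")
        return PipelineConfig(
            registration=reg, segmentation=seg, matching=match,
            thresholds=thresholds, seed=seed,
        )

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"no such config file: {path}")
        raw = yaml.safe_load(path.read_text())
        if raw is not None and not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping in {path}")
        return PipelineConfig.from_dict(raw or {})
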