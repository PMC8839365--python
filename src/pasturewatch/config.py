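"""Pipeline configuration: one YAML document with per-stage blocks.

Every stage of the pipeline reads its parameters from a
:class:`PipelineConfig`; unspecified blocks fall back to the package
defaults (the study-like design of 3 months x 2 cycles x 6 days x 2 groups
x 10 cows, a 629/592 training split, limit multiplier k = 3, the full
eight-variable predictor set, and the combined reference).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .simulate import EffectConfig, ExperimentDesign

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    seed: int = 0
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    effects: EffectConfig = field(default_factory=EffectConfig)
    herd: dict = field(default_factory=dict)  # overrides for make_herd keyword defaults
    n_sufficient: int = 629
    n_scarce: int = 592
    limit_k: float = 3.0
    predictor_variant: str = "full8"
    reference: str = "combined"  # milk | rumen | combined
    n_trees: int = 500
    paddock_exclusions: tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        if self.reference not in ("milk", "rumen", "combined"):
            raise ValueError("reference must be milk, rumen, or combined")
        if self.predictor_variant not in ("full8", "reduced5"):
            raise ValueError("predictor_variant must be full8 or reduced5")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        design = raw.pop("design", {})
        effects = raw.pop("effects", {})
        if "grazing_mode_per_month" in design:
            design["grazing_mode_per_month"] = tuple(design["grazing_mode_per_month"])
        for key in ("day_curves",):
            if key in effects:
                effects[key] = {k: tuple(v) for k, v in effects[key].items()}
        for key in ("milk_decline_curve", "rumen_decline_curve"):
            if key in effects:
                effects[key] = tuple(effects[key])
        if "paddock_exclusions" in raw:
            raw["paddock_exclusions"] = tuple(raw["paddock_exclusions"])
        cfg = cls(
            design=ExperimentDesign(**design),
            effects=EffectConfig(**effects),
            **raw,
        )
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def content_hash(self) -> str:
        """Stable hash of the full configuration, recorded in the manifest."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Copy of this configuration with the run seed replaced."""
        d = self.to_dict()
        d["seed"] = seed
        d["effects"]["seed"] = seed
        return PipelineConfig.from_dict(d)
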