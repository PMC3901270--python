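"""Structured pipeline configuration.

A YAML config file holds one block per pipeline stage plus a global
seed and log level; unknown keys are rejected, missing blocks fall back
to the stage defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Dict

import yaml

from .classify import ModelSpec
from .detect_lms import LMSConfig
from .detect_pme import PMEConfig
from .detect_regionmerge import RegionMergeConfig
from .detect_watershed import WatershedConfig
from .homogenize import HomogenizationRules
from .postprocess import MergeConditions
from .preprocess import PreprocessConfig
from .synthdata import CohortSpec, SyntheticPeakSpec

_BLOCKS = {
    "homogenize": HomogenizationRules,
    "preprocess": PreprocessConfig,
    "lms": LMSConfig,
    "watershed": WatershedConfig,
    "regionmerge": RegionMergeConfig,
    "pme": PMEConfig,
    "merge": MergeConditions,
    "classify": ModelSpec,
    "simulate": CohortSpec,
}


@dataclass
class PipelineConfig:
    seed: int = 0
    log_level: str = "INFO"
    homogenize: HomogenizationRules = field(default_factory=HomogenizationRules)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    lms: LMSConfig = field(default_factory=LMSConfig)
    watershed: WatershedConfig = field(default_factory=WatershedConfig)
    regionmerge: RegionMergeConfig = field(default_factory=RegionMergeConfig)
    pme: PMEConfig = field(default_factory=PMEConfig)
    merge: MergeConditions = field(default_factory=MergeConditions)
    classify: ModelSpec = field(default_factory=ModelSpec)
    simulate: CohortSpec = field(default_factory=CohortSpec)

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "PipelineConfig":
        cfg = cls()
        for key, value in (data or {}).items():
            if key == "seed":
                cfg.seed = int(value)
            elif key == "log_level":
                cfg.log_level = str(value)
            elif key in _BLOCKS:
                block_cls = _BLOCKS[key]
                known = {f.name for f in dataclasses.fields(block_cls)}
                unknown = set(value) - known
                if unknown:
                    raise ValueError(
                        f"unknown key(s) {sorted(unknown)} in config block {key!r}"
                    )
                value = dict(value)
                if key == "simulate" and "peaks" in value:
                    value["peaks"] = [SyntheticPeakSpec(**p) for p in value["peaks"]]
                if key == "simulate":
                    for rng_key in ("t_range", "r_range"):
                        if rng_key in value:
                            value[rng_key] = tuple(value[rng_key])
                setattr(cfg, key, block_cls(**value))
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> Dict[str, Any]:
        out: Dict[str, Any] = {"seed": self.seed, "log_level": self.log_level}
        for key in _BLOCKS:
            out[key] = dataclasses.asdict(getattr(self, key))
        return out

    def digest(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
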