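"""Pipeline configuration: one YAML file mirroring every module's knobs.

Omitted sections fall back to each module's defaults, so an empty file is a
valid configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import AugmentationConfig
from .coco_io import SplitSpec
from .seedsynth import SceneParams
from .selftrain import StageConfig


@dataclass
class DetectorSettings:
    opening_radius: int = 2
    min_component_px: int = 24
    score_threshold: float = 0.5


@dataclass
class PipelineConfig:
    scene: SceneParams = field(default_factory=SceneParams)
    augment: AugmentationConfig = field(default_factory=AugmentationConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    detector: DetectorSettings = field(default_factory=DetectorSettings)
    selftrain: StageConfig = field(default_factory=StageConfig)
    n_scenes: int = 4
    rng_seed: int = 0
    log_level: str = "INFO"

    def reseed(self) -> "PipelineConfig":
        """Propagate the global seed into every per-module seed."""
        return dataclasses.replace(
            self,
            scene=dataclasses.replace(self.scene, rng_seed=self.rng_seed),
            augment=dataclasses.replace(self.augment, rng_seed=self.rng_seed + 1),
            split=dataclasses.replace(self.split, rng_seed=self.rng_seed + 2),
            selftrain=dataclasses.replace(self.selftrain,
                                          rng_seed=self.rng_seed + 3),
        )


def _build(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in data.items():
        if key not in fields:
            raise ValueError(f"unknown {cls.__name__} key {key!r}")
        if isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    return cls(**kwargs)


def load_config(path=None) -> PipelineConfig:
    """Load a PipelineConfig from YAML; missing file/sections use defaults."""
    if path is None:
        return PipelineConfig()
    doc = yaml.safe_load(Path(path).read_text()) or {}
    sections = {
        "scene": SceneParams, "augment": AugmentationConfig,
        "split": SplitSpec, "detector": DetectorSettings,
        "selftrain": StageConfig,
    }
    kwargs = {}
    for key, val in doc.items():
        if key in sections:
            kwargs[key] = _build(sections[key], val or {})
        elif key in ("n_scenes", "rng_seed", "log_level"):
            kwargs[key] = val
        else:
            raise ValueError(f"unknown config section {key!r}")
    return PipelineConfig(**kwargs)
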