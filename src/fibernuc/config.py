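"""Pipeline configuration: every tunable numeric constant in one place.

The configuration serializes to/from YAML or JSON with a full round
trip, so a run is completely described by its config file plus the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fusion import FusionConfig


@dataclass
class ClusteringConfig:
    overlap_threshold: float = 0.02
    alpha: float = 1.2
    beta: float = 0.05
    vicinity_radius: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_threshold <= 1.0:
            raise ValueError("overlap threshold outside [0, 1]")
        if self.alpha <= 0 or self.beta < 0 or self.vicinity_radius <= 0:
            raise ValueError("invalid clustering parameters")


@dataclass
class PipelineConfig:
    tile_size: int = 400
    overlap_fraction: float = 0.2
    min_visible_fraction: float = 0.1
    fusion: FusionConfig = field(default_factory=lambda: FusionConfig(score_threshold=None))
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    channel_policy: str = "blue"
    backend: str = "toy-threshold"
    output_dir: str = "fibernuc_out"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        if "fusion" in kwargs and isinstance(kwargs["fusion"], dict):
            kwargs["fusion"] = FusionConfig(**kwargs["fusion"])
        if "clustering" in kwargs and isinstance(kwargs["clustering"], dict):
            kwargs["clustering"] = ClusteringConfig(**kwargs["clustering"])
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        data = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)
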