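"""Pipeline configuration: one YAML file drives every stage.

Defaults equal the study protocol constants wherever one exists: 75 ms
interpolation gap, 30% missing / 50% face-time exclusion thresholds, 250 ms
epochs, dichotomous-AQ cutoff 26, SPIN cutoff 19, moderator levels -1/0/+1.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .preprocess import PreprocessParams
from .simulate import SimulationParams


@dataclass
class MetricsParams:
    window_ms: float = 250.0
    step_ms: float = 50.0
    aq_cutoff: int = 26
    spin_cutoff: int = 19


@dataclass
class InferenceParams:
    df_method: str = "satterthwaite"
    n_perm: int = 1000
    cluster_alpha: float = 0.05
    aq_levels: tuple[float, ...] = (-1.0, 0.0, 1.0)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "traitgaze_out"
    simulation: SimulationParams = field(default_factory=SimulationParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    metrics: MetricsParams = field(default_factory=MetricsParams)
    inference: InferenceParams = field(default_factory=InferenceParams)

    def __post_init__(self) -> None:
        # the one global seed flows into the simulator
        self.simulation.seed = self.seed

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (("simulation", SimulationParams),
                         ("preprocess", PreprocessParams),
                         ("metrics", MetricsParams),
                         ("inference", InferenceParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        cfg = cls(**d)
        if "inference" in d:
            cfg.inference.aq_levels = tuple(cfg.inference.aq_levels)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh,
                           sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
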