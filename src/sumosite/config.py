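"""Pipeline configuration: one YAML file, flag overrides, a run manifest.

Defaults mirror the documented study settings per module: 7-residue
windows (3+3), all 137 features on, ReliefF with 10 distance-weighted
neighbours (sigma 2), the doubling hyperparameter grid with 1:5 class
weights, decision thresholds -0.5/0/0.5, and 25-repeat stratified
cross-validation.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__


@dataclass
class ReliefFConfig:
    k_neighbors: int = 10
    weight_sigma: float = 2.0
    stride: int = 1
    folds: int = 10


@dataclass
class SvmSettings:
    C: float | None = None  # None -> grid search
    gamma: float | None = None
    weight_negative: float = 1.0
    weight_positive: float = 5.0
    grid_folds: int = 10
    grid_step: int = 1
    threshold: str = "medium"


@dataclass
class EvaluationConfig:
    folds: int = 5
    repeats: int = 25


@dataclass
class SyntheticConfig:
    n_sites: int = 2600
    n_proteins: int = 260
    length_min: int = 100
    length_max: int = 600


@dataclass
class PipelineConfig:
    """Aggregate configuration for the CLI pipeline."""

    seed: int = 0
    use_flexibility: bool = True
    use_disorder: bool = True
    relieff: ReliefFConfig = field(default_factory=ReliefFConfig)
    svm: SvmSettings = field(default_factory=SvmSettings)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    @property
    def dropped_features(self) -> tuple[str, ...]:
        dropped: list[str] = []
        if not self.use_flexibility:
            dropped.append("Flexible")
        if not self.use_disorder:
            dropped.extend(["DisorderReal", "DisorderBinary"])
        return tuple(dropped)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {
            "relieff": ReliefFConfig,
            "svm": SvmSettings,
            "evaluation": EvaluationConfig,
            "synthetic": SyntheticConfig,
        }
        kwargs: dict = {}
        for key, value in d.items():
            if key in known:
                kwargs[key] = known[key](**value)
            elif key in cls.__dataclass_fields__:
                kwargs[key] = value
            else:
                raise ValueError(f"unknown configuration key {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def write_manifest(out_dir: str | Path, config: PipelineConfig, stage: str, extra: dict | None = None) -> Path:
    """Snapshot config, seed and versions next to a stage's artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "config": config.to_dict(),
        "versions": {
            "sumosite": __version__,
            "python": platform.python_version(),
        },
    }
    if extra:
        manifest.update(extra)
    path = out / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
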