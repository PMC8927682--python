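"""YAML experiment configuration with strict schema validation.

An experiment file wires together every stage: the data source (synthetic
spec or a corpus directory), the patch grid, the split, the model, the
training schedule, the preprocessing parameters and the ensemble
thresholds.  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .model_core import ModelConfig
from .preprocessing import PreprocessConfig
from .synthetic import SyntheticSpec
from .training import TrainConfig

__all__ = ["DataConfig", "SplitConfig", "EnsembleSettings",
           "ExperimentConfig", "load_config", "config_hash"]


@dataclass
class DataConfig:
    """Either a synthetic spec or a corpus root with a manifest.json."""

    synthetic: SyntheticSpec | None = None
    root: str | None = None
    template: int = 64
    stride: int = 48

    def __post_init__(self):
        if (self.synthetic is None) == (self.root is None):
            raise ConfigurationError(
                "data config needs exactly one of 'synthetic' or 'root'")


@dataclass
class SplitConfig:
    n_train: int = 3
    seed: int = 0


@dataclass
class EnsembleSettings:
    T: float = 0.5
    T1: float | None = None


@dataclass
class ExperimentConfig:
    data: DataConfig = field(default_factory=lambda: DataConfig(
        synthetic=SyntheticSpec()))
    split: SplitConfig = field(default_factory=SplitConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    ensemble: EnsembleSettings = field(default_factory=EnsembleSettings)
    seed: int = 0
    out: str = "runs/experiment"


_TUPLE_FIELDS = {"attention_scales", "n_vessels", "width_range",
                 "clahe_grid", "tile_grid"}


def _build(cls, payload, context: str):
    if payload is None:
        return cls()
    if not isinstance(payload, dict):
        raise ConfigurationError(f"{context}: expected a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(payload) - set(names)
    if unknown:
        raise ConfigurationError(
            f"{context}: unknown keys {sorted(unknown)}; "
            f"allowed: {sorted(names)}")
    kwargs = {}
    for key, value in payload.items():
        if key in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate a YAML experiment file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    payload = yaml.safe_load(path.read_text()) or {}
    if not isinstance(payload, dict):
        raise ConfigurationError("top-level config must be a mapping")
    allowed = {"data", "split", "model", "train", "preprocess", "ensemble",
               "seed", "out"}
    unknown = set(payload) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown top-level keys {sorted(unknown)}; allowed {sorted(allowed)}")

    data_payload = payload.get("data") or {}
    if "synthetic" in (data_payload or {}):
        data_payload = dict(data_payload)
        data_payload["synthetic"] = _build(SyntheticSpec,
                                           data_payload["synthetic"],
                                           "data.synthetic")
    data = _build(DataConfig, data_payload, "data") if data_payload else \
        DataConfig(synthetic=SyntheticSpec())
    return ExperimentConfig(
        data=data,
        split=_build(SplitConfig, payload.get("split"), "split"),
        model=_build(ModelConfig, payload.get("model"), "model"),
        train=_build(TrainConfig, payload.get("train"), "train"),
        preprocess=_build(PreprocessConfig, payload.get("preprocess"),
                          "preprocess"),
        ensemble=_build(EnsembleSettings, payload.get("ensemble"), "ensemble"),
        seed=int(payload.get("seed", 0)),
        out=str(payload.get("out", "runs/experiment")),
    )


def config_hash(config: ExperimentConfig) -> str:
    """Stable short hash of a config, for run logging."""
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
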