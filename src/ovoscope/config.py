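"""YAML run configuration: nested blocks for the generator, preprocessing,
model and training, one global seed, strict unknown-key rejection, and a
lossless round-trip (`load_config(save_config(c)) == c`)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .experiment import TrainConfig
from .models import ModelSpec
from .preprocess import PreprocessConfig
from .synthetic import GeneratorParams

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


def _tuplify(value):
    if isinstance(value, list):
        return tuple(_tuplify(v) for v in value)
    if isinstance(value, dict):
        return {k: _tuplify(v) for k, v in value.items()}
    return value


def _listify(value):
    if isinstance(value, tuple):
        return [_listify(v) for v in value]
    if isinstance(value, dict):
        return {k: _listify(v) for k, v in value.items()}
    return value


def _dataclass_from_dict(cls, data: dict, context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {context} config")
    return cls(**{k: _tuplify(v) for k, v in data.items()})


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: str = "runs"
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    training: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "generator": _listify(dataclasses.asdict(self.generator)),
            "preprocess": _listify(dataclasses.asdict(self.preprocess)),
            "model": _listify(dataclasses.asdict(self.model)),
            "training": _listify(dataclasses.asdict(self.training)),
        }

    @staticmethod
    def from_dict(data: dict) -> "RunConfig":
        data = dict(data)
        unknown = set(data) - {"seed", "out_dir", "generator", "preprocess",
                               "model", "training"}
        if unknown:
            raise ValueError(f"unknown top-level config key(s) {sorted(unknown)}")
        seed = int(data.get("seed", 0))
        training = dict(data.get("training", {}))
        training.setdefault("seed", seed)  # one global seed by default
        return RunConfig(
            seed=seed,
            out_dir=str(data.get("out_dir", "runs")),
            generator=_dataclass_from_dict(GeneratorParams,
                                           dict(data.get("generator", {})),
                                           "generator"),
            preprocess=_dataclass_from_dict(PreprocessConfig,
                                            dict(data.get("preprocess", {})),
                                            "preprocess"),
            model=_dataclass_from_dict(ModelSpec, dict(data.get("model", {})),
                                       "model"),
            training=_dataclass_from_dict(TrainConfig, training, "training"),
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    """Short stable hash of a config, used to name run directories."""
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:10]
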