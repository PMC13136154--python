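"""Run configuration: nested dataclasses with YAML/JSON round-tripping."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .adfnet import NetworkConfig
from .phantom import PhantomConfig
from .preprocessing import AugmentationParams
from .training import TrainConfig


@dataclass(frozen=True)
class RunConfig:
    n_cases: int = 100
    prevalence: float = 0.2
    expansion: int | str = "auto"
    tta_k: int = 5
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    augmentation: AugmentationParams = field(default_factory=AugmentationParams)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)


_SUBCONFIGS = {"phantom": PhantomConfig, "augmentation": AugmentationParams,
               "network": NetworkConfig, "train": TrainConfig}
_TUPLE_FIELDS = {"adam_betas", "skull_center", "skull_axes", "cc_center",
                 "cc_axes", "cavum_axes"}


def config_to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_from_dict(data: dict) -> RunConfig:
    kwargs = dict(data)
    for key, cls in _SUBCONFIGS.items():
        if key in kwargs and isinstance(kwargs[key], dict):
            sub = {k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list)
                   else v for k, v in kwargs[key].items()}
            kwargs[key] = cls(**sub)
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """YAML config (JSON is a YAML subset, so .json files load too)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return config_from_dict(data)


def save_config(cfg: RunConfig, path: str | Path):
    path = Path(path)
    data = config_to_dict(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
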