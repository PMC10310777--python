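"""Structured run configuration.

A single YAML file with nested sections drives multi-stage runs; every
stochastic component carries its own seed so stages are independently
reproducible.  CLI flags override file values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .feature_eval import ClassifierHeadSpec, TrainSchedule
from .gan import DiscriminatorSpec, GeneratorSpec, LossWeights
from .phantom import PhantomConfig
from .training import TrainConfig

__all__ = ["RunConfig", "load_config", "save_config"]


def _from_mapping(cls, mapping: dict[str, Any] | None):
    mapping = mapping or {}
    names = {f.name for f in fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = dict(mapping)
    for f in fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


@dataclass
class RunConfig:
    """Nested configuration for the end-to-end pipeline."""

    phantom: PhantomConfig = field(
        default_factory=lambda: PhantomConfig(grid_shape=(48, 48, 48), noise_sd_hu=10.0)
    )
    generator: GeneratorSpec = field(default_factory=GeneratorSpec.tiny)
    discriminator: DiscriminatorSpec = field(default_factory=DiscriminatorSpec.tiny)
    loss_weights: LossWeights = field(default_factory=LossWeights)
    training: TrainConfig = field(
        default_factory=lambda: TrainConfig(patch_size=32, n_iterations=150)
    )
    head: ClassifierHeadSpec = field(default_factory=ClassifierHeadSpec)
    # desk-scale head schedule; TrainSchedule() carries the full-scale preset
    head_schedule: TrainSchedule = field(
        default_factory=lambda: TrainSchedule(
            epochs=80, learning_rate=1e-3, batch_size=16, n_validation=16
        )
    )
    n_contrast: int = 4
    n_noncontrast: int = 4
    patch_size: int = 32
    stride: int = 16
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data or {})
        sections = {
            "phantom": PhantomConfig,
            "generator": GeneratorSpec,
            "discriminator": DiscriminatorSpec,
            "loss_weights": LossWeights,
            "training": TrainConfig,
            "head": ClassifierHeadSpec,
            "head_schedule": TrainSchedule,
        }
        kwargs: dict[str, Any] = {}
        for name, section_cls in sections.items():
            if name in data:
                kwargs[name] = _from_mapping(section_cls, data.pop(name))
        kwargs.update(data)
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
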