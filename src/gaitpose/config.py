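"""YAML pipeline configuration with strict key checking."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError
from .gait_events import EventConfig
from .preprocess import PreprocessConfig
from .simulate import CameraModel, DegradationModel


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    routing_override: dict[str, str] = field(default_factory=dict)
    exact_max_n: int = 12


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline, grouped by stage.

    Unknown keys anywhere in the document are rejected so that a typo in a
    config file cannot silently fall back to a default.
    """

    camera: CameraModel = field(default_factory=CameraModel)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    events: EventConfig = field(default_factory=EventConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    degradation: DegradationModel = field(default_factory=DegradationModel)
    pixels_per_meter: float | None = None  # overrides camera scale for real data
    seed: int = 0


_BLOCKS = {
    "camera": CameraModel,
    "preprocess": PreprocessConfig,
    "events": EventConfig,
    "stats": StatsConfig,
    "degradation": DegradationModel,
}


def _build(cls, data: dict[str, Any], context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in {context}: {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            if f.name == "resolution" and isinstance(v, list):
                v = tuple(v)
            coerced[f.name] = v
    return cls(**coerced)


def config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    data = dict(data or {})
    top_names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_names
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, cls in _BLOCKS.items():
        if name in data:
            block = data[name]
            if not isinstance(block, dict):
                raise ConfigError(f"config block {name!r} must be a mapping")
            kwargs[name] = _build(cls, block, name)
    for scalar in ("pixels_per_meter", "seed"):
        if scalar in data:
            kwargs[scalar] = data[scalar]
    return PipelineConfig(**kwargs)


def config_to_dict(cfg: PipelineConfig) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for name, _ in _BLOCKS.items():
        block = dataclasses.asdict(getattr(cfg, name))
        if name == "camera":
            block["resolution"] = list(block["resolution"])
        out[name] = block
    out["pixels_per_meter"] = cfg.pixels_per_meter
    out["seed"] = cfg.seed
    return out


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    doc = yaml.safe_load(Path(path).read_text())
    return config_from_dict(doc or {})


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
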