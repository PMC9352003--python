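"""Pipeline configuration with strict YAML round-tripping."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidParameterError
from .vision import VisionConfig

__all__ = ["ChemometricsConfig", "PipelineConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class ChemometricsConfig:
    method: str = "cars-pls"  # pls | spa-pls | cars-pls
    keep_every: int = 3
    apply_msc: bool = True
    apply_snv: bool = True
    split_ratio: tuple[int, int] = (3, 1)
    max_components: int = 15
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("pls", "spa-pls", "cars-pls"):
            raise InvalidParameterError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class PipelineConfig:
    vision: VisionConfig = field(default_factory=VisionConfig)
    chemometrics: ChemometricsConfig = field(default_factory=ChemometricsConfig)


def _from_mapping(cls, data: dict):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise InvalidParameterError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = names[key].type
        if isinstance(value, dict):
            sub = {"vision": VisionConfig, "chemometrics": ChemometricsConfig}.get(key)
            value = _from_mapping(sub, value) if sub else value
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _from_mapping(PipelineConfig, data)


def dump_config(config: PipelineConfig, path=None) -> str:
    def _plain(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: _plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return [_plain(v) for v in obj]
        return obj

    text = yaml.safe_dump(_plain(config), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
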