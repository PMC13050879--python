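"""Layered run configuration: built-in defaults < YAML file < overrides.

A run config has nested sections (data, preprocess, augment, model, sat,
train, simulate) plus a global seed and output directory.  Unknown keys are
rejected by name.  The global seed fans out to per-stage seeds by hashing
the stage name, so stages are individually reproducible without coupling.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .augmentation import AugmentConfig
from .model import ModelConfig
from .preprocessing import PreprocConfig
from .sat import SATConfig
from .synthetic import SyntheticSpec
from .training import TrainProtocol


class ConfigError(ValueError):
    pass


@dataclass
class DataSection:
    bundle: str | None = None
    channel_subset: str | None = None


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs"
    data: DataSection = field(default_factory=DataSection)
    preprocess: PreprocConfig = field(default_factory=PreprocConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainProtocol = field(default_factory=TrainProtocol)
    simulate: SyntheticSpec = field(default_factory=SyntheticSpec)

    @property
    def sat(self) -> SATConfig:
        return self.model.sat

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the global seed and the stage name."""
        return (self.seed * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2**31)

    def to_dict(self) -> dict:
        def convert(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: convert(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, (tuple, list)):
                return [convert(v) for v in obj]
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            return obj

        return convert(self)

    def snapshot(self, path: Path) -> None:
        path.write_text(json.dumps(self.to_dict(), indent=2, default=str))


_TUPLE_FIELDS = {"temporal_kernels", "pae_kernels", "rhythm_freqs",
                 "erd_channels"}


def _apply(obj: Any, key: str, value: Any, path: str) -> None:
    if not dataclasses.is_dataclass(obj):
        raise ConfigError(f"cannot set {path}: not a config section")
    names = {f.name for f in dataclasses.fields(obj)}
    if key not in names:
        raise ConfigError(f"unknown config key {path!r}")
    current = getattr(obj, key)
    if dataclasses.is_dataclass(current) and isinstance(value, dict):
        for sub_key, sub_value in value.items():
            _apply(current, sub_key, sub_value, f"{path}.{sub_key}")
        return
    if dataclasses.is_dataclass(current):
        raise ConfigError(f"{path} is a section; set its fields instead")
    if key in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
        value = tuple(tuple(v) if isinstance(v, (list, tuple)) else v
                      for v in value)
    if current is not None and not isinstance(current, bool) \
            and isinstance(current, (int, float)) and isinstance(value, str):
        raise ConfigError(f"type mismatch for {path!r}: expected number")
    setattr(obj, key, value)


def _parse_override(text: str) -> tuple[list[str], Any]:
    if "=" not in text:
        raise ConfigError(f"override {text!r} must look like key=value")
    key, raw = text.split("=", 1)
    try:
        value = yaml.safe_load(raw)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse override value {raw!r}") from exc
    return key.strip().split("."), value


def resolve_config(
    file: str | Path | None = None,
    overrides: list[str] | None = None,
    base: RunConfig | None = None,
) -> RunConfig:
    """Merge defaults, an optional YAML file, and key=value overrides.

    Precedence: built-in defaults < file < overrides.  ``sat.*`` keys are
    routed to the model's attention section.  Every unknown key raises a
    :class:`ConfigError` naming the key; the merged config is validated.
    """
    cfg = copy.deepcopy(base) if base is not None else RunConfig()
    if file is not None:
        try:
            loaded = yaml.safe_load(Path(file).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config file {file}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        for key, value in loaded.items():
            _route(cfg, [key], value)
    for text in overrides or []:
        keys, value = _parse_override(text)
        _route(cfg, keys, value)
    _validate(cfg)
    return cfg


def _route(cfg: RunConfig, keys: list[str], value: Any) -> None:
    if keys[0] == "sat":
        target: Any = cfg.model.sat
        keys = keys[1:]
        if not keys:
            if not isinstance(value, dict):
                raise ConfigError("sat section must be a mapping")
            for k, v in value.items():
                _apply(target, k, v, f"sat.{k}")
            return
    else:
        target = cfg
    path = ".".join(["sat"] * (target is cfg.model.sat) + keys) or keys[0]
    obj = target
    for key in keys[:-1]:
        if not dataclasses.is_dataclass(obj) or key not in {
                f.name for f in dataclasses.fields(obj)}:
            raise ConfigError(f"unknown config key {path!r}")
        obj = getattr(obj, key)
    _apply(obj, keys[-1], value, path)


def _validate(cfg: RunConfig) -> None:
    try:
        cfg.model.validate()
        cfg.train.validate()
        cfg.simulate.validate()
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
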