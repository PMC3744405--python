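"""Experiment configuration: schema, defaults, YAML/JSON round-tripping.

A configuration bundles every tunable of the search model.  Unknown keys
are rejected with the offending field path, defaults are filled in and the
set of defaulted fields is recorded so result sidecars can state exactly
which masked parameters were left at package defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

SCHEMA_VERSION = 1


@dataclass
class EnvironmentConfig:
    mean_count: float = 600.0  # expected prey per field
    dimension: int = 2
    clustered: bool = False
    seed_fraction: float = 0.1  # fraction of prey acting as cluster seeds
    local_density_factor: float = 100.0  # cluster density / global density


@dataclass
class ScentConfig:
    emission_rate: float = 100.0  # patches per second at the source
    decay_length: float = 2.5  # bl
    patch_radius: float = 1.0  # bl
    scan_duration: float = 1.0  # s
    olfaction_radius: float = 500.0  # bl


@dataclass
class KernelConfig:
    min_move: float = 1.0  # bl
    tail_exponent: float = 1.0  # mu; superdiffusive default


@dataclass
class SearcherConfigBlock:
    speed: float = 1.0  # bl per second
    encounter_radius: float = 1.0  # bl
    k_max: int = 1
    max_scans: int = 10_000_000


@dataclass
class SweepConfig:
    densities: list = field(default_factory=lambda: [0.5, 1.0, 2.0, 5.0, 10.0, 20.0])
    replicates: int = 300
    k: int = 1


@dataclass
class ExperimentConfig:
    strategy: str = "scent_modulated"
    seed: int = 0
    environment: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    scent: ScentConfig = field(default_factory=ScentConfig)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    searcher: SearcherConfigBlock = field(default_factory=SearcherConfigBlock)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    schema_version: int = SCHEMA_VERSION
    defaulted_fields: list = field(default_factory=list, compare=False)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("defaulted_fields")
        return d

    def save(self, path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)


_BLOCKS = {
    "environment": EnvironmentConfig,
    "scent": ScentConfig,
    "kernel": KernelConfig,
    "searcher": SearcherConfigBlock,
    "sweep": SweepConfig,
}
_SCALARS = {"strategy", "seed", "schema_version"}


class ConfigError(ValueError):
    """Schema violation, annotated with the offending field path."""


def config_from_dict(raw: dict) -> ExperimentConfig:
    """Build a validated config; unknown keys raise, defaults are recorded."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    cfg = ExperimentConfig()
    defaulted: list[str] = []
    for key in raw:
        if key not in _BLOCKS and key not in _SCALARS:
            raise ConfigError(f"unknown configuration key: {key!r}")
    for key in _SCALARS:
        if key in raw:
            setattr(cfg, key, raw[key])
        else:
            defaulted.append(key)
    for name, cls in _BLOCKS.items():
        block_raw = raw.get(name, {})
        if not isinstance(block_raw, dict):
            raise ConfigError(f"{name} must be a mapping")
        fields = {f.name for f in dataclasses.fields(cls)}
        for k in block_raw:
            if k not in fields:
                raise ConfigError(f"unknown configuration key: {name}.{k!r}")
        block = cls(**block_raw)
        setattr(cfg, name, block)
        defaulted.extend(f"{name}.{f}" for f in fields - set(block_raw))
    if cfg.strategy not in ("perfect", "uniform", "scent_modulated"):
        raise ConfigError(f"strategy must be perfect|uniform|scent_modulated, got {cfg.strategy!r}")
    cfg.defaulted_fields = sorted(defaulted)
    return cfg


def load_config(path) -> ExperimentConfig:
    """Read a YAML or JSON configuration file and validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    return config_from_dict(raw)
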