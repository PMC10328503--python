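"""Declarative run configuration (YAML) for the end-to-end pipeline.

One file holds every stage's parameters with defaults equal to the
study-mimicking values; a loaded config dumps back to an identical
structure (load → dump → load is the identity), which the pipeline relies
on for reproducible, self-describing runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .cluster import ClusterParams
from .process import ProcessingParams
from .stats import StatsParams
from .template import DEFAULT_PATTERN

CONFIG_SCHEMA_VERSION = 1


@dataclass
class SimulateSection:
    """Generative-stage settings for a pipeline run (desk-scale defaults)."""

    enabled: bool = True
    template: str = DEFAULT_PATTERN
    n_library_molecules: int = 200_000
    pcr_cycles: int = 10
    pcr_efficiency_a: float = 8.0
    pcr_efficiency_b: float = 2.0
    n_founders: int = 200
    copy_lambda: float = 3.0
    jackpot_prob: float = 0.05
    jackpot_factor_log_sd: float = 1.0
    n_integrants: int = 50_000
    depth: int = 20_000
    error_rate: float = 0.001
    duplicate_rate: float = 0.5
    read_length: int = 87
    quality_mean: float = 36.0
    quality_sd: float = 3.0
    quality_low_tail_prob: float = 0.0


@dataclass
class RunConfig:
    """Full pipeline configuration: paths, seed and per-stage sections."""

    out_dir: str = "results/run"
    fastq: str | None = None  # external input when simulate.enabled is false
    seed: int = 0
    log_level: str = "INFO"
    schema_version: int = CONFIG_SCHEMA_VERSION
    simulate: SimulateSection = field(default_factory=SimulateSection)
    process: ProcessingParams = field(default_factory=ProcessingParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    stats: StatsParams = field(default_factory=StatsParams)

    def to_dict(self) -> dict:
        return asdict(self)


def _section(cls, data: dict | None):
    data = data or {}
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(data)
    # YAML has no tuple type; restore tuple-valued fields
    for f in fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data)
    sections = {
        "simulate": _section(SimulateSection, data.pop("simulate", None)),
        "process": _section(ProcessingParams, data.pop("process", None)),
        "cluster": _section(ClusterParams, data.pop("cluster", None)),
        "stats": _section(StatsParams, data.pop("stats", None)),
    }
    top = {f.name for f in fields(RunConfig)} - set(sections)
    unknown = set(data) - top
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data, **sections)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
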