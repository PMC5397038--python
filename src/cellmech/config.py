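"""Run configuration: a single YAML file validated into typed sections.

Unknown keys are rejected so typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Optional

import yaml

from .mechanics import Probe
from .methylation import RegionSpec
from .pipeline import FitConfig

__all__ = ["StatsConfig", "MethylConfig", "RunConfig", "load_config", "config_to_dict"]


@dataclass(frozen=True)
class StatsConfig:
    bin_rule: str | int = "fd"
    trim_sigmas: float = 2.0
    equal_var: bool = True
    alpha: float = 0.05


@dataclass(frozen=True)
class MethylConfig:
    detection_p_max: float = 0.01
    max_fail_fraction: float = 0.30
    beta_threshold: float = 0.3
    min_probes: int = 1
    linkage_method: str = "complete"
    linkage_metric: str = "euclidean"
    min_conversion: float = 0.95


@dataclass(frozen=True)
class RunConfig:
    probe: Probe
    fit: FitConfig = field(default_factory=FitConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    methyl: MethylConfig = field(default_factory=MethylConfig)
    regions: tuple[RegionSpec, ...] = ()
    output_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def region(self, name: str) -> RegionSpec:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(f"no region named {name!r} in configuration")


def _build(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Expected top-level sections: ``probe`` (required), ``fit``, ``stats``,
    ``methyl``, ``regions`` (list of region mappings, each either explicit
    start/end or a TSS window with ``upstream``/``downstream`` offsets), and
    scalars ``output_dir``, ``seed``, ``log_level``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    top_known = {"probe", "fit", "stats", "methyl", "regions",
                 "output_dir", "seed", "log_level"}
    unknown = set(raw) - top_known
    if unknown:
        raise ValueError(f"{path}: unknown top-level key(s): {sorted(unknown)}")
    if "probe" not in raw:
        raise ValueError(f"{path}: a 'probe' section (with half_angle) is required")

    probe = _build(Probe, dict(raw["probe"]), "probe")
    fit = _build(FitConfig, dict(raw.get("fit", {})), "fit")
    stats = _build(StatsConfig, dict(raw.get("stats", {})), "stats")
    methyl = _build(MethylConfig, dict(raw.get("methyl", {})), "methyl")

    regions = []
    for rd in raw.get("regions", []) or []:
        rd = dict(rd)
        if "tss" in rd and "start" not in rd:
            regions.append(RegionSpec.promoter_window(
                name=rd.pop("name"), chromosome=rd.pop("chromosome"),
                tss=rd.pop("tss"), strand=rd.pop("strand", "+"),
                upstream=rd.pop("upstream", -37), downstream=rd.pop("downstream", 333),
                build=rd.pop("build", "hg19"),
            ))
            if rd:
                raise ValueError(f"unknown key(s) in region: {sorted(rd)}")
        else:
            regions.append(_build(RegionSpec, rd, f"region {rd.get('name')!r}"))

    return RunConfig(
        probe=probe, fit=fit, stats=stats, methyl=methyl,
        regions=tuple(regions),
        output_dir=str(raw.get("output_dir", "results")),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def config_to_dict(cfg: RunConfig) -> dict:
    """Full effective configuration, for report provenance."""
    d = dataclasses.asdict(cfg)
    return d
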