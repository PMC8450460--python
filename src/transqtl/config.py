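"""YAML configuration schema shared by the CLI subcommands.

One flat document with optional sections; unknown keys are rejected by
name.  An empty file resolves to all defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .evaluation import GridConfig
from .genotypes import SimPopConfig
from .models import GBMConfig, RFConfig
from .weighting import WeightingConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Validated configuration for all pipeline stages."""

    genotypes: SimPopConfig = field(default_factory=SimPopConfig)
    weighting: WeightingConfig = field(default_factory=WeightingConfig)
    rf: RFConfig = field(default_factory=RFConfig)
    gbm: GBMConfig = field(default_factory=GBMConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    effect_size: float = 0.4
    suppression_factor: float = 1.0

    def validate(self) -> None:
        self.genotypes.validate()
        self.weighting.validate()
        self.rf.validate()
        self.gbm.validate()
        self.grid.validate()
        if not (0.0 < self.effect_size <= 1.0):
            raise ValueError("effect_size must be in (0, 1]")
        if not (0.0 <= self.suppression_factor <= 1.0):
            raise ValueError("suppression_factor must be in [0, 1]")


def _build_section(cls, raw: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) in section '{section}': {sorted(unknown)} "
            f"(known: {sorted(known)})"
        )
    coerced = {}
    for f in fields(cls):
        if f.name in raw:
            v = raw[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


_SECTIONS = {
    "genotypes": SimPopConfig,
    "weighting": WeightingConfig,
    "rf": RFConfig,
    "gbm": GBMConfig,
    "grid": GridConfig,
}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; empty file means all defaults."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    top_known = set(_SECTIONS) | {"effect_size", "suppression_factor"}
    unknown = set(raw) - top_known
    if unknown:
        raise ValueError(f"{path}: unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {})
        if not isinstance(section, dict):
            raise ValueError(f"{path}: section '{name}' must be a mapping")
        if name == "grid":
            # the grid's nested panel section reuses the genotypes schema
            panel_raw = section.pop("panel", None)
            grid = _build_section(GridConfig, section, name)
            if panel_raw is not None:
                grid.panel = _build_section(SimPopConfig, panel_raw, "grid.panel")
            kwargs[name] = grid
        else:
            kwargs[name] = _build_section(cls, section, name)
    cfg = RunConfig(
        effect_size=raw.get("effect_size", 0.4),
        suppression_factor=raw.get("suppression_factor", 1.0),
        **kwargs,
    )
    cfg.validate()
    return cfg
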