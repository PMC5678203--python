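"""Run configuration: validated schema, file parsing, flag overrides.

Configurations are plain YAML/JSON mappings validated against pydantic
models (unknown keys are rejected, naming the offender).  Defaults are the
reference parameter set: D = 3, mu = 0.05, k = s = 1, patch time T = 12.5.
The JSON schema is available as ``RunConfig.model_json_schema()`` and is
shipped in the repo (docs/config_schema.json).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .metapopulation import MetapopConfig
from .model import CellTypeParams, TradeParams


class ConfigError(ValueError):
    """Configuration file or flags violate the schema."""


class CellTypeModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    a_A: float = Field(gt=0)
    a_B: float = Field(gt=0)
    k: float = Field(default=1.0, gt=0)
    s_A: float = Field(default=1.0, ge=0)
    s_B: float = Field(default=1.0, ge=0)
    manipulator: bool = False

    def build(self) -> CellTypeParams:
        return CellTypeParams(**self.model_dump())


class TradeModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    type1: CellTypeModel = CellTypeModel(a_A=1.0, a_B=1.0)
    type2: CellTypeModel = CellTypeModel(a_A=0.67, a_B=1.49)
    D: float = Field(default=3.0, ge=0)
    mu: float = Field(default=0.05, gt=0)
    budget: float = Field(default=1.0, gt=0)

    def build(self) -> TradeParams:
        return TradeParams(type1=self.type1.build(), type2=self.type2.build(),
                           D=self.D, mu=self.mu, budget=self.budget)


class AxisModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: Literal["a_A2", "a_B2"]
    start: float = Field(gt=0)
    stop: float = Field(gt=0)
    count: int = Field(ge=2)


class MetapopModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    variants: list[CellTypeModel]
    D: float = Field(default=3.0, ge=0)
    mu: float = Field(default=0.05, gt=0)
    patch_growth_time: float = Field(default=12.5, gt=0)
    rounds_max: int = Field(default=500, ge=1)
    freq_tol: float = Field(default=1e-10, gt=0)
    pairing: Literal["expectation", "stochastic"] = "expectation"
    n_patches: int = Field(default=100_000, ge=1)
    seed: int | None = None
    initial_freqs: list[float] | None = None
    curve_points: int = Field(default=81, ge=11)

    def build(self) -> MetapopConfig:
        data = self.model_dump()
        data["variants"] = tuple(v.build() for v in self.variants)
        if data["initial_freqs"] is not None:
            data["initial_freqs"] = tuple(data["initial_freqs"])
        return MetapopConfig(**data)


class RunConfig(BaseModel):
    """Top-level run configuration shared by all CLI subcommands."""

    model_config = ConfigDict(extra="forbid")

    trade: TradeModel = TradeModel()
    metapop: MetapopModel | None = None
    axes: list[AxisModel] | None = None
    scan_points: int = Field(default=41, ge=5)
    seed: int = 0
    output: str = "results"
    log_level: str = "INFO"


def _deep_update(base: dict[str, Any], overrides: dict[str, Any]) -> dict[str, Any]:
    out = dict(base)
    for key, value in overrides.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], value)
        elif value is not None:
            out[key] = value
    return out


def parse_config(path: str | Path | None = None,
                 overrides: dict[str, Any] | None = None) -> RunConfig:
    """Load a YAML/JSON config file and apply flag overrides (flags win)."""
    data: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        data = loaded
    try:
        resolved = RunConfig.model_validate(data)
        if overrides:
            # flags override individual keys of the resolved configuration
            merged = _deep_update(resolved.model_dump(), overrides)
            resolved = RunConfig.model_validate(merged)
        return resolved
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigError(f"invalid configuration at '{loc}': {first['msg']}") from exc


def dump_schema(path: str | Path) -> None:
    """Write the published JSON schema of :class:`RunConfig`."""
    with open(path, "w") as fh:
        json.dump(RunConfig.model_json_schema(), fh, indent=2, sort_keys=True)
        fh.write("\n")
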