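"""Pipeline configuration: a validated YAML-compatible key-value tree."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PipelineConfig", "SimulationBlock", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class SimulationBlock:
    """Parameters for generating the two samples instead of reading files."""

    model: str                       # additive | conjunctive | twopl
    seed: int | None = None
    n_persons_fit: int = 600
    n_persons_cv: int = 600
    n_items: int = 18
    max_weight: int = 2
    eta: list[float] | None = None           # additive world
    c: float = 0.0
    curve_difficulty: list[float] | None = None   # conjunctive world
    curve_discrimination: list[float] | None = None
    a: list[float] | None = None              # twopl world
    b: list[float] | None = None

    def validate(self) -> None:
        if self.model not in ("additive", "conjunctive", "twopl"):
            raise ConfigError(f"unknown simulation model {self.model!r}")
        if self.seed is None:
            raise ConfigError("simulation block requires an integer seed")
        if self.n_persons_fit < 2 or self.n_persons_cv < 2:
            raise ConfigError("each simulated sample needs at least 2 persons")


@dataclass
class PipelineConfig:
    output_dir: str = "cdm_output"
    responses_fit: str | None = None
    responses_cv: str | None = None
    qmatrix: str | None = None
    grid_min: float = -4.0
    grid_max: float = 4.0
    grid_count: int = 61
    quad_nodes: int = 21
    item_fit_alpha: float = 0.05
    item_fit_min_group: int = 30
    screen_items: bool = True
    lsdm_constrained: bool = True
    prob_eps: float = 1e-6
    listwise_deletion: bool = False
    simulation: SimulationBlock | None = None

    def validate(self) -> None:
        if self.grid_count < 11:
            raise ConfigError("grid_count must be >= 11")
        if not self.grid_min < self.grid_max:
            raise ConfigError("grid_min must be < grid_max")
        if not 0 < self.item_fit_alpha < 1:
            raise ConfigError("item_fit_alpha must be in (0, 1)")
        if self.quad_nodes < 5:
            raise ConfigError("quad_nodes must be >= 5")
        if self.simulation is not None:
            self.simulation.validate()
        else:
            missing = [n for n in ("responses_fit", "responses_cv", "qmatrix")
                       if getattr(self, n) is None]
            if missing:
                raise ConfigError(
                    f"config needs either a simulation block or file paths; missing {missing}")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulation", None)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if sim is not None:
            sim_known = set(SimulationBlock.__dataclass_fields__)
            sim_unknown = set(sim) - sim_known
            if sim_unknown:
                raise ConfigError(f"unknown simulation keys: {sorted(sim_unknown)}")
            cfg.simulation = SimulationBlock(**sim)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        out = {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "simulation"}
        if self.simulation is not None:
            out["simulation"] = dict(vars(self.simulation))
        return out


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return PipelineConfig.from_dict(data)
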