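"""Experiment configuration: schema, validation, (de)serialisation.

A configuration is a single YAML document with flat top-level experiment
keys plus optional nested parameter blocks mirroring the parameter
dataclasses (``signal``, ``cycle``, ``mechanics``, ``dish``,
``scenario``).  Unknown keys anywhere are rejected so typos fail loudly;
all numeric constraints are enforced by the dataclasses themselves.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import Dish
from .dynamics import CycleParams
from .engine import Mechanism, Scenario, ScenarioKind, SimulationParams
from .mechanics import MechanicsParams
from .signaling import SignalParams


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    """Full experiment grid: mechanisms × target densities × replicates.

    Each replicate runs with seed = base_seed + replicate index.
    n_iterations defaults to 480 (10 simulated days of 30-minute steps).
    """

    mechanisms: tuple[Mechanism, ...] = (
        Mechanism.REPELLENT_R, Mechanism.ATTRACTANT_A_BINARY,
        Mechanism.ATTRACTANT_A_CONTINUOUS)
    target_densities: tuple[float, ...] = (0.05, 0.10, 0.25, 0.40)
    replicates: int = 12
    n_iterations: int = 480
    base_seed: int = 0
    output_dir: str = "results"
    window: int = 48
    initial_cell_count: int = 150
    dish: Dish = field(default_factory=Dish)
    signal: SignalParams = field(default_factory=SignalParams)
    cycle: CycleParams = field(default_factory=CycleParams)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    neighbor_count_inclusive: bool = False
    use_calibrated_thresholds: bool = True

    def __post_init__(self) -> None:
        self.mechanisms = tuple(Mechanism(m) for m in self.mechanisms)
        self.target_densities = tuple(float(d) for d in self.target_densities)
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if any(not (0.0 < d < 1.0) for d in self.target_densities):
            raise ConfigError("target densities must be in (0, 1)")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        if self.window < 1 or self.window > self.n_iterations:
            raise ConfigError("window must be in [1, n_iterations]")

    def simulation_params(self) -> SimulationParams:
        return SimulationParams(
            dish=self.dish, signal=self.signal, cycle=self.cycle,
            mechanics=self.mechanics,
            neighbor_count_inclusive=self.neighbor_count_inclusive)


_BLOCKS = {"dish": Dish, "signal": SignalParams, "cycle": CycleParams,
           "mechanics": MechanicsParams}


def _build(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid {context}: {exc}") from exc


def config_from_dict(data: dict) -> ExperimentConfig:
    data = dict(data or {})
    kwargs = {}
    for key, cls in _BLOCKS.items():
        if key in data:
            kwargs[key] = _build(cls, data.pop(key), key)
    top_names = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(data) - top_names
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs.update(data)
    try:
        return ExperimentConfig(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate a YAML experiment configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a YAML mapping")
    return config_from_dict(data)


def config_to_dict(cfg: ExperimentConfig) -> dict:
    out = dataclasses.asdict(cfg)
    out["mechanisms"] = [m.value for m in cfg.mechanisms]
    out["target_densities"] = list(cfg.target_densities)
    return out


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg),
                                         sort_keys=True))
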