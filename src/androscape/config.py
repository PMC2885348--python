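"""YAML scenario configuration: validation, defaults, canonical hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .evolution import EvolutionParams
from .growth import GrowthParams
from .kinetics import InfluxParams, KineticParams

__all__ = ["ScenarioConfig", "SweepSpec", "parse_config", "config_hash"]


@dataclass(frozen=True)
class SweepSpec:
    """Value lists the scenario commands iterate over."""

    T_S: tuple[float, ...] = (1.0, 5.0, 10.0)       # serum testosterone (nM)
    R_t: tuple[float, ...] = (25.0, 35.0, 45.0, 60.0)  # AR set points (nM)
    eta: tuple[float, ...] = (1.0,)                  # effective-K_M multipliers
    T_S_grid: tuple[float, ...] = tuple(float(x) for x in range(1, 11))

    def __post_init__(self):
        for name in ("T_S", "R_t", "eta", "T_S_grid"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ConfigError("sweep list must be non-empty", key=f"sweep.{name}")
            if any(v < 0 for v in vals):
                raise ConfigError("sweep values must be >= 0", key=f"sweep.{name}")
        if any(e < 1 for e in self.eta):
            raise ConfigError("eta values must be >= 1", key="sweep.eta")


@dataclass(frozen=True)
class ScenarioConfig:
    """Fully validated run configuration with all defaults filled."""

    kinetics: KineticParams = field(default_factory=KineticParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    evolution: EvolutionParams = field(default_factory=EvolutionParams)
    grid_Q: int = 100
    grid_Rt_min: float = 15.0
    grid_step: float = 1.0
    sweep: SweepSpec = field(default_factory=SweepSpec)
    noise_cv: float = 0.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer", key="seed")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0", key="noise_cv")


def _build(cls, data: dict, path: str):
    """Construct a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping, got {type(data).__name__}", key=path)
    data = dict(data)
    eta = None
    if cls is KineticParams and "eta" in data:
        # convenience: eta >= 1 maps to the inhibitor level I = (eta-1)*K_I
        eta = data.pop("eta")
        if not isinstance(eta, (int, float)) or eta < 1:
            raise ConfigError("eta must be a number >= 1", key=f"{path}.eta")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys {sorted(unknown)}", key=path)
    kwargs = {}
    for key, value in data.items():
        sub = f"{path}.{key}" if path else key
        if cls is KineticParams and key == "influx":
            value = _build(InfluxParams, _listify(value), sub)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        obj = cls(**kwargs)
        if eta is not None:
            from .kinetics import with_eta

            obj = with_eta(obj, float(eta))
        return obj
    except ConfigError:
        raise
    except Exception as exc:
        raise ConfigError(str(exc), key=path or cls.__name__) from exc


def _listify(value):
    if isinstance(value, dict) and isinstance(value.get("table"), list):
        value = dict(value, table=tuple(tuple(row) for row in value["table"]))
    return value


def parse_config(path: str | Path | None) -> ScenarioConfig:
    """Load and validate a YAML config; missing sections get defaults.

    An absent path or empty file yields the all-defaults configuration.
    Unknown keys and out-of-range values raise ConfigError naming the key.
    """
    raw: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError("config file not found", key=str(p))
        try:
            raw = yaml.safe_load(p.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML: {exc}", key=str(p)) from exc
    if not isinstance(raw, dict):
        raise ConfigError("top level must be a mapping", key=str(path))

    known = {"kinetics", "growth", "evolution", "grid", "sweep",
             "noise_cv", "seed", "log_level"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown sections {sorted(unknown)}", key="<root>")

    grid = raw.get("grid", {})
    if not isinstance(grid, dict):
        raise ConfigError("grid section must be a mapping", key="grid")
    grid_unknown = set(grid) - {"Q", "Rt_min", "step"}
    if grid_unknown:
        raise ConfigError(f"unknown keys {sorted(grid_unknown)}", key="grid")

    return ScenarioConfig(
        kinetics=_build(KineticParams, raw.get("kinetics", {}), "kinetics"),
        growth=_build(GrowthParams, raw.get("growth", {}), "growth"),
        evolution=_build(EvolutionParams, raw.get("evolution", {}), "evolution"),
        grid_Q=int(grid.get("Q", 100)),
        grid_Rt_min=float(grid.get("Rt_min", 15.0)),
        grid_step=float(grid.get("step", 1.0)),
        sweep=_build(SweepSpec, raw.get("sweep", {}), "sweep"),
        noise_cv=float(raw.get("noise_cv", 0.0)),
        seed=raw.get("seed", 0),
        log_level=str(raw.get("log_level", "INFO")),
    )


def config_hash(cfg: ScenarioConfig) -> str:
    """Stable hash of the full parameter set, for run manifests."""
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
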