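"""TOML configuration for the analysis and simulation pipelines.

Unknown keys are rejected so that a typo (``alpha`` under the wrong
section, a misspelled field) fails loudly instead of silently running with
defaults.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .errors import ConfigError
from .synthetic import GroundTruth, PanelDesign


@dataclass(frozen=True)
class PathsConfig:
    titration: str = ""
    absorbance: str = ""
    out: str = "."


@dataclass(frozen=True)
class IOConfig:
    emission_nm: float | str = 340.0  # fixed wavelength or "peak"
    excitation_nm: float = 295.0
    protein_conc_M: float = 3e-6


@dataclass(frozen=True)
class IFEConfig:
    mode: str = "sidecar"  # sidecar | linear_model | off
    path_weight: float = 0.5
    ceiling: float = 2.0
    epsilon_ex: float = 0.0
    epsilon_em: float = 0.0
    baseline_ex: float = 0.0
    baseline_em: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("sidecar", "linear_model", "off"):
            raise ConfigError(f"ife.mode must be sidecar|linear_model|off, got {self.mode!r}")


@dataclass(frozen=True)
class QuenchingConfig:
    tau0_s: float = 5.9e-9
    min_segment: int = 3
    alpha: float = 0.05
    diffusion_limit: float = 1e10


@dataclass(frozen=True)
class BindingConfig:
    quench_floor: float = 1e-3


@dataclass(frozen=True)
class ThermoConfig:
    ki_temperature_K: float = 298.15


@dataclass(frozen=True)
class AnalysisConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    io: IOConfig = field(default_factory=IOConfig)
    ife: IFEConfig = field(default_factory=IFEConfig)
    quenching: QuenchingConfig = field(default_factory=QuenchingConfig)
    binding: BindingConfig = field(default_factory=BindingConfig)
    thermo: ThermoConfig = field(default_factory=ThermoConfig)
    log_level: str = "INFO"
    seed: int = 0


@dataclass(frozen=True)
class SimulationConfig:
    truth: GroundTruth = field(default_factory=GroundTruth)
    design: PanelDesign = field(default_factory=PanelDesign)


def _build(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section {context!r} must be a table")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown key(s) in {context!r}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        if dataclasses.is_dataclass(_resolve(cls, name)):
            value = _build(_resolve(cls, name), value, f"{context}.{name}")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"invalid {context!r} section: {exc}") from exc


def _resolve(cls, name):
    for f in fields(cls):
        if f.name == name:
            default = f.default_factory() if f.default_factory is not dataclasses.MISSING else f.default
            return type(default)
    return None


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    return _build(AnalysisConfig, _read_toml(path), "analysis config")


def load_simulation_config(path: str | Path) -> SimulationConfig:
    data = _read_toml(path)
    if "design" in data and "quencher_uM" in data["design"]:
        grid = data["design"].pop("quencher_uM")
        data["design"]["quencher_M"] = [q * 1e-6 for q in grid]
    return _build(SimulationConfig, data, "simulation config")


def _read_toml(path: str | Path) -> dict:
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    with open(p, "rb") as fh:
        try:
            return tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"malformed TOML in {p}: {exc}") from exc
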