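"""Binding thermodynamics: Van't Hoff regression and related conversions.

The temperature dependence of the binding constant follows
ln kb = -dH/(R T) + dS/R for a temperature-independent enthalpy: an
unweighted least-squares line of ln kb against 1/T yields
dH = -R * slope and dS = R * intercept.  Gibbs energies are then
bookkept as dG = dH - T dS (kJ/mol with dS in J mol^-1 K^-1).

The sign pattern of (dH, dS) reads out the dominant interaction forces:
both negative -> hydrogen bonding / Van der Waals; both positive ->
hydrophobic; mixed signs -> a mixture.

Docking free energies (kcal/mol) interconvert with inhibition constants via
Ki = exp(dG / (R_kcal T)) at 298.15 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DomainError

R_GAS = 8.314  # J mol^-1 K^-1
R_KCAL = 1.987e-3  # kcal mol^-1 K^-1
STANDARD_T_K = 298.15


@dataclass(frozen=True)
class ThermoResult:
    """Van't Hoff estimates with per-temperature Gibbs energies."""

    delta_H: float  # kJ/mol
    delta_S: float  # J mol^-1 K^-1
    delta_G_by_T: dict[float, float]  # K -> kJ/mol
    r_squared: float
    gas_constant: float = R_GAS


def gibbs(delta_H: float, delta_S: float, temperature: float) -> float:
    """dG = dH - T*dS, with dH in kJ/mol and dS in J mol^-1 K^-1."""
    if temperature <= 0:
        raise DomainError(f"temperature must be > 0 K, got {temperature}")
    return delta_H - temperature * delta_S / 1000.0


def entropy_from_enthalpy_gibbs(
    delta_H: float, delta_G: float, temperature: float
) -> float:
    """dS = (dH - dG) * 1000 / T in J mol^-1 K^-1 (inverse of :func:`gibbs`)."""
    if temperature <= 0:
        raise DomainError(f"temperature must be > 0 K, got {temperature}")
    return (delta_H - delta_G) * 1000.0 / temperature


def vant_hoff(kb_by_temperature: Mapping[float, float]) -> ThermoResult:
    """Unweighted Van't Hoff regression of ln kb on 1/T.

    Keys are absolute temperatures (K), values binding constants (L/mol).
    """
    temps = np.array(sorted(kb_by_temperature), dtype=float)
    if len(temps) < 2:
        raise DomainError("Van't Hoff regression needs >= 2 temperatures")
    if len(np.unique(temps)) != len(temps):
        raise DomainError("duplicate temperatures")
    kb = np.array([kb_by_temperature[t] for t in temps], dtype=float)
    if np.any(kb <= 0) or not np.all(np.isfinite(kb)):
        raise DomainError("binding constants must be finite and > 0")

    x = 1.0 / temps
    y = np.log(kb)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    sst = float(((y - ym) ** 2).sum())
    r2 = 1.0 if sst == 0.0 else 1.0 - float((resid**2).sum()) / sst

    delta_H = -R_GAS * slope / 1000.0  # kJ/mol
    delta_S = R_GAS * intercept  # J mol^-1 K^-1
    return ThermoResult(
        delta_H=delta_H,
        delta_S=delta_S,
        delta_G_by_T={float(t): gibbs(delta_H, delta_S, float(t)) for t in temps},
        r_squared=r2,
    )


def ki_from_binding_energy(delta_G: float, temperature: float = STANDARD_T_K) -> float:
    """Inhibition constant (mol/L) from a binding free energy in kcal/mol."""
    if temperature <= 0:
        raise DomainError(f"temperature must be > 0 K, got {temperature}")
    return math.exp(delta_G / (R_KCAL * temperature))


def binding_energy_from_ki(ki: float, temperature: float = STANDARD_T_K) -> float:
    """Binding free energy (kcal/mol) from an inhibition constant in mol/L."""
    if temperature <= 0:
        raise DomainError(f"temperature must be > 0 K, got {temperature}")
    if ki <= 0:
        raise DomainError(f"Ki must be > 0, got {ki}")
    return R_KCAL * temperature * math.log(ki)


@dataclass(frozen=True)
class DockingEnergy:
    """A docking binding free energy with its implied inhibition constant."""

    delta_G_binding: float  # kcal/mol
    temperature: float = STANDARD_T_K
    ki: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "ki", ki_from_binding_energy(self.delta_G_binding, self.temperature)
        )


def force_signature(delta_H: float, delta_S: float) -> str:
    """Dominant-force read-out from the signs of dH and dS."""
    if delta_H < 0 and delta_S < 0:
        return "hydrogen_bond_vdw"
    if delta_H > 0 and delta_S > 0:
        return "hydrophobic"
    return "mixed"
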