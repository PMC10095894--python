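"""Forward simulation of two-site quenching titration panels.

The generator emulates the serum-albumin/indomethacin study conditions: a
3 uM protein with a single intrinsic fluorophore titrated with 0-10 uM
ligand at 25/35/45 C, quenched statically through two binding sites of
unequal affinity, with the ligand's own absorbance imposing an inner filter
effect and multiplicative Gaussian noise on intensities.

Model
-----
Site association constants derive from fixed enthalpies and entropies,
K_i(T) = exp(-dH_i/(R T) + dS_i/R), so noiseless panels are exactly Van't
Hoff-consistent.  With both sites open, the single fluorophore's accessible
fraction is partitioned between the two quenching pathways:

    F = F0 * (1 - q1*theta1 - q2*theta2),   theta_i = K_i Q / (1 + K_i Q)

with quench efficiencies q1 + q2 <= 1; unequal efficiencies with saturating
occupancy produce the downward Stern-Volmer curvature of the study system.
When a site marker leaves exactly one site open, the remaining 1:1
association is modeled as a fully dark complex, F = F0 / (1 + K_app Q) --
an exactly linear Stern-Volmer response, which is what pre-blocked panels
show experimentally.  The apparent constants are K_app = marker_retention*K1
when only the primary site is open (marker-induced loss of apparent
affinity) and K_app = allosteric_factor*K2 when only the secondary site is
open (the primary-site marker allosterically enhances the secondary site).
With both sites blocked, a weak nonspecific residual site quenches
partially: F = F0 * (1 - 0.2*q1*theta(residual_K)).

By default isotherms are evaluated in total ligand concentration, as the
downstream analysis assumes; ``ligand_depletion="exact"`` instead solves the
mass balance for free ligand.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ValidationError
from .spectra_io import TitrationPoint
from .thermodynamics import R_GAS, STANDARD_T_K

# Calibrated site constants at 25 C: primary 5.9e5 L/mol, secondary 1.9e3
# L/mol, with enthalpies -47.4 and -11.6 kJ/mol; entropies follow from
# dS = R ln K + dH/T and land at -48.5 and +23.9 J mol^-1 K^-1.
DEFAULT_K1_25C = 5.9e5
DEFAULT_K2_25C = 1.9e3
DEFAULT_DH1_KJ = -47.4
DEFAULT_DH2_KJ = -11.6


def entropy_for_reference_k(
    k_ref: float, delta_H_kJ: float, t_ref: float = STANDARD_T_K
) -> float:
    """dS (J mol^-1 K^-1) such that K(t_ref) = k_ref given dH (kJ/mol)."""
    return R_GAS * math.log(k_ref) + delta_H_kJ * 1000.0 / t_ref


DEFAULT_DS1 = entropy_for_reference_k(DEFAULT_K1_25C, DEFAULT_DH1_KJ)
DEFAULT_DS2 = entropy_for_reference_k(DEFAULT_K2_25C, DEFAULT_DH2_KJ)

#: Fixed per-condition stream indices so adding a condition to a design
#: never perturbs the noise draws of the others.
CONDITION_STREAM = {
    "free": 0,
    "warfarin": 1,
    "ibuprofen": 2,
    "hemin": 3,
    "warfarin+hemin": 4,
    "custom": 5,
}

#: Which sites each marker condition occupies.
CONDITION_BLOCKS = {
    "free": (False, False),
    "warfarin": (True, False),  # drug site 1 marker
    "ibuprofen": (False, False),  # drug site 2 marker; neither modeled site
    "hemin": (False, True),  # FA1 marker (the secondary site)
    "warfarin+hemin": (True, True),
    "custom": (False, False),
}


@dataclass(frozen=True)
class GroundTruth:
    """Hidden parameters of a simulated titration panel.

    Defaults are the calibrated study conditions (see module docstring);
    they are what parameter-recovery tests measure against.
    """

    delta_H1: float = DEFAULT_DH1_KJ  # kJ/mol
    delta_S1: float = DEFAULT_DS1  # J mol^-1 K^-1
    delta_H2: float = DEFAULT_DH2_KJ
    delta_S2: float = DEFAULT_DS2
    q1: float = 0.90  # quench efficiency, primary site
    q2: float = 0.10  # quench efficiency, secondary site
    f0: float = 1000.0  # unquenched intensity, arbitrary units
    protein_conc: float = 3e-6  # mol/L
    epsilon_ex: float = 2.0e4  # ligand extinction at 295 nm, L mol^-1 cm^-1
    epsilon_em: float = 4.0e3  # ligand extinction at 340 nm
    baseline_ex: float = 0.05  # protein absorbance at 295 nm, AU
    noise_cv: float = 0.01  # relative sd of multiplicative intensity noise
    seed: int = 0
    blocks_site1: bool = False
    blocks_site2: bool = False
    allosteric_factor: float = 14.7  # on K2 when site 1 is marker-blocked
    marker_retention: float = 0.356  # on K1 when site 2 is marker-blocked
    residual_K: float = 6.0e4  # nonspecific constant when both blocked
    residual_efficiency_scale: float = 0.2  # times q1
    ligand_depletion: str = "off"  # off | exact

    def __post_init__(self) -> None:
        if not (0 <= self.q1 <= 1 and 0 <= self.q2 <= 1 and self.q1 + self.q2 <= 1):
            raise ValidationError("need q1, q2 in [0, 1] with q1 + q2 <= 1")
        if self.k1_at(STANDARD_T_K) <= self.k2_at(STANDARD_T_K):
            raise ValidationError("K1 must exceed K2 at the reference temperature")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.ligand_depletion not in ("off", "exact"):
            raise ValidationError("ligand_depletion must be 'off' or 'exact'")

    def k1_at(self, temperature_K: float) -> float:
        return k_from_thermo(self.delta_H1, self.delta_S1, temperature_K)

    def k2_at(self, temperature_K: float) -> float:
        return k_from_thermo(self.delta_H2, self.delta_S2, temperature_K)

    @property
    def K1(self) -> float:
        """Primary-site association constant at 298.15 K (L/mol)."""
        return self.k1_at(STANDARD_T_K)

    @property
    def K2(self) -> float:
        """Secondary-site association constant at 298.15 K (L/mol)."""
        return self.k2_at(STANDARD_T_K)


def k_from_thermo(delta_H_kJ: float, delta_S: float, temperature_K: float) -> float:
    """K(T) = exp(-dH/(R T) + dS/R)."""
    return math.exp(-delta_H_kJ * 1000.0 / (R_GAS * temperature_K) + delta_S / R_GAS)


def site_occupancy(K: float, Q_free: float) -> float:
    """One-site isotherm K*Q/(1 + K*Q), in [0, 1]."""
    if K < 0 or Q_free < 0:
        raise ValidationError("K and Q must be >= 0")
    kq = K * Q_free
    return kq / (1.0 + kq)


def free_ligand(K1: float, K2: float, P_total: float, Q_total: float) -> float:
    """Free ligand concentration from the two-site mass balance.

    Solves Q_total = Qf + P_total*(theta1(Qf) + theta2(Qf)); the left side
    minus the right is strictly monotone in Qf so the root on [0, Q_total]
    is unique.
    """
    if min(K1, K2, P_total, Q_total) < 0:
        raise ValidationError("all arguments must be >= 0")
    if Q_total == 0.0 or (K1 == 0.0 and K2 == 0.0) or P_total == 0.0:
        return Q_total

    def residual(qf: float) -> float:
        return (
            qf
            + P_total * (site_occupancy(K1, qf) + site_occupancy(K2, qf))
            - Q_total
        )

    if residual(Q_total) <= 0:  # numerically saturated; no binding possible
        return Q_total
    return float(brentq(residual, 0.0, Q_total, xtol=1e-30, rtol=8.9e-16))


def true_intensity(gt: GroundTruth, Q: float, temperature_K: float) -> float:
    """Noise-free emission intensity at total ligand concentration Q."""
    if Q < 0:
        raise ValidationError("Q must be >= 0")
    K1 = gt.k1_at(temperature_K)
    K2 = gt.k2_at(temperature_K)
    if gt.ligand_depletion == "exact":
        blocked_sites = gt.blocks_site1 + gt.blocks_site2
        if blocked_sites == 0:
            Q_eff = free_ligand(K1, K2, gt.protein_conc, Q)
        elif blocked_sites == 1:
            open_K = K2 * gt.allosteric_factor if gt.blocks_site1 else K1 * gt.marker_retention
            Q_eff = free_ligand(open_K, 0.0, gt.protein_conc, Q)
        else:
            Q_eff = free_ligand(gt.residual_K, 0.0, gt.protein_conc, Q)
    else:
        Q_eff = Q

    if gt.blocks_site1 and gt.blocks_site2:
        theta = site_occupancy(gt.residual_K, Q_eff)
        return gt.f0 * (1.0 - gt.residual_efficiency_scale * gt.q1 * theta)
    if gt.blocks_site1:  # only the secondary site open: dark 1:1 complex
        return gt.f0 / (1.0 + gt.allosteric_factor * K2 * Q_eff)
    if gt.blocks_site2:  # only the primary site open: dark 1:1 complex
        return gt.f0 / (1.0 + gt.marker_retention * K1 * Q_eff)
    theta1 = site_occupancy(K1, Q_eff)
    theta2 = site_occupancy(K2, Q_eff)
    return gt.f0 * (1.0 - gt.q1 * theta1 - gt.q2 * theta2)


def observe(gt: GroundTruth, f_true: float, Q: float, rng: np.random.Generator) -> TitrationPoint:
    """Apply IFE attenuation and multiplicative noise; attach absorbances."""
    a_ex = gt.epsilon_ex * Q + gt.baseline_ex
    a_em = gt.epsilon_em * Q
    f_obs = f_true * 10.0 ** (-(a_ex + a_em) / 2.0)
    if gt.noise_cv > 0:
        f_obs *= 1.0 + gt.noise_cv * rng.standard_normal()
    return TitrationPoint(
        quencher_total=Q,
        intensity=f_obs,
        absorbance_ex=a_ex,
        absorbance_em=a_em,
    )


@dataclass(frozen=True)
class PanelDesign:
    """The measurement grid: quencher concentrations, temperatures, conditions."""

    quencher_M: tuple[float, ...] = tuple(i * 1e-6 for i in range(11))
    temperatures_C: tuple[float, ...] = (25.0, 35.0, 45.0)
    conditions: tuple[str, ...] = (
        "free",
        "warfarin",
        "ibuprofen",
        "hemin",
        "warfarin+hemin",
    )

    def __post_init__(self) -> None:
        if any(c not in CONDITION_STREAM for c in self.conditions):
            unknown = [c for c in self.conditions if c not in CONDITION_STREAM]
            raise ValidationError(f"unknown condition label(s): {unknown}")
        q = np.asarray(self.quencher_M)
        if q[0] != 0 or np.any(np.diff(q) <= 0):
            raise ValidationError("quencher grid must start at 0 and strictly increase")


def _condition_truth(gt: GroundTruth, condition: str) -> GroundTruth:
    b1, b2 = CONDITION_BLOCKS[condition]
    return replace(gt, blocks_site1=b1, blocks_site2=b2)


def generate_panel(
    gt: GroundTruth, design: PanelDesign = PanelDesign()
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a full panel.

    Returns (titration table, absorbance sidecar table, ground-truth dict).
    Each condition draws noise from its own fixed substream of ``gt.seed``,
    so panels are reproducible and conditions independent.
    """
    tit_rows, abs_rows = [], []
    for condition in design.conditions:
        cgt = _condition_truth(gt, condition)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=gt.seed, spawn_key=(CONDITION_STREAM[condition],))
        )
        for temp_c in design.temperatures_C:
            t_k = temp_c + 273.15
            for Q in design.quencher_M:
                p = observe(cgt, true_intensity(cgt, Q, t_k), Q, rng)
                tit_rows.append(
                    dict(
                        condition=condition,
                        temperature_C=temp_c,
                        quencher_total_M=Q,
                        intensity=p.intensity,
                    )
                )
                abs_rows.append(
                    dict(
                        condition=condition,
                        temperature_C=temp_c,
                        quencher_total_M=Q,
                        absorbance_ex=p.absorbance_ex,
                        absorbance_em=p.absorbance_em,
                    )
                )
    truth = asdict(gt)
    truth["K1_25C"] = gt.K1
    truth["K2_25C"] = gt.K2
    truth["design"] = {
        "quencher_M": list(design.quencher_M),
        "temperatures_C": list(design.temperatures_C),
        "conditions": list(design.conditions),
    }
    return pd.DataFrame(tit_rows), pd.DataFrame(abs_rows), truth


def write_panel(
    gt: GroundTruth,
    design: PanelDesign = PanelDesign(),
    out_dir: str | Path = ".",
) -> dict[str, Path]:
    """Write titration.csv, absorbance.csv and ground_truth.json.

    Output is byte-deterministic for a given (config, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tit, absorb, truth = generate_panel(gt, design)
    paths = {
        "titration": out / "titration.csv",
        "absorbance": out / "absorbance.csv",
        "ground_truth": out / "ground_truth.json",
    }
    tit.to_csv(paths["titration"], index=False, float_format="%.17g")
    absorb.to_csv(paths["absorbance"], index=False, float_format="%.17g")
    paths["ground_truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths
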