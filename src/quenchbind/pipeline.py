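"""End-to-end orchestration: IFE correction, per-condition Stern-Volmer and
double-log fits, mechanism classification, Van't Hoff thermodynamics and the
site-marker competition report, assembled into a single JSON-ready document.
"""

from __future__ import annotations

import dataclasses
import io
import logging
import warnings
from dataclasses import replace
from pathlib import Path

import pandas as pd

from . import __version__
from .binding import BindingResult, analyze_binding
from .competitive import CompetitionReport, analyze_panel
from .config import AnalysisConfig, SimulationConfig
from .errors import ConfigError, QuenchbindError
from .ife import LinearAbsorbanceModel, correct_series
from .quenching import (
    QuenchingResult,
    classify_mechanism,
    fit_piecewise,
    quenching_constants,
    sv_ratios,
)
from .spectra_io import (
    TitrationSeries,
    attach_absorbances,
    read_absorbance_csv,
    read_titration_csv,
    write_report,
)
from .synthetic import generate_panel, write_panel
from .thermodynamics import force_signature, vant_hoff

log = logging.getLogger("quenchbind")


def series_from_frame(df: pd.DataFrame, **read_kwargs) -> list[TitrationSeries]:
    """Build validated series from an in-memory titration table by routing it
    through the CSV reader (one parsing path for files and frames)."""
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return read_titration_csv(buf, **read_kwargs)


def _apply_ife(series_list: list[TitrationSeries], config: AnalysisConfig):
    mode = config.ife.mode
    if mode == "off":
        return series_list
    if mode == "linear_model":
        model = LinearAbsorbanceModel(
            epsilon_ex=config.ife.epsilon_ex,
            epsilon_em=config.ife.epsilon_em,
            baseline_ex=config.ife.baseline_ex,
            baseline_em=config.ife.baseline_em,
        )
    else:
        model = None  # sidecar absorbances must be present per point
    return [
        correct_series(
            s, model=model, path_weight=config.ife.path_weight, ceiling=config.ife.ceiling
        )
        for s in series_list
    ]


def _analyze_series(series: TitrationSeries, config: AnalysisConfig):
    fit = fit_piecewise(
        sv_ratios(series),
        min_segment=config.quenching.min_segment,
        alpha=config.quenching.alpha,
        require_slope_decrease=True,
    )
    quench = quenching_constants(fit, tau0=config.quenching.tau0_s)
    try:
        bind = analyze_binding(
            series,
            quench_floor=config.binding.quench_floor,
            min_segment=config.quenching.min_segment,
            alpha=config.quenching.alpha,
        )
    except QuenchbindError as exc:
        warnings.warn(f"binding analysis skipped: {exc}")
        bind = None
    return quench, bind


def _sv_dict(q: QuenchingResult) -> dict:
    fit = q.fit
    return {
        "two_segment": fit.two_segment,
        "ksv1": q.ksv1,
        "ksv2": q.ksv2,
        "kq1": q.kq1,
        "kq2": q.kq2,
        "intercepts": [fit.intercept1, fit.intercept2],
        "r2": [fit.r2_segment1, fit.r2_segment2],
        "breakpoint_Q": fit.breakpoint_x,
    }


def _binding_dict(b: BindingResult | None) -> dict | None:
    if b is None:
        return None
    return {"kb1": b.kb1, "kb2": b.kb2, "n1": b.n1, "n2": b.n2}


def run_analysis_frames(
    titration: pd.DataFrame,
    absorbance: pd.DataFrame | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> dict:
    """Run the full analysis on in-memory tables; returns the report document."""
    series_list = series_from_frame(
        titration,
        emission_wavelength=config.io.emission_nm,
        excitation_wavelength=config.io.excitation_nm,
        protein_conc=config.io.protein_conc_M,
    )
    if config.ife.mode == "sidecar":
        needs_sidecar = any(
            p.absorbance_ex is None for s in series_list for p in s.points
        )
        if needs_sidecar:
            if absorbance is None:
                raise ConfigError(
                    "ife.mode='sidecar' but no absorbances inline or in a sidecar"
                )
            series_list = attach_absorbances(series_list, absorbance)
    return _run(series_list, config)


def run_analysis(config: AnalysisConfig) -> dict:
    """File-based entry point; reads paths from the config and writes the report."""
    if not config.paths.titration:
        raise ConfigError("paths.titration is required")
    titration = pd.read_csv(config.paths.titration)
    absorbance = None
    if config.paths.absorbance:
        absorbance = read_absorbance_csv(config.paths.absorbance)
    report = run_analysis_frames(titration, absorbance, config)
    out_dir = Path(config.paths.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_report(report, out_dir / "report.json")
    return report


def _run(series_list: list[TitrationSeries], config: AnalysisConfig) -> dict:
    captured: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        series_list = _apply_ife(series_list, config)

        per_condition_temperature: dict[tuple[str, float], tuple] = {}
        for s in series_list:
            try:
                per_condition_temperature[(s.condition, s.temperature)] = (
                    s,
                    *_analyze_series(s, config),
                )
            except QuenchbindError as exc:
                warnings.warn(
                    f"condition ({s.condition}, {s.temperature} C) skipped: {exc}"
                )

        conditions_out = [
            {
                "label": cond,
                "temperature_C": temp,
                "stern_volmer": _sv_dict(quench),
                "binding": _binding_dict(bind),
            }
            for (cond, temp), (s, quench, bind) in sorted(per_condition_temperature.items())
        ]

        mechanism, thermo_out = _thermo_section(per_condition_temperature, config)
        competition_out = _competition_section(per_condition_temperature, config)
        captured = sorted({str(w.message) for w in wlist})

    return {
        "meta": {"version": __version__, "config_echo": dataclasses.asdict(config)},
        "conditions": conditions_out,
        "mechanism": mechanism,
        "thermodynamics": thermo_out,
        "competition": competition_out,
        "warnings": captured,
    }


def _thermo_section(per_ct: dict, config: AnalysisConfig):
    free = {
        temp: (quench, bind)
        for (cond, temp), (_, quench, bind) in per_ct.items()
        if cond == "free"
    }
    if len(free) < 2:
        warnings.warn("thermodynamics skipped: need the free condition at >= 2 temperatures")
        quench_by_T = {t + 273.15: q for t, (q, _) in free.items()}
        mechanism = classify_mechanism(quench_by_T) if len(free) >= 2 else "indeterminate"
        return mechanism, None

    quench_by_T = {t + 273.15: q for t, (q, _) in free.items()}
    mechanism = classify_mechanism(
        quench_by_T, diffusion_limit=config.quenching.diffusion_limit
    )

    thermo_out = {}
    for site, pick in (("site1", "kb1"), ("site2", "kb2")):
        kb_by_T = {}
        for t, (_, bind) in free.items():
            value = getattr(bind, pick, None) if bind is not None else None
            if value is not None:
                kb_by_T[t + 273.15] = value
        if len(kb_by_T) >= 2:
            res = vant_hoff(kb_by_T)
            thermo_out[site] = {
                "dH_kJ_mol": res.delta_H,
                "dS_J_mol_K": res.delta_S,
                "dG_by_T": {f"{t:.2f}": g for t, g in res.delta_G_by_T.items()},
                "r_squared": res.r_squared,
                "force_signature": force_signature(res.delta_H, res.delta_S),
            }
    if not thermo_out:
        return mechanism, None
    thermo_out["force_signature"] = thermo_out.get("site1", {}).get("force_signature")
    return mechanism, thermo_out


def _competition_section(per_ct: dict, config: AnalysisConfig):
    by_temp: dict[float, dict[str, TitrationSeries]] = {}
    for (cond, temp), (s, _, _) in per_ct.items():
        by_temp.setdefault(temp, {})[cond] = s
    candidates = {t: conds for t, conds in by_temp.items() if len(conds) > 1 and "free" in conds}
    if not candidates:
        return None
    temp = min(candidates)
    report = analyze_panel(
        candidates[temp],
        tau0=config.quenching.tau0_s,
        min_segment=config.quenching.min_segment,
        alpha=config.quenching.alpha,
    )
    return _competition_dict(report, temp)


def _competition_dict(report: CompetitionReport, temperature_C: float) -> dict:
    out = {
        "temperature_C": temperature_C,
        "curvature_classes": report.curvature_classes,
        "allosteric_flag": report.allosteric_flag,
        "inferred_sites": None,
    }
    if report.inference is not None:
        out["inferred_sites"] = {
            "assignment": report.inference.assignment,
            "evidence": list(report.inference.evidence),
            "conclusive": report.inference.conclusive,
        }
    return out


def run_simulate(
    sim: SimulationConfig, out_dir: str | Path, seed: int | None = None
) -> dict[str, Path]:
    """Write a simulated panel (titration + absorbance + ground truth)."""
    gt = sim.truth if seed is None else replace(sim.truth, seed=seed)
    paths = write_panel(gt, sim.design, out_dir)
    log.info("simulated panel written to %s", out_dir)
    return paths


def run_recover(
    sim: SimulationConfig,
    replicates: int = 20,
    seed: int = 0,
    config: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Simulate -> analyze -> compare with ground truth, per replicate.

    Returns one row per replicate with recovered free-condition constants,
    relative errors against the generator's truth, and panel classification
    outcomes.
    """
    rows = []
    for rep in range(replicates):
        gt = replace(sim.truth, seed=(seed + 1000003 * rep) % (2**31 - 1))
        tit, absorb, truth = generate_panel(gt, sim.design)
        report = run_analysis_frames(tit, absorb, config)
        row = {"replicate": rep, "seed": gt.seed}
        free25 = _pick_condition(report, "free")
        if free25 is not None:
            sv, bind = free25["stern_volmer"], free25["binding"]
            row["two_segment"] = sv["two_segment"]
            row["ksv1"] = sv["ksv1"]
            row["ksv2"] = sv["ksv2"]
            if bind:
                row["kb1"] = bind["kb1"]
                row["n1"] = bind["n1"]
                row["kb1_rel_err"] = bind["kb1"] / truth["K1_25C"] - 1.0
        warf = _pick_condition(report, "warfarin")
        if warf is not None:
            row["warfarin_linear"] = not warf["stern_volmer"]["two_segment"]
        row["mechanism"] = report["mechanism"]
        if report.get("thermodynamics"):
            row["dH1_kJ_mol"] = report["thermodynamics"]["site1"]["dH_kJ_mol"]
        rows.append(row)
    return pd.DataFrame(rows)


def _pick_condition(report: dict, label: str, temperature_C: float = 25.0):
    for c in report["conditions"]:
        if c["label"] == label and c["temperature_C"] == temperature_C:
            return c
    return None
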