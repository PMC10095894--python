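"""Site-marker competition analysis.

A panel of titrations of the same ligand against protein pre-incubated with
site markers (warfarin for drug site 1, ibuprofen for drug site 2, hemin for
fatty-acid site 1, or warfarin+hemin together) is analyzed condition by
condition.  The diagnostic read-out is the curvature class of each
Stern-Volmer plot: with two ligand sites open the plot bends downward (two
linear portions); with exactly one open it is a straight line; and the
inference rules of the study design follow:

* straight lines under a site-1 blocker and under a site-2 blocker, with a
  two-regime free curve, place the ligand in both blocked sites;
* constants unchanged under a blocker mean that blocker's site is not used
  by the ligand;
* the per-condition binding constants rank the sites' affinities;
* a secondary-site constant under the site-1 blocker exceeding the free
  protein's secondary constant flags allosteric coupling between the sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .binding import BindingResult, analyze_binding
from .errors import AnalysisError, DataWarning, QuenchbindError, ValidationError
from .quenching import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_SEGMENT,
    DEFAULT_TAU0_S,
    QuenchingResult,
    fit_piecewise,
    quenching_constants,
    sv_ratios,
)
from .spectra_io import TitrationSeries


@dataclass(frozen=True)
class MarkerCondition:
    """A panel condition and which modeled ligand sites its marker occupies."""

    label: str
    blocks_site1: bool
    blocks_site2: bool


MARKERS = {
    "free": MarkerCondition("free", False, False),
    "warfarin": MarkerCondition("warfarin", True, False),
    "ibuprofen": MarkerCondition("ibuprofen", False, False),
    "hemin": MarkerCondition("hemin", False, True),
    "warfarin+hemin": MarkerCondition("warfarin+hemin", True, True),
}

#: |relative difference| below which marker-condition constants count as
#: "unchanged" from the free condition.
UNCHANGED_RTOL = 0.25


@dataclass(frozen=True)
class ConditionAnalysis:
    label: str
    quenching: QuenchingResult
    binding: BindingResult | None
    curvature_class: str  # linear | downward

    def __post_init__(self) -> None:
        expected = "downward" if self.quenching.fit.two_segment else "linear"
        if self.curvature_class != expected:
            raise AnalysisError("curvature class inconsistent with fit")


@dataclass(frozen=True)
class SiteInference:
    assignment: str
    evidence: tuple[str, ...]
    conclusive: bool


@dataclass(frozen=True)
class CompetitionReport:
    conditions: dict[str, ConditionAnalysis]
    curvature_classes: dict[str, str]
    allosteric_flag: bool
    inference: SiteInference | None = None


def _analyze_condition(
    label: str,
    series: TitrationSeries,
    tau0: float,
    min_segment: int,
    alpha: float,
) -> ConditionAnalysis:
    fit = fit_piecewise(
        sv_ratios(series),
        min_segment=min_segment,
        alpha=alpha,
        require_slope_decrease=True,
    )
    quench = quenching_constants(fit, tau0=tau0)
    try:
        bind = analyze_binding(series, min_segment=min_segment, alpha=alpha)
    except QuenchbindError as exc:
        warnings.warn(
            f"binding analysis unavailable for condition {label!r}: {exc}",
            DataWarning,
            stacklevel=3,
        )
        bind = None
    return ConditionAnalysis(
        label=label,
        quenching=quench,
        binding=bind,
        curvature_class="downward" if fit.two_segment else "linear",
    )


def analyze_panel(
    series_by_condition: dict[str, TitrationSeries],
    tau0: float = DEFAULT_TAU0_S,
    min_segment: int = DEFAULT_MIN_SEGMENT,
    alpha: float = DEFAULT_ALPHA,
    infer: bool = True,
) -> CompetitionReport:
    """Run the quenching + binding pipeline per condition and classify the panel."""
    if "free" not in series_by_condition:
        raise ValidationError("panel must contain a 'free' condition")
    temps = {s.temperature for s in series_by_condition.values()}
    if len(temps) != 1:
        raise ValidationError(f"panel conditions span several temperatures: {sorted(temps)}")

    conditions: dict[str, ConditionAnalysis] = {}
    for label, series in series_by_condition.items():
        try:
            conditions[label] = _analyze_condition(label, series, tau0, min_segment, alpha)
        except QuenchbindError as exc:
            if label == "free":
                raise
            warnings.warn(
                f"marker condition {label!r} skipped: {exc}", DataWarning, stacklevel=2
            )
    allosteric = _allosteric_flag(conditions)
    report = CompetitionReport(
        conditions=conditions,
        curvature_classes={c.label: c.curvature_class for c in conditions.values()},
        allosteric_flag=allosteric,
    )
    if infer and len(conditions) > 1:
        report = CompetitionReport(
            conditions=report.conditions,
            curvature_classes=report.curvature_classes,
            allosteric_flag=report.allosteric_flag,
            inference=infer_sites(report),
        )
    return report


def _allosteric_flag(conditions: dict[str, ConditionAnalysis]) -> bool:
    """Secondary-site binding under the site-1 blocker vs the free protein."""
    free = conditions.get("free")
    warf = conditions.get("warfarin")
    if free is None or warf is None:
        return False
    if free.binding is None or free.binding.kb2 is None or warf.binding is None:
        return False
    if warf.curvature_class != "linear":
        return False
    return bool(warf.binding.kb1 > free.binding.kb2)


def infer_sites(report: CompetitionReport) -> SiteInference:
    """Apply the displacement-panel rule set; returns a structured verdict."""
    conds = report.conditions
    free = conds.get("free")
    if free is None or len(conds) < 2:
        return SiteInference(
            assignment="inconclusive",
            evidence=("panel needs the free condition plus at least one marker",),
            conclusive=False,
        )

    evidence: list[str] = []
    free_two = free.curvature_class == "downward"
    evidence.append(
        f"free condition is {free.curvature_class}"
        + (" (two binding regimes)" if free_two else "")
    )

    blocker_linear: dict[str, bool] = {}
    contradictions: list[str] = []
    for label, cond in conds.items():
        if label == "free":
            continue
        marker = MARKERS.get(label)
        blocks_any = marker is not None and (marker.blocks_site1 or marker.blocks_site2)
        single_block = marker is not None and marker.blocks_site1 != marker.blocks_site2
        if single_block:
            blocker_linear[label] = cond.curvature_class == "linear"
            evidence.append(f"{label}: {cond.curvature_class}")
            if cond.curvature_class == "downward" and not free_two:
                contradictions.append(
                    f"{label} shows two regimes although the free curve is linear"
                )
        if not blocks_any and _unchanged_from_free(free, cond):
            evidence.append(f"{label}: constants unchanged; its site is not a ligand site")

    if contradictions:
        return SiteInference(
            assignment="inconclusive",
            evidence=tuple(evidence + contradictions),
            conclusive=False,
        )

    site1_blocked_linear = blocker_linear.get("warfarin", False)
    site2_blocked_linear = blocker_linear.get("hemin", False)
    if free_two and site1_blocked_linear and site2_blocked_linear:
        ranking = _affinity_ranking(conds)
        assignment = (
            "primary site = drug site 1 (warfarin site); "
            "secondary site = FA1/hemin site; drug site 2 not used"
        )
        return SiteInference(
            assignment=assignment,
            evidence=tuple(evidence + ranking),
            conclusive=True,
        )
    if not free_two and all(
        _unchanged_from_free(free, c) for label, c in conds.items() if label != "free"
    ):
        return SiteInference(
            assignment="no modeled site shared with any marker",
            evidence=tuple(evidence),
            conclusive=True,
        )
    return SiteInference(
        assignment="partial: see evidence",
        evidence=tuple(evidence),
        conclusive=False,
    )


def _unchanged_from_free(free: ConditionAnalysis, cond: ConditionAnalysis) -> bool:
    if cond.curvature_class != free.curvature_class:
        return False
    ref, got = free.quenching.ksv1, cond.quenching.ksv1
    return abs(got - ref) <= UNCHANGED_RTOL * ref


def _affinity_ranking(conds: dict[str, ConditionAnalysis]) -> list[str]:
    out = []
    hem = conds.get("hemin")
    warf = conds.get("warfarin")
    if (
        hem is not None
        and warf is not None
        and hem.binding is not None
        and warf.binding is not None
    ):
        if hem.binding.kb1 > warf.binding.kb1:
            out.append(
                "affinity at drug site 1 (open under hemin) exceeds affinity at "
                "the hemin site (open under warfarin)"
            )
        else:
            out.append(
                "affinity at the hemin site (open under warfarin) exceeds "
                "affinity at drug site 1 (open under hemin)"
            )
    return out
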