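"""Double-logarithmic binding analysis.

For static quenching by ligand association, log((F0-F)/F) = log kb + n log[Q]:
a line whose intercept gives the binding constant kb (base-10 throughout) and
whose slope n is the apparent number of binding sites.  As in the
Stern-Volmer analysis, a system with a strong primary and a weaker secondary
site bends downward and is fit as two straight lines; the low-concentration
block is the primary site (kb1, n1), the high-concentration block the
secondary (kb2, n2).

Points with [Q] = 0, with F >= F0, or with fractional quenching below a
floor (default (F0-F)/F < 1e-3, where the log is numerically meaningless)
are excluded with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError, DataWarning
from .quenching import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_SEGMENT,
    SegmentedLinearFit,
    fit_piecewise,
)
from .spectra_io import TitrationSeries

DEFAULT_QUENCH_FLOOR = 1e-3


@dataclass(frozen=True)
class BindingResult:
    """Per-site binding constants and site numbers from the double-log fit.

    kb is reported in L/mol (the field's usage even when n != 1; n is carried
    alongside).
    """

    kb1: float
    n1: float
    fit: SegmentedLinearFit
    kb2: float | None = None
    n2: float | None = None

    def __post_init__(self) -> None:
        if self.kb1 <= 0 or self.n1 <= 0:
            raise AnalysisError("kb1 and n1 must be > 0")
        if self.kb2 is not None and not (0 < self.kb2 < self.kb1):
            raise AnalysisError(
                f"kb2 must satisfy 0 < kb2 < kb1, got {self.kb2} vs {self.kb1}"
            )


def double_log_points(
    series: TitrationSeries, quench_floor: float = DEFAULT_QUENCH_FLOOR
) -> np.ndarray:
    """Ordered pairs (log10[Q], log10((F0-F)/F)) for usable titration points."""
    f0 = series.f0
    q = series.quencher
    f = series.intensities
    usable_x, usable_y, n_excluded = [], [], 0
    for qi, fi in zip(q[1:], f[1:]):  # skip the defining [Q]=0 point
        if fi >= f0:
            n_excluded += 1
            continue
        quench = (f0 - fi) / fi
        if quench < quench_floor:
            n_excluded += 1
            continue
        usable_x.append(np.log10(qi))
        usable_y.append(np.log10(quench))
    if n_excluded:
        warnings.warn(
            f"{n_excluded} point(s) excluded from double-log analysis "
            "(no quenching or below floor)",
            DataWarning,
            stacklevel=2,
        )
    if len(usable_x) < 3:
        raise AnalysisError(
            f"only {len(usable_x)} usable double-log points; >= 3 required"
        )
    return np.column_stack([usable_x, usable_y])


def fit_binding(
    points: np.ndarray,
    min_segment: int = DEFAULT_MIN_SEGMENT,
    alpha: float = DEFAULT_ALPHA,
) -> BindingResult:
    """Segmented fit of double-log points; kb = 10^intercept, n = slope."""
    fit = fit_piecewise(points, min_segment=min_segment, alpha=alpha)
    kb2 = n2 = None
    if fit.two_segment:
        kb2 = 10.0 ** fit.intercept2
        n2 = fit.slope2
    return BindingResult(
        kb1=10.0**fit.intercept1,
        n1=fit.slope1,
        fit=fit,
        kb2=kb2,
        n2=n2,
    )


def analyze_binding(
    series: TitrationSeries,
    quench_floor: float = DEFAULT_QUENCH_FLOOR,
    min_segment: int = DEFAULT_MIN_SEGMENT,
    alpha: float = DEFAULT_ALPHA,
) -> BindingResult:
    """Convenience composition: double_log_points then fit_binding."""
    return fit_binding(
        double_log_points(series, quench_floor=quench_floor),
        min_segment=min_segment,
        alpha=alpha,
    )
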