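"""Stern-Volmer quenching analysis with two-site segmentation.

For a single class of fluorophore quenched by a single process the
Stern-Volmer plot F0/F vs [Q] is linear with slope K_SV.  A downward bend
(concave toward the concentration axis) signals heterogeneous accessibility
-- here, a second, weaker binding site -- and the plot is then described by
two linear portions: the low-concentration slope K_SV1 (primary site) and
the high-concentration slope K_SV2 < K_SV1 (secondary site).

Segmentation is exhaustive: every admissible breakpoint splitting the
ordered points into two blocks of at least ``min_segment`` points is fit by
ordinary least squares with free intercepts, the split with minimal total
SSE is retained, and the two-segment model is accepted only when an
extra-parameters F-test against the single line is significant.  Because
the breakpoint is chosen to minimize SSE, the nominal F-test level is
inflated; the p-value is Bonferroni-corrected across the candidate
breakpoints searched, which restores an empirical false-split rate close
to the nominal alpha.

The bimolecular quenching constant K_q = K_SV / tau0 (tau0 the unquenched
fluorophore lifetime) discriminates mechanism: values far above the
diffusion-controlled limit ~1e10 L mol^-1 s^-1, together with K_SV falling
as temperature rises, indicate static (ground-state complex) quenching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import AnalysisError, DataWarning, DomainError
from .spectra_io import TitrationSeries

DEFAULT_TAU0_S = 5.9e-9
DEFAULT_DIFFUSION_LIMIT = 1e10
DEFAULT_MIN_SEGMENT = 3
DEFAULT_ALPHA = 0.05

#: Relative SSE/SST below which a single line is accepted outright.  The
#: F-test is scale-free, so without this floor it would split data whose
#: departure from one line is at numerical-noise level.
_COLLINEAR_RTOL = 1e-9


@dataclass(frozen=True)
class SegmentedLinearFit:
    """A one- or two-regime linear fit over ordered abscissae.

    ``breakpoint_index`` is the index of the first point of the second
    segment (None for a single line).  Slopes/intercepts of the second
    segment are None for a single line.  ``f_statistic``/``p_value`` compare
    the best two-segment candidate against the single line (p is
    Bonferroni-corrected over candidate breakpoints); they are None when no
    two-segment candidate exists.  ``candidate_slope1``/``candidate_slope2``
    always record the best two-segment candidate's slopes, whether or not it
    was accepted - the two "linear portions" read off the plot.
    """

    two_segment: bool
    slope1: float
    intercept1: float
    r2_segment1: float
    sse_total: float
    breakpoint_index: int | None = None
    slope2: float | None = None
    intercept2: float | None = None
    r2_segment2: float | None = None
    f_statistic: float | None = None
    p_value: float | None = None
    candidate_slope1: float | None = None
    candidate_slope2: float | None = None
    n_points: int = 0

    @property
    def breakpoint_x(self):
        return None if self.breakpoint_index is None else self._break_x

    # populated via object.__setattr__ in fit_piecewise
    _break_x: float | None = None


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Least squares line. Returns (intercept, slope, sse, r2)."""
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise DomainError("degenerate abscissa: zero variance within a segment")
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    intercept = float(ym - slope * xm)
    resid = y - intercept - slope * x
    sse = float((resid**2).sum())
    sst = float(((y - ym) ** 2).sum())
    r2 = 1.0 if sst == 0.0 else 1.0 - sse / sst
    return intercept, slope, sse, float(r2)


def fit_piecewise(
    points: Sequence[tuple[float, float]] | np.ndarray,
    min_segment: int = DEFAULT_MIN_SEGMENT,
    alpha: float = DEFAULT_ALPHA,
    require_slope_decrease: bool = False,
) -> SegmentedLinearFit:
    """Fit one line, or two lines about the SSE-optimal breakpoint.

    Every breakpoint leaving at least ``min_segment`` points per side is
    evaluated; SSE ties break toward the earlier breakpoint.  The split is
    accepted when the extra-parameters F-test (2 extra parameters,
    Bonferroni-corrected over candidates) has p < ``alpha`` and, if
    ``require_slope_decrease`` (the Stern-Volmer downward-curvature
    constraint), slope2 < slope1.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DomainError("points must be an (n, 2) array of (x, y) pairs")
    x, y = arr[:, 0], arr[:, 1]
    n = len(x)
    if n < min_segment:
        raise AnalysisError(f"{n} points; at least {min_segment} required")
    if np.any(np.diff(x) <= 0):
        raise DomainError("abscissae must be strictly increasing")

    int1, slo1, sse1, r2_1 = _ols(x, y)
    single = SegmentedLinearFit(
        two_segment=False,
        slope1=slo1,
        intercept1=int1,
        r2_segment1=r2_1,
        sse_total=sse1,
        n_points=n,
    )
    if n < 2 * min_segment:
        return single

    candidates = range(min_segment, n - min_segment + 1)
    best = None
    for k in candidates:
        iL, bL, sL, rL = _ols(x[:k], y[:k])
        iR, bR, sR, rR = _ols(x[k:], y[k:])
        sse2 = sL + sR
        if best is None or sse2 < best[0]:  # strict: ties keep earlier k
            best = (sse2, k, iL, bL, rL, iR, bR, rR)
    sse2, k, iL, bL, rL, iR, bR, rR = best

    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0 or sse1 <= _COLLINEAR_RTOL * sst:
        # The single line already explains the data to numerical precision.
        return single

    if sse2 == 0.0:
        f_stat, p_val = float("inf"), 0.0
    else:
        f_stat = ((sse1 - sse2) / 2.0) / (sse2 / (n - 4))
        p_val = min(1.0, float(stats.f.sf(f_stat, 2, n - 4)) * len(candidates))

    # In Stern-Volmer mode a valid second regime must still be quenching
    # (positive slope) and shallower than the first (downward curvature).
    accept = p_val < alpha and (not require_slope_decrease or 0.0 < bR < bL)
    fit = SegmentedLinearFit(
        two_segment=accept,
        slope1=bL if accept else slo1,
        intercept1=iL if accept else int1,
        r2_segment1=rL if accept else r2_1,
        sse_total=sse2 if accept else sse1,
        breakpoint_index=k if accept else None,
        slope2=bR if accept else None,
        intercept2=iR if accept else None,
        r2_segment2=rR if accept else None,
        f_statistic=f_stat,
        p_value=p_val,
        candidate_slope1=bL,
        candidate_slope2=bR,
        n_points=n,
    )
    if accept:
        object.__setattr__(fit, "_break_x", float(x[k]))
    return fit


def sv_ratios(series: TitrationSeries) -> np.ndarray:
    """Stern-Volmer pairs ([Q], F0/F) for a validated series."""
    f = series.intensities
    if np.any(f <= 0):
        raise DomainError("non-positive intensity in series")
    q = series.quencher
    if len(q) < DEFAULT_MIN_SEGMENT:
        raise AnalysisError("insufficient points for Stern-Volmer analysis")
    return np.column_stack([q, series.f0 / f])


@dataclass(frozen=True)
class QuenchingResult:
    """Per-site Stern-Volmer and bimolecular quenching constants."""

    ksv1: float  # L/mol
    kq1: float  # L mol^-1 s^-1
    tau0: float  # s
    fit: SegmentedLinearFit
    ksv2: float | None = None
    kq2: float | None = None
    mechanism: str = "indeterminate"

    def __post_init__(self) -> None:
        if self.ksv1 <= 0:
            raise AnalysisError(f"ksv1 must be > 0, got {self.ksv1}")
        if self.ksv2 is not None and not (0 < self.ksv2 < self.ksv1):
            raise AnalysisError(
                f"ksv2 must satisfy 0 < ksv2 < ksv1, got {self.ksv2} vs {self.ksv1}"
            )


def quenching_constants(
    fit: SegmentedLinearFit, tau0: float = DEFAULT_TAU0_S
) -> QuenchingResult:
    """Read K_SV per segment off a Stern-Volmer fit and derive K_q = K_SV/tau0."""
    if tau0 <= 0:
        raise DomainError(f"tau0 must be > 0, got {tau0}")
    if fit.slope1 <= 0:
        raise AnalysisError(
            f"Stern-Volmer slope {fit.slope1:.3g} <= 0: not a quencher"
        )
    ksv2 = kq2 = None
    if fit.two_segment:
        if fit.slope2 is None or fit.slope2 <= 0:
            raise AnalysisError("second-segment slope <= 0: not a quencher")
        ksv2 = fit.slope2
        kq2 = ksv2 / tau0
    return QuenchingResult(
        ksv1=fit.slope1,
        kq1=fit.slope1 / tau0,
        tau0=tau0,
        fit=fit,
        ksv2=ksv2,
        kq2=kq2,
    )


def classify_mechanism(
    results_by_temperature: Mapping[float, QuenchingResult],
    diffusion_limit: float = DEFAULT_DIFFUSION_LIMIT,
) -> str:
    """Static vs dynamic quenching from the temperature trend of K_SV1.

    Static: every K_q1 above the diffusion limit and K_SV1 strictly
    decreasing with temperature.  Dynamic: K_SV1 strictly increasing and
    every K_q1 at or below the limit.  Anything else is indeterminate.
    """
    temps = sorted(results_by_temperature)
    if len(temps) < 2:
        warnings.warn(
            "mechanism classification needs >= 2 temperatures", DataWarning, stacklevel=2
        )
        return "indeterminate"
    ksv = np.array([results_by_temperature[t].ksv1 for t in temps])
    kq = np.array([results_by_temperature[t].kq1 for t in temps])
    decreasing = bool(np.all(np.diff(ksv) < 0))
    increasing = bool(np.all(np.diff(ksv) > 0))
    if decreasing and np.all(kq > diffusion_limit):
        return "static"
    if increasing and np.all(kq <= diffusion_limit):
        return "dynamic"
    return "indeterminate"
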