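"""Inner filter effect (IFE) correction.

A quencher that absorbs at the excitation or emission wavelength attenuates
the measured fluorescence beyond any true quenching.  For a standard 1 cm
cuvette with centered beam geometry the observed intensity is restored by

    F_corr = F_obs * 10^(w * (A_ex + A_em))

with path weight w = 1/2 (excitation and emission each traverse half the
cell on average).  A_ex and A_em are the absorbances of the whole sample at
the excitation wavelength and at the analysis emission wavelength, measured
per titration point (they grow with quencher concentration).  Above roughly
A = 2 the multiplicative correction becomes unreliable and a warning is
emitted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

from .errors import ConfigError, IFEWarning, ValidationError
from .spectra_io import TitrationSeries

DEFAULT_PATH_WEIGHT = 0.5
DEFAULT_ABSORBANCE_CEILING = 2.0


@dataclass(frozen=True)
class AbsorbancePair:
    """Sample absorbances at the excitation and emission wavelengths (AU)."""

    absorbance_ex: float
    absorbance_em: float

    def __post_init__(self) -> None:
        for name in ("absorbance_ex", "absorbance_em"):
            a = getattr(self, name)
            if not math.isfinite(a) or a < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {a}")


@dataclass(frozen=True)
class LinearAbsorbanceModel:
    """Beer-Lambert model A(Q) = epsilon * [Q] + baseline at each wavelength.

    ``epsilon_ex``/``epsilon_em`` are quencher molar extinction coefficients
    (L mol^-1 cm^-1); the baselines absorb the contribution of everything
    that does not change along the titration (protein, buffer).
    """

    epsilon_ex: float
    epsilon_em: float
    baseline_ex: float = 0.0
    baseline_em: float = 0.0

    def pair_at(self, quencher_total: float) -> AbsorbancePair:
        return AbsorbancePair(
            absorbance_ex=self.epsilon_ex * quencher_total + self.baseline_ex,
            absorbance_em=self.epsilon_em * quencher_total + self.baseline_em,
        )


def ife_factor(
    pair: AbsorbancePair,
    path_weight: float = DEFAULT_PATH_WEIGHT,
    ceiling: float = DEFAULT_ABSORBANCE_CEILING,
) -> float:
    """Multiplicative correction 10^(w*(A_ex+A_em)); always >= 1.

    Warns (:class:`IFEWarning`) when either absorbance exceeds ``ceiling``.
    """
    if max(pair.absorbance_ex, pair.absorbance_em) > ceiling:
        warnings.warn(
            f"absorbance above {ceiling} AU; IFE correction unreliable",
            IFEWarning,
            stacklevel=2,
        )
    return 10.0 ** (path_weight * (pair.absorbance_ex + pair.absorbance_em))


def correct_series(
    series: TitrationSeries,
    model: LinearAbsorbanceModel | None = None,
    path_weight: float = DEFAULT_PATH_WEIGHT,
    ceiling: float = DEFAULT_ABSORBANCE_CEILING,
) -> TitrationSeries:
    """Return a series with every intensity IFE-corrected.

    Per-point absorbances take precedence; a :class:`LinearAbsorbanceModel`
    fills in for points without them.  F0 is corrected with its own pair.
    """
    new_points = []
    for p in series.points:
        if p.absorbance_ex is not None and p.absorbance_em is not None:
            pair = AbsorbancePair(p.absorbance_ex, p.absorbance_em)
        elif model is not None:
            pair = model.pair_at(p.quencher_total)
        else:
            raise ConfigError(
                "point lacks absorbances and no linear absorbance model configured"
            )
        factor = ife_factor(pair, path_weight=path_weight, ceiling=ceiling)
        new_points.append(replace(p, intensity=p.intensity * factor))
    return series.with_points(new_points)
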