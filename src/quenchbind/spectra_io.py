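"""Reading, validation and serialization of fluorescence titration data.

The unit of analysis is a :class:`TitrationSeries`: a protein at fixed
concentration titrated with increasing total quencher, at one temperature and
under one condition label (free protein or protein pre-incubated with a site
marker).  Emission may arrive either already reduced to a single intensity per
titration point, or as full emission spectra in long format, in which case the
analysis intensity is taken at a fixed wavelength (340 nm, the tryptophan
emission maximum) or at the band peak.

Concentrations are mol/L internally; temperatures are degrees Celsius at the
I/O boundary and Kelvin inside computations.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, ValidationError

#: Default analysis emission wavelength (nm): tryptophan emission maximum.
DEFAULT_EMISSION_NM = 340.0

#: Default excitation wavelength (nm): selective tryptophan excitation.
DEFAULT_EXCITATION_NM = 295.0

CELSIUS_OFFSET = 273.15

KNOWN_CONDITIONS = ("free", "warfarin", "ibuprofen", "hemin", "warfarin+hemin")


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + CELSIUS_OFFSET


@dataclass(frozen=True)
class EmissionSpectrum:
    """A single emission scan at fixed excitation.

    Wavelengths must be strictly increasing and intensities non-negative.
    """

    excitation_wavelength: float
    wavelengths: tuple[float, ...]
    intensities: tuple[float, ...]
    temperature: float = 25.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if wl.size != inten.size:
            raise ValidationError(
                f"wavelengths ({wl.size}) and intensities ({inten.size}) differ in length"
            )
        if wl.size == 0:
            raise ValidationError("empty spectrum")
        if not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(inten)) or np.any(inten < 0):
            raise ValidationError("intensities must be finite and >= 0")


def intensity_at(spectrum: EmissionSpectrum, wavelength: float | str) -> float:
    """Intensity at a fixed wavelength (linear interpolation) or at the peak.

    Pass ``"peak"`` for the maximum intensity of the scan.
    """
    inten = np.asarray(spectrum.intensities, dtype=float)
    if isinstance(wavelength, str):
        if wavelength != "peak":
            raise DomainError(f"unknown wavelength selector {wavelength!r}")
        return float(inten.max())
    wl = np.asarray(spectrum.wavelengths, dtype=float)
    if not (wl[0] <= wavelength <= wl[-1]):
        raise DomainError(
            f"wavelength {wavelength} nm outside spectrum range [{wl[0]}, {wl[-1]}]"
        )
    return float(np.interp(wavelength, wl, inten))


@dataclass(frozen=True)
class TitrationPoint:
    """One titration point: total quencher concentration and emission intensity.

    ``absorbance_ex``/``absorbance_em`` are the optional absorbances of the
    sample at the excitation and analysis-emission wavelengths, used for
    inner-filter-effect correction.
    """

    quencher_total: float  # mol/L
    intensity: float  # fluorescence units
    absorbance_ex: float | None = None
    absorbance_em: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.quencher_total) or self.quencher_total < 0:
            raise ValidationError(f"quencher_total must be >= 0, got {self.quencher_total}")
        if not math.isfinite(self.intensity) or self.intensity <= 0:
            raise ValidationError(f"intensity must be > 0, got {self.intensity}")
        for name in ("absorbance_ex", "absorbance_em"):
            a = getattr(self, name)
            if a is not None and (not math.isfinite(a) or a < 0):
                raise ValidationError(f"{name} must be finite and >= 0, got {a}")


@dataclass(frozen=True)
class TitrationSeries:
    """An ordered titration under one condition at one temperature."""

    condition: str
    temperature: float  # degrees C
    points: tuple[TitrationPoint, ...]
    protein_conc: float = 3e-6  # mol/L

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValidationError(
                f"series ({self.condition}, {self.temperature} C) has "
                f"{len(self.points)} points; >= 3 required"
            )
        q = self.quencher
        if np.any(np.diff(q) <= 0):
            raise ValidationError("points must have strictly increasing quencher_total")
        if q[0] != 0:
            raise ValidationError(
                f"series ({self.condition}, {self.temperature} C) has no "
                "zero-quencher point to define F0"
            )

    @property
    def quencher(self) -> np.ndarray:
        return np.array([p.quencher_total for p in self.points], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.points], dtype=float)

    @property
    def f0(self) -> float:
        return self.points[0].intensity

    @property
    def temperature_K(self) -> float:
        return celsius_to_kelvin(self.temperature)

    def with_points(self, points: Sequence[TitrationPoint]) -> "TitrationSeries":
        return replace(self, points=tuple(points))


_SUMMARY_REQUIRED = ("condition", "temperature_C", "intensity")
_SPECTRAL_EXTRA = "wavelength_nm"


def _quencher_column(df: pd.DataFrame) -> tuple[str, float]:
    """Return (column name, scale to mol/L) for the quencher column."""
    if "quencher_total_M" in df.columns:
        return "quencher_total_M", 1.0
    if "quencher_total_uM" in df.columns:
        return "quencher_total_uM", 1e-6
    raise FormatError("missing required column 'quencher_total_M' (or 'quencher_total_uM')")


def read_titration_csv(
    source,
    emission_wavelength: float | str = DEFAULT_EMISSION_NM,
    excitation_wavelength: float = DEFAULT_EXCITATION_NM,
    protein_conc: float = 3e-6,
) -> list[TitrationSeries]:
    """Parse a titration CSV into validated :class:`TitrationSeries`.

    Accepts either the summary format (one intensity per point, columns
    ``condition,temperature_C,quencher_total_M,intensity`` plus optional
    ``absorbance_ex,absorbance_em``) or the spectral long format with
    additional ``wavelength_nm`` column, reduced via :func:`intensity_at`.
    Row order is irrelevant: series are sorted by quencher concentration.
    """
    if isinstance(source, (str, bytes)) and "\n" in str(source):
        source = io.StringIO(source if isinstance(source, str) else source.decode())
    try:
        df = pd.read_csv(source)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"could not parse CSV: {exc}") from exc

    for col in _SUMMARY_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    qcol, qscale = _quencher_column(df)
    df = df.copy()
    df["_q"] = df[qcol].astype(float) * qscale

    spectral = _SPECTRAL_EXTRA in df.columns
    series_out: list[TitrationSeries] = []
    for (cond, temp), grp in sorted(
        df.groupby(["condition", "temperature_C"], sort=False),
        key=lambda kv: (str(kv[0][0]), float(kv[0][1])),
    ):
        if spectral:
            points = _reduce_spectral_group(
                grp, cond, float(temp), emission_wavelength, excitation_wavelength
            )
        else:
            points = _summary_points(grp, cond, float(temp))
        series_out.append(
            TitrationSeries(
                condition=str(cond),
                temperature=float(temp),
                points=tuple(points),
                protein_conc=protein_conc,
            )
        )
    return series_out


def _summary_points(grp: pd.DataFrame, cond, temp) -> list[TitrationPoint]:
    grp = grp.sort_values("_q", kind="mergesort")
    qvals = grp["_q"].to_numpy()
    if np.unique(qvals).size != qvals.size:
        raise ValidationError(
            f"duplicate quencher concentration in series ({cond}, {temp} C)"
        )
    has_abs = {"absorbance_ex", "absorbance_em"} <= set(grp.columns)
    points = []
    for _, row in grp.iterrows():
        kwargs = {}
        if has_abs and not (pd.isna(row["absorbance_ex"]) or pd.isna(row["absorbance_em"])):
            kwargs = {
                "absorbance_ex": float(row["absorbance_ex"]),
                "absorbance_em": float(row["absorbance_em"]),
            }
        points.append(
            TitrationPoint(
                quencher_total=float(row["_q"]),
                intensity=float(row["intensity"]),
                **kwargs,
            )
        )
    return points


def _reduce_spectral_group(
    grp: pd.DataFrame, cond, temp, emission_wavelength, excitation_wavelength
) -> list[TitrationPoint]:
    points = []
    for q, sub in sorted(grp.groupby("_q", sort=False), key=lambda kv: float(kv[0])):
        sub = sub.sort_values("wavelength_nm", kind="mergesort")
        spec = EmissionSpectrum(
            excitation_wavelength=excitation_wavelength,
            wavelengths=tuple(sub["wavelength_nm"].astype(float)),
            intensities=tuple(sub["intensity"].astype(float)),
            temperature=temp,
        )
        points.append(
            TitrationPoint(
                quencher_total=float(q),
                intensity=intensity_at(spec, emission_wavelength),
            )
        )
    qs = [p.quencher_total for p in points]
    if len(set(qs)) != len(qs):
        raise ValidationError(f"duplicate quencher concentration in series ({cond}, {temp} C)")
    return points


def read_absorbance_csv(source) -> pd.DataFrame:
    """Parse an absorbance sidecar CSV.

    Columns: condition, temperature_C, quencher_total_M (or _uM),
    absorbance_ex, absorbance_em.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source)
    for col in ("condition", "temperature_C", "absorbance_ex", "absorbance_em"):
        if col not in df.columns:
            raise FormatError(f"absorbance sidecar missing column {col!r}")
    qcol, qscale = _quencher_column(df)
    df = df.copy()
    df["quencher_total_M"] = df[qcol].astype(float) * qscale
    return df


def attach_absorbances(
    series_list: Iterable[TitrationSeries], sidecar: pd.DataFrame
) -> list[TitrationSeries]:
    """Merge sidecar absorbances onto series points, matching on
    (condition, temperature, quencher concentration)."""
    keyed: dict[tuple[str, float], dict[float, tuple[float, float]]] = {}
    for _, row in sidecar.iterrows():
        keyed.setdefault((str(row["condition"]), float(row["temperature_C"])), {})[
            float(row["quencher_total_M"])
        ] = (float(row["absorbance_ex"]), float(row["absorbance_em"]))
    out = []
    for series in series_list:
        table = keyed.get((series.condition, series.temperature))
        if table is None:
            raise ValidationError(
                f"no absorbance rows for series ({series.condition}, {series.temperature} C)"
            )
        new_points = []
        for p in series.points:
            match = _lookup_quencher(table, p.quencher_total)
            if match is None:
                raise ValidationError(
                    f"no absorbance row for [Q]={p.quencher_total} in series "
                    f"({series.condition}, {series.temperature} C)"
                )
            a_ex, a_em = match
            new_points.append(replace(p, absorbance_ex=a_ex, absorbance_em=a_em))
        out.append(series.with_points(new_points))
    return out


def _lookup_quencher(table: Mapping[float, tuple], q: float):
    if q in table:
        return table[q]
    for qk, v in table.items():  # tolerate last-digit float formatting
        if math.isclose(qk, q, rel_tol=1e-9, abs_tol=1e-15):
            return v
    return None


def write_report(report: Mapping, sink) -> None:
    """Serialize an analysis report to JSON at full float precision."""
    if not report:
        raise ValidationError("refusing to write an empty report")
    text = json.dumps(report, indent=2, allow_nan=False, default=_json_default)
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w") as fh:
            fh.write(text)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"unserializable field of type {type(obj).__name__}")


def read_report(source) -> dict:
    if hasattr(source, "read"):
        return json.load(source)
    with open(source) as fh:
        return json.load(fh)
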