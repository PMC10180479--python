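"""Spectrum data model plus delimited-text readers and writers.

One :class:`Spectrum` is a single wavelength–intensity trace from a scanning
spectrofluorometer, tagged with its acquisition condition.  The four standard
conditions are

====================  ==========================  =====================
condition             mode                        fixed wavelength (nm)
====================  ==========================  =====================
``em310``             emission (390–600 nm)       excitation at 310
``em366``             emission (390–600 nm)       excitation at 366
``exc570``            excitation (300–540 nm)     detection at 570
``em280``             emission (albumin readout)  excitation at 280
====================  ==========================  =====================

Spectra travel as long-format delimited tables (comma or tab, auto-detected)
with the columns ``sample_id, group, replicate, mode, fixed_wavelength_nm,
wavelength_nm, intensity_au`` — one row per wavelength point.  Derived
results are written as tidy per-family tables (fractions, absolute
contributions, markers, group statistics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("serafluor")

__all__ = [
    "Spectrum",
    "ParseError",
    "SpectrumValidationError",
    "STANDARD_CONDITIONS",
    "read_spectra",
    "write_spectra",
    "write_results",
    "SPECTRA_COLUMNS",
]

GROUPS = ("sham", "IR", "IR_OCA")

#: (mode, fixed wavelength) pairs of the four acquisition conditions.
STANDARD_CONDITIONS: dict[tuple[str, float], str] = {
    ("emission", 310.0): "em310",
    ("emission", 366.0): "em366",
    ("excitation", 570.0): "exc570",
    ("emission", 280.0): "em280",
}

SPECTRA_COLUMNS = (
    "sample_id",
    "group",
    "replicate",
    "mode",
    "fixed_wavelength_nm",
    "wavelength_nm",
    "intensity_au",
)

_FLOAT_FMT = "%.17g"  # lossless round-trip for doubles


class ParseError(ValueError):
    """A spectra file could not be parsed (message names the offending line)."""


class SpectrumValidationError(ValueError):
    """A spectrum violates the data-model invariants."""


@dataclass(frozen=True)
class Spectrum:
    """One wavelength–intensity trace with acquisition metadata.

    Wavelengths must be strictly increasing on a uniform grid with at least
    10 points.  ``mode``/``fixed_wavelength_nm`` must be one of the four
    standard acquisition conditions unless ``permissive`` is set.
    """

    wavelengths_nm: np.ndarray
    intensities_au: np.ndarray
    mode: str
    fixed_wavelength_nm: float
    sample_id: str = ""
    group: str | None = None
    replicate_index: int = 1
    permissive: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths_nm", np.asarray(self.wavelengths_nm, float))
        object.__setattr__(self, "intensities_au", np.asarray(self.intensities_au, float))
        self._validate()

    def _validate(self) -> None:
        wl, y = self.wavelengths_nm, self.intensities_au
        label = f"{self.sample_id or '<unnamed>'} rep {self.replicate_index}"
        if wl.ndim != 1 or y.ndim != 1 or len(wl) != len(y):
            raise SpectrumValidationError(
                f"spectrum {label}: wavelengths and intensities must be 1-D and equal length"
            )
        if len(wl) < 10:
            raise SpectrumValidationError(f"spectrum {label}: needs >= 10 points, got {len(wl)}")
        steps = np.diff(wl)
        if np.any(steps <= 0):
            raise SpectrumValidationError(
                f"spectrum {label}: wavelengths must be strictly increasing"
            )
        if np.max(steps) - np.min(steps) > 1e-6:
            raise SpectrumValidationError(
                f"spectrum {label}: wavelength step is not uniform (tolerance 1e-6 nm)"
            )
        if self.mode not in ("emission", "excitation"):
            raise SpectrumValidationError(
                f"spectrum {label}: mode must be 'emission' or 'excitation', got {self.mode!r}"
            )
        if self.replicate_index < 1:
            raise SpectrumValidationError(f"spectrum {label}: replicate_index must be >= 1")
        if not self.permissive:
            key = (self.mode, float(self.fixed_wavelength_nm))
            if key not in STANDARD_CONDITIONS:
                raise SpectrumValidationError(
                    f"spectrum {label}: ({self.mode}, {self.fixed_wavelength_nm} nm) is not a "
                    "standard acquisition condition; pass permissive=True to allow it"
                )

    @property
    def condition(self) -> str:
        """Short condition label (``em310``/``em366``/``exc570``/``em280``) if standard."""
        key = (self.mode, float(self.fixed_wavelength_nm))
        try:
            return STANDARD_CONDITIONS[key]
        except KeyError:
            return f"{self.mode}@{self.fixed_wavelength_nm:g}"

    @property
    def step_nm(self) -> float:
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return replace(self, intensities_au=np.asarray(intensities, float))

    def allclose(self, other: "Spectrum", rtol: float = 1e-12) -> bool:
        return (
            self.mode == other.mode
            and self.sample_id == other.sample_id
            and self.group == other.group
            and self.replicate_index == other.replicate_index
            and np.isclose(self.fixed_wavelength_nm, other.fixed_wavelength_nm, rtol=rtol)
            and self.wavelengths_nm.shape == other.wavelengths_nm.shape
            and np.allclose(self.wavelengths_nm, other.wavelengths_nm, rtol=rtol)
            and np.allclose(self.intensities_au, other.intensities_au, rtol=rtol)
        )


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_spectra(path, format: str = "auto", permissive: bool = False) -> list[Spectrum]:
    """Read a long-format delimited spectra table into validated records.

    ``format`` is ``auto`` (sniff the delimiter), ``csv`` or ``tsv``.
    Malformed rows raise :class:`ParseError` naming the line; non-monotone or
    non-uniform wavelength grids raise :class:`SpectrumValidationError`
    naming the spectrum.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = {"auto": _sniff_sep(path), "csv": ",", "tsv": "\t"}.get(format)
    if sep is None:
        raise ValueError(f"unsupported format {format!r}; use 'auto', 'csv' or 'tsv'")
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(SPECTRA_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")

    for col in ("replicate", "fixed_wavelength_nm", "wavelength_nm", "intensity_au"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & (df[col].str.len() > 0)
        if df[col].str.len().eq(0).any():
            bad |= df[col].str.len().eq(0)
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = converted

    spectra: list[Spectrum] = []
    keys = ["sample_id", "mode", "fixed_wavelength_nm", "replicate"]
    for (sample_id, mode, fixed_wl, rep), sub in df.groupby(keys, sort=False):
        group = sub["group"].iloc[0] or None
        spectra.append(
            Spectrum(
                wavelengths_nm=sub["wavelength_nm"].to_numpy(),
                intensities_au=sub["intensity_au"].to_numpy(),
                mode=str(mode),
                fixed_wavelength_nm=float(fixed_wl),
                sample_id=str(sample_id),
                group=group,
                replicate_index=int(rep),
                permissive=permissive,
            )
        )
    counts = pd.Series([f"{s.sample_id}/{s.condition}" for s in spectra]).value_counts()
    logger.info(
        "read %d spectra from %s (%d sample/condition series, replicates %s)",
        len(spectra),
        path,
        len(counts),
        dict(counts.head(10)),
    )
    return spectra


def write_spectra(spectra: Iterable[Spectrum], path, sep: str = ",") -> None:
    """Write spectra to a long-format delimited table (re-readable round trip)."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to write")
    frames = []
    for s in spectra:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": s.sample_id,
                    "group": s.group or "",
                    "replicate": s.replicate_index,
                    "mode": s.mode,
                    "fixed_wavelength_nm": s.fixed_wavelength_nm,
                    "wavelength_nm": s.wavelengths_nm,
                    "intensity_au": s.intensities_au,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep=sep, index=False, float_format=_FLOAT_FMT
    )


# ---------------------------------------------------------------------------
# Tidy results tables
# ---------------------------------------------------------------------------

def _fit_rows(fit) -> tuple[list[dict], list[dict]]:
    """Fraction and absolute-contribution rows for one FitResult."""
    frac_rows, abs_rows = [], []
    positive = set(fit.library.positive_names())
    for name in fit.library.names:
        frac_rows.append(
            {
                "sample_id": fit.sample_id,
                "condition": fit.condition,
                "band": name,
                "amplitude_au": fit.amplitudes[name],
                "area_au_nm": fit.band_areas[name],
                "fraction_pct": fit.fractions_pct.get(name, np.nan),
                "r_squared": fit.r_squared,
                "converged": fit.converged,
            }
        )
        if name in positive:
            abs_rows.append(
                {
                    "sample_id": fit.sample_id,
                    "condition": fit.condition,
                    "band": name,
                    "absolute_af": fit.fractions_pct[name] / 100.0 * fit.scale,
                    "amplitude_metric": "peak_intensity",
                    "measured_amplitude_au": fit.scale,
                }
            )
    return frac_rows, abs_rows


def write_results(results, path) -> dict[str, Path]:
    """Write fit results and marker statistics as tidy delimited tables.

    ``results`` is either a ``StudyResult`` (from
    :func:`serafluor.cohort_stats.run_study`) or an iterable of result
    objects (``FitResult``, ``BilirubinResult``, ``AlbuminResult``,
    ``GroupComparison``).  One CSV per non-empty result family is written
    under ``path`` (a directory, created if needed): ``fractions.csv``,
    ``absolute.csv``, ``markers.csv``, ``group_stats.csv`` and, for a study,
    ``per_animal.csv``.  Returns the mapping family → file path.
    """
    from .cohort_stats import StudyResult  # local import to avoid a cycle

    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)

    tables: dict[str, pd.DataFrame] = {}
    if isinstance(results, StudyResult):
        tables["per_animal"] = results.per_animal
        tables["group_stats"] = results.group_stats
        items: list = list(results.fits.values())
    else:
        items = list(results)
    if not isinstance(results, StudyResult) and not items:
        raise ValueError("no results to write")

    frac_rows: list[dict] = []
    abs_rows: list[dict] = []
    marker_rows: list[dict] = []
    stat_rows: list[dict] = []
    for item in items:
        kind = type(item).__name__
        if kind == "FitResult":
            fr, ar = _fit_rows(item)
            frac_rows.extend(fr)
            abs_rows.extend(ar)
        elif kind == "BilirubinResult":
            marker_rows.append(
                {
                    "sample_id": item.fit.sample_id,
                    "parameter": "bilirubin_fraction_pct",
                    "value": item.bilirubin_fraction_pct,
                }
            )
            if item.ratio_long_short is not None:
                marker_rows.append(
                    {
                        "sample_id": item.fit.sample_id,
                        "parameter": "ratio_long_short",
                        "value": item.ratio_long_short,
                    }
                )
        elif kind == "AlbuminResult":
            marker_rows.append(
                {
                    "sample_id": getattr(item, "sample_id", ""),
                    "parameter": "albumin_af",
                    "value": item.albumin_af,
                }
            )
        elif kind == "GroupComparison":
            stat_rows.extend(item.to_rows())
        else:
            raise TypeError(f"cannot serialize result of type {kind}")

    if frac_rows:
        tables["fractions"] = pd.DataFrame(frac_rows)
    if abs_rows:
        tables["absolute"] = pd.DataFrame(abs_rows)
    if marker_rows:
        tables["markers"] = pd.DataFrame(marker_rows)
    if stat_rows:
        tables.setdefault("group_stats", pd.DataFrame(stat_rows))

    written: dict[str, Path] = {}
    for family, df in tables.items():
        target = outdir / f"{family}.csv"
        df.to_csv(target, index=False, float_format=_FLOAT_FMT)
        written[family] = target
        logger.info("wrote %d %s rows to %s", len(df), family, target)
    return written
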