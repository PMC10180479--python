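"""Derived serum biomarkers: bilirubin contribution and ratio, albumin readout.

Bilirubin is read from the 570 nm-detected excitation spectrum in two ways:

* the summed percentage contribution of the three bilirubin bands
  (400/435/470 nm) in the band-library fit, and
* the excitation-profile ratio (Σ intensity > 407 nm) / (Σ intensity in
  404–407 nm), a direct, fit-free profile parameter sensitive to the
  molecular environment of the bilirubin bi-chromophore (albumin binding).

Albumin is read as the mean emission intensity in a 340 ± 10 nm window under
280 nm excitation, its most selective detection condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .spectra_io import Spectrum
from .unmixing import FitResult

__all__ = [
    "RatioTerms",
    "BilirubinResult",
    "AlbuminResult",
    "bilirubin_ratio",
    "bilirubin_contribution",
    "albumin_af",
    "BILIRUBIN_BANDS",
]

BILIRUBIN_BANDS = ("bilirubin_400", "bilirubin_435", "bilirubin_470")

#: Ratio windows: closed denominator, strictly-greater numerator (grid-point sums).
RATIO_DENOM_NM = (404.0, 407.0)
RATIO_NUMER_ABOVE_NM = 407.0


class RatioTerms(NamedTuple):
    ratio: float
    numerator: float
    denominator: float


@dataclass(frozen=True)
class BilirubinResult:
    """Bilirubin readouts from one exc570 spectrum/fit pair."""

    bilirubin_fraction_pct: float
    ratio_long_short: float | None
    fit: FitResult


@dataclass(frozen=True)
class AlbuminResult:
    """Mean albumin emission intensity over the readout window."""

    albumin_af: float
    window_nm: tuple[float, float]
    sample_id: str = ""


def bilirubin_ratio(spectrum: Spectrum) -> RatioTerms:
    """Excitation-profile ratio (Σ > 407 nm) / (Σ 404–407 nm).

    Sums intensities over grid points: the denominator over the closed
    interval [404, 407] nm, the numerator over points strictly above 407 nm.
    Requires an excitation spectrum detected at 570 nm whose grid covers both
    windows; a non-positive denominator is an error.  Invariant under
    rescaling of the spectrum.
    """
    if spectrum.condition != "exc570":
        raise ValueError(
            f"bilirubin ratio requires an exc570 spectrum, got {spectrum.condition!r}"
        )
    wl = spectrum.wavelengths_nm
    lo, hi = RATIO_DENOM_NM
    if wl[0] > lo or wl[-1] <= RATIO_NUMER_ABOVE_NM:
        raise ValueError("spectrum grid does not cover the 404-407 nm and >407 nm windows")
    den_mask = (wl >= lo) & (wl <= hi)
    num_mask = wl > RATIO_NUMER_ABOVE_NM
    if not den_mask.any():
        raise ValueError("no grid points fall inside the 404-407 nm denominator window")
    numerator = float(np.sum(spectrum.intensities_au[num_mask]))
    denominator = float(np.sum(spectrum.intensities_au[den_mask]))
    if denominator <= 0:
        raise ValueError(f"ratio denominator must be > 0, got {denominator}")
    return RatioTerms(numerator / denominator, numerator, denominator)


def bilirubin_contribution(fit: FitResult, spectrum: Spectrum | None = None) -> BilirubinResult:
    """Summed percentage contribution of the three bilirubin bands.

    ``fit`` must be a converged exc570 fit containing the 400/435/470 nm
    bilirubin bands.  When the measured spectrum is also given, the
    long/short excitation ratio is computed on it as well.
    """
    if fit.condition != "exc570":
        raise ValueError(f"bilirubin contribution requires an exc570 fit, got {fit.condition!r}")
    if not fit.converged:
        raise ValueError("bilirubin contribution requires a converged fit")
    missing = [b for b in BILIRUBIN_BANDS if b not in fit.fractions_pct]
    if missing:
        raise ValueError(f"fit is missing bilirubin bands: {missing}")
    fraction = float(sum(fit.fractions_pct[b] for b in BILIRUBIN_BANDS))
    ratio = bilirubin_ratio(spectrum).ratio if spectrum is not None else None
    return BilirubinResult(bilirubin_fraction_pct=fraction, ratio_long_short=ratio, fit=fit)


def albumin_af(
    spectrum: Spectrum,
    center_nm: float = 340.0,
    half_width_nm: float = 10.0,
) -> AlbuminResult:
    """Mean emission intensity in the albumin window (default 340 ± 10 nm).

    Requires an emission spectrum excited at 280 nm whose grid contains the
    full window.
    """
    if spectrum.condition != "em280":
        raise ValueError(
            f"albumin readout requires an em280 spectrum, got {spectrum.condition!r}"
        )
    lo, hi = center_nm - half_width_nm, center_nm + half_width_nm
    wl = spectrum.wavelengths_nm
    if wl[0] > lo or wl[-1] < hi:
        raise ValueError(
            f"window [{lo}, {hi}] nm lies outside the recorded grid "
            f"[{wl[0]}, {wl[-1]}] nm"
        )
    mask = (wl >= lo) & (wl <= hi)
    value = float(np.mean(spectrum.intensities_au[mask]))
    return AlbuminResult(albumin_af=value, window_nm=(lo, hi), sample_id=spectrum.sample_id)
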