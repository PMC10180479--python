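"""Half-Gaussian Modified Gaussian (GMG) peak shapes and fluorophore band libraries.

Measured serum autofluorescence spectra are modelled as additive mixtures of
fixed fluorophore bands.  Each band is a GMG profile: the convolution of a
Gaussian of width ``sigma_g`` with a one-sided half-Gaussian of width
``sigma_h``.  The convolution has a closed form — a skew-normal-type
expression ``f(x) ∝ φ(z) Φ(a z)`` with ``a = sigma_h / sigma_g`` — which this
module evaluates directly.  At asymmetry ``a = 0`` the shape is exactly
Gaussian.

A band is specified by the wavelength of its maximum (``center_nm``), its
full width at half maximum (``fwhm_nm``) and the asymmetry ratio.  Internal
location/scale parameters are calibrated numerically from those three
quantities, so the rendered peak always tops out at ``center_nm`` and has the
requested composite FWHM for any asymmetry.

The shipped band libraries fix, per acquisition condition, the centre
wavelength and FWHM of every fluorophore as established from
reference-compound profiles:

* ``em310`` / ``em366`` — emission spectra (390–600 nm) excited at 310 or
  366 nm: retinol and the fluorescing fatty acids (arachidonic, oleic,
  linoleic), a free protein band, a minor "undefined" ~440 nm band, an
  optional ~560 nm band (366 nm only) and a negative hemoglobin-absorption
  dip at ~410 nm.
* ``exc570`` — excitation spectra (300–540 nm) detected at 570 nm: a dominant
  330 nm band plus the three bilirubin bands at 400/435/470 nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import ndtr

__all__ = [
    "BandShape",
    "BandLibrary",
    "gmg_profile",
    "gmg_unit_area",
    "default_library",
    "model_spectrum",
    "library_to_yaml",
    "library_from_yaml",
    "CONDITIONS",
]

CONDITIONS = ("em310", "em366", "exc570")

_SQRT2PI = math.sqrt(2.0 * math.pi)
#: FWHM of a unit-sigma Gaussian.
GAUSSIAN_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


def _phi(z: float | np.ndarray) -> float | np.ndarray:
    return np.exp(-0.5 * np.square(z)) / _SQRT2PI


@lru_cache(maxsize=None)
def _calibrate(asym: float) -> tuple[float, float, float]:
    """Unit-scale shape constants for a given asymmetry ratio.

    Returns ``(z_mode, fwhm_z, peak_value)`` of the un-normalised shape
    ``f(z) = φ(z) Φ(asym · z)`` on the standardised axis: the position of the
    maximum, the full width at half maximum and the value at the maximum.
    """
    if asym == 0.0:
        return 0.0, GAUSSIAN_FWHM_FACTOR, float(_phi(0.0)) * 0.5

    def dlog(z: float) -> float:
        return -z + asym * float(_phi(asym * z)) / float(ndtr(asym * z))

    z_mode = brentq(dlog, 0.0, 10.0 + 10.0 * asym, xtol=1e-14)
    peak = float(_phi(z_mode)) * float(ndtr(asym * z_mode))

    def half(z: float) -> float:
        return float(_phi(z)) * float(ndtr(asym * z)) - 0.5 * peak

    z_lo = brentq(half, z_mode - 20.0, z_mode, xtol=1e-13)
    z_hi = brentq(half, z_mode, z_mode + 20.0, xtol=1e-13)
    return float(z_mode), float(z_hi - z_lo), peak


@dataclass(frozen=True)
class BandShape:
    """One GMG component of a band library.

    ``center_nm`` is the wavelength of the rendered maximum, ``fwhm_nm`` the
    composite full width at half maximum and ``asymmetry`` the half-Gaussian
    to Gaussian width ratio (0 = symmetric Gaussian).  ``sign`` is
    ``"negative"`` only for the hemoglobin-absorption dip.  ``center_free`` /
    ``width_free`` mark shape parameters to be fitted (the protein band);
    their search boxes are ``center_bounds`` / ``fwhm_bounds``.
    """

    name: str
    center_nm: float
    fwhm_nm: float
    asymmetry: float = 0.0
    sign: str = "positive"
    center_free: bool = False
    width_free: bool = False
    amplitude_bounds: tuple[float, float] = (0.0, math.inf)
    center_bounds: tuple[float, float] | None = None
    fwhm_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.fwhm_nm > 0:
            raise ValueError(f"band {self.name!r}: fwhm_nm must be > 0, got {self.fwhm_nm}")
        if self.asymmetry < 0:
            raise ValueError(f"band {self.name!r}: asymmetry must be >= 0")
        if self.sign not in ("positive", "negative"):
            raise ValueError(f"band {self.name!r}: sign must be 'positive' or 'negative'")
        if self.sign == "negative" and "hemoglobin" not in self.name:
            raise ValueError(
                "a negative sign is reserved for the hemoglobin-absorption band; "
                f"got negative band {self.name!r}"
            )
        lo, hi = self.amplitude_bounds
        if not lo <= hi:
            raise ValueError(f"band {self.name!r}: amplitude_bounds must be ordered")
        if self.center_free and self.center_bounds is None:
            raise ValueError(f"band {self.name!r}: center_free requires center_bounds")
        if self.width_free and self.fwhm_bounds is None:
            raise ValueError(f"band {self.name!r}: width_free requires fwhm_bounds")


def gmg_profile(
    wavelengths: Sequence[float] | np.ndarray,
    band: BandShape,
    amplitude: float,
) -> np.ndarray:
    """Evaluate one GMG band on a wavelength grid.

    The returned curve peaks at ``band.center_nm`` with value ``amplitude``
    and has full width ``band.fwhm_nm`` at half of that value.

    Raises ``ValueError`` when the amplitude sign contradicts the band sign.
    """
    if band.sign == "positive" and amplitude < 0:
        raise ValueError(f"band {band.name!r} is positive but amplitude {amplitude} < 0")
    if band.sign == "negative" and amplitude > 0:
        raise ValueError(f"band {band.name!r} is negative but amplitude {amplitude} > 0")
    wl = np.asarray(wavelengths, dtype=float)
    z_mode, fwhm_z, _peak = _calibrate(float(band.asymmetry))
    omega = band.fwhm_nm / fwhm_z
    z = (wl - band.center_nm) / omega + z_mode
    a = band.asymmetry
    shape = np.exp(-0.5 * (z * z - z_mode * z_mode))
    if a > 0:
        shape *= ndtr(a * z) / ndtr(a * z_mode)
    return amplitude * shape


def _gmg_with_shape_grad(
    wl: np.ndarray, band: BandShape, amplitude: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Band values plus analytic derivatives w.r.t. center_nm and fwhm_nm.

    Used by the fitter for the free protein band.  With
    ``z = (λ - c)·fwhm_z/F + z_mode`` the chain rule gives
    ``∂s/∂c = s·q·(−fwhm_z/F)`` and ``∂s/∂F = s·q·(−(z−z_mode)/F)`` where
    ``q = d log s/dz = −z + a φ(az)/Φ(az)``.
    """
    z_mode, fwhm_z, _peak = _calibrate(float(band.asymmetry))
    omega = band.fwhm_nm / fwhm_z
    z = (wl - band.center_nm) / omega + z_mode
    a = band.asymmetry
    shape = np.exp(-0.5 * (z * z - z_mode * z_mode))
    if a > 0:
        shape *= ndtr(a * z) / ndtr(a * z_mode)
        q = -z + a * _phi(a * z) / np.maximum(ndtr(a * z), 1e-300)
    else:
        q = -z
    s = amplitude * shape
    d_center = s * q * (-1.0 / omega)
    d_fwhm = s * q * (-(z - z_mode) / band.fwhm_nm)
    return s, d_center, d_fwhm


def gmg_unit_area(band: BandShape) -> float:
    """Analytic area (a.u.·nm) under the band at unit peak amplitude."""
    z_mode, fwhm_z, peak = _calibrate(float(band.asymmetry))
    omega = band.fwhm_nm / fwhm_z
    # ∫ φ(z)Φ(az) dz = 1/2; peak-normalising divides by the unit-scale peak.
    return omega * 0.5 / peak


@dataclass(frozen=True)
class BandLibrary:
    """The named set of band shapes valid for one acquisition condition."""

    condition: str
    bands: tuple[BandShape, ...]

    def __post_init__(self) -> None:
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate band names in library: {names}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    def band(self, name: str) -> BandShape:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(f"no band named {name!r} in {self.condition} library")

    def positive_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands if b.sign == "positive")

    def without(self, *names: str) -> "BandLibrary":
        """A copy of the library with the named bands removed."""
        missing = set(names) - set(self.names)
        if missing:
            raise KeyError(f"bands not in library: {sorted(missing)}")
        return BandLibrary(self.condition, tuple(b for b in self.bands if b.name not in names))

    def with_fixed_shapes(self) -> "BandLibrary":
        """A copy with every free center/width flag cleared (shapes frozen at defaults)."""
        return BandLibrary(
            self.condition,
            tuple(replace(b, center_free=False, width_free=False) for b in self.bands),
        )


def _protein_band(default_center: float, default_fwhm: float) -> BandShape:
    # The protein band is left free to adapt its profile within fixed boxes.
    return BandShape(
        name="protein",
        center_nm=default_center,
        fwhm_nm=default_fwhm,
        center_free=True,
        width_free=True,
        center_bounds=(360.0, 420.0),
        fwhm_bounds=(30.0, 120.0),
    )


def _hemoglobin_band() -> BandShape:
    # Negative absorption dip from residual hemolysis, peak near 410 nm.
    return BandShape(
        name="hemoglobin",
        center_nm=410.0,
        fwhm_nm=20.0,
        sign="negative",
        amplitude_bounds=(-math.inf, 0.0),
    )


_DEFAULT_LIBRARIES: dict[str, tuple[BandShape, ...]] = {
    # Emission excited at 310 nm: reference-compound (λ, FWHM) pairs.
    "em310": (
        _protein_band(400.0, 80.0),
        BandShape("oleic", 370.0, 85.0),
        BandShape("linoleic", 417.0, 92.0),
        BandShape("arachidonic", 425.0, 120.0),
        BandShape("undefined", 440.0, 40.0),
        BandShape("retinol", 490.0, 112.0),
        _hemoglobin_band(),
    ),
    # Emission excited at 366 nm.
    "em366": (
        _protein_band(400.0, 70.0),
        BandShape("linoleic", 428.0, 73.0),
        BandShape("undefined", 440.0, 40.0),
        BandShape("oleic", 462.0, 90.0),
        BandShape("arachidonic", 470.0, 93.0),
        BandShape("retinol", 490.0, 112.0),
        BandShape("band560", 560.0, 50.0),
        _hemoglobin_band(),
    ),
    # Excitation detected at 570 nm: dominant short-wavelength tail band plus
    # the three bilirubin bands.
    "exc570": (
        BandShape("dominant", 330.0, 60.0),
        BandShape("bilirubin_400", 400.0, 35.0),
        BandShape("bilirubin_435", 435.0, 40.0),
        BandShape("bilirubin_470", 470.0, 70.0),
    ),
}

#: Bands fitted as minor auxiliary curves, subject to the area budget.
MINOR_BANDS = ("undefined", "band560", "hemoglobin")


def default_library(condition: str) -> BandLibrary:
    """The shipped band library for one acquisition condition.

    ``condition`` is one of ``em310``, ``em366`` or ``exc570``.
    """
    try:
        bands = _DEFAULT_LIBRARIES[condition]
    except KeyError:
        raise ValueError(
            f"unknown acquisition condition {condition!r}; expected one of {CONDITIONS}"
        ) from None
    return BandLibrary(condition=condition, bands=bands)


def model_spectrum(
    library: BandLibrary,
    amplitudes: Mapping[str, float],
    wavelengths: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Pointwise sum of the library bands at the given amplitudes.

    Linear in every amplitude; amplitudes for band names not in the library
    raise ``KeyError``.
    """
    wl = np.asarray(wavelengths, dtype=float)
    unknown = set(amplitudes) - set(library.names)
    if unknown:
        raise KeyError(f"amplitudes given for unknown bands: {sorted(unknown)}")
    total = np.zeros_like(wl)
    for band in library.bands:
        amp = amplitudes.get(band.name, 0.0)
        if amp != 0.0:
            total += gmg_profile(wl, band, amp)
    return total


# ---------------------------------------------------------------------------
# Library serialization
# ---------------------------------------------------------------------------

def _band_to_dict(band: BandShape) -> dict:
    d = {
        "name": band.name,
        "center_nm": band.center_nm,
        "fwhm_nm": band.fwhm_nm,
        "asymmetry": band.asymmetry,
        "sign": band.sign,
        "center_free": band.center_free,
        "width_free": band.width_free,
        "amplitude_bounds": [
            None if math.isinf(b) else float(b) for b in band.amplitude_bounds
        ],
    }
    if band.center_bounds is not None:
        d["center_bounds"] = list(band.center_bounds)
    if band.fwhm_bounds is not None:
        d["fwhm_bounds"] = list(band.fwhm_bounds)
    return d


def _band_from_dict(d: Mapping) -> BandShape:
    lo, hi = d.get("amplitude_bounds", [0.0, None])
    sign = d.get("sign", "positive")
    lo = -math.inf if lo is None else float(lo)
    hi = math.inf if hi is None else float(hi)
    return BandShape(
        name=d["name"],
        center_nm=float(d["center_nm"]),
        fwhm_nm=float(d["fwhm_nm"]),
        asymmetry=float(d.get("asymmetry", 0.0)),
        sign=sign,
        center_free=bool(d.get("center_free", False)),
        width_free=bool(d.get("width_free", False)),
        amplitude_bounds=(lo, hi),
        center_bounds=tuple(d["center_bounds"]) if "center_bounds" in d else None,
        fwhm_bounds=tuple(d["fwhm_bounds"]) if "fwhm_bounds" in d else None,
    )


def library_to_yaml(library: BandLibrary, path) -> None:
    """Write a band library to a YAML file (documented schema)."""
    doc = {
        "condition": library.condition,
        "bands": [_band_to_dict(b) for b in library.bands],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def library_from_yaml(path) -> BandLibrary:
    """Read a band library from a YAML file written by :func:`library_to_yaml`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return BandLibrary(
        condition=doc["condition"],
        bands=tuple(_band_from_dict(b) for b in doc["bands"]),
    )
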