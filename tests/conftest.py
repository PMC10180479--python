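"""Shared fixtures and independent oracles for the serafluor test suite."""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

import serafluor as sf
from serafluor.synthetic_data import GRIDS

DATA_DIR = Path(__file__).parent / "data"


# ---------------------------------------------------------------------------
# Independent peak-shape oracle
# ---------------------------------------------------------------------------

def gmg_convolution_oracle(
    wavelengths,
    center_nm: float,
    fwhm_nm: float,
    asymmetry: float,
    amplitude: float = 1.0,
    step: float = 0.01,
) -> np.ndarray:
    """Brute-force Gaussian ⊛ one-sided half-Gaussian peak shape.

    Convolves a unit Gaussian with a half-Gaussian of relative width
    ``asymmetry`` numerically on a fine grid, then shifts/scales the result
    so its maximum sits at ``center_nm`` with the requested composite FWHM
    and peak value ``amplitude``.  Entirely independent of the closed-form
    implementation under test.
    """
    from scipy.interpolate import CubicSpline
    from scipy.optimize import brentq, minimize_scalar

    wl = np.asarray(wavelengths, dtype=float)
    if asymmetry == 0:
        sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return amplitude * np.exp(-0.5 * ((wl - center_nm) / sigma) ** 2)

    x = np.arange(-12.0, 12.0 + step, step)
    g = np.exp(-0.5 * x * x)
    t = np.arange(0.0, 12.0 * asymmetry + step, step)
    h = np.exp(-0.5 * (t / asymmetry) ** 2)
    h[0] *= 0.5  # trapezoid weight at the half-Gaussian edge
    conv = np.convolve(g, h) * step
    xc = x[0] + t[0] + np.arange(conv.size) * step
    spline = CubicSpline(xc, conv)

    i = int(np.argmax(conv))
    mode = minimize_scalar(
        lambda z: -float(spline(z)), bracket=(xc[i - 1], xc[i], xc[i + 1])
    ).x
    peak = float(spline(mode))
    lo = brentq(lambda z: float(spline(z)) - 0.5 * peak, xc[0], mode)
    hi = brentq(lambda z: float(spline(z)) - 0.5 * peak, mode, xc[-1])
    scale = fwhm_nm / (hi - lo)

    z = mode + (wl - center_nm) / scale
    inside = (z >= xc[0]) & (z <= xc[-1])
    out = np.zeros_like(wl)
    out[inside] = spline(z[inside]) / peak
    return amplitude * out


def gaussian_band_sum(wl: np.ndarray, bands: dict[str, tuple[float, float, float]]) -> np.ndarray:
    """Independent additive-Gaussian evaluation: {name: (amp, center, fwhm)}."""
    wl = np.asarray(wl, float)
    total = np.zeros_like(wl)
    for amp, center, fwhm in bands.values():
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        total += amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    return total


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def printed_bands() -> dict:
    with open(DATA_DIR / "printed_bands.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def quiet_profiles() -> dict[str, sf.GroupProfile]:
    """Default group profiles with all variability and noise switched off."""
    return {
        g: replace(p, between_animal_cv=0.0, replicate_cv=0.0, noise_sd_au=0.0)
        for g, p in sf.default_profiles().items()
    }


@pytest.fixture(scope="session")
def em_grid() -> np.ndarray:
    return GRIDS["em310"].copy()


@pytest.fixture(scope="session")
def exc_grid() -> np.ndarray:
    return GRIDS["exc570"].copy()


def make_spectrum(grid, intensities, condition="em310", sample_id="s", **kw) -> sf.Spectrum:
    mode, fixed = {
        "em310": ("emission", 310.0),
        "em366": ("emission", 366.0),
        "exc570": ("excitation", 570.0),
        "em280": ("emission", 280.0),
    }[condition]
    return sf.Spectrum(
        wavelengths_nm=np.asarray(grid, float),
        intensities_au=np.asarray(intensities, float),
        mode=mode,
        fixed_wavelength_nm=fixed,
        sample_id=sample_id,
        **kw,
    )


def make_fit_result(
    library: sf.BandLibrary,
    band_areas: dict[str, float],
    fractions_pct: dict[str, float] | None = None,
    converged: bool = True,
    scale: float = 100.0,
) -> sf.FitResult:
    """Hand-constructed FitResult for tests of downstream arithmetic."""
    areas = {name: band_areas.get(name, 0.0) for name in library.names}
    if fractions_pct is None:
        pos = library.positive_names()
        total = sum(areas[n] for n in pos)
        fractions_pct = {n: 100.0 * areas[n] / total for n in pos} if total > 0 else {}
    return sf.FitResult(
        condition=library.condition,
        amplitudes={n: 0.0 for n in library.names},
        free_params={},
        band_areas=areas,
        fractions_pct=fractions_pct,
        r_squared=1.0,
        residuals=np.zeros(3),
        rms_residual=0.0,
        lag1_autocorr=float("nan"),
        converged=converged,
        n_iterations=1,
        cost=0.0,
        scale=scale,
        condition_number=1.0,
        library=library,
        sample_id="fixture",
    )
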