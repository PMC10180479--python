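"""Constrained least-squares unmixing of a spectrum into its band library.

The measured spectrum is first peak-normalized to 100 a.u., then decomposed
into the fixed GMG band library by bounded nonlinear least squares
(trust-region Levenberg-Marquardt-type, multistart over amplitude
initializations).  Fluorophore amplitudes are constrained non-negative, the
hemoglobin-absorption amplitude non-positive, and the free protein-band
center/width stay inside their boxes.  Per-band areas are integrated
analytically and expressed as percentages of the summed positive-band area;
the stored pre-normalization peak lets percentages be converted back into
absolute autofluorescence values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .band_model import (
    MINOR_BANDS,
    BandLibrary,
    BandShape,
    _gmg_with_shape_grad,
    gmg_profile,
    gmg_unit_area,
)
from .spectra_io import Spectrum

logger = logging.getLogger("serafluor")

__all__ = [
    "FitOptions",
    "FitResult",
    "AbsoluteContribution",
    "DegenerateSpectrumError",
    "normalize_peak",
    "fit_spectrum",
    "goodness_of_fit",
    "area_fractions",
    "absolute_contributions",
    "check_minor_band_budget",
    "MINOR_BAND_BUDGET_PCT",
]

#: Maximum spectral-area share (percent) the minor auxiliary curves may cover.
MINOR_BAND_BUDGET_PCT = {"em310": 10.0, "em366": 3.0}


class DegenerateSpectrumError(ValueError):
    """The spectrum cannot be normalized or fitted (e.g. non-positive maximum)."""


@dataclass(frozen=True)
class FitOptions:
    """Options controlling :func:`fit_spectrum`.

    ``n_starts`` multistart amplitude initializations guard against local
    minima when free shape parameters are present; with all shapes fixed the
    problem is convex and a single start is used.  ``free_shapes=False``
    freezes every free center/width at its library default (useful for
    linear-recovery checks).  ``fraction_denominator`` selects the
    percentage denominator: the summed fitted positive-component area
    (default, self-normalizing) or the trapezoidal area of the measured
    spectrum.
    """

    auto_normalize: bool = True
    normalize_target: float = 100.0
    n_starts: int = 8
    seed: int = 0
    free_shapes: bool = True
    max_nfev: int = 2000
    ftol: float = 1e-10
    xtol: float = 1e-8
    fraction_denominator: str = "component_sum"  # or "measured_area"

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.fraction_denominator not in ("component_sum", "measured_area"):
            raise ValueError("fraction_denominator must be 'component_sum' or 'measured_area'")


@dataclass
class FitResult:
    """Outcome of fitting one spectrum against one band library."""

    condition: str
    amplitudes: dict[str, float]
    free_params: dict[str, dict[str, float]]
    band_areas: dict[str, float]
    fractions_pct: dict[str, float]
    r_squared: float
    residuals: np.ndarray
    rms_residual: float
    lag1_autocorr: float
    converged: bool
    n_iterations: int
    cost: float
    scale: float
    condition_number: float
    library: BandLibrary = field(repr=False)
    sample_id: str = ""
    normalize_target: float = 100.0

    def amplitudes_measured_scale(self) -> dict[str, float]:
        """Fitted amplitudes mapped back to the pre-normalization scale."""
        factor = self.scale / self.normalize_target
        return {k: v * factor for k, v in self.amplitudes.items()}


@dataclass(frozen=True)
class AbsoluteContribution:
    """A band's percentage contribution re-expressed on the measured scale."""

    band: str
    absolute_af: float
    amplitude_metric: str


def normalize_peak(spectrum: Spectrum, target: float = 100.0) -> tuple[Spectrum, float]:
    """Scale a spectrum so its maximum equals ``target`` (default 100 a.u.).

    Returns the normalized spectrum and the original peak value, kept for the
    later reconstruction of absolute contributions.
    """
    peak = float(np.max(spectrum.intensities_au))
    if not peak > 0:
        raise DegenerateSpectrumError(
            f"spectrum {spectrum.sample_id!r}: maximum must be strictly positive to normalize"
        )
    scaled = (spectrum.intensities_au / peak) * target
    return spectrum.with_intensities(scaled), peak


def goodness_of_fit(measured: Spectrum | np.ndarray, fitted: Sequence[float]) -> dict[str, float]:
    """Coefficient of determination plus residual diagnostics.

    Returns ``r_squared`` (1 − SS_res/SS_tot), ``rms_residual`` and the
    lag-1 autocorrelation of the residuals (a residual-structure indicator;
    NaN when the residuals have zero variance).
    """
    y = measured.intensities_au if isinstance(measured, Spectrum) else np.asarray(measured, float)
    f = np.asarray(fitted, float)
    if y.shape != f.shape:
        raise ValueError("measured and fitted must have equal length")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r^2 undefined for a zero-variance measured spectrum")
    res = y - f
    ss_res = float(np.sum(res**2))
    c = res - res.mean()
    denom = float(np.sum(c**2))
    lag1 = float(np.sum(c[:-1] * c[1:]) / denom) if denom > 0 else math.nan
    return {
        "r_squared": 1.0 - ss_res / ss_tot,
        "rms_residual": float(np.sqrt(np.mean(res**2))),
        "lag1_autocorr": lag1,
    }


def _effective_bands(library: BandLibrary, options: FitOptions) -> list[BandShape]:
    if options.free_shapes:
        return list(library.bands)
    return list(library.with_fixed_shapes().bands)


def _design_matrix(wl: np.ndarray, bands: Sequence[BandShape]) -> np.ndarray:
    cols = [gmg_profile(wl, band, 1.0 if band.sign == "positive" else -1.0) for band in bands]
    return np.column_stack(cols)


def fit_spectrum(
    spectrum: Spectrum,
    library: BandLibrary,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit the band library to a spectrum by bounded least squares.

    Minimizes the sum of squared deviations between the additive band model
    and the (peak-normalized) intensities.  The returned result carries
    fitted amplitudes, analytically integrated per-band areas, percentage
    contributions over the positive bands, goodness-of-fit diagnostics, the
    design-matrix condition number and an honest ``converged`` flag.
    """
    options = options or FitOptions()
    if spectrum.condition != library.condition:
        raise ValueError(
            f"spectrum condition {spectrum.condition!r} does not match "
            f"library condition {library.condition!r}"
        )
    if options.auto_normalize:
        spec, scale = normalize_peak(spectrum, options.normalize_target)
    else:
        spec, scale = spectrum, float(np.max(spectrum.intensities_au))
    wl = spec.wavelengths_nm
    y = spec.intensities_au
    bands = _effective_bands(library, options)
    n_bands = len(bands)

    # Parameter vector: one amplitude per band, then (center, fwhm) per free band.
    shape_slots: list[tuple[int, str]] = []  # (band index, 'center'|'fwhm')
    lo = np.empty(n_bands)
    hi = np.empty(n_bands)
    for i, b in enumerate(bands):
        blo, bhi = b.amplitude_bounds
        if b.sign == "negative":
            blo, bhi = min(blo, 0.0), min(bhi, 0.0)
        else:
            blo = max(blo, 0.0)
        lo[i], hi[i] = blo, bhi
    extra_lo: list[float] = []
    extra_hi: list[float] = []
    for i, b in enumerate(bands):
        if b.center_free:
            shape_slots.append((i, "center"))
            extra_lo.append(b.center_bounds[0])
            extra_hi.append(b.center_bounds[1])
        if b.width_free:
            shape_slots.append((i, "fwhm"))
            extra_lo.append(b.fwhm_bounds[0])
            extra_hi.append(b.fwhm_bounds[1])
    lower = np.concatenate([lo, extra_lo]) if shape_slots else lo
    upper = np.concatenate([hi, extra_hi]) if shape_slots else hi
    n_shape = len(shape_slots)
    linear = n_shape == 0

    def unpack(p: np.ndarray) -> list[BandShape]:
        if linear:
            return bands
        current = list(bands)
        for k, (i, which) in enumerate(shape_slots):
            b = current[i]
            val = float(p[n_bands + k])
            if which == "center":
                current[i] = _dc_replace(b, center_nm=val)
            else:
                current[i] = _dc_replace(b, fwhm_nm=val)
        return current

    def model_and_jac(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        current = unpack(p)
        jac = np.zeros((len(wl), len(p)))
        total = np.zeros_like(wl)
        grads: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        free_idx = {i for i, _ in shape_slots}
        for i, b in enumerate(current):
            if i in free_idx:
                s, d_c, d_f = _gmg_with_shape_grad(wl, b, 1.0)
                grads[i] = (d_c, d_f)
            else:
                s = gmg_profile(wl, b, 1.0 if b.sign == "positive" else -1.0)
                if b.sign == "negative":
                    s = -s  # unit-amplitude column; amplitude itself is signed
            jac[:, i] = s
            total += p[i] * s
        for k, (i, which) in enumerate(shape_slots):
            d_c, d_f = grads[i]
            jac[:, n_bands + k] = p[i] * (d_c if which == "center" else d_f)
        return total, jac

    def residual(p: np.ndarray) -> np.ndarray:
        total, _ = model_and_jac(p)
        return total - y

    def jacobian(p: np.ndarray) -> np.ndarray:
        _, jac = model_and_jac(p)
        return jac

    # Multistart initializations (first deterministic, rest seeded random).
    rng = np.random.default_rng(options.seed)
    peak = float(np.max(y))
    n_pos = max(1, sum(1 for b in bands if b.sign == "positive"))
    starts = []
    p0 = np.zeros(n_bands + n_shape)
    for i, b in enumerate(bands):
        p0[i] = peak / n_pos if b.sign == "positive" else -0.01 * peak
    for k, (i, which) in enumerate(shape_slots):
        b = bands[i]
        p0[n_bands + k] = b.center_nm if which == "center" else b.fwhm_nm
    starts.append(np.clip(p0, lower, upper))
    n_starts = 1 if linear else options.n_starts
    for _ in range(n_starts - 1):
        p = np.empty_like(p0)
        for i, b in enumerate(bands):
            p[i] = rng.uniform(0, peak) if b.sign == "positive" else -rng.uniform(0, 0.1 * peak)
        for k in range(n_shape):
            p[n_bands + k] = rng.uniform(extra_lo[k], extra_hi[k])
        starts.append(np.clip(p, lower, upper))

    best = None
    for p_init in starts:
        sol = least_squares(
            residual,
            p_init,
            jac=jacobian,
            bounds=(lower, upper),
            method="trf",
            ftol=options.ftol,
            xtol=options.xtol,
            gtol=1e-12,
            max_nfev=options.max_nfev,
            x_scale="jac",
        )
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    converged = bool(best.success)
    if not converged:
        logger.warning(
            "fit of %s (%s) did not converge after %d starts: %s",
            spectrum.sample_id,
            library.condition,
            n_starts,
            best.message,
        )

    fitted_bands = unpack(best.x)
    amplitudes = {b.name: float(best.x[i]) for i, b in enumerate(fitted_bands)}
    free_params = {}
    for k, (i, which) in enumerate(shape_slots):
        name = fitted_bands[i].name
        free_params.setdefault(name, {})[f"{which}_nm" if which == "center" else "fwhm_nm"] = float(
            best.x[n_bands + k]
        )
    # rename center key for clarity
    free_params = {
        name: {("center_nm" if k.startswith("center") else "fwhm_nm"): v for k, v in d.items()}
        for name, d in free_params.items()
    }
    band_areas = {
        b.name: amplitudes[b.name] * gmg_unit_area(b) for b in fitted_bands
    }
    model = best.fun + y
    gof = goodness_of_fit(y, model)
    fractions = _fractions_from_areas(band_areas, fitted_bands, wl, y, options)
    cond = float(np.linalg.cond(_design_matrix(wl, fitted_bands)))

    return FitResult(
        condition=library.condition,
        amplitudes=amplitudes,
        free_params=free_params,
        band_areas=band_areas,
        fractions_pct=fractions,
        r_squared=gof["r_squared"],
        residuals=np.asarray(best.fun),
        rms_residual=gof["rms_residual"],
        lag1_autocorr=gof["lag1_autocorr"],
        converged=converged,
        n_iterations=int(best.nfev),
        cost=float(best.cost),
        scale=scale,
        condition_number=cond,
        library=library,
        sample_id=spectrum.sample_id,
        normalize_target=options.normalize_target if options.auto_normalize else scale,
    )


def _fractions_from_areas(
    band_areas: Mapping[str, float],
    bands: Sequence[BandShape],
    wl: np.ndarray,
    y: np.ndarray,
    options: FitOptions,
) -> dict[str, float]:
    positive = [b.name for b in bands if b.sign == "positive"]
    pos_total = sum(band_areas[n] for n in positive)
    if not pos_total > 0:
        raise DegenerateSpectrumError("all positive band amplitudes are zero; fractions undefined")
    if options.fraction_denominator == "component_sum":
        denom = pos_total
    else:
        denom = float(np.trapezoid(y, wl))
    return {n: 100.0 * band_areas[n] / denom for n in positive}


def area_fractions(result: FitResult) -> dict[str, float]:
    """Percentage-of-area contributions of the positive bands (sum to 100)."""
    positive = result.library.positive_names()
    total = sum(result.band_areas[n] for n in positive)
    if not total > 0:
        raise DegenerateSpectrumError("all positive band areas are zero; fractions undefined")
    return {n: 100.0 * result.band_areas[n] / total for n in positive}


def absolute_contributions(
    fractions: Mapping[str, float],
    measured_amplitude: float,
    metric: str = "peak_intensity",
) -> list[AbsoluteContribution]:
    """Convert percentage contributions to the measured amplitude scale.

    ``absolute_af = fraction/100 × measured_amplitude`` where the amplitude
    metric is the pre-normalization peak intensity (default) or the spectrum
    integral.
    """
    if metric not in ("peak_intensity", "spectrum_area"):
        raise ValueError("metric must be 'peak_intensity' or 'spectrum_area'")
    if not measured_amplitude > 0:
        raise ValueError("measured_amplitude must be > 0")
    total = sum(fractions.values())
    if abs(total - 100.0) > 1e-6:
        raise ValueError(f"fractions must sum to 100, got {total}")
    return [
        AbsoluteContribution(band=name, absolute_af=f / 100.0 * measured_amplitude,
                             amplitude_metric=metric)
        for name, f in fractions.items()
    ]


def check_minor_band_budget(result: FitResult, condition: str | None = None) -> tuple[bool, float]:
    """Check the auxiliary-curve area budget of an emission fit.

    The undefined, 560 nm and (absolute) hemoglobin band areas may together
    cover at most 10% (em310) or 3% (em366) of the summed positive-band
    area.  Returns ``(ok, share_pct)`` where ``ok`` is False when the share
    exceeds the budget (fit flagged suspect for review).
    """
    condition = condition or result.condition
    try:
        budget = MINOR_BAND_BUDGET_PCT[condition]
    except KeyError:
        raise ValueError(
            f"no minor-band budget defined for condition {condition!r}"
        ) from None
    positive = result.library.positive_names()
    denom = sum(result.band_areas[n] for n in positive)
    if not denom > 0:
        raise DegenerateSpectrumError("no positive band area; budget share undefined")
    minor = sum(abs(result.band_areas[n]) for n in MINOR_BANDS if n in result.band_areas)
    share = 100.0 * minor / denom
    ok = not share > budget
    if not ok:
        logger.warning(
            "%s fit of %s: minor-band share %.2f%% exceeds the %.0f%% budget",
            condition,
            result.sample_id,
            share,
            budget,
        )
    return ok, share
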