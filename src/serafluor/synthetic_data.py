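"""Synthetic serum-autofluorescence cohorts with the assumed statistical structure.

Each cohort emulates a three-group rat study (sham-operated, hepatic
ischemia/reperfusion, I/R + obeticholic acid; 5 animals per group, 10
replicate scans per serum sample and acquisition condition).  Spectra are
additive mixtures of the default band libraries plus a free-protein band, a
negative hemoglobin-absorption dip and Gaussian detector noise, rendered on
the standard scan grids (emission 390–600 nm at 310/366 nm excitation,
excitation 300–540 nm detected at 570 nm, emission 300–450 nm at 280 nm for
albumin).

Abundances are drawn log-normally around group means (multiplicative
between-animal biology), jittered again per replicate, and scaled by a
group-level gain that carries the absolute-amplitude differences between
groups.  The default profiles encode the directional findings the analysis
is meant to detect: overall gain IR > sham > IR+OCA; arachidonic, oleic,
linoleic and bilirubin raised in IR; the retinol share lowered in IR; the
~560 nm band present only in IR 366 nm spectra at <1% of area; albumin
lowered in IR.  Magnitudes themselves are generator choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .band_model import BandLibrary, BandShape, default_library, model_spectrum
from .spectra_io import Spectrum

__all__ = [
    "GroupProfile",
    "CohortSample",
    "default_profiles",
    "generate_cohort",
    "GRIDS",
    "ALBUMIN_BAND",
]

#: Standard scan grids (nm), all at 1 nm step.
GRIDS: dict[str, np.ndarray] = {
    "em310": np.arange(390.0, 601.0),
    "em366": np.arange(390.0, 601.0),
    "exc570": np.arange(300.0, 541.0),
    "em280": np.arange(300.0, 451.0),
}

_CONDITION_META = {
    "em310": ("emission", 310.0),
    "em366": ("emission", 366.0),
    "exc570": ("excitation", 570.0),
    "em280": ("emission", 280.0),
}

#: Single albumin emission band used to render the em280 readout spectra.
ALBUMIN_BAND = BandShape("albumin", 340.0, 60.0)

_ALBUMIN_LIBRARY = BandLibrary("em280", (ALBUMIN_BAND,))


@dataclass(frozen=True)
class GroupProfile:
    """Generating distribution of one experimental group.

    ``mean_abundances`` maps condition → band name → mean amplitude (a.u.,
    before the group gain).  ``between_animal_cv`` and ``replicate_cv`` are
    log-normal coefficients of variation; ``noise_sd_au`` is additive
    Gaussian detector noise; ``hemoglobin_dip_amp`` (≤ 0) is the mean of the
    410 nm absorption dip applied to the emission conditions;
    ``overall_gain`` carries absolute-amplitude differences between groups.
    """

    group: str
    mean_abundances: Mapping[str, Mapping[str, float]]
    between_animal_cv: float = 0.20
    replicate_cv: float = 0.05
    noise_sd_au: float = 1.0
    hemoglobin_dip_amp: float = -1.5
    overall_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.between_animal_cv < 0 or self.replicate_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.noise_sd_au < 0:
            raise ValueError("noise_sd_au must be >= 0")
        if self.hemoglobin_dip_amp > 0:
            raise ValueError("hemoglobin_dip_amp must be <= 0")
        if self.overall_gain <= 0:
            raise ValueError("overall_gain must be > 0")
        for cond, amps in self.mean_abundances.items():
            for band, amp in amps.items():
                if amp < 0:
                    raise ValueError(
                        f"{self.group}/{cond}/{band}: mean abundances must be >= 0"
                    )


@dataclass
class CohortSample:
    """One synthetic animal: generating truth plus its replicate spectra.

    ``true_abundances`` holds the animal-level generating amplitudes
    (condition → band → a.u., gain applied, hemoglobin signed);
    ``replicate_abundances`` additionally records the per-replicate jittered
    amplitudes the individual scans were rendered from.
    """

    sample_id: str
    group: str
    true_abundances: dict[str, dict[str, float]]
    spectra: list[Spectrum] = field(default_factory=list)
    replicate_abundances: dict[str, list[dict[str, float]]] = field(default_factory=dict)

    def spectra_for(self, condition: str) -> list[Spectrum]:
        return [s for s in self.spectra if s.condition == condition]


def default_profiles() -> dict[str, GroupProfile]:
    """Default generating profiles for the sham / IR / IR_OCA groups.

    The means satisfy every directional ordering the analysis tests for;
    see the module docstring.
    """
    sham = GroupProfile(
        group="sham",
        overall_gain=1.0,
        mean_abundances={
            "em310": {"protein": 14.0, "oleic": 9.0, "linoleic": 4.0,
                      "arachidonic": 28.0, "undefined": 2.5, "retinol": 50.0},
            "em366": {"protein": 8.0, "linoleic": 7.0, "oleic": 11.0,
                      "arachidonic": 26.0, "undefined": 2.0, "retinol": 48.0,
                      "band560": 0.0},
            "exc570": {"dominant": 85.0, "bilirubin_400": 6.0,
                       "bilirubin_435": 8.0, "bilirubin_470": 10.0},
            "em280": {"albumin": 60.0},
        },
    )
    ir = GroupProfile(
        group="IR",
        overall_gain=1.8,
        mean_abundances={
            "em310": {"protein": 12.0, "oleic": 13.0, "linoleic": 7.0,
                      "arachidonic": 45.0, "undefined": 2.5, "retinol": 38.0},
            "em366": {"protein": 7.0, "linoleic": 11.0, "oleic": 15.0,
                      "arachidonic": 40.0, "undefined": 2.0, "retinol": 35.0,
                      "band560": 1.0},
            "exc570": {"dominant": 75.0, "bilirubin_400": 12.0,
                       "bilirubin_435": 14.0, "bilirubin_470": 16.0},
            "em280": {"albumin": 25.0},
        },
    )
    ir_oca = GroupProfile(
        group="IR_OCA",
        overall_gain=0.85,
        mean_abundances={
            "em310": {"protein": 14.0, "oleic": 8.0, "linoleic": 3.5,
                      "arachidonic": 25.0, "undefined": 2.5, "retinol": 52.0},
            "em366": {"protein": 8.0, "linoleic": 6.0, "oleic": 10.0,
                      "arachidonic": 23.0, "undefined": 2.0, "retinol": 50.0,
                      "band560": 0.0},
            "exc570": {"dominant": 83.0, "bilirubin_400": 7.0,
                       "bilirubin_435": 9.0, "bilirubin_470": 11.0},
            "em280": {"albumin": 65.0},
        },
    )
    return {"sham": sham, "IR": ir, "IR_OCA": ir_oca}


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative log-normal factor with the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _render_library(condition: str) -> BandLibrary:
    return _ALBUMIN_LIBRARY if condition == "em280" else default_library(condition)


def generate_cohort(
    profiles: Mapping[str, GroupProfile] | None = None,
    n_animals: int = 5,
    n_replicates: int = 10,
    seed: int = 0,
    conditions: Sequence[str] = ("em310", "em366", "exc570", "em280"),
) -> list[CohortSample]:
    """Generate a reproducible synthetic cohort.

    Per animal, band abundances are drawn log-normally around the group
    means (scaled by the group gain); per replicate they are jittered with
    the replicate CV, rendered through the additive band model on the
    standard grid and corrupted with Gaussian detector noise.  The whole
    cohort is a deterministic function of ``seed``.
    """
    if n_animals < 1 or n_replicates < 1:
        raise ValueError("n_animals and n_replicates must be >= 1")
    profiles = default_profiles() if profiles is None else profiles
    rng = np.random.default_rng(seed)
    libraries = {c: _render_library(c) for c in conditions}

    cohort: list[CohortSample] = []
    for group, profile in profiles.items():
        for a in range(1, n_animals + 1):
            sample_id = f"{group}_{a:02d}"
            truth: dict[str, dict[str, float]] = {}
            rep_truth: dict[str, list[dict[str, float]]] = {}
            spectra: list[Spectrum] = []
            for condition in conditions:
                means = profile.mean_abundances.get(condition, {})
                lib = libraries[condition]
                animal_amps: dict[str, float] = {}
                for name in lib.names:
                    if name == "hemoglobin":
                        amp = profile.hemoglobin_dip_amp * profile.overall_gain
                        amp *= float(_lognormal_factor(rng, profile.between_animal_cv))
                    else:
                        amp = means.get(name, 0.0) * profile.overall_gain
                        amp *= float(_lognormal_factor(rng, profile.between_animal_cv))
                    animal_amps[name] = amp
                truth[condition] = dict(animal_amps)
                rep_truth[condition] = []
                wl = GRIDS[condition]
                mode, fixed_wl = _CONDITION_META[condition]
                for r in range(1, n_replicates + 1):
                    rep_amps = {
                        name: amp * float(_lognormal_factor(rng, profile.replicate_cv))
                        for name, amp in animal_amps.items()
                    }
                    rep_truth[condition].append(rep_amps)
                    y = model_spectrum(lib, rep_amps, wl)
                    if profile.noise_sd_au > 0:
                        y = y + rng.normal(0.0, profile.noise_sd_au, size=wl.shape)
                    spectra.append(
                        Spectrum(
                            wavelengths_nm=wl.copy(),
                            intensities_au=y,
                            mode=mode,
                            fixed_wavelength_nm=fixed_wl,
                            sample_id=sample_id,
                            group=group,
                            replicate_index=r,
                        )
                    )
            cohort.append(
                CohortSample(
                    sample_id=sample_id,
                    group=group,
                    true_abundances=truth,
                    spectra=spectra,
                    replicate_abundances=rep_truth,
                )
            )
    return cohort
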