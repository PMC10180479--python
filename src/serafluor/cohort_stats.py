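"""Group-level summaries and significance tests of the derived AF parameters.

The animal is the experimental unit: the 10 replicate scans per animal and
condition are averaged into a single spectrum before fitting, so every
statistical test runs on at most n-animals values per group — never on
replicates.  The default test battery is non-parametric (Kruskal-Wallis
omnibus, pairwise Mann-Whitney with Holm adjustment), appropriate for
five-animal groups where normality cannot be verified; a parametric
alternative (one-way ANOVA with Tukey HSD) is available.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .band_model import BandLibrary, default_library
from .markers import albumin_af, bilirubin_contribution, bilirubin_ratio
from .spectra_io import Spectrum
from .unmixing import (
    FitOptions,
    FitResult,
    check_minor_band_budget,
    fit_spectrum,
    normalize_peak,
)

logger = logging.getLogger("serafluor")

__all__ = [
    "GroupComparison",
    "StudyResult",
    "summarize_parameter",
    "run_study",
]


@dataclass(frozen=True)
class GroupComparison:
    """Per-group summaries plus omnibus and adjusted pairwise p-values."""

    parameter: str
    group_n: dict[str, int]
    group_mean: dict[str, float]
    group_sd: dict[str, float]
    omnibus_p: float
    omnibus_test: str
    pairwise_raw_p: dict[tuple[str, str], float]
    pairwise_adj_p: dict[tuple[str, str], float]
    pairwise_test: str
    alpha: float
    significant_pairs: tuple[tuple[str, str], ...]

    def to_rows(self) -> list[dict]:
        """Tidy rows (one per group plus one per pairwise contrast)."""
        rows = []
        for g in self.group_n:
            rows.append(
                {
                    "parameter": self.parameter,
                    "kind": "group",
                    "group": g,
                    "contrast": "",
                    "n": self.group_n[g],
                    "mean": self.group_mean[g],
                    "sd": self.group_sd[g],
                    "p_value": np.nan,
                    "p_adjusted": np.nan,
                    "test": "",
                    "significant": np.nan,
                }
            )
        rows.append(
            {
                "parameter": self.parameter,
                "kind": "omnibus",
                "group": "",
                "contrast": " vs ".join(self.group_n),
                "n": sum(self.group_n.values()),
                "mean": np.nan,
                "sd": np.nan,
                "p_value": self.omnibus_p,
                "p_adjusted": np.nan,
                "test": self.omnibus_test,
                "significant": bool(self.omnibus_p < self.alpha)
                if not math.isnan(self.omnibus_p)
                else np.nan,
            }
        )
        for pair, raw in self.pairwise_raw_p.items():
            rows.append(
                {
                    "parameter": self.parameter,
                    "kind": "pairwise",
                    "group": "",
                    "contrast": f"{pair[0]} vs {pair[1]}",
                    "n": self.group_n[pair[0]] + self.group_n[pair[1]],
                    "mean": np.nan,
                    "sd": np.nan,
                    "p_value": raw,
                    "p_adjusted": self.pairwise_adj_p[pair],
                    "test": self.pairwise_test,
                    "significant": pair in self.significant_pairs,
                }
            )
        return rows


def summarize_parameter(
    values: Mapping[str, Sequence[float]],
    parameter: str = "",
    alpha: float = 0.05,
    test: str = "kw",
) -> GroupComparison:
    """Summarize one derived parameter across groups and test for differences.

    ``values`` maps group label → per-animal values (replicates must already
    be collapsed to one value per animal).  ``test`` is ``"kw"``
    (Kruskal-Wallis + pairwise Mann-Whitney, Holm-adjusted) or ``"anova"``
    (one-way ANOVA + Tukey HSD).  With a single group, summaries are
    returned without tests (p-values NaN) and a warning is logged; a group
    with fewer than two values is an error.
    """
    if test not in ("kw", "anova"):
        raise ValueError("test must be 'kw' or 'anova'")
    groups = {g: np.asarray(v, float) for g, v in values.items()}
    if not groups:
        raise ValueError("no groups given")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has {len(v)} value(s); need >= 2 per group")
    group_n = {g: int(len(v)) for g, v in groups.items()}
    group_mean = {g: float(np.mean(v)) for g, v in groups.items()}
    group_sd = {g: float(np.std(v, ddof=1)) for g, v in groups.items()}

    if len(groups) < 2:
        logger.warning("parameter %s: single group, summaries without tests", parameter)
        return GroupComparison(
            parameter=parameter,
            group_n=group_n,
            group_mean=group_mean,
            group_sd=group_sd,
            omnibus_p=math.nan,
            omnibus_test="",
            pairwise_raw_p={},
            pairwise_adj_p={},
            pairwise_test="",
            alpha=alpha,
            significant_pairs=(),
        )

    labels = list(groups)
    samples = [groups[g] for g in labels]
    pairs = list(itertools.combinations(labels, 2))
    if test == "kw":
        omnibus_test = "kruskal-wallis"
        pairwise_test = "mann-whitney (holm)"
        try:
            omnibus_p = float(stats.kruskal(*samples).pvalue)
        except ValueError:  # all values identical across every group
            omnibus_p = 1.0
        raw = []
        for g1, g2 in pairs:
            raw.append(float(stats.mannwhitneyu(groups[g1], groups[g2],
                                                alternative="two-sided").pvalue))
        adj = multipletests(raw, method="holm")[1]
    else:
        omnibus_test = "one-way anova"
        pairwise_test = "tukey hsd"
        omnibus_p = float(stats.f_oneway(*samples).pvalue)
        tk = stats.tukey_hsd(*samples)
        raw = [float(tk.pvalue[labels.index(g1), labels.index(g2)]) for g1, g2 in pairs]
        adj = np.asarray(raw)  # Tukey HSD p-values are already family-adjusted

    pairwise_raw = dict(zip(pairs, raw))
    pairwise_adj = dict(zip(pairs, (float(p) for p in adj)))
    significant = tuple(p for p in pairs if pairwise_adj[p] < alpha)
    return GroupComparison(
        parameter=parameter,
        group_n=group_n,
        group_mean=group_mean,
        group_sd=group_sd,
        omnibus_p=omnibus_p,
        omnibus_test=omnibus_test,
        pairwise_raw_p=pairwise_raw,
        pairwise_adj_p=pairwise_adj,
        pairwise_test=pairwise_test,
        alpha=alpha,
        significant_pairs=significant,
    )


@dataclass
class StudyResult:
    """Full results bundle of :func:`run_study`."""

    per_animal: pd.DataFrame
    group_stats: pd.DataFrame
    comparisons: dict[str, GroupComparison]
    fits: dict[tuple[str, str], FitResult]
    warnings: list[str] = field(default_factory=list)


def _average_replicates(spectra: Sequence[Spectrum]) -> Spectrum:
    base = spectra[0]
    for s in spectra[1:]:
        if s.wavelengths_nm.shape != base.wavelengths_nm.shape or not np.allclose(
            s.wavelengths_nm, base.wavelengths_nm
        ):
            raise ValueError(
                f"replicates of {base.sample_id}/{base.condition} are on different grids"
            )
    mean = np.mean([s.intensities_au for s in spectra], axis=0)
    return base.with_intensities(mean)


def run_study(
    cohort,
    libraries: Mapping[str, BandLibrary] | None = None,
    options: FitOptions | None = None,
    alpha: float = 0.05,
    test: str = "kw",
    albumin_window: tuple[float, float] = (340.0, 10.0),
) -> StudyResult:
    """Run the full per-animal pipeline and the group comparisons.

    For each animal: average the replicate scans per condition, record the
    pre-normalization peak, normalize to 100 a.u., fit the band library,
    derive percentage and absolute fluorophore contributions, the bilirubin
    fraction and excitation ratio, and the albumin readout.  Each derived
    parameter is then summarized across groups with
    :func:`summarize_parameter`.  Animals whose fit fails to converge for a
    condition are excluded from that condition's parameters with a logged
    warning.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    options = options or FitOptions()
    fit_conditions = ("em310", "em366", "exc570")
    libraries = libraries or {c: default_library(c) for c in fit_conditions}

    rows: list[dict] = []
    fits: dict[tuple[str, str], FitResult] = {}
    warnings: list[str] = []
    for sample in cohort:
        row: dict = {"sample_id": sample.sample_id, "group": sample.group}
        for condition in fit_conditions:
            spectra = sample.spectra_for(condition)
            if not spectra:
                continue
            avg = _average_replicates(spectra)
            try:
                fit = fit_spectrum(avg, libraries[condition], options)
            except Exception as exc:  # surfaced, not swallowed silently
                msg = f"{sample.sample_id}/{condition}: fit failed ({exc})"
                warnings.append(msg)
                logger.warning(msg)
                continue
            fits[(sample.sample_id, condition)] = fit
            if not fit.converged:
                msg = f"{sample.sample_id}/{condition}: fit did not converge; excluded"
                warnings.append(msg)
                logger.warning(msg)
                continue
            row[f"{condition}_peak_amplitude_au"] = fit.scale
            row[f"{condition}_r_squared"] = fit.r_squared
            for band, frac in fit.fractions_pct.items():
                row[f"{condition}_{band}_fraction_pct"] = frac
                row[f"{condition}_{band}_absolute_af"] = frac / 100.0 * fit.scale
            if condition in ("em310", "em366"):
                ok, share = check_minor_band_budget(fit)
                row[f"{condition}_minor_band_share_pct"] = share
                row[f"{condition}_minor_band_ok"] = ok
            else:
                bili = bilirubin_contribution(fit)
                row["bilirubin_fraction_pct"] = bili.bilirubin_fraction_pct
                # the ratio is scale-invariant; computed on the normalized
                # measured spectrum, not the fitted model
                norm_avg, _ = normalize_peak(avg)
                row["ratio_long_short"] = bilirubin_ratio(norm_avg).ratio
        em280 = sample.spectra_for("em280")
        if em280:
            avg = _average_replicates(em280)
            row["albumin_af"] = albumin_af(avg, albumin_window[0], albumin_window[1]).albumin_af
        rows.append(row)

    per_animal = pd.DataFrame(rows)
    id_cols = {"sample_id", "group"}
    flag_cols = {c for c in per_animal.columns if c.endswith("_ok")}
    param_cols = [c for c in per_animal.columns if c not in id_cols | flag_cols]

    comparisons: dict[str, GroupComparison] = {}
    stat_rows: list[dict] = []
    n_groups = per_animal["group"].nunique()
    for col in param_cols:
        sub = per_animal[["group", col]].dropna()
        values = {g: v[col].to_numpy() for g, v in sub.groupby("group", sort=False)}
        values = {g: v for g, v in values.items() if len(v) >= 2}
        if not values:
            continue
        if len(values) < 2:
            if n_groups < 2:
                comp = summarize_parameter(values, parameter=col, alpha=alpha, test=test)
            else:
                warnings.append(f"parameter {col}: fewer than 2 usable groups; skipped tests")
                comp = summarize_parameter(values, parameter=col, alpha=alpha, test=test)
        else:
            comp = summarize_parameter(values, parameter=col, alpha=alpha, test=test)
        comparisons[col] = comp
        stat_rows.extend(comp.to_rows())

    group_stats = pd.DataFrame(stat_rows)
    return StudyResult(
        per_animal=per_animal,
        group_stats=group_stats,
        comparisons=comparisons,
        fits=fits,
        warnings=warnings,
    )
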