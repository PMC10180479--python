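"""Normalization, constrained band fitting and contribution arithmetic."""

import numpy as np
import pytest
from scipy.optimize import nnls

import serafluor as sf
from conftest import make_fit_result, make_spectrum


def render(condition, amplitudes, grid, noise_sd=0.0, rng=None):
    lib = sf.default_library(condition)
    y = sf.model_spectrum(lib, amplitudes, grid)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, grid.shape)
    return make_spectrum(grid, y, condition)


class TestNormalizePeak:
    def test_scales_maximum_to_target_and_returns_scale(self, em_grid):
        s = make_spectrum(em_grid, 412.7 * np.exp(-0.5 * ((em_grid - 450) / 30) ** 2), "em310")
        norm, scale = sf.normalize_peak(s)
        assert np.max(norm.intensities_au) == 100.0  # exact
        assert scale == pytest.approx(412.7, rel=1e-12)

    def test_idempotent_on_normalized_scale(self, em_grid):
        s = make_spectrum(em_grid, 100.0 * np.exp(-0.5 * ((em_grid - 450) / 30) ** 2), "em310")
        norm, scale = sf.normalize_peak(s)
        assert scale == pytest.approx(100.0)
        assert np.allclose(norm.intensities_au, s.intensities_au, rtol=1e-12)

    def test_degenerate_spectrum_rejected(self, em_grid):
        s = make_spectrum(em_grid, np.zeros_like(em_grid), "em310")
        with pytest.raises(sf.DegenerateSpectrumError):
            sf.normalize_peak(s)


class TestFitSpectrum:
    def test_noiseless_two_band_recovery(self, em_grid):
        truth = {"retinol": 70.0, "arachidonic": 30.0}
        spec = render("em366", truth, em_grid)
        res = sf.fit_spectrum(spec, sf.default_library("em366"),
                              sf.FitOptions(free_shapes=False))
        est = res.amplitudes_measured_scale()
        assert est["retinol"] == pytest.approx(70.0, rel=1e-4)
        assert est["arachidonic"] == pytest.approx(30.0, rel=1e-4)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noisy_two_band_fractions_within_two_points(self, em_grid):
        lib = sf.default_library("em366")
        truth = {"retinol": 70.0, "arachidonic": 30.0}
        rng = np.random.default_rng(42)
        spec = render("em366", truth, em_grid, noise_sd=1.0, rng=rng)
        res = sf.fit_spectrum(spec, lib, sf.FitOptions(free_shapes=False))
        true_areas = {n: truth[n] * sf.gmg_unit_area(lib.band(n)) for n in truth}
        total = sum(true_areas.values())
        for name, area in true_areas.items():
            assert abs(res.fractions_pct[name] - 100 * area / total) < 2.0

    def test_single_bilirubin_band_self_fit(self, exc_grid):
        spec = render("exc570", {"bilirubin_435": 60.0}, exc_grid)
        res = sf.fit_spectrum(spec, sf.default_library("exc570"), sf.FitOptions())
        bili = [res.fractions_pct[b] for b in
                ("bilirubin_400", "bilirubin_435", "bilirubin_470")]
        assert res.fractions_pct["bilirubin_435"] == pytest.approx(100.0, abs=1e-5)
        assert sum(bili) == pytest.approx(100.0, abs=1e-5)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_matches_nonnegative_linear_least_squares_oracle(self, em_grid):
        """With fixed shapes the fit must equal the bounded linear solution."""
        lib = sf.default_library("em310").with_fixed_shapes()
        rng = np.random.default_rng(10)
        A = np.column_stack(
            [sf.gmg_profile(em_grid, b, 1.0 if b.sign == "positive" else -1.0)
             for b in lib.bands]
        )
        signs = np.array([1.0 if b.sign == "positive" else -1.0 for b in lib.bands])
        for _ in range(10):
            amps = {b.name: (rng.uniform(5, 60) if b.sign == "positive"
                             else -rng.uniform(0.2, 3)) for b in lib.bands}
            y = sf.model_spectrum(lib, amps, em_grid) + rng.normal(0, 1.0, em_grid.shape)
            spec = make_spectrum(em_grid, y, "em310")
            res = sf.fit_spectrum(spec, lib, sf.FitOptions(free_shapes=False))
            sol, _ = nnls(A, spec.intensities_au / y.max() * 100.0)
            oracle = sol * signs
            fitted = np.array([res.amplitudes[b.name] for b in lib.bands])
            assert np.all(np.abs(fitted - oracle) <= 1e-6 * np.maximum(1.0, np.abs(oracle)))

    def test_scale_equivariance(self, em_grid):
        lib = sf.default_library("em310")
        rng = np.random.default_rng(3)
        base = render("em310", {"retinol": 50.0, "arachidonic": 30.0, "protein": 10.0},
                      em_grid, noise_sd=0.5, rng=rng)
        res1 = sf.fit_spectrum(base, lib, sf.FitOptions(seed=1))
        scaled = base.with_intensities(7.5 * base.intensities_au)
        res2 = sf.fit_spectrum(scaled, lib, sf.FitOptions(seed=1))
        for name in lib.positive_names():
            assert res2.fractions_pct[name] == pytest.approx(
                res1.fractions_pct[name], rel=1e-9, abs=1e-9
            )
        est1 = res1.amplitudes_measured_scale()
        est2 = res2.amplitudes_measured_scale()
        for name in lib.names:
            assert est2[name] == pytest.approx(7.5 * est1[name], rel=1e-9, abs=1e-9)

    def test_positive_fractions_sum_to_100(self, em_grid):
        rng = np.random.default_rng(8)
        spec = render("em310", {"retinol": 40.0, "arachidonic": 30.0, "oleic": 10.0,
                                "protein": 12.0, "hemoglobin": -1.5},
                      em_grid, noise_sd=1.0, rng=rng)
        res = sf.fit_spectrum(spec, sf.default_library("em310"), sf.FitOptions())
        assert sum(res.fractions_pct.values()) == pytest.approx(100.0, abs=1e-6)
        assert "hemoglobin" not in res.fractions_pct
        assert res.band_areas["hemoglobin"] <= 0.0  # signed, reported separately

    def test_free_protein_parameters_stay_in_boxes(self, em_grid):
        rng = np.random.default_rng(9)
        spec = render("em310", {"retinol": 45.0, "arachidonic": 25.0, "protein": 15.0},
                      em_grid, noise_sd=1.0, rng=rng)
        res = sf.fit_spectrum(spec, sf.default_library("em310"), sf.FitOptions())
        protein = res.free_params["protein"]
        assert 360.0 <= protein["center_nm"] <= 420.0
        assert 30.0 <= protein["fwhm_nm"] <= 120.0

    def test_condition_mismatch_rejected(self, em_grid):
        spec = render("em310", {"retinol": 50.0}, em_grid)
        with pytest.raises(ValueError, match="does not match"):
            sf.fit_spectrum(spec, sf.default_library("em366"))


class TestGoodnessOfFit:
    def test_perfect_fit(self, em_grid):
        y = np.sin(em_grid / 40.0) + 2.0
        s = make_spectrum(em_grid, y, "em310")
        gof = sf.goodness_of_fit(s, y)
        assert gof["r_squared"] == 1.0
        assert gof["rms_residual"] == 0.0

    def test_mean_predictor_gives_r2_zero(self, em_grid):
        y = np.linspace(0, 10, em_grid.size)
        s = make_spectrum(em_grid, y, "em310")
        gof = sf.goodness_of_fit(s, np.full_like(y, y.mean()))
        assert gof["r_squared"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_gives_degenerate_autocorrelation(self, em_grid):
        y = np.sin(em_grid / 40.0) + 2.0
        s = make_spectrum(em_grid, y, "em310")
        gof = sf.goodness_of_fit(s, y + 5.0)
        assert gof["rms_residual"] == pytest.approx(5.0, rel=1e-12)
        assert np.isnan(gof["lag1_autocorr"])

    def test_hand_computed_five_point_example(self):
        # measured [1..5], fitted [1.5,1.5,3.5,3.5,5.5]:
        # residuals [-.5,.5,-.5,.5,-.5] -> SS_res=1.25, SS_tot=10,
        # r^2=0.875, rms=0.5, lag-1 autocorr -0.96/1.2 = -0.8
        measured = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fitted = np.array([1.5, 1.5, 3.5, 3.5, 5.5])
        gof = sf.goodness_of_fit(measured, fitted)
        assert gof["r_squared"] == pytest.approx(0.875, rel=1e-12)
        assert gof["rms_residual"] == pytest.approx(0.5, rel=1e-12)
        assert gof["lag1_autocorr"] == pytest.approx(-0.8, rel=1e-12)

    def test_zero_variance_measured_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            sf.goodness_of_fit(np.full(11, 3.0), np.full(11, 3.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            sf.goodness_of_fit(np.arange(5.0), np.arange(6.0))


class TestContributionArithmetic:
    def test_area_fraction_ratios(self):
        lib = sf.default_library("exc570")
        fit = make_fit_result(lib, {"dominant": 2.0, "bilirubin_400": 1.0,
                                    "bilirubin_435": 1.0})
        frac = sf.area_fractions(fit)
        assert frac["dominant"] == pytest.approx(50.0)
        assert frac["bilirubin_400"] == pytest.approx(25.0)
        assert frac["bilirubin_435"] == pytest.approx(25.0)
        assert frac["bilirubin_470"] == 0.0

    def test_single_band_gets_everything(self):
        lib = sf.default_library("exc570")
        fit = make_fit_result(lib, {"dominant": 7.0})
        assert sf.area_fractions(fit)["dominant"] == pytest.approx(100.0)

    def test_all_zero_areas_rejected(self):
        lib = sf.default_library("exc570")
        fit = make_fit_result(lib, {}, fractions_pct={})
        with pytest.raises(sf.DegenerateSpectrumError):
            sf.area_fractions(fit)

    def test_absolute_contributions_arithmetic(self):
        (single,) = sf.absolute_contributions({"x": 100.0}, 321.5)
        assert single.absolute_af == pytest.approx(321.5)
        result = sf.absolute_contributions({"a": 25.0, "b": 75.0}, 400.0)
        values = {c.band: c.absolute_af for c in result}
        assert values == {"a": pytest.approx(100.0), "b": pytest.approx(300.0)}
        result = sf.absolute_contributions({"a": 60.0, "b": 40.0}, 250.0)
        assert sum(c.absolute_af for c in result) == pytest.approx(250.0, abs=1e-9)

    def test_absolute_contribution_preconditions(self):
        with pytest.raises(ValueError, match="measured_amplitude"):
            sf.absolute_contributions({"a": 100.0}, -5.0)
        with pytest.raises(ValueError, match="sum to 100"):
            sf.absolute_contributions({"a": 50.0}, 100.0)
        with pytest.raises(ValueError, match="metric"):
            sf.absolute_contributions({"a": 100.0}, 10.0, metric="bogus")


class TestMinorBandBudget:
    @pytest.mark.parametrize(
        "condition,share,expect_ok",
        [
            ("em366", 0.0, True),
            ("em366", 2.9, True),
            ("em366", 3.0, True),
            ("em366", 3.1, False),
            ("em310", 9.9, True),
            ("em310", 10.0, True),
            ("em310", 10.1, False),
        ],
    )
    def test_budget_trips_strictly_above_threshold(self, condition, share, expect_ok):
        lib = sf.default_library(condition)
        fit = make_fit_result(lib, {"retinol": 100.0 - share, "undefined": share})
        ok, measured = sf.check_minor_band_budget(fit)
        assert measured == pytest.approx(share, rel=1e-12, abs=1e-12)
        assert ok is expect_ok

    def test_hemoglobin_counts_by_absolute_area(self):
        lib = sf.default_library("em366")
        fit = make_fit_result(lib, {"retinol": 98.0, "hemoglobin": -2.0})
        _, share = sf.check_minor_band_budget(fit)
        assert share == pytest.approx(100.0 * 2.0 / 98.0)

    def test_no_budget_for_excitation_condition(self):
        lib = sf.default_library("exc570")
        fit = make_fit_result(lib, {"dominant": 10.0})
        with pytest.raises(ValueError, match="no minor-band budget"):
            sf.check_minor_band_budget(fit)
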