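"""Tests of the spline basis, spectral predictors, model fit and band effects."""

import numpy as np
import pytest

from fruitsignals.spline import (
    CollinearityError,
    band_effect,
    band_effects,
    build_basis,
    fit_model,
    proportion_spectrum,
    spectrum_predictors,
)
from fruitsignals.synth import CommunityConfig, generate_community
from fruitsignals.traits import Spectrum

FINE_GRID = np.arange(300.0, 701.0, 10.0)  # contains the 650 nm referent


class TestBuildBasis:
    def test_default_shape_and_rank(self, default_basis):
        assert default_basis.basis_matrix.shape == (21, 5)
        assert np.linalg.matrix_rank(default_basis.basis_matrix) == 5
        assert default_basis.boundary == (350.0, 650.0)

    def test_vanishes_at_referent(self, default_basis):
        assert np.allclose(default_basis.evaluate([650.0]), 0.0, atol=1e-9)

    def test_natural_linear_extrapolation(self, default_basis):
        # second differences vanish outside the outer knots (350, 650)
        for pts in ([300.0, 310.0, 320.0, 330.0], [660.0, 670.0, 680.0, 690.0]):
            vals = default_basis.evaluate(pts)
            second_diff = np.diff(vals, n=2, axis=0)
            assert np.allclose(second_diff, 0.0, atol=1e-8)

    def test_referent_must_differ_from_knots(self):
        with pytest.raises(ValueError, match="referent"):
            build_basis(knots=(350, 410, 470, 530, 650), referent=650.0)

    def test_wrong_column_count_is_configuration_error(self):
        with pytest.raises(ValueError, match="columns"):
            build_basis(boundary=(300.0, 700.0))


class TestSpectrumPredictors:
    def test_zero_spectrum_gives_zero_predictors(self, default_basis):
        assert np.allclose(
            spectrum_predictors(np.zeros(21), default_basis), 0.0
        )

    def test_mass_at_referent_gives_zero_predictors(self):
        basis = build_basis(grid=FINE_GRID)
        values = np.zeros(FINE_GRID.size)
        values[FINE_GRID == 650.0] = 100.0
        assert np.allclose(spectrum_predictors(values, basis), 0.0, atol=1e-9)

    def test_additivity(self, default_basis):
        rng = np.random.default_rng(2)
        v1, v2 = rng.uniform(size=21), rng.uniform(size=21)
        lhs = spectrum_predictors(v1 + v2, default_basis)
        rhs = spectrum_predictors(v1, default_basis) + spectrum_predictors(
            v2, default_basis
        )
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_grid_mismatch_is_an_error(self, default_basis):
        spec = Spectrum(FINE_GRID, np.full(FINE_GRID.size, 0.2), species="X")
        with pytest.raises(ValueError, match="grid"):
            spectrum_predictors(spec, default_basis)

    def test_proportion_spectrum_percent_scale(self):
        spec = Spectrum(np.array([450.0, 550.0, 650.0]),
                        np.array([0.1, 0.3, 0.2]), normalized=True)
        values = proportion_spectrum(spec)
        assert values.sum() == pytest.approx(100.0)


class TestFitModel:
    def test_perfect_fit_without_noise(self, default_basis):
        cfg = CommunityConfig(n_species=30, blue_voc_effect=0.0,
                              saw_voc_effect=0.7, voc_noise_sd=0.0, seed=4)
        com = generate_community(cfg)
        fit = fit_model(com.records, com.spectra, default_basis)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_f_test_degrees_of_freedom(self, default_basis):
        com = generate_community(CommunityConfig(n_species=40, seed=6))
        fit = fit_model(com.records, com.spectra, default_basis)
        assert fit.f_df == (5, 40 - 7)
        assert 0.0 <= fit.r_squared <= 1.0

    def test_invariant_to_constant_spectrum_offset(self, default_basis):
        from dataclasses import replace

        com = generate_community(CommunityConfig(n_species=30, seed=8))
        shifted = {
            sp: replace(s, reflectance=np.clip(s.reflectance, 0, 0.8) + 0.1)
            for sp, s in com.spectra.items()
        }
        base = {
            sp: replace(s, reflectance=np.clip(s.reflectance, 0, 0.8))
            for sp, s in com.spectra.items()
        }
        fit_a = fit_model(com.records, base, default_basis)
        fit_b = fit_model(com.records, shifted, default_basis)
        for name in fit_a.names:
            assert fit_a.coefficients[name] == pytest.approx(
                fit_b.coefficients[name], abs=1e-9
            )

    def test_collinear_design_is_reported(self, default_basis):
        com = generate_community(CommunityConfig(n_species=30, seed=9))
        one = next(iter(com.spectra.values()))
        same = {rec.species: Spectrum(one.wavelengths, one.reflectance,
                                      species=rec.species)
                for rec in com.records}
        with pytest.raises(CollinearityError):
            fit_model(com.records, same, default_basis)

    def test_too_few_observations(self, default_basis):
        com = generate_community(CommunityConfig(n_species=30, seed=1))
        with pytest.raises(ValueError, match="at least"):
            fit_model(com.records[:6], com.spectra, default_basis)


class TestBandEffects:
    def test_recovery_of_injected_blue_effect(self, default_basis):
        """The blue band effect estimates a spline-smoothed version of the
        injected box effect: negative, strongly significant, attenuated by
        the documented factor, with the size coefficient unbiased."""
        cfg = CommunityConfig(n_species=500, seed=1)
        com = generate_community(cfg)
        fit = fit_model(com.records, com.spectra, default_basis)
        blue = band_effect(fit, default_basis, "blue")
        assert blue.cumulative_coefficient < 0
        assert blue.p_two_tailed < 1e-6
        attenuation = blue.cumulative_coefficient / cfg.blue_voc_effect
        assert 0.75 < attenuation < 0.98
        saw_se = np.sqrt(fit.covariance[fit.names.index("log_saw"),
                                        fit.names.index("log_saw")])
        assert abs(fit.coefficients["log_saw"] - 0.5) < 2 * saw_se

    def test_null_bands_are_nonsignificant(self, default_basis):
        cfg = CommunityConfig(n_species=200, blue_voc_effect=0.0, seed=3)
        com = generate_community(cfg)
        fit = fit_model(com.records, com.spectra, default_basis)
        effects = band_effects(fit, default_basis)
        assert set(effects) == {"uv", "blue", "green", "red"}
        assert effects["blue"].p_two_tailed > 0.01

    def test_delta_method_variance_matches_monte_carlo(self, default_basis):
        com = generate_community(CommunityConfig(n_species=200, seed=12))
        fit = fit_model(com.records, com.spectra, default_basis)
        rng = np.random.default_rng(99)
        L = np.linalg.cholesky(fit.spline_covariance)
        draws = fit.spline_coefficients + rng.standard_normal((200_000, 5)) @ L.T
        for band in ("blue", "green"):
            eff = band_effect(fit, default_basis, band)
            from fruitsignals.spline import _band_contrast

            c = _band_contrast(default_basis, band, "mean")
            mc_var = np.var(draws @ c, ddof=1)
            assert mc_var == pytest.approx(eff.std_error**2, rel=0.02)

    def test_band_at_referent_only_has_zero_effect(self):
        grid = np.array([300.0, 370.0, 440.0, 510.0, 580.0, 650.0])
        basis = build_basis(grid=grid)
        com = generate_community(
            CommunityConfig(n_species=30, wavelength_grid=grid, seed=2)
        )
        fit = fit_model(com.records, com.spectra, basis)
        red = band_effect(fit, basis, "red")  # 650 nm is the only red point
        assert red.cumulative_coefficient == 0.0
        assert red.std_error == 0.0

    def test_unknown_band_rejected(self, default_basis):
        com = generate_community(CommunityConfig(n_species=30, seed=2))
        fit = fit_model(com.records, com.spectra, default_basis)
        with pytest.raises(ValueError, match="band"):
            band_effect(fit, default_basis, "infrared")
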