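"""Fluorescence-derived quantities: tau/Sigma(II), step derivation, PE and
NPQ fits, spectral indices."""
import numpy as np
import pandas as pd
import pytest

import specphyto as sp
from specphyto.photo import (PARII_FACTOR, fit_npq, fit_pe, fit_tau,
                             index_regression, sigma_psii)
from specphyto.synth import simulate_induction, simulate_rlc

PAR14 = np.array([0, 25, 50, 100, 150, 225, 325, 450, 625, 850, 1150, 1450,
                  1750, 2000], float)


class TestFitTau:
    def test_noise_free_recovery(self):
        curves = [simulate_induction(4e-4, 0.3, 0.75, subsample=1, repeat=r)
                  for r in (1, 2, 3)]
        assert fit_tau(curves) == pytest.approx(4e-4, rel=1e-9)

    def test_flat_curve_no_rise(self):
        c = simulate_induction(4e-4, 0.3, 0.75)
        c.fluorescence[:] = 0.5
        with pytest.raises(sp.FitError, match="no rise"):
            fit_tau([c])

    def test_mean_of_three_repeats(self):
        curves = [simulate_induction(tau, 0.3, 0.75, subsample=1, repeat=r)
                  for r, tau in enumerate((3e-4, 4e-4, 5e-4), start=1)]
        assert fit_tau(curves) == pytest.approx(4e-4, rel=1e-8)

    def test_mismatched_repeats_rejected(self):
        curves = [simulate_induction(4e-4, 0.3, 0.75, subsample=s)
                  for s in (1, 2)]
        with pytest.raises(sp.ValidationError):
            fit_tau(curves)


class TestSigmaPsii:
    def test_direct_arithmetic(self):
        assert sigma_psii(4e-4, 1000) == pytest.approx(
            1e18 / (4e-4 * 6.02214076e23 * 1e-3), rel=1e-12)
        assert sigma_psii(4e-4, 1000) == pytest.approx(4.151, abs=5e-4)

    def test_blue_population_scale(self):
        assert sigma_psii(2.731e-4, 1000) == pytest.approx(6.08, abs=0.005)

    def test_inverse_proportionality_in_par(self):
        assert sigma_psii(4e-4, 2000) == pytest.approx(
            sigma_psii(4e-4, 1000) / 2, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(sp.ValidationError):
            sigma_psii(-1e-4, 1000)


class TestDeriveSteps:
    def test_yield_and_retr_arithmetic(self):
        rlc = sp.RapidLightCurve(wavelength=440, replicate=1,
                                 par=[0.0, 100.0],
                                 f=[0.4, 0.3], fm_prime=[1.0, 0.6])
        fvfm, steps = sp.derive_steps(rlc, sigma=5.0)
        assert fvfm == pytest.approx(0.6)
        assert steps.loc[1, "y_ii"] == pytest.approx(0.5)
        assert steps.loc[1, "r_etr"] == pytest.approx(25.0)

    def test_par_ii_and_etr_ii_arithmetic(self):
        # sigma=5 nm2, PAR=100 -> PAR(II) = 5 * 0.602214076 * 100 = 301.107
        rlc = sp.RapidLightCurve(wavelength=440, replicate=1,
                                 par=[0.0, 100.0],
                                 f=[0.4, 0.7], fm_prime=[1.0, 1.0])
        _, steps = sp.derive_steps(rlc, sigma=5.0)
        assert steps.loc[1, "par_ii"] == pytest.approx(301.107038, rel=1e-8)
        # Y=0.3, Fv/Fm=0.6 -> ETR(II) = 301.107 * 0.5 = 150.55
        assert steps.loc[1, "etr_ii"] == pytest.approx(150.553519, rel=1e-8)

    def test_npq_zero_when_fm_prime_equals_fm(self):
        rlc = sp.RapidLightCurve(wavelength=440, replicate=1,
                                 par=[0.0, 50.0], f=[0.4, 0.5],
                                 fm_prime=[1.0, 1.0])
        _, steps = sp.derive_steps(rlc, sigma=2.0)
        assert np.allclose(steps["npq"], 0.0)

    def test_dark_step_rates_zero_and_ratio_constant(self):
        rlc = simulate_rlc((1.25e-6, 0.015, 5.0), 0.6,
                           lambda e: 1.5 * e / (700 + e))
        _, steps = sp.derive_steps(rlc, sigma=4.0)
        assert steps.loc[0, "etr_ii"] == 0.0 and steps.loc[0, "r_etr"] == 0.0
        light = steps["par"] > 0
        ratio = steps.loc[light, "etr_ii"] / steps.loc[light, "r_etr"]
        assert np.allclose(ratio, ratio.iloc[0], rtol=1e-9)


class TestFitPe:
    A, B, C = 1.25e-6, 0.015, 5.0

    def points(self):
        p = PAR14 / (self.A * PAR14**2 + self.B * PAR14 + self.C)
        p[0] = 0.0
        return PAR14, p

    def test_noise_free_recovery(self):
        e, p = self.points()
        fit = fit_pe(e, p)
        assert fit.alpha == pytest.approx(0.2, rel=1e-6)
        assert fit.etr_max == pytest.approx(50.0, rel=1e-6)
        assert fit.e_op == pytest.approx(2000.0, rel=1e-6)
        assert fit.e_k == pytest.approx(250.0, rel=1e-6)

    def test_derived_identities(self):
        e, p = self.points()
        fit = fit_pe(e, p)
        assert fit.alpha * fit.c == pytest.approx(1.0, rel=1e-9)
        assert fit.e_op**2 * fit.a == pytest.approx(fit.c, rel=1e-9)
        assert fit.e_k * fit.alpha == pytest.approx(fit.etr_max, rel=1e-9)

    def test_homogeneity(self):
        e, p = self.points()
        fit = fit_pe(e, 3.7 * p)
        assert fit.alpha == pytest.approx(3.7 * 0.2, rel=1e-6)
        assert fit.etr_max == pytest.approx(3.7 * 50.0, rel=1e-6)
        assert fit.e_k == pytest.approx(250.0, rel=1e-6)
        assert fit.e_op == pytest.approx(2000.0, rel=1e-6)

    def test_too_few_levels_rejected(self):
        with pytest.raises(sp.ValidationError):
            fit_pe([0, 10, 20, 30, 40], [0, 1, 2, 3, 4])


class TestFitNpq:
    E = PAR14[1:]

    def test_michaelis_menten_closed_form(self):
        npq = 3.0 * self.E / (600.0 + self.E)
        fit = fit_npq(self.E, npq)
        assert fit.model == "michaelis_menten"
        assert fit.npq300 == pytest.approx(1.0, rel=1e-8)
        assert fit.npq1200 == pytest.approx(2.0, rel=1e-8)

    def test_linear_origin(self):
        fit = fit_npq(self.E, 0.001 * self.E)
        assert fit.npq300 == pytest.approx(0.3, rel=1e-8)
        assert fit.npq1200 == pytest.approx(1.2, rel=1e-8)

    def test_all_zero_returns_zero_model(self):
        fit = fit_npq(self.E, np.zeros_like(self.E))
        assert fit.model == "zero" and fit.npq300 == 0.0 and fit.npq1200 == 0.0

    def test_selected_model_non_decreasing(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            npq = np.maximum(
                1.5 * self.E / (400 + self.E) + rng.normal(0, 0.1, self.E.size),
                0.0)
            fit = fit_npq(self.E, npq)
            grid = fit.predict(np.linspace(0, 2000, 100))
            assert np.all(np.diff(grid) >= -1e-12)
            assert fit.npq300 <= fit.npq1200 + 1e-12


class TestSpectralIndices:
    @staticmethod
    def tables():
        params = pd.DataFrame({
            "station": ["A"] * 3, "wavelength": [440, 540, 625],
            "r_ek": [200.0, 200.0, 200.0], "ek_ii": [700.0, 700.0, 700.0]})
        stations = pd.DataFrame({
            "station": ["A"], "e_avg": [200.0], "ratio_rb": [0.8],
            "ratio_gb": [1.5], "ratio_gr": [2.0], "z_eu": [20.0],
            "z_umixl": [10.0], "tss": [3.0], "stratified": [True],
        }).set_index("station")
        return params, stations

    def test_unity_indices(self):
        params, stations = self.tables()
        idx = sp.spectral_indices(params, stations)
        assert idx.loc["A", "ek_r_440_over_eavg"] == pytest.approx(1.0)
        assert idx.loc["A", "ek_ii_625_440"] == pytest.approx(1.0)
        assert idx.loc["A", "ek_r_540_625"] == pytest.approx(1.0)

    def test_missing_pair_wavelength_yields_nan(self):
        params, stations = self.tables()
        idx = sp.spectral_indices(params[params.wavelength != 625], stations)
        assert np.isnan(idx.loc["A", "ek_ii_625_440"])

    def test_missing_anchor_wavelength_omits_station(self):
        params, stations = self.tables()
        with pytest.raises(sp.ValidationError):
            sp.spectral_indices(params[params.wavelength != 440], stations)

    def test_regression_recovers_exact_line(self):
        x = np.linspace(0.2, 1.4, 8)
        y = 0.5789 * x + 0.2516
        idx = pd.DataFrame({"x": x, "y": y, "stratified": True})
        res = index_regression(idx, "x", "y")
        assert res["slope"] == pytest.approx(0.5789, rel=1e-12)
        assert res["intercept"] == pytest.approx(0.2516, rel=1e-12)
        assert res["r"] == pytest.approx(1.0, rel=1e-12)
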