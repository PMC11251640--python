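"""Direct extrapolation, linear regression, and the NB GLM with offset."""

import math
import shutil
import subprocess

import numpy as np
import pytest

from hauloutsurvey import (
    ExtrapolationWarning,
    NBModelFit,
    Terrain,
    deviance_explained,
    direct_extrapolation,
    fit_linear,
    fit_nb_glm,
    predict_linear,
    predict_nb,
)


class TestDirectExtrapolation:
    def test_zero_sd_degenerate_ci(self):
        e = direct_extrapolation(1000, 0.5, 0.0, seed=0)
        assert (e.point, e.ci_lower, e.ci_upper) == (500.0, 500.0, 500.0)

    def test_simulation_ci_matches_analytic_quantiles(self):
        # at 10^6 draws the empirical CI converges to A x (d -/+ 1.96 sd)
        e = direct_extrapolation(1000, 0.5, 0.1, n_sims=10**6, seed=7)
        assert e.point == 500.0
        assert e.ci_lower == pytest.approx(1000 * (0.5 - 1.959964 * 0.1), rel=0.01)
        assert e.ci_upper == pytest.approx(1000 * (0.5 + 1.959964 * 0.1), rel=0.01)

    def test_negative_lower_bound_floored(self):
        e = direct_extrapolation(1000, 0.05, 0.5, n_sims=10_000, seed=1)
        assert e.ci_lower == 0.0 and e.lower_floored

    def test_input_validation(self):
        with pytest.raises(ValueError):
            direct_extrapolation(1000, 0.5, -0.1)
        with pytest.raises(ValueError):
            direct_extrapolation(1000, 0.5, 0.1, n_sims=10)


class TestLinearModel:
    def test_exact_line(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_linear(0.8 * a, a)
        assert fit.slope == pytest.approx(0.8)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.resid_var == pytest.approx(0.0, abs=1e-20)
        est = predict_linear(fit, 3.5)
        assert est.ci_lower == pytest.approx(est.ci_upper)

    def test_hand_normal_equations(self):
        fit = fit_linear([1, 3, 5], [1, 2, 3])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(-1.0)

    def test_permutation_invariance(self, rng):
        a = rng.uniform(10, 400, 20)
        c = 0.7 * a + rng.normal(0, 5, 20)
        fit1 = fit_linear(c, a)
        perm = rng.permutation(20)
        fit2 = fit_linear(c[perm], a[perm])
        assert fit1.slope == pytest.approx(fit2.slope)
        assert fit1.intercept == pytest.approx(fit2.intercept)

    def test_se_at_mean_area_is_sqrt_s2_over_n(self, rng):
        a = rng.uniform(10, 400, 25)
        c = 0.7 * a + rng.normal(0, 5, 25)
        fit = fit_linear(c, a)
        est = predict_linear(fit, float(a.mean()), z=1.0)
        se = (est.ci_upper - est.point)  # z = 1 => halfwidth = SE
        assert se == pytest.approx(math.sqrt(fit.resid_var / len(a)), rel=1e-9)

    def test_extrapolation_warning(self):
        fit = fit_linear([1, 3, 5], [1, 2, 3])
        with pytest.warns(ExtrapolationWarning):
            predict_linear(fit, 100.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_linear([1, 2], [1, 2])
        with pytest.raises(ValueError):
            fit_linear([1, 2, 3], [5, 5, 5])


def _simulate_nb(rng, n_per=250, beta0=-0.434, bs=0.305, theta=8.979):
    areas = rng.uniform(50, 390, 2 * n_per)
    terr = np.array([Terrain.ROCKY.value] * n_per + [Terrain.SANDY.value] * n_per)
    mu = np.exp(beta0 + bs * (terr == Terrain.SANDY.value) + np.log(areas))
    y = rng.negative_binomial(theta, theta / (theta + mu))
    return y, areas, terr


class TestNBGLM:
    def test_intercept_only_on_constant_data(self):
        y = np.full(6, 20.0)
        a = np.full(6, 100.0)
        with pytest.warns(UserWarning, match="single terrain"):
            fit = fit_nb_glm(y, a, [Terrain.ROCKY] * 6)
        assert fit.intercept == pytest.approx(math.log(20 / 100), abs=1e-6)
        assert deviance_explained(fit) == 0.0

    def test_offset_algebra(self, rng):
        y, areas, terr = _simulate_nb(rng)
        fit1 = fit_nb_glm(y, areas, terr)
        fit2 = fit_nb_glm(y, 2 * areas, terr)
        assert fit2.intercept == pytest.approx(fit1.intercept - math.log(2), abs=1e-6)
        assert fit2.sandy_coef == pytest.approx(fit1.sandy_coef, abs=1e-6)

    def test_poisson_data_drives_theta_large(self, rng):
        areas = rng.uniform(50, 390, 400)
        terr = [Terrain.ROCKY.value, Terrain.SANDY.value] * 200
        mu = np.exp(-0.4 + np.log(areas))
        y = rng.poisson(mu)
        fit = fit_nb_glm(y, areas, terr)
        assert fit.theta > 50

    def test_matches_r_mass_glm_nb(self, rng, tmp_path):
        """Cross-implementation oracle: R MASS::glm.nb on the same data."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript is required for the NB GLM oracle check")
        y, areas, terr = _simulate_nb(rng, n_per=100)
        csv = tmp_path / "nb.csv"
        np.savetxt(csv, np.column_stack([y, areas, terr == Terrain.SANDY.value]),
                   delimiter=",", header="count,area,sandy", comments="")
        r_code = f"""
        suppressMessages(library(MASS))
        d <- read.csv("{csv}")
        m <- glm.nb(count ~ sandy + offset(log(area)), data = d, init.theta = 0.1)
        cat(coef(m), m$theta, m$SE.theta, m$null.deviance, m$deviance, sep = "\\n")
        """
        out = subprocess.run(["Rscript", "-e", r_code], capture_output=True,
                             text=True, timeout=300, check=True)
        r_b0, r_bs, r_theta, r_se_theta, r_null, r_dev = map(float, out.stdout.split())
        fit = fit_nb_glm(y, areas, terr)
        assert fit.intercept == pytest.approx(r_b0, abs=1e-5)
        assert fit.sandy_coef == pytest.approx(r_bs, abs=1e-5)
        assert fit.theta == pytest.approx(r_theta, rel=1e-4)
        assert fit.se_theta == pytest.approx(r_se_theta, rel=1e-3)
        assert fit.null_deviance == pytest.approx(r_null, rel=1e-6)
        assert fit.resid_deviance == pytest.approx(r_dev, rel=1e-6)
        # deviance explained agrees with a fully independent refit
        assert deviance_explained(fit) == pytest.approx(
            100 * (1 - r_dev / r_null), abs=1e-4)


class TestPredictNB:
    def test_published_coefficient_densities(self):
        fit = NBModelFit.from_coefficients(-0.434, 0.305, theta=8.979)
        rocky = predict_nb(fit, 1.0, "rocky_type")
        sandy = predict_nb(fit, 1.0, "sandy_type")
        assert rocky.point == pytest.approx(math.exp(-0.434))
        assert round(rocky.point, 3) == 0.648
        assert sandy.point == pytest.approx(math.exp(-0.434 + 0.305))
        assert round(sandy.point, 3) == 0.879

    def test_zero_variance_collapses_ci(self):
        fit = NBModelFit.from_coefficients(-0.434, 0.305, theta=8.979)
        e = predict_nb(fit, 5000.0, Terrain.SANDY)
        assert e.ci_lower == pytest.approx(e.point) == pytest.approx(e.ci_upper)

    def test_delta_method_ci_shape(self, rng):
        y, areas, terr = _simulate_nb(rng)
        fit = fit_nb_glm(y, areas, terr)
        e = predict_nb(fit, 10_000.0, Terrain.ROCKY)
        assert 0 < e.ci_lower < e.point < e.ci_upper
        # asymmetric on the natural scale: upper spread exceeds lower spread
        assert (e.ci_upper - e.point) > (e.point - e.ci_lower)
        # and consistent with the stated construction
        var_eta = float(np.array([1.0, 0.0]) @ fit.cov @ np.array([1.0, 0.0]))
        sd_log = math.sqrt(math.log1p(var_eta))
        assert e.ci_upper / e.point == pytest.approx(math.exp(2 * sd_log))

    def test_monotone_in_area_and_terrain(self, rng):
        y, areas, terr = _simulate_nb(rng)
        fit = fit_nb_glm(y, areas, terr)
        p1 = predict_nb(fit, 1000.0, Terrain.ROCKY).point
        p2 = predict_nb(fit, 2000.0, Terrain.ROCKY).point
        assert p2 > p1
        if fit.sandy_coef > 0:
            assert predict_nb(fit, 1000.0, Terrain.SANDY).point > p1

    def test_unseen_terrain_rejected(self):
        fit = NBModelFit.from_coefficients(-0.434, theta=8.979)
        with pytest.raises(ValueError, match="not a fitted level"):
            predict_nb(fit, 100.0, Terrain.SANDY)


class TestDevianceExplained:
    def test_bounds(self):
        fit = NBModelFit.from_coefficients(-0.4, 0.3, theta=5.0)
        fit.null_deviance, fit.resid_deviance = 100.0, 100.0
        assert deviance_explained(fit) == 0.0
        fit.resid_deviance = 0.0
        assert deviance_explained(fit) == 100.0
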