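"""Probit engine: transforms, IRLS fits, dispersion, tests, sigma/p50."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize, stats

from seedaging.io import AgingDesign, paper_design
from seedaging.probit import (
    DesignMatrixSpec,
    FitError,
    ProbitFitResult,
    fit_probit,
    dispersion_pearson,
    inv_probit,
    nested_f_test,
    p50,
    probit,
    sigma_from_fit,
    slope_wald_test,
)
from seedaging.simulate import simulate_lot

from conftest import exact_proportion_dishes


def erf_normal_cdf(x):
    """Independent normal CDF via math.erf (oracle, no scipy)."""
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def bisect_probit(p):
    """Oracle probit: bisection of the erf-based CDF."""
    lo, hi = -10.0, 10.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if erf_normal_cdf(mid) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestProbitTransform:
    def test_median_maps_to_zero(self):
        assert probit(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_against_bisection_oracle(self):
        assert probit(0.85) == pytest.approx(bisect_probit(0.85), abs=1e-5)
        assert probit(0.85) == pytest.approx(1.036433, abs=1e-5)
        assert probit(0.999) == pytest.approx(bisect_probit(0.999), abs=1e-5)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_domain_error(self, p):
        with pytest.raises(ValueError):
            probit(p)

    @given(st.floats(-6, 6))
    def test_inverse_pair(self, x):
        assert probit(inv_probit(x)) == pytest.approx(x, abs=1e-9)


class TestFitProbit:
    def test_noiseless_line_recovered_exactly(self):
        """Proportions exactly on Phi(2 - 0.1 t) give back (2, -0.1)."""
        dishes = exact_proportion_dishes(2.0, -0.1, range(0, 75, 5))
        fit = fit_probit(dishes, DesignMatrixSpec("single_lot", ("L",)))
        assert fit.coefficients == pytest.approx([2.0, -0.1], abs=1e-6)
        # oracle 1: weighted least squares directly on the probit scale
        t = np.array([d.aging_days for d in dishes])
        z = np.array([probit(d.proportion) for d in dishes])
        X = np.column_stack([np.ones_like(t), t])
        beta_wls = np.linalg.lstsq(X, z, rcond=None)[0]
        assert fit.coefficients == pytest.approx(beta_wls, abs=1e-6)
        # oracle 2: dense grid around the optimum of the binomial likelihood
        n = np.array([d.n_seeds for d in dishes])
        y = np.array([d.proportion for d in dishes])

        def nll(b):
            mu = stats.norm.cdf(b[0] + b[1] * t)
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            return -np.sum(n * (y * np.log(mu) + (1 - y) * np.log(1 - mu)))

        kis = np.linspace(1.99, 2.01, 41)
        slopes = np.linspace(-0.101, -0.099, 41)
        grid = [(k, s) for k in kis for s in slopes]
        best = min(grid, key=lambda b: nll(b))
        assert fit.coefficients == pytest.approx(best, abs=5e-4)

    def test_constant_proportion_flat_slope(self):
        dishes = exact_proportion_dishes(probit(0.8), 0.0, [0, 10, 20, 40, 72])
        fit = fit_probit(dishes, DesignMatrixSpec("single_lot", ("L",)))
        _, pval = slope_wald_test(fit, 1)
        assert abs(fit.coefficients[1]) < 1e-10
        assert pval >= 0.05

    def test_dispersion_internally_consistent(self, design, rng):
        obs = simulate_lot(2.0, 20.0, design, rho=0.1, rng=rng, lot_id="L")
        fit = fit_probit(obs, DesignMatrixSpec("single_lot", ("L",)))
        # recompute Pearson chi2 from the fitted curve
        t = np.array([o.aging_days for o in obs])
        y = np.array([o.proportion for o in obs])
        n = np.array([o.n_seeds for o in obs], float)
        eta = np.clip(fit.coefficients[0] + fit.coefficients[1] * t, -8, 8)
        mu = np.clip(stats.norm.cdf(eta), 1e-12, 1 - 1e-12)
        chi2 = np.sum(n * (y - mu) ** 2 / (mu * (1 - mu)))
        assert dispersion_pearson(fit) == pytest.approx(chi2 / fit.residual_df, rel=1e-9)

    def test_matches_statsmodels_glm(self, design, rng):
        import statsmodels.api as sm

        obs = simulate_lot(1.8, 25.0, design, rho=0.08, rng=rng, lot_id="L")
        fit = fit_probit(obs, DesignMatrixSpec("single_lot", ("L",)))
        t = np.array([o.aging_days for o in obs])
        y = np.array([o.proportion for o in obs])
        n = np.array([o.n_seeds for o in obs], float)
        m = sm.GLM(
            y, sm.add_constant(t),
            family=sm.families.Binomial(sm.families.links.Probit()),
            var_weights=n,
        ).fit(scale="X2")
        assert fit.coefficients == pytest.approx(m.params, abs=1e-6)
        assert fit.dispersion_phi == pytest.approx(m.scale, rel=1e-5)
        assert np.sqrt(np.diag(fit.covariance)) == pytest.approx(m.bse, rel=1e-5)

    def test_degenerate_all_zero_flagged(self, design):
        dishes = exact_proportion_dishes(0.0, 0.0, [0, 10, 20])
        for d in dishes:
            d.n_germinated = 0.0
            d.proportion = 0.0
        fit = fit_probit(dishes, DesignMatrixSpec("single_lot", ("L",)))
        assert not fit.converged
        assert "degenerate" in fit.message

    def test_rank_deficiency_single_duration(self, design):
        dishes = exact_proportion_dishes(2.0, -0.1, [10])
        with pytest.raises(FitError):
            fit_probit(dishes, DesignMatrixSpec("single_lot", ("L",)))


class TestDispersion:
    def test_binomial_data_phi_near_one(self, design, rng):
        phis = []
        for _ in range(400):
            obs = simulate_lot(2.0, 20.0, design, rho=0.0, rng=rng, lot_id="L")
            phis.append(
                fit_probit(obs, DesignMatrixSpec("single_lot", ("L",))).dispersion_phi
            )
        assert np.mean(phis) == pytest.approx(1.0, abs=0.08)

    def test_beta_binomial_inflation(self, design, rng):
        """phi targets 1 + rho (n-1) = 3.9; a near-flat survival curve keeps
        expected proportions moderate so the Pearson statistic is well
        behaved at every duration."""
        phis = []
        for _ in range(400):
            obs = simulate_lot(0.8, 500.0, design, rho=0.1, rng=rng, lot_id="L")
            phis.append(
                fit_probit(obs, DesignMatrixSpec("single_lot", ("L",))).dispersion_phi
            )
        assert np.mean(phis) == pytest.approx(3.9, abs=0.35)

    def test_zero_residuals_zero_phi(self):
        dishes = exact_proportion_dishes(2.0, -0.1, range(0, 45, 5))
        fit = fit_probit(dishes, DesignMatrixSpec("single_lot", ("L",)))
        assert fit.dispersion_phi == pytest.approx(0.0, abs=1e-12)


def _fake_fit(beta, se, df, spec=None):
    cov = np.diag(np.asarray(se, float) ** 2)
    return ProbitFitResult(
        coefficients=np.asarray(beta, float), covariance=cov, cov_unscaled=cov,
        dispersion_phi=1.0, deviance=0.0, pearson_chi2=float(df), residual_df=df,
        n_obs=df + len(beta), converged=True,
        spec=spec or DesignMatrixSpec("single_lot", ("L",)),
    )


class TestWald:
    def test_t_statistic_and_tail(self):
        fit = _fake_fit([2.0, -0.1], [0.5, 0.02], df=28)
        t, p = slope_wald_test(fit, 1)
        assert t == pytest.approx(-5.0)
        # oracle: t tail by numerical integration of the density
        from scipy.integrate import quad

        tail, _ = quad(lambda x: stats.t.pdf(x, 28), 5.0, np.inf)
        assert p == pytest.approx(2 * tail, rel=1e-6)
        assert p < 0.001

    def test_zero_coefficient_p_one(self):
        fit = _fake_fit([2.0, 0.0], [0.5, 0.02], df=28)
        assert slope_wald_test(fit, 1)[1] == 1.0

    def test_invariance_to_time_rescaling(self, design, rng):
        obs = simulate_lot(2.0, 20.0, design, rho=0.05, rng=rng, lot_id="L")
        fit_d = fit_probit(obs, DesignMatrixSpec("single_lot", ("L",)))
        hours = [
            type(o)(**{**o.__dict__, "aging_days": o.aging_days * 24.0})
            for o in obs
        ]
        fit_h = fit_probit(hours, DesignMatrixSpec("single_lot", ("L",)))
        assert fit_h.coefficients[1] == pytest.approx(fit_d.coefficients[1] / 24.0, rel=1e-8)
        assert slope_wald_test(fit_h, 1)[1] == pytest.approx(
            slope_wald_test(fit_d, 1)[1], rel=1e-6
        )
        est_d = sigma_from_fit(fit_d, "L")
        est_h = sigma_from_fit(fit_h, "L")
        assert est_h.sigma_days == pytest.approx(24.0 * est_d.sigma_days, rel=1e-8)


class TestNestedF:
    def test_identical_models_f_zero(self, design, rng):
        obs = simulate_lot(2.0, 20.0, design, rho=0.05, rng=rng, lot_id="A")
        fit = fit_probit(obs, DesignMatrixSpec("single_lot", ("A",)))
        f, dfn, dfd, p = nested_f_test(fit, fit)
        assert (f, p) == (0.0, 1.0)

    def test_non_nested_rejected(self, design, rng):
        a = simulate_lot(2.0, 20.0, design, rho=0.0, rng=rng, lot_id="A")
        b = simulate_lot(2.0, 20.0, design, rho=0.0, rng=rng, lot_id="B")
        full = fit_probit(a + b, DesignMatrixSpec("lot_intercepts_lot_slopes", ("A", "B")))
        other = fit_probit(a, DesignMatrixSpec("single_lot", ("A",)))
        with pytest.raises(ValueError):
            nested_f_test(full, other)

    def test_power_distinct_sigmas(self, design, rng):
        """Two lots with sigma 10 vs 40 days: the interaction test should
        nearly always reject."""
        rej = 0
        n_sim = 200
        for _ in range(n_sim):
            obs = simulate_lot(2.0, 10.0, design, rho=0.05, rng=rng, lot_id="A") + \
                simulate_lot(2.0, 40.0, design, rho=0.05, rng=rng, lot_id="B")
            full = fit_probit(obs, DesignMatrixSpec("lot_intercepts_lot_slopes", ("A", "B")))
            red = fit_probit(obs, DesignMatrixSpec("lot_intercepts_common_slope", ("A", "B")))
            rej += nested_f_test(full, red)[3] < 0.05
        assert rej / n_sim > 0.9


class TestSigma:
    def test_point_estimate_arithmetic(self):
        fit = _fake_fit([2.0, -0.05], [0.1, 0.01], df=28)
        assert sigma_from_fit(fit, "L").sigma_days == pytest.approx(20.0)

    def test_boundary_sigma_72(self):
        fit = _fake_fit([2.0, -1.0 / 72.0], [0.1, 0.001], df=28)
        assert sigma_from_fit(fit, "L").sigma_days == pytest.approx(72.0)

    def test_ci_endpoint_transform(self):
        """slope -0.1, SE 0.02, df 28: CI from mapping the slope t-interval
        through x -> -1/x (values frozen from the t-quantile oracle)."""
        fit = _fake_fit([2.0, -0.1], [0.1, 0.02], df=28)
        est = sigma_from_fit(fit, "L")
        tq = stats.t.ppf(0.975, 28)
        assert est.ci_low_days == pytest.approx(-1.0 / (-0.1 - tq * 0.02), rel=1e-9)
        assert est.ci_high_days == pytest.approx(-1.0 / (-0.1 + tq * 0.02), rel=1e-9)
        assert est.ci_low_days == pytest.approx(7.0938, abs=1e-3)
        assert est.ci_high_days == pytest.approx(16.9400, abs=1e-3)
        assert est.ci_low_days <= est.sigma_days <= est.ci_high_days

    def test_positive_slope_flagged(self):
        fit = _fake_fit([2.0, 0.02], [0.1, 0.01], df=28)
        est = sigma_from_fit(fit, "L")
        assert est.sigma_days is None and "non-negative" in est.flag

    def test_interval_reaching_zero_flagged(self):
        fit = _fake_fit([2.0, -0.01], [0.1, 0.02], df=28)
        est = sigma_from_fit(fit, "L")
        assert est.sigma_days == pytest.approx(100.0)
        assert est.ci_low_days is None and "CI undefined" in est.flag

    def test_estimate_invariant_to_order_and_duplication(self, design, rng):
        obs = simulate_lot(2.0, 15.0, design, rho=0.05, rng=rng, lot_id="L")
        spec = DesignMatrixSpec("single_lot", ("L",))
        est = sigma_from_fit(fit_probit(obs, spec), "L")
        est_rev = sigma_from_fit(fit_probit(list(reversed(obs)), spec), "L")
        assert est_rev.sigma_days == pytest.approx(est.sigma_days, rel=1e-10)
        doubled = obs + [
            type(o)(**{**o.__dict__, "replicate_id": o.replicate_id + "x"}) for o in obs
        ]
        est2 = sigma_from_fit(fit_probit(doubled, spec), "L")
        assert est2.sigma_days == pytest.approx(est.sigma_days, rel=1e-8)
        assert (est2.ci_high_days - est2.ci_low_days) < (
            est.ci_high_days - est.ci_low_days
        )


class TestP50:
    def test_known_value(self):
        assert p50(probit(0.999), 10.0) == pytest.approx(30.902, abs=1e-2)

    def test_fifty_percent_start(self):
        assert p50(0.0, 25.0) == 0.0

    @given(st.floats(1.0, 100.0))
    def test_three_fold_ratio_for_any_sigma(self, sigma):
        ratio = p50(probit(0.999), sigma) / p50(probit(0.85), sigma)
        assert ratio == pytest.approx(2.98, abs=0.01)

    def test_equivalent_to_solving_cdf(self):
        """p50 solves Phi(ki + slope t) = 0.5."""
        ki, sigma = 1.7, 23.0
        t50 = p50(ki, sigma)
        assert inv_probit(ki - t50 / sigma) == pytest.approx(0.5, abs=1e-12)
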