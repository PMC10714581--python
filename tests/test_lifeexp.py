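"""Life-expectancy integrals: closed forms, identities, quadrature behaviour."""

import numpy as np
import pandas as pd
import pytest

from lifelost import (
    IntegrationScheme,
    Scenario,
    crude_probs,
    fit_expected_fpm,
    fit_fprm,
    le_cancer,
    le_cancer_crude_route,
    le_exp,
    lle,
    rmst_variants,
    simulate_comparators,
    true_values,
)
from lifelost.excess import predict_relative
from lifelost.population import predict_expected


@pytest.fixture(scope="module")
def const_hazard_fit():
    """df=1 fit to exponential ages: hazard ≈ exact constant rate r."""
    rng = np.random.default_rng(21)
    n = 30000
    r = 0.08
    td = rng.exponential(1.0 / r, size=n)
    t = np.minimum(td, 60.0)
    data = pd.DataFrame({
        "age_entry": np.full(n, 70.0),
        "age_exit": 70.0 + np.maximum(t, 1e-9),
        "died": (td <= 60.0).astype(int),
        "year_match": np.full(n, 1997.0),
    })
    return fit_expected_fpm(data, df_baseline=1)


class TestLeExp:
    def test_constant_hazard_closed_form(self, const_hazard_fit):
        """LE_exp for an exactly constant hazard r is (1 − e^{−r t*})/r."""
        import copy

        r, t_star = 0.08, 30.0
        # the fitted df=1 model approximately recovers the rate ...
        r_hat_grid = predict_expected(const_hazard_fit,
                                      np.linspace(70.5, 99.5, 40))["hazard"]
        assert np.allclose(r_hat_grid, r, rtol=0.05)
        # ... and with coefficients set to the exact exponential ln H = ln r + ln a
        # the quadrature must hit the closed form to integration tolerance
        fit = copy.deepcopy(const_hazard_fit)
        raw = np.zeros(fit.design.n_params)
        raw[0], raw[1] = np.log(r), 1.0
        fit.theta = fit.design.to_ortho_coefs(raw)
        est = le_exp(fit, a0=70.0, scheme=IntegrationScheme(t_star=t_star),
                     with_gradient=False)
        closed = (1.0 - np.exp(-r * t_star)) / r
        assert est.value == pytest.approx(closed, abs=1e-4)

    def test_quadrature_matches_fine_trapezoid_oracle(self, small_fits):
        """Gauss–Legendre vs a 10^6-step trapezoid of the same fitted S*."""
        fit2 = small_fits["fit2"]
        a0 = 67.0
        est = le_exp(fit2, a0=a0, with_gradient=False)
        u = np.linspace(0.0, 110.0 - a0, 1_000_001)
        s0 = predict_expected(fit2, np.array([a0]))["survival"][0]
        s = predict_expected(fit2, a0 + np.maximum(u, 1e-12))["survival"] / s0
        oracle = np.trapezoid(s, u)
        assert est.value == pytest.approx(oracle, abs=1e-3)

    def test_zero_hazard_gives_t_star(self, small_fits):
        """If H ≈ 0 over the window the integrand is 1 and LE_exp = t*."""
        import copy

        fit2 = copy.deepcopy(small_fits["fit2"])
        raw = np.zeros(fit2.design.n_params)
        raw[0] = -40.0  # ln H = -40 everywhere: hazard effectively zero
        fit2.theta = fit2.design.to_ortho_coefs(raw)
        sch = IntegrationScheme(t_star=20.0)
        est = le_exp(fit2, a0=70.0, scheme=sch, with_gradient=False)
        assert est.value == pytest.approx(20.0, abs=1e-6)


class TestLeCancer:
    def test_zero_excess_reduces_to_le_exp(self, small_fits):
        """An excess fit with Λ ≈ 0 makes LE_C = LE_exp."""
        import copy

        fit1 = copy.deepcopy(small_fits["fit1"])
        raw = np.zeros(fit1.design.n_params)
        raw[0] = -40.0  # ln Λ = -40: R ≡ 1 for practical purposes
        fit1.theta = fit1.design.to_ortho_coefs(raw)
        fit2 = small_fits["fit2"]
        cov = {"age_dx": 70.0}
        a = le_cancer(fit1, fit2, 70.0, cov, with_gradient=False)
        b = le_exp(fit2, 70.0, cov, with_gradient=False)
        assert a.value == pytest.approx(b.value, abs=2e-4)

    def test_pure_net_survival_when_sstar_is_one(self, small_fits):
        """S* ≡ 1 limit: LE_C = restricted mean of net survival R."""
        import copy

        fit2 = copy.deepcopy(small_fits["fit2"])
        raw = np.zeros(fit2.design.n_params)
        raw[0] = -40.0
        fit2.theta = fit2.design.to_ortho_coefs(raw)
        fit1 = small_fits["fit1"]
        cov = {"age_dx": 70.0}
        sch = IntegrationScheme(t_star=40.0)
        est = le_cancer(fit1, fit2, 70.0, cov, scheme=sch, with_gradient=False)
        u = np.linspace(1e-9, 40.0, 1_000_001)
        r = predict_relative(fit1, u, {"age_dx": np.full_like(u, 70.0)})[
            "relative_survival"]
        assert est.value == pytest.approx(np.trapezoid(r, u), abs=1e-3)

    def test_crude_probability_route_agrees(self, small_fits):
        """t* − ∫(Cr_c + Cr_o) equals the direct R·S* integral to 1e-4 y."""
        fit1, fit2 = small_fits["fit1"], small_fits["fit2"]
        cov = {"age_dx": 72.0}
        direct = le_cancer(fit1, fit2, 72.0, cov, with_gradient=False).value
        via_crude = le_cancer_crude_route(fit1, fit2, 72.0, cov)
        assert via_crude == pytest.approx(direct, abs=1e-4)


class TestCrudeProbs:
    def test_small_t_near_zero(self, small_fits):
        cr = crude_probs(small_fits["fit1"], small_fits["fit2"], 1e-6, 70.0,
                         {"age_dx": 70.0})
        assert cr["Cr_cancer"] < 1e-3 and cr["Cr_other"] < 1e-3

    def test_sum_identity_with_survival(self, small_fits):
        """Cr_cancer(t) + Cr_other(t) = 1 − R(t)·S*(t+a0)/S*(a0) to 1e-6."""
        fit1, fit2 = small_fits["fit1"], small_fits["fit2"]
        a0 = 68.0
        cov = {"age_dx": a0}
        s0 = predict_expected(fit2, np.array([a0]))["survival"][0]
        for t in np.linspace(0.8, 35.0, 10):
            cr = crude_probs(fit1, fit2, t, a0, cov)
            r = predict_relative(fit1, np.array([t]), {"age_dx": np.array([a0])})[
                "relative_survival"][0]
            s = predict_expected(fit2, np.array([a0 + t]))["survival"][0] / s0
            assert cr["Cr_cancer"] + cr["Cr_other"] == pytest.approx(
                1.0 - r * s, abs=1e-6)

    def test_monotone_in_t(self, small_fits):
        fit1, fit2 = small_fits["fit1"], small_fits["fit2"]
        cov = {"age_dx": 70.0}
        ts = np.linspace(0.5, 30.0, 8)
        vals = [crude_probs(fit1, fit2, t, 70.0, cov) for t in ts]
        cc = [v["Cr_cancer"] for v in vals]
        co = [v["Cr_other"] for v in vals]
        assert np.all(np.diff(cc) >= -1e-12) and np.all(np.diff(co) >= -1e-12)

    def test_zero_hstar_single_cause_limit(self, small_fits):
        """h* ≡ 0 (S* ≡ 1): Cr_other = 0 and Cr_cancer = 1 − R(t)."""
        import copy

        fit1 = small_fits["fit1"]
        fit2 = copy.deepcopy(small_fits["fit2"])
        raw = np.zeros(fit2.design.n_params)
        raw[0] = -40.0  # expected hazard effectively zero
        fit2.theta = fit2.design.to_ortho_coefs(raw)
        t, cov = 5.0, {"age_dx": 70.0}
        cr = crude_probs(fit1, fit2, t, 70.0, cov)
        r = predict_relative(fit1, np.array([t]), {"age_dx": np.array([70.0])})[
            "relative_survival"][0]
        assert cr["Cr_other"] == pytest.approx(0.0, abs=1e-8)
        assert cr["Cr_cancer"] == pytest.approx(1.0 - r, abs=1e-6)


class TestLLEAndRmst:
    def test_lle_identity_machine_precision(self, small_fits):
        fit1, fit2 = small_fits["fit1"], small_fits["fit2"]
        cov = {"age_dx": 75.0}
        l = lle(fit1, fit2, 75.0, cov)
        c = le_cancer(fit1, fit2, 75.0, cov)
        e = le_exp(fit2, 75.0, cov, fit1=fit1)
        assert l.value + c.value == pytest.approx(e.value, abs=1e-12)
        assert np.allclose(l.gradient, e.gradient - c.gradient, atol=1e-12)

    def test_lle_within_3se_of_simulation_truth(self, small_scenario, small_fits):
        from lifelost.uncertainty import BlockCovariance, se_from

        fit1, fit2 = small_fits["fit1"], small_fits["fit2"]
        est = lle(fit1, fit2, 70.0, {"age_dx": 70.0})
        truth = true_values(small_scenario, 70.0, 1997.0, n_steps=200000)["lle"]
        se = se_from(est.gradient, BlockCovariance(V2=fit2.vcov, V1=fit1.vcov))
        assert abs(est.value - truth) < 3.0 * se + 0.05

    def test_rmst_variants_window(self, small_fits):
        fit1, fit2 = small_fits["fit1"], small_fits["fit2"]
        cov = {"age_dx": 70.0}
        out = rmst_variants(fit1, fit2, 70.0, cov, window=15.0,
                            with_gradient=False)
        # restricted versions are bounded by the window and by the full values
        assert 0 < out["rmst_c"].value < out["rmst_exp"].value < 15.0
        assert out["lrmst"].value == pytest.approx(
            out["rmst_exp"].value - out["rmst_c"].value, abs=1e-12)
        full = lle(fit1, fit2, 70.0, cov, with_gradient=False)
        assert out["lrmst"].value < full.value
        # window = t* reproduces the unrestricted value
        t_star = full.t_star
        same = rmst_variants(fit1, fit2, 70.0, cov, window=t_star,
                             with_gradient=False)
        assert same["lrmst"].value == pytest.approx(full.value, abs=1e-10)

    def test_tiny_window_near_zero(self, small_fits):
        out = rmst_variants(small_fits["fit1"], small_fits["fit2"], 70.0,
                            {"age_dx": 70.0}, window=1e-4, with_gradient=False)
        assert out["rmst_exp"].value == pytest.approx(1e-4, rel=1e-3)
        assert abs(out["lrmst"].value) < 1e-6

    def test_quadrature_doubling_converged(self, small_fits):
        fit1, fit2 = small_fits["fit1"], small_fits["fit2"]
        cov = {"age_dx": 70.0}
        v100 = lle(fit1, fit2, 70.0, cov,
                   scheme=IntegrationScheme(n_nodes=100), with_gradient=False).value
        v200 = lle(fit1, fit2, 70.0, cov,
                   scheme=IntegrationScheme(n_nodes=200), with_gradient=False).value
        assert abs(v200 - v100) < 1e-4

    def test_protective_excess_degenerates_to_zero_loss(self, const_hazard_fit):
        """Uniformly protective data drives LLE to its structural floor.

        Because the model writes R = exp(−exp(ln Λ)), the cumulative excess
        hazard is positive and R < 1 everywhere, so LLE ≥ 0 by construction.
        Data in which patients die SLOWER than expected (true excess −0.03/y)
        must therefore collapse to R ≈ 1 and LLE ≈ 0, not go negative.
        """
        rng = np.random.default_rng(14)
        n = 4000
        td = rng.exponential(1.0 / 0.05, size=n)  # expected rate is 0.08
        t = np.minimum(td, 15.0)
        pat = pd.DataFrame({
            "t": np.maximum(t, 1e-9), "died": (td <= 15.0).astype(int),
            "age_dx": np.full(n, 70.0), "year_dx": np.full(n, 1997.0),
        })
        pat["h_star"] = 0.08
        fit1 = fit_fprm(pat, df_baseline=1)
        r = predict_relative(fit1, np.linspace(0.5, 15.0, 30))["relative_survival"]
        assert np.all(r <= 1.0)
        est = lle(fit1, const_hazard_fit, 70.0, {},
                  scheme=IntegrationScheme(t_star=15.0), with_gradient=False)
        assert -1e-9 <= est.value < 0.3
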