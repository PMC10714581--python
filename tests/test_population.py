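"""Attained-age FPM with delayed entry, Poisson rates, life-table lookup."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from lifelost.exceptions import DomainError, InsufficientEventsError
from lifelost.population import (
    RateTable,
    fit_expected_fpm,
    fit_poisson_rates,
    lexis_split,
    lookup_life_table,
    merge_expected_rates,
    predict_expected,
)


def _sim_exponential(rate, n, entry, admin, seed):
    rng = np.random.default_rng(seed)
    td = rng.exponential(1.0 / rate, size=n)
    t = np.minimum(td, admin)
    return pd.DataFrame({
        "age_entry": np.full(n, float(entry)),
        "age_exit": entry + np.maximum(t, 1e-9),
        "died": (td <= admin).astype(int),
        "year_match": np.full(n, 1997.0),
    })


def _sim_gompertz(alpha, b, n, rng, entry_lo=50.0, entry_hi=90.0, admin=15.0):
    a0 = rng.uniform(entry_lo, entry_hi, size=n)
    e = rng.exponential(size=n)
    A = np.exp(alpha + b * a0)
    td = np.log1p(b * e / A) / b
    t = np.minimum(td, admin)
    return pd.DataFrame({
        "age_entry": a0,
        "age_exit": a0 + np.maximum(t, 1e-9),
        "died": (td <= admin).astype(int),
        "year_match": np.full(n, 1997.0),
    })


class TestExpectedFPM:
    def test_constant_hazard_recovered(self):
        data = _sim_exponential(0.05, 20000, entry=70.0, admin=15.0, seed=10)
        fit = fit_expected_fpm(data, df_baseline=1)
        pred = predict_expected(fit, np.array([75.0, 85.0]))
        assert np.allclose(pred["hazard"], 0.05, rtol=0.10)

    def test_no_deaths_rejected(self):
        data = pd.DataFrame({
            "age_entry": [70.0], "age_exit": [75.0], "died": [0],
            "year_match": [1997.0],
        })
        with pytest.raises(InsufficientEventsError):
            fit_expected_fpm(data, df_baseline=1)

    def test_gompertz_conditional_survival_closed_form(self):
        # h*(a) = exp(-10) * exp(0.1 a), delayed entry at matching ages 50-90
        rng = np.random.default_rng(3)
        data = _sim_gompertz(-10.0, 0.1, 5000, rng, admin=40.0)
        fit = fit_expected_fpm(data, df_baseline=5)
        ages = np.linspace(70.0, 90.0, 9)
        pred = predict_expected(fit, ages)
        s_cond = pred["survival"] / predict_expected(fit, np.array([70.0]))["survival"][0]
        H = lambda a: np.exp(-10.0) / 0.1 * (np.exp(0.1 * a) - 1.0)
        s_true = np.exp(-(H(ages) - H(70.0)))
        assert np.max(np.abs(s_cond - s_true)) < 0.02

    def test_markov_split_invariance(self):
        """Splitting records at an interior age leaves the fit unchanged."""
        rng = np.random.default_rng(8)
        data = _sim_gompertz(-10.0, 0.1, 800, rng)
        fit = fit_expected_fpm(data, df_baseline=2)
        mid = (data["age_entry"] + data["age_exit"]) / 2
        first = data.assign(age_exit=mid, died=0)
        second = data.assign(age_entry=mid)
        split = pd.concat([first, second], ignore_index=True)
        fit_split = fit_expected_fpm(split, df_baseline=2,
                                     design=fit.design)
        assert fit_split.loglik == pytest.approx(fit.loglik, abs=1e-4)
        assert np.allclose(fit_split.theta, fit.theta, atol=1e-4)

    def test_weibull_mle_matches_direct_optimisation(self):
        """df=1 on the age scale (no truncation) is exactly Weibull."""
        rng = np.random.default_rng(5)
        ages = rng.weibull(3.0, size=4000) * 80.0
        admin = 120.0
        data = pd.DataFrame({
            "age_entry": np.full(ages.size, 1e-8 + 1e-9),
            "age_exit": ages,
            "died": np.ones(ages.size, dtype=int),
            "year_match": np.full(ages.size, 1997.0),
        })
        # entry age ~0 contributes H(a0)~0: equivalent to no truncation
        data["age_entry"] = 0.0001
        fit = fit_expected_fpm(data, df_baseline=1)
        raw = fit.raw_coefs  # ln H = raw[0] + raw[1] ln a

        def negll(par):
            lnlam, p = par
            if p <= 0:
                return 1e10
            lam = np.exp(lnlam)
            H = lam * ages**p
            H0 = lam * 0.0001**p
            return -(np.sum(np.log(lam * p * ages ** (p - 1.0))) - H.sum() + H0 * ages.size)

        direct = minimize(negll, [-13.0, 3.0], method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        assert raw[1] == pytest.approx(direct.x[1], rel=1e-4)
        assert raw[0] == pytest.approx(direct.x[0], rel=1e-4)

    def test_se_shrinks_like_sqrt_n(self):
        ses, ns = [], [2500, 10000, 40000]
        for n in ns:
            rng = np.random.default_rng(100 + n)
            data = _sim_gompertz(-10.0, 0.1, n, rng)
            fit = fit_expected_fpm(data, df_baseline=1)
            ses.append(np.sqrt(fit.vcov[1, 1]))
        slope = np.polyfit(np.log(ns), np.log(ses), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.05)


class TestPredictExpected:
    def test_survival_identity_and_hazard_fd(self, small_fits):
        fit = small_fits["fit2"]
        rng = np.random.default_rng(0)
        ages = rng.uniform(55.0, 100.0, size=50)
        pred = predict_expected(fit, ages)
        assert np.allclose(pred["survival"], np.exp(-pred["H"]), rtol=1e-12)
        h = 1e-5
        Hp = predict_expected(fit, ages[:20] + h)["H"]
        Hm = predict_expected(fit, ages[:20] - h)["H"]
        assert np.allclose(pred["hazard"][:20], (Hp - Hm) / (2 * h), rtol=1e-5)

    def test_conditioning_at_entry_is_one(self, small_fits):
        fit = small_fits["fit2"]
        s = predict_expected(fit, np.array([70.0]))["survival"]
        assert s[0] / s[0] == 1.0


class TestPoissonRates:
    def test_single_cell_saturated(self):
        data = pd.DataFrame({
            "age_entry": np.full(40, 70.1),
            "age_exit": np.full(40, 70.9),
            "died": [1] * 10 + [0] * 30,
            "year_match": np.full(40, 1997.2),
        })
        table = fit_poisson_rates(data, saturated=True)
        assert table.rate_at(70, 1997) == pytest.approx(10 / (40 * 0.8))

    def test_two_cells_saturated_equal_hand_rates(self):
        # two disjoint cells: deaths/person-years 4/200 and 16/200
        def block(age, year, deaths, n, frac=0.5):
            return pd.DataFrame({
                "age_entry": np.full(n, age + 0.25),
                "age_exit": np.full(n, age + 0.25 + frac),
                "died": [1] * deaths + [0] * (n - deaths),
                "year_match": np.full(n, year + 0.2),
            })
        data = pd.concat([block(70, 1995, 4, 400), block(80, 1999, 16, 400)])
        table = fit_poisson_rates(data, saturated=True)
        assert table.rate_at(70, 1995) == pytest.approx(4 / 200.0)
        assert table.rate_at(80, 1999) == pytest.approx(16 / 200.0)

    def test_gompertz_rates_recovered_within_15pct(self, small_scenario, small_data):
        comp, _ = small_data
        table = fit_poisson_rates(comp, age_range=(55, 100), year_range=(1992, 2019))
        cells = lexis_split(comp)
        py = cells.groupby("age")["pyrs"].sum()
        ages = [a for a in py.index if py[a] >= 50 and 55 <= a <= 100]
        rel_err = [
            abs(table.rate_at(a, 1997) / small_scenario.pop_hazard(a + 0.5, 1997.5) - 1.0)
            for a in ages
        ]
        assert np.median(rel_err) < 0.15
        assert np.mean(np.asarray(rel_err) < 0.15) > 0.8

    def test_zero_deaths_degenerate(self):
        data = pd.DataFrame({
            "age_entry": [70.0], "age_exit": [71.5], "died": [0],
            "year_match": [1997.0],
        })
        with pytest.raises(InsufficientEventsError):
            fit_poisson_rates(data)


class TestLexisSplit:
    def test_persontime_conserved_and_one_death(self):
        data = pd.DataFrame({
            "age_entry": [69.3], "age_exit": [72.8], "died": [1],
            "year_match": [1996.6],
        })
        cells = lexis_split(data)
        assert cells["pyrs"].sum() == pytest.approx(3.5, abs=1e-12)
        assert cells["deaths"].sum() == 1
        # death lands in the cell containing the exit corner
        last = cells[cells["deaths"] == 1].iloc[0]
        assert last["age"] == 72 and last["year"] == 2000


class TestLifeTableLookup:
    def test_constant_rate(self):
        table = RateTable(np.arange(60, 80), np.arange(1990, 2010),
                          np.full((20, 20), 0.1))
        out = lookup_life_table(table, 65.0, 1995.0, 7.0)
        assert out["survival"] == pytest.approx(np.exp(-0.7), rel=1e-12)

    def test_two_year_piecewise_sum(self):
        rates = np.full((5, 5), 0.1)
        rates[1, 1] = 0.3  # second age-year diagonal cell
        table = RateTable(np.arange(70, 75), np.arange(2000, 2005), rates)
        out = lookup_life_table(table, 70.0, 2000.0, 2.0)
        assert out["survival"] == pytest.approx(np.exp(-0.4), rel=1e-12)

    def test_matches_bruteforce_accumulation(self):
        rng = np.random.default_rng(12)
        rates = rng.uniform(0.01, 0.5, size=(6, 6))
        table = RateTable(np.arange(70, 76), np.arange(2000, 2006), rates)
        for _ in range(20):
            a0 = rng.uniform(70.0, 72.0)
            y0 = rng.uniform(2000.0, 2002.0)
            t = rng.uniform(0.1, 3.5)
            # exact step-by-step accumulation: walk to the next integer age
            # or year boundary, accumulate rate x occupancy
            H, u = 0.0, 0.0
            while u < t:
                nxt = min(np.floor(a0 + u) + 1 - a0, np.floor(y0 + u) + 1 - y0, t)
                H += table.rate_at(a0 + (u + nxt) / 2, y0 + (u + nxt) / 2) * (nxt - u)
                u = nxt
            out = lookup_life_table(table, a0, y0, t)
            assert out["survival"] == pytest.approx(np.exp(-H), abs=1e-12)

    def test_out_of_range_signals_coordinate(self):
        table = RateTable(np.arange(70, 75), np.arange(2000, 2005),
                          np.full((5, 5), 0.1))
        with pytest.raises(DomainError, match="age"):
            lookup_life_table(table, 74.0, 2000.0, 3.0)

    def test_merge_uses_cohort_diagonal(self):
        rates = np.zeros((40, 40))
        rates[:, :] = 0.02
        rates[30, 25] = 0.7  # age 100, year 2015
        table = RateTable(np.arange(70, 110), np.arange(1990, 2030), rates)
        pats = pd.DataFrame({
            "t": [10.4], "died": [1], "age_dx": [90.2], "year_dx": [2005.1],
        })
        merged = merge_expected_rates(pats, table)
        assert merged["h_star"].iloc[0] == pytest.approx(0.7)
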