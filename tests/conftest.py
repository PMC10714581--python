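"""Shared fixtures: one small simulated study, fitted once per session.

The small study uses a compact, correctly-specified model pair (the excess
hazard is exactly Weibull with a log-linear age effect, so a 1-df baseline
plus linear age covariate is the true model) to keep the suite fast while
still exercising every stage: simulation, delayed-entry FPM, Poisson rates,
h* merging and the excess-hazard fit.
"""

import numpy as np
import pandas as pd
import pytest

from lifelost import (
    Scenario,
    fit_expected_fpm,
    fit_fprm,
    fit_poisson_rates,
    merge_expected_rates,
    simulate_comparators,
    simulate_patients,
)


@pytest.fixture(scope="session")
def small_scenario():
    return Scenario(n_comparators=2000, n_patients=1000, year_trend=0.0, seed=42)


@pytest.fixture(scope="session")
def small_data(small_scenario):
    comp = simulate_comparators(small_scenario)
    pat = simulate_patients(small_scenario)
    return comp, pat


@pytest.fixture(scope="session")
def small_fits(small_scenario, small_data):
    comp, pat = small_data
    fit2 = fit_expected_fpm(comp, df_baseline=3)
    table = fit_poisson_rates(
        comp, age_range=(int(comp.age_entry.min()), 106), year_range=(1990, 2021)
    )
    pat_h = merge_expected_rates(pat, table)
    fit1 = fit_fprm(pat_h, df_baseline=1, covariate_spec=[("age_dx", 1)])
    return {"fit1": fit1, "fit2": fit2, "table": table,
            "patients": pat_h, "comparators": comp}
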