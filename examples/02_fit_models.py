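"""Fit the two survival models whose parameters drive every estimate.

1. The comparator model: a flexible parametric model of the log cumulative
   hazard on log ATTAINED AGE with delayed entry (individuals enter the risk
   set at their matching age).  Its parameter covariance V2 is the expected-
   rate uncertainty that the package propagates.
2. An auxiliary Poisson model on a Lexis expansion supplies fixed expected
   rates h* per (age, year) cell for the excess-hazard likelihood.
3. The excess-hazard model: log cumulative EXCESS hazard on log time since
   diagnosis, with each patient's h* entering the likelihood as an offset.
"""

import numpy as np

from lifelost import (
    Scenario,
    fit_expected_fpm,
    fit_fprm,
    fit_poisson_rates,
    merge_expected_rates,
    predict_expected,
    predict_relative,
    simulate_comparators,
    simulate_patients,
)

scenario = Scenario(n_comparators=5000, n_patients=5000, seed=1)
comparators = simulate_comparators(scenario)
patients = simulate_patients(scenario)

expected_fit = fit_expected_fpm(
    comparators, df_baseline=5,
    covariate_spec=[("year_match", 3)], tvc_spec=[("year_match", 2, 2)],
)
print(f"comparator FPM: loglik={expected_fit.loglik:.1f}, "
      f"{expected_fit.n_params} parameters")
print("  baseline knots (log attained age):",
      np.round(expected_fit.design.baseline.knots, 3))

rate_table = fit_poisson_rates(comparators, df_age=5, df_year=3,
                               age_range=(50, 107), year_range=(1991, 2020))
patients = merge_expected_rates(patients, rate_table)
print(f"rate table: ages {rate_table.ages[0]}–{rate_table.ages[-1]}, "
      f"years {rate_table.years[0]}–{rate_table.years[-1]}")

excess_fit = fit_fprm(
    patients, df_baseline=5,
    covariate_spec=[("age_dx", 3)], tvc_spec=[("age_dx", 2, 3)],
)
print(f"excess FPRM:   loglik={excess_fit.loglik:.1f}, "
      f"{excess_fit.n_params} parameters")

pe = predict_expected(expected_fit, np.array([75.0, 85.0]),
                      {"year_match": np.array([1997.0, 1997.0])})
print("\nexpected mortality rate at ages 75/85 (per year):",
      np.round(pe["hazard"], 4))
pr = predict_relative(excess_fit, np.array([1.0, 5.0, 10.0]),
                      {"age_dx": np.full(3, 70.0)})
print("relative survival at 1/5/10 years (age 70 at dx):",
      np.round(pr["relative_survival"], 3))
# Relative survival is the fraction of patients surviving relative to what
# matched disease-free individuals would experience; its decay reflects the
# excess (cancer-attributable) mortality.
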