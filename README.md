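# lifelost

Loss in life expectancy for cancer patients, with the sampling uncertainty of
expected mortality rates propagated from a general-population **sample**.

## The problem

Population-based cancer studies summarise prognosis with the life expectancy
of patients since diagnosis (LE_C), the life expectancy they would have had
without the cancer (LE_exp), and the difference — the **loss in life
expectancy** (LLE).  These are computed in the relative-survival framework,
where the all-cause survival of patients factorises as

    S(t | Z) = R(t | Z₁) · S*(t | Z₂),

with S\* the expected survival of matched disease-free individuals and R the
relative (net) survival.  Conventionally S\* comes from national life tables
and is treated as known.  When whole-population life tables are unavailable —
matched-cohort studies, trials, registries lacking key covariates — S\* must
be **estimated from a sample** of comparators (here ~5,000 individuals), and
its sampling uncertainty is no longer negligible.  Ignoring it understates
the variances of LE_exp, LE_C and LLE, most severely for older patients.

## The method

Two flexible parametric (log-cumulative-hazard spline) survival models are
fitted:

* comparators, on attained age *a* with delayed entry:
  `ln H(a|Z₂) = s(ln a | γ₂, k₂) + β₂Z₂`, covariance **V₂**;
* patients, an excess-hazard model on time since diagnosis *t* with fixed
  expected rates h\* in the likelihood:
  `ln Λ(t|Z₁) = s(ln t | γ₁, k₁) + β₁Z₁`, covariance **V₁**.

Life-expectancy measures are integrals of the fitted survival curves up to a
horizon t\* (attained age 110 by default), e.g.

    LE_C(Z) = ∫₀^{t*} R(u|Z₁) · S*(u + a₀|Z₂) / S*(a₀|Z₂) du.

Because the two models share no parameters, the joint covariance is
block-diagonal, V = diag(V₂, V₁), and for the stacked gradient
G = (G_E\*; G_C) of (LE_exp, LE_C) the delta method gives

    Σ = Gᵀ V G,     Var(LLE) = Var(LE_exp) + Var(LE_C) − 2·Cov(LE_exp, LE_C).

The fixed-rates ("modelled w/o u.") variance restricts G to the
excess-model block and uses V₁ only; the variance inflation is summarised by
the relative % precision `RP = 100·((SE_wu/SE_wo)² − 1)`.  Marginal
(cohort-standardised) measures average the individual predictions over the
cancer cohort; their gradients average correspondingly.

## Worked example

```python
from lifelost import *

scenario = Scenario(n_comparators=5000, n_patients=5000, seed=1)
comparators = simulate_comparators(scenario)
patients = simulate_patients(scenario)

fit2 = fit_expected_fpm(comparators, df_baseline=5,
                        covariate_spec=[("year_match", 3)])
table = fit_poisson_rates(comparators, age_range=(50, 107),
                          year_range=(1991, 2020))
fit1 = fit_fprm(merge_expected_rates(patients, table), df_baseline=5,
                covariate_spec=[("age_dx", 3)])

V = BlockCovariance(V2=fit2.vcov, V1=fit1.vcov)
est = lle(fit1, fit2, 70.0, {"age_dx": 70.0, "year_match": 1997.0})
print(est.value, se_from(est.gradient, V))
```

Running `python examples/03_life_expectancy.py` (which executes exactly this
analysis) prints:

```
age 70, year 1997 (horizon t* = 40 y):
  LE_exp =  17.00 y   SE(w.u.) = 0.252   95% CI (16.50, 17.49)
  LE_C   =   7.28 y   SE(w.u.) = 0.185   95% CI (6.92, 7.64)
  LLE    =   9.72 y   SE(w.u.) = 0.251   95% CI (9.23, 10.21)

LLE SE with fixed expected rates : 0.171
LLE SE with rate uncertainty     : 0.251
RP = 115.4%  (variance inflation from acknowledging the comparator sample size)
```

A 70-year-old patient in this (colon-cancer-like) scenario loses on average
9.7 of her 17.0 expected remaining years.  Treating the 5,000-comparator
rates as fixed would report an LLE standard error of 0.171 instead of 0.251 —
the fixed-rates variance misses more than half of the true variance
(RP ≈ 115%).

The other scripts in `examples/` walk through simulation, model fitting and
the marginal comparison table; a thin `lifelost` CLI (`simulate`,
`fit-expected`, `fit-excess`, `predict`, `marginal`, `run`,
`validate-variance`) wraps the same functions for shell use.

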