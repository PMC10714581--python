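# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data generator and the known limitations of `lifelost`.

## Models

**Spline basis.** Both survival models place a restricted cubic spline on the
log cumulative hazard scale.  With knots `k₁ < … < k_K` the basis has `K − 1`
columns: the identity, plus one restricted cubic term per interior knot,
constrained to be linear beyond both boundary knots.  `df` counts the spline
coefficients excluding the intercept (`K = df + 1`); two knots give exactly a
Weibull (log-linear) model.  Knot placement: boundary knots at the min/max of
the uncensored log event values, interior knots at equally spaced centiles of
those values (the de-facto standard for this model family).  Covariate
splines use the same construction on the covariate's natural scale.
The **linear tail** is the extrapolation contract: beyond the last knot the
log cumulative (excess) hazard continues linearly in log time / log age,
which is what carries survival out to the horizon t*.

**Comparator model.**  `ln H(a|Z₂) = s(ln a|γ₂,k₂) + β₂Z₂` on attained age
with delayed entry: each record contributes
`d·ln h*(a) − [H(a) − H(a₀)]`, with `h* = H · ds/d ln a / a`.
Non-proportional effects enter as products of a covariate spline and a
spline of log age.  Default analysis settings: 5 df baseline, calendar year
at matching as a continuous covariate with 3 df, year×age interaction with
2 df × 2 df.

**Excess-hazard model.**  `ln Λ(t|Z₁) = s(ln t|γ₁,k₁) + β₁Z₁` on time since
diagnosis, each patient's fixed expected rate h\* at exit entering the
likelihood `d·ln(h* + λ) − Λ`.  The excess hazard λ may be negative wherever
the total stays positive.  Defaults: 5 df baseline, age at diagnosis with
3 df, age×log-time interaction with 2 df × 3 df.  Year of diagnosis is not
included by default (estimates still vary by year through the expected
rates); it can be added through the covariate spec.
Because `R = exp(−exp(ln Λ))`, relative survival is strictly below one:
uniformly protective exposures are represented by Λ → 0 (LLE → 0), not by
R > 1.

**Auxiliary Poisson rate model.**  The h\* values fed to the excess
likelihood come from a log-linear Poisson model on a Lexis expansion of the
comparators (default one-year bands in both attained age and calendar year),
with restricted-cubic effects of age and year (defaults 5 df and 3 df,
2 df × 2 df interaction), predicted per single-year cell and **treated as
fixed** thereafter.  A classical life-table lookup (piecewise-constant hazard
along the cohort diagonal) is provided for the conventional
fixed-whole-population mode; probability-dialect tables are converted with
rate = −ln(1 − p).

## Life-expectancy integrals

All measures integrate fitted survival over time since diagnosis on
`[0, t*]` with t\* defaulting to `110 − a₀` (everyone assumed dead by
attained age 110; override via `IntegrationScheme.t_star`).  Expected
survival is conditioned on being alive at a₀:
`S*(u + a₀|Z₂)/S*(a₀|Z₂)`.

* Outer integrals: Gauss–Legendre, 100 nodes (default).  Doubling the node
  count moves any LE value by < 1e−4 years, which we quote as the
  integration tolerance.  LLE is computed as LE_exp − LE_C on shared nodes,
  so LLE + LE_C = LE_exp holds to machine precision.
* Crude probabilities of death, `Cr_cancer = ∫ S*·R·λ` and
  `Cr_other = ∫ S*·R·h*`: the excess hazard behaves like `t^{ρ−1}` near 0
  (integrable singularity when the fitted log-time slope ρ < 1), so these
  use a graded mesh `u = t·s⁴` with (cumulative) Simpson weights, 2049
  nodes.  The competing-risks route
  `LE_C = t* − ∫ (Cr_cancer + Cr_other)` agrees with the direct product
  integral to ~1e−5 years and is kept as an internal cross-check.
* RMST variants replace t\* with a fixed window (default 15 years).

## Variance estimation

Parameter covariances V₂, V₁ are inverse observed information matrices:
central finite differences of the analytic score with step `1e−4·(1+|θ|)`,
symmetrised, inverted through an eigenvalue decomposition with a relative
floor of 1e−12 (guaranteeing positive semi-definiteness).

Gradients of LE functionals with respect to the stacked vector
θ = (β₂, γ₂, β₁, γ₁) are central finite differences with step
`1e−5·(1+|θⱼ|)`; the functional chain (fixed design tensors → matrix
product → exp → quadrature) is smooth and cheap, and the gradients were
validated against Richardson extrapolation.  Blocks a functional does not
touch come out exactly zero (LE_exp has an exactly-zero excess block).
Then `Σ = GᵀVG` with V block-diagonal, `Var(LLE)` by the
variance-of-difference identity (clamped at 0 with a warning if round-off
makes it ~−1e−16), and the fixed-rates mode restricts the quadratic form to
the excess block and V₁.  By positive semi-definiteness of the V₂ block the
fixed-rates variance can never exceed the with-uncertainty variance, so
RP ≥ 0 always.  Confidence intervals are normal-based on the natural (years)
scale by default; a log-scale option exists but is off.

Marginal measures are plain cohort averages of individual predictions
(regression standardisation over the cancer cohort itself; external weights
optional); by linearity their gradients equal the finite-difference gradient
of the mean functional, which is what is computed.

**Numerical fitting.**  BFGS on the unconstrained coefficients with analytic
scores; steps producing a non-positive total hazard at any death time are
rejected through a smooth exterior penalty; a Nelder–Mead restart backs up
the rare failure.  Initial values come from an OLS fit of a Nelson–Aalen
pseudo log cumulative hazard on the design (for the excess model the
all-cause Nelson–Aalen overestimates Λ, guaranteeing a feasible start).
Designs are orthogonalised by default via a stored QR transform; estimates
are invariant to toggling this (tested).

## Synthetic data generator

The generator emulates an older-female matched-cohort cancer study:

* population hazard `exp(α + γ_age·a + trend·(y − 1997))` with α = −13.2,
  γ_age = 0.125, trend = −0.01/yr — close to Swedish female all-cause rates
  (≈1.2%/yr at 70, ≈8%/yr at 85) with a 1%/yr secular decline;
* matching/diagnosis ages uniform 50–90, years uniform 1992–2004,
  administrative censoring at 15 years, 5,000 comparators and 5,000–9,000
  patients in the reference configurations;
* excess hazard `κρt^{ρ−1}·e^{φ(a₀−70)}` with κ = 0.25, ρ = 0.6, φ = 0.02 —
  decaying excess mortality and ~55% net survival at 5 years, a
  colon-cancer-like prognosis.

Along the cohort diagonal the population hazard is `A·e^{(γ_age+trend)u}`,
so its cumulative hazard is closed-form; comparator event ages are drawn by
exact inversion, patient event times (population + Weibull excess) by
vectorised bisection to 1e−9 years.  `true_values` integrates the exact
survival curves with a 10⁶-step trapezoid, independent of all model code.

What the generator does **not** emulate: emigration/loss to follow-up,
matching ratios and within-set correlation, non-comparability between the
sample and the patients' true background mortality, cohort effects beyond a
log-linear trend, and covariates other than age and calendar time.  Passing
tests therefore demonstrate correctness of the estimation and
variance-propagation machinery under a known, well-specified data law — not
robustness to those real-data features.

## Validation studies and their problem sizes

* Delta vs bootstrap: reference study (5,000 comparators, 5,000 patients,
  full default model specs); delta SEs of conditional and marginal LLE and
  LE_C agree with a 1,000-draw Gaussian parametric bootstrap within 10%.
* Variance dominance: 50 replicates at 1,200/600 with compact models; the
  with-uncertainty variance dominates on every replicate (structural).
* Coverage: 200 replicates at 2,000 comparators / 1,000 patients with
  compact, correctly specified models (trend-free scenario: 3 df comparator
  baseline, Weibull excess with linear age).  The trend is switched off here
  deliberately so the study isolates the variance-propagation property being
  claimed (see limitation below); 95% with-uncertainty intervals for
  marginal LLE cover the generator truth within the binomial band 91–98%.

## Known limitations

* **Calendar-trend approximation.**  With calendar year *at matching* as a
  proportional-hazards covariate (the conventional specification), the
  attained-age model cannot exactly represent a secular trend that acts on
  *attained* year: along a prediction diagonal the true hazard keeps
  declining while the model's year effect is frozen at baseline.  Under the
  generator's −1%/yr trend this leaves a systematic ≈ −0.3 to −0.5 year
  error in long-horizon LE_exp (and hence LLE); re-parameterising the
  covariate as birth year removes it for a log-linear trend.  The default
  keeps the conventional specification; the acceptance report states the
  resulting truth error honestly.
* The expected-rate uncertainty is propagated into the LE estimates but not
  into the excess-model *fit* itself — the h\* offsets in the excess
  likelihood remain the fixed Poisson predictions.
* First-order delta method: second-order (curvature) contributions to bias
  and variance of the nonlinear LE functionals are ignored; the bootstrap
  comparison bounds their practical impact at the reference sample sizes.
  Conversely, the Gaussian parametric bootstrap itself is tail-sensitive
  here: a handful of far-tail parameter draws in weakly identified
  tail-slope directions can explode the exp-exp functional and inflate the
  plain draw SD, which is why the validation oracle also offers an
  IQR-based robust scale.
* t\* is fixed (age 110); uncertainty in its choice is out of scope, as are
  cure models, frailty excess models and non-parametric net-survival
  estimators.
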