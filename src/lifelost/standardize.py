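"""Regression-standardised (marginal) life-expectancy measures.

The marginal estimate of a measure is the mean of the individual model
predictions over the N patients of the cancer cohort (the cohort itself is
the standard population).  Because the delta method is linear, the gradient
of the marginal measure is the mean of the individual gradients — computed
here directly as the finite-difference gradient of the mean functional.

:func:`compare_approaches` assembles the two-variance-mode comparison: the
point estimates are identical by construction; only the standard errors
differ between the fixed-rates mode ("modelled w/o u.", excess-model block
and V1 only) and the with-uncertainty mode ("modelled w.u.", full block
covariance), summarised by the relative % precision RP.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .lifeexp import IntegrationScheme, LEPredictor, LifeExpectancyEstimate
from .uncertainty import (
    BlockCovariance,
    confint,
    gradient_of,
    rp,
    se_from,
    sigma,
    var_fixed_rates,
    var_lle,
)

__all__ = ["marginal_estimate", "conditional_estimate_table", "compare_approaches"]

_KIND_KEY = {"le_exp": "le_exp", "rmst_exp": "le_exp",
             "le_c": "le_c", "rmst_c": "le_c",
             "lle": "lle", "lrmst": "lle"}


def _cohort_predictor(fit1, fit2, cohort: pd.DataFrame,
                      scheme: IntegrationScheme | None) -> LEPredictor:
    needed = {t.name for t, _ in fit2.design.covariate_terms}
    needed |= {t.name for t, _ in fit1.design.covariate_terms}
    needed |= {t.name for t, _, _ in fit2.design.tvc_terms}
    needed |= {t.name for t, _, _ in fit1.design.tvc_terms}
    missing = needed - set(cohort.columns)
    if missing:
        raise DomainError(f"cohort is missing model covariates {sorted(missing)}")
    cov = {k: cohort[k].to_numpy(dtype=float) for k in needed}
    # patients condition the expected survival on their age at diagnosis
    cov.setdefault("age_dx", cohort["age_dx"].to_numpy(dtype=float))
    if "year_dx" in cohort.columns:
        cov.setdefault("year_dx", cohort["year_dx"].to_numpy(dtype=float))
    a0 = cohort["age_dx"].to_numpy(dtype=float)
    return LEPredictor(fit2, fit1, a0, cov, scheme)


def marginal_estimate(fit1, fit2, cohort: pd.DataFrame, kind: str = "lle",
                      scheme: IntegrationScheme | None = None,
                      window: float = 15.0,
                      weights=None,
                      with_gradient: bool = True) -> LifeExpectancyEstimate:
    """Cohort-averaged measure with the averaged gradient.

    ``kind`` in {le_exp, le_c, lle, rmst_exp, rmst_c, lrmst}; the RMST kinds
    replace the horizon with ``window``.  Optional ``weights`` (e.g. an
    external standard population) re-weight the average; by default every
    patient carries weight 1/N.
    """
    if len(cohort) < 1:
        raise DomainError("empty cohort")
    if kind not in _KIND_KEY:
        raise DomainError(f"unknown kind {kind!r}")
    if kind.startswith(("rmst", "lrmst")):
        base = scheme or IntegrationScheme()
        scheme = IntegrationScheme(rule=base.rule, n_nodes=base.n_nodes, t_star=window)
    pred = _cohort_predictor(fit1, fit2, cohort, scheme)
    if weights is None:
        wts = np.full(pred.n, 1.0 / pred.n)
    else:
        wts = np.asarray(weights, dtype=float)
        wts = wts / wts.sum()
    key = _KIND_KEY[kind]

    def functional(theta):
        return float(pred.values(theta)[key] @ wts)

    value = functional(pred.theta0)
    grad = gradient_of(functional, pred.theta0) if with_gradient else None
    return LifeExpectancyEstimate(
        kind=kind, value=value, t_star=float(np.max(pred.t_star)),
        a0=float(np.average(pred.a0, weights=wts)), covariates={},
        gradient=grad, p2=pred.p2,
    )


def _measure_rows(estimates: dict, V: BlockCovariance, level: float) -> list[dict]:
    """Rows of the Table-1 style comparison for one set of estimates.

    ``estimates`` maps kind -> LifeExpectancyEstimate for the trio
    (le_exp-like, le_c-like, lle-like) on shared nodes.
    """
    exp_kind = [k for k in estimates if _KIND_KEY[k] == "le_exp"][0]
    c_kind = [k for k in estimates if _KIND_KEY[k] == "le_c"][0]
    l_kind = [k for k in estimates if _KIND_KEY[k] == "lle"][0]
    gE = estimates[exp_kind].gradient
    gC = estimates[c_kind].gradient
    sig = sigma(gE, gC, V)
    var_wu = {
        exp_kind: float(sig[0, 0]),
        c_kind: float(sig[1, 1]),
        l_kind: var_lle(sig),
    }
    var_wo = {
        exp_kind: 0.0,  # expected survival treated as fixed
        c_kind: var_fixed_rates(estimates[c_kind].gradient_block1, V.V1),
        l_kind: var_fixed_rates(estimates[l_kind].gradient_block1, V.V1),
    }
    rows = []
    for kind in (l_kind, c_kind, exp_kind):
        pe = estimates[kind].value
        se_wo = float(np.sqrt(var_wo[kind]))
        se_wu = float(np.sqrt(var_wu[kind]))
        for approach, se in (("modelled w/o u.", se_wo), ("modelled w.u.", se_wu)):
            lci, uci = confint(pe, se**2, level)
            is_wu = approach == "modelled w.u."
            rows.append({
                "measure": kind, "approach": approach, "PE": pe, "SE": se,
                "RP": rp(se_wu, se_wo) if (is_wu and se_wo > 0) else np.nan,
                "LCI": lci, "UCI": uci,
            })
    return rows


def compare_approaches(fit1, fit2, cohort: pd.DataFrame,
                       kinds: str = "both",
                       scheme: IntegrationScheme | None = None,
                       window: float = 15.0,
                       level: float = 0.95) -> pd.DataFrame:
    """Marginal comparison table in the two variance modes.

    One row per (measure, approach) with PE, SE, RP and normal-based CI.
    ``kinds``: "life_expectancy", "rmst", or "both".  Point estimates are
    identical between approaches — only SEs (and hence CIs and RP) differ.
    """
    V = BlockCovariance(V2=fit2.vcov, V1=fit1.vcov)
    rows = []
    if kinds in ("life_expectancy", "both"):
        est = {k: marginal_estimate(fit1, fit2, cohort, k, scheme)
               for k in ("lle", "le_c", "le_exp")}
        rows += _measure_rows(est, V, level)
    if kinds in ("rmst", "both"):
        est = {k: marginal_estimate(fit1, fit2, cohort, k, scheme, window=window)
               for k in ("lrmst", "rmst_c", "rmst_exp")}
        rows += _measure_rows(est, V, level)
    return pd.DataFrame(rows)


def conditional_estimate_table(fit1, fit2, ages, years,
                               scheme: IntegrationScheme | None = None,
                               level: float = 0.95,
                               age_name: str = "age_dx",
                               year_name: str = "year_dx") -> pd.DataFrame:
    """LE_exp, LE_C and LLE by age and year at diagnosis, both variance modes.

    Mirrors the presentation grid of population-based reports: one block of
    rows per (age, year) covariate pattern.
    """
    V = BlockCovariance(V2=fit2.vcov, V1=fit1.vcov)
    rows = []
    for a in ages:
        for y in years:
            cohort = pd.DataFrame({age_name: [a], year_name: [y]})
            est = {k: marginal_estimate(fit1, fit2, cohort, k, scheme)
                   for k in ("lle", "le_c", "le_exp")}
            for r in _measure_rows(est, V, level):
                rows.append({"age": a, "year": y, **r})
    return pd.DataFrame(rows)
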