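"""Flexible parametric relative survival model (excess-hazard model).

The log cumulative excess hazard is modelled as

    ln Λ(t|Z1) = s(ln t | γ1, k1) + β1·Z1,

optionally with time-dependent effects through covariate x log-time spline
interactions.  Each patient's expected mortality rate at exit, h*, enters the
likelihood as a fixed offset:

    l_i = d_i · ln[ h*_i + λ(t_i|Z1_i) ] + ln R(t_i|Z1_i),

with λ = Λ · (d s / d ln t) / t and ln R = −Λ.  The excess hazard λ may be
negative wherever the total hazard h* + λ stays positive.  Relative survival
and all extrapolation beyond the last knot follow the linear log-time tail of
the spline.

Patient data is a DataFrame with columns ``t, died, age_dx, year_dx`` plus an
``h_star`` column (expected rate at exit, merged in from a rate table) and any
covariates the model uses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DomainError, InsufficientEventsError
from .fpm import FPMDesign, LCHFit, build_design, fit_lch

__all__ = ["RelativeModelFit", "fit_fprm", "predict_relative"]


class RelativeModelFit(LCHFit):
    """Fitted excess-hazard model (parameters β1, γ1; covariance V1)."""


def _validate_patients(data: pd.DataFrame, require_hstar: bool):
    required = {"t", "died"}
    missing = required - set(data.columns)
    if missing:
        raise DomainError(f"patient table missing columns {sorted(missing)}")
    if np.any(data["t"].to_numpy(dtype=float) <= 0):
        raise DomainError("non-positive follow-up times")
    if require_hstar:
        if "h_star" not in data.columns:
            raise DomainError(
                "patient table needs an h_star column (expected rate at exit); "
                "merge one in with population.merge_expected_rates"
            )
        hs = data["h_star"].to_numpy(dtype=float)
        d = data["died"].to_numpy().astype(bool)
        if np.any(~np.isfinite(hs[d])) or np.any(hs < 0):
            raise DomainError("every death record needs a finite, non-negative h_star")


def fit_fprm(
    data: pd.DataFrame,
    df_baseline: int = 5,
    covariate_spec=None,
    tvc_spec=None,
    ortho: bool = True,
    design: FPMDesign | None = None,
) -> RelativeModelFit:
    """Maximise the excess-hazard likelihood with fixed expected rates.

    With all ``h_star`` equal to zero this reduces to an ordinary all-cause
    flexible parametric model.  Returns estimates plus V1, the inverse
    observed information.
    """
    _validate_patients(data, require_hstar=True)
    d = data["died"].to_numpy().astype(bool)
    if d.sum() < 1:
        raise InsufficientEventsError("patient cohort has no deaths")
    t = data["t"].to_numpy(dtype=float)
    lnt = np.log(t)
    hstar = data["h_star"].to_numpy(dtype=float)
    covs = {c: data[c].to_numpy(dtype=float) for c in data.columns
            if c not in ("t", "died", "h_star", "id")}
    if design is None:
        design = build_design(
            t[d],
            df_baseline,
            covariate_spec,
            tvc_spec,
            data=data,
            timescale_label="log time since diagnosis",
            ortho=ortho,
            fit_lnx=lnt,
            fit_covariates=covs,
        )
    fit = fit_lch(design, lnt, t, d, covariates=covs, hstar=hstar)
    return RelativeModelFit(**fit.__dict__)


def predict_relative(fit: RelativeModelFit, t, covariates=None) -> dict:
    """Cumulative excess hazard Λ, excess hazard λ and relative survival R.

    R = exp(−Λ); λ is the analytic derivative Λ · d s/d ln t / t including
    interaction terms.  Beyond the boundary knots the log cumulative excess
    hazard is linear in log time, which is what extrapolates R to t*.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise DomainError("time since diagnosis must be positive")
    lnt = np.log(t)
    covariates = covariates or {}
    X = fit.design.matrix(lnt, covariates)
    Xd = fit.design.deriv_matrix(lnt, covariates)
    lnL = X @ fit.theta
    Lam = np.exp(lnL)
    lam = Lam * (Xd @ fit.theta) / t
    return {"Lambda": Lam, "excess_hazard": lam, "relative_survival": np.exp(-Lam)}
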