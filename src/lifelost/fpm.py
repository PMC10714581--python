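"""Shared core for flexible parametric (log-cumulative-hazard spline) models.

Both survival models in the package live on this scale:

* the excess-hazard model:      ln Λ(t|Z1) = s(ln t | γ1, k1) + β1·Z1
* the population (expected)
  mortality model:              ln H(a|Z2) = s(ln a | γ2, k2) + β2·Z2

with optional non-proportional (time-varying) covariate effects formed as
products of a covariate spline and a spline of the log timescale.  This module
builds the design matrices (value and derivative with respect to the log
timescale), maximises the likelihoods, and computes the covariance of the
estimates as the inverse observed information.

The likelihood handled here is the general form

    l(θ) = Σ_i d_i · ln[ h*_i + H_i · u_i / x_i ] − Σ_i H_i + Σ_i H0_i

where ``H = exp(X θ)`` is the (excess or expected) cumulative hazard at exit,
``u = Xd θ`` is d ln H / d ln x, ``x`` is the timescale value at exit, ``h*``
is an optional fixed offset hazard (zero for the population model; the
expected mortality rate at exit for the excess model), and the ``H0`` term is
the delayed-entry correction (population model only).  The hazard itself may
not be positive everywhere — for the excess model only the total ``h* + λ``
must be positive at death times — so steps violating positivity are rejected
through a smooth penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .exceptions import ConvergenceError, InsufficientEventsError
from .splines import SplineBasis, make_knots

__all__ = [
    "TermSpec",
    "TvcSpec",
    "FPMDesign",
    "LCHFit",
    "build_design",
    "fit_lch",
]

_ETA_CAP = 50.0  # ln H above this is astronomically far from any optimum
_PENALTY = 1e8


@dataclass(frozen=True)
class TermSpec:
    """A continuous covariate entering through its own RCS (df=1 => linear)."""

    name: str
    df: int
    log: bool = False


@dataclass(frozen=True)
class TvcSpec:
    """A time-varying effect: covariate spline x spline of the log timescale."""

    name: str
    df_cov: int
    df_time: int
    log: bool = False


def _normalize_cov_spec(spec) -> tuple[TermSpec, ...]:
    if spec is None:
        return ()
    out = []
    for item in spec:
        if isinstance(item, TermSpec):
            out.append(item)
        else:
            out.append(TermSpec(*item))
    return tuple(out)


def _normalize_tvc_spec(spec) -> tuple[TvcSpec, ...]:
    if spec is None:
        return ()
    out = []
    for item in spec:
        if isinstance(item, TvcSpec):
            out.append(item)
        else:
            out.append(TvcSpec(*item))
    return tuple(out)


@dataclass
class FPMDesign:
    """Design-matrix builder for one log-cumulative-hazard model.

    Holds the baseline spline basis on the log timescale, one RCS basis per
    covariate, per-effect bases for time-varying effects, and (optionally) the
    QR-derived linear map that orthogonalises the fit-time design.  Because the
    map is stored, predictions are invariant to whether orthogonalisation is
    switched on.
    """

    baseline: SplineBasis
    covariate_terms: tuple = ()   # ((TermSpec, SplineBasis), ...)
    tvc_terms: tuple = ()         # ((TvcSpec, cov SplineBasis, time SplineBasis), ...)
    r_inv: np.ndarray | None = None  # (P, P); X_ortho = X_raw @ r_inv
    r_mat: np.ndarray | None = None  # inverse map, for constructing raw coefs

    @property
    def n_params(self) -> int:
        p = 1 + self.baseline.n_basis
        p += sum(t.df for t, _ in self.covariate_terms)
        p += sum(t.df_cov * t.df_time for t, _, _ in self.tvc_terms)
        return p

    @property
    def param_names(self) -> list[str]:
        names = ["gamma0"] + [f"gamma{j}" for j in range(1, self.baseline.n_basis + 1)]
        for term, _ in self.covariate_terms:
            names += [f"{term.name}_{j}" for j in range(1, term.df + 1)]
        for term, _, _ in self.tvc_terms:
            names += [
                f"{term.name}_tvc_{j}_{l}"
                for j in range(1, term.df_cov + 1)
                for l in range(1, term.df_time + 1)
            ]
        return names

    # -- raw (un-orthogonalised) matrices -------------------------------

    def _cov_value(self, term, covariates):
        v = np.asarray(covariates[term.name], dtype=float)
        return np.log(v) if term.log else v

    def raw_matrix(self, lnx, covariates) -> np.ndarray:
        """Design rows for ln H at log-timescale values ``lnx``."""
        lnx = np.asarray(lnx, dtype=float)
        cols = [np.ones_like(lnx)[..., None], self.baseline.eval(lnx)]
        for term, basis in self.covariate_terms:
            v = np.broadcast_to(self._cov_value(term, covariates), lnx.shape)
            cols.append(basis.eval(v))
        for term, cbasis, tbasis in self.tvc_terms:
            v = np.broadcast_to(self._cov_value(term, covariates), lnx.shape)
            c = cbasis.eval(v)                      # (..., df_cov)
            tt = tbasis.eval(lnx)                   # (..., df_time)
            prod = c[..., :, None] * tt[..., None, :]
            cols.append(prod.reshape(lnx.shape + (-1,)))
        return np.concatenate(cols, axis=-1)

    def raw_deriv_matrix(self, lnx, covariates) -> np.ndarray:
        """d(design)/d(lnx): derivative rows for the same parameterisation."""
        lnx = np.asarray(lnx, dtype=float)
        cols = [np.zeros_like(lnx)[..., None], self.baseline.deriv(lnx)]
        for term, basis in self.covariate_terms:
            cols.append(np.zeros(lnx.shape + (term.df,)))
        for term, cbasis, tbasis in self.tvc_terms:
            v = np.broadcast_to(self._cov_value(term, covariates), lnx.shape)
            c = cbasis.eval(v)
            td = tbasis.deriv(lnx)
            prod = c[..., :, None] * td[..., None, :]
            cols.append(prod.reshape(lnx.shape + (-1,)))
        return np.concatenate(cols, axis=-1)

    # -- public (possibly orthogonalised) matrices ----------------------

    def matrix(self, lnx, covariates=None) -> np.ndarray:
        X = self.raw_matrix(lnx, covariates or {})
        return X @ self.r_inv if self.r_inv is not None else X

    def deriv_matrix(self, lnx, covariates=None) -> np.ndarray:
        Xd = self.raw_deriv_matrix(lnx, covariates or {})
        return Xd @ self.r_inv if self.r_inv is not None else Xd

    def set_ortho_from(self, X_raw: np.ndarray) -> None:
        """Store the QR map that orthogonalises the given fit-time design."""
        n = X_raw.shape[0]
        r = np.linalg.qr(X_raw / np.sqrt(n), mode="r")
        sign = np.sign(np.diag(r))
        sign[sign == 0] = 1.0
        r = r * sign[:, None]
        self.r_mat = r
        self.r_inv = np.linalg.inv(r)

    def to_ortho_coefs(self, raw_coefs: np.ndarray) -> np.ndarray:
        return self.r_mat @ raw_coefs if self.r_mat is not None else raw_coefs

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "baseline": {
                "knots": self.baseline.knots.tolist(),
                "scale_label": self.baseline.scale_label,
            },
            "covariates": [
                {
                    "name": t.name,
                    "df": t.df,
                    "log": t.log,
                    "knots": b.knots.tolist(),
                    "scale_label": b.scale_label,
                }
                for t, b in self.covariate_terms
            ],
            "tvc": [
                {
                    "name": t.name,
                    "df_cov": t.df_cov,
                    "df_time": t.df_time,
                    "log": t.log,
                    "cov_knots": cb.knots.tolist(),
                    "time_knots": tb.knots.tolist(),
                }
                for t, cb, tb in self.tvc_terms
            ],
            "r_inv": None if self.r_inv is None else self.r_inv.tolist(),
            "r_mat": None if self.r_mat is None else self.r_mat.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FPMDesign":
        baseline = SplineBasis(
            np.asarray(d["baseline"]["knots"]), d["baseline"]["scale_label"]
        )
        cov = tuple(
            (
                TermSpec(c["name"], c["df"], c["log"]),
                SplineBasis(np.asarray(c["knots"]), c["scale_label"]),
            )
            for c in d["covariates"]
        )
        tvc = tuple(
            (
                TvcSpec(c["name"], c["df_cov"], c["df_time"], c["log"]),
                SplineBasis(np.asarray(c["cov_knots"])),
                SplineBasis(np.asarray(c["time_knots"])),
            )
            for c in d["tvc"]
        )
        r_inv = d.get("r_inv")
        r_mat = d.get("r_mat")
        return cls(
            baseline=baseline,
            covariate_terms=cov,
            tvc_terms=tvc,
            r_inv=None if r_inv is None else np.asarray(r_inv),
            r_mat=None if r_mat is None else np.asarray(r_mat),
        )


def build_design(
    event_timescale_values,
    df_baseline: int,
    covariate_spec=None,
    tvc_spec=None,
    data=None,
    timescale_label: str = "log time",
    ortho: bool = True,
    fit_lnx=None,
    fit_covariates=None,
) -> FPMDesign:
    """Choose knots and assemble an :class:`FPMDesign`.

    Baseline (and tvc time-spline) knots come from the uncensored event
    values on the log scale; covariate-spline knots from the covariate values
    over all records in ``data``.
    """
    baseline = make_knots(event_timescale_values, df_baseline, timescale_label, log=True)
    cov_terms = []
    for term in _normalize_cov_spec(covariate_spec):
        vals = np.asarray(data[term.name], dtype=float)
        basis = make_knots(vals, term.df, scale_label=term.name, log=term.log)
        cov_terms.append((term, basis))
    tvc_terms = []
    for term in _normalize_tvc_spec(tvc_spec):
        vals = np.asarray(data[term.name], dtype=float)
        cbasis = make_knots(vals, term.df_cov, scale_label=term.name, log=term.log)
        tbasis = make_knots(
            event_timescale_values, term.df_time, timescale_label, log=True
        )
        tvc_terms.append((term, cbasis, tbasis))
    design = FPMDesign(
        baseline=baseline,
        covariate_terms=tuple(cov_terms),
        tvc_terms=tuple(tvc_terms),
    )
    if ortho and fit_lnx is not None:
        design.set_ortho_from(design.raw_matrix(fit_lnx, fit_covariates or {}))
    return design


@dataclass
class LCHFit:
    """A fitted log-cumulative-hazard model."""

    design: FPMDesign
    theta: np.ndarray
    vcov: np.ndarray
    loglik: float
    n_events: int
    converged: bool
    grad_norm: float

    @property
    def n_params(self) -> int:
        return self.theta.size

    @property
    def raw_coefs(self) -> np.ndarray:
        """Coefficients on the raw (un-orthogonalised) basis."""
        if self.design.r_inv is None:
            return self.theta.copy()
        return self.design.r_inv @ self.theta

    def to_dict(self) -> dict:
        return {
            "design": self.design.to_dict(),
            "theta": self.theta.tolist(),
            "vcov": self.vcov.tolist(),
            "loglik": float(self.loglik),
            "n_events": int(self.n_events),
            "converged": bool(self.converged),
            "grad_norm": float(self.grad_norm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LCHFit":
        return cls(
            design=FPMDesign.from_dict(d["design"]),
            theta=np.asarray(d["theta"]),
            vcov=np.asarray(d["vcov"]),
            loglik=d["loglik"],
            n_events=d["n_events"],
            converged=d["converged"],
            grad_norm=d["grad_norm"],
        )


def _penalty_value_grad(theta, X, Xd, xvals, d, hstar):
    eta = np.minimum(X @ theta, _ETA_CAP)
    H = np.exp(eta)
    u = Xd @ theta
    tot = hstar + H * u / xvals
    bad = d & (tot <= 0.0)
    f = _PENALTY * (1.0 + (-tot[bad]).sum())
    dlam = (H[bad] / xvals[bad])[:, None] * (X[bad] * u[bad][:, None] + Xd[bad])
    g = -_PENALTY * dlam.sum(axis=0)
    return f, g


def _objective(theta, X, Xd, X0, xvals, d, hstar):
    with np.errstate(over="ignore", invalid="ignore"):
        eta = np.minimum(X @ theta, _ETA_CAP)
        H = np.exp(eta)
        u = Xd @ theta
        tot = hstar + H * u / xvals
        if np.any(tot[d] <= 0.0):
            return _penalty_value_grad(theta, X, Xd, xvals, d, hstar)
        tot_d = tot[d]
        ll = np.log(tot_d).sum() - H.sum()
        dlam_d = (H[d] / xvals[d])[:, None] * (X[d] * u[d][:, None] + Xd[d])
        grad = (dlam_d / tot_d[:, None]).sum(axis=0) - H @ X
        if X0 is not None:
            eta0 = np.minimum(X0 @ theta, _ETA_CAP)
            H0 = np.exp(eta0)
            ll += H0.sum()
            grad += H0 @ X0
        if not np.isfinite(ll):
            return _penalty_value_grad(theta, X, Xd, xvals, d, hstar)
        return -ll, -grad


def _observed_information(theta, args, rel_step=1e-4):
    """Central finite differences of the analytic score."""
    p = theta.size
    info = np.empty((p, p))
    for j in range(p):
        h = rel_step * (1.0 + abs(theta[j]))
        tp = theta.copy()
        tp[j] += h
        _, gp = _objective(tp, *args)
        tm = theta.copy()
        tm[j] -= h
        _, gm = _objective(tm, *args)
        info[j] = (gp - gm) / (2.0 * h)  # of the NEGATIVE loglik => information
    return 0.5 * (info + info.T)


def _psd_inverse(info):
    w, v = np.linalg.eigh(info)
    floor = max(w.max(), 1.0) * 1e-12
    w = np.maximum(w, floor)
    return (v / w) @ v.T


def fit_lch(
    design: FPMDesign,
    lnx,
    xvals,
    d,
    covariates=None,
    entry_lnx=None,
    hstar=None,
    init=None,
    gtol: float = 1e-8,
    maxiter: int = 2000,
) -> LCHFit:
    """Maximise the general LCH likelihood and return estimates + covariance.

    Parameters
    ----------
    lnx, xvals
        Log and natural timescale values at exit (ln t and t, or ln a and a).
    d
        Death indicators (0/1).
    entry_lnx
        Log timescale at entry for delayed-entry (left-truncated) data.
    hstar
        Fixed expected mortality rate at exit per record (excess model); the
        model's own hazard may go negative wherever ``hstar`` keeps the total
        positive.
    """
    covariates = covariates or {}
    lnx = np.asarray(lnx, dtype=float)
    xvals = np.asarray(xvals, dtype=float)
    d = np.asarray(d).astype(bool)
    n_events = int(d.sum())
    if n_events < 1:
        raise InsufficientEventsError("no deaths: the model is not identified")
    X = design.matrix(lnx, covariates)
    Xd = design.deriv_matrix(lnx, covariates)
    X0 = design.matrix(entry_lnx, covariates) if entry_lnx is not None else None
    hs = np.zeros_like(xvals) if hstar is None else np.asarray(hstar, dtype=float)
    args = (X, Xd, X0, xvals, d, hs)

    if init is None:
        init = _default_init(design, X, Xd, lnx, xvals, d, hs)
    res = minimize(
        _objective, init, args=args, jac=True, method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    f0, g0 = _objective(res.x, *args)
    if (not np.isfinite(f0)) or f0 >= _PENALTY or np.linalg.norm(g0) > 1e-3 * (1 + abs(f0)):
        # restart: simplex walk out of a bad region, then quasi-Newton polish
        res_nm = minimize(
            lambda th: _objective(th, *args)[0], init, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        res2 = minimize(
            _objective, res_nm.x, args=args, jac=True, method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
        if res2.fun <= res.fun:
            res = res2
        f0, g0 = _objective(res.x, *args)
    grad_norm = float(np.linalg.norm(g0))
    if f0 >= _PENALTY:
        raise ConvergenceError(
            f"optimiser stuck in infeasible region (gradient norm {grad_norm:.3g})",
            grad_norm,
        )
    converged = grad_norm <= 1e-3 * (1.0 + abs(f0))
    if not converged:
        raise ConvergenceError(
            f"no convergence after restarts; last gradient norm {grad_norm:.3g}",
            grad_norm,
        )
    info = _observed_information(res.x, args)
    vcov = _psd_inverse(info)
    return LCHFit(
        design=design,
        theta=res.x.copy(),
        vcov=vcov,
        loglik=-float(f0),
        n_events=n_events,
        converged=converged,
        grad_norm=grad_norm,
    )


def _default_init(design, X, Xd, lnx, xvals, d, hstar):
    """OLS of a Nelson–Aalen pseudo log cumulative hazard on the design.

    For the excess model the all-cause Nelson–Aalen overestimates the excess
    cumulative hazard, which guarantees a valid (positive total hazard)
    starting point.
    """
    from lifelines import NelsonAalenFitter

    naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
    naf.fit(durations=xvals, event_observed=d.astype(int))
    na = naf.cumulative_hazard_at_times(xvals[d]).to_numpy()
    y = np.log(np.maximum(na, 1e-8))
    Xdth = X[d]
    theta0, *_ = np.linalg.lstsq(Xdth, y, rcond=None)
    # validity check: total hazard positive at deaths
    eta = np.minimum(X @ theta0, _ETA_CAP)
    tot = hstar + np.exp(eta) * (Xd @ theta0) / xvals
    if np.all(tot[d] > 0):
        return theta0
    # fall back to a plain Weibull-like line on the raw scale
    lx = lnx[d]
    slope, icpt = np.polyfit(lx, y, 1)
    slope = max(slope, 0.2)
    raw = np.zeros(design.n_params)
    raw[0] = icpt
    raw[1] = slope
    return design.to_ortho_coefs(raw)
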