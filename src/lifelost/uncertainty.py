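"""Delta-method variance machinery.

The two fitted models share no parameters, so the joint covariance of the
stacked parameter vector θ = (β2, γ2, β1, γ1) is block-diagonal:

    V = [[V2, 0], [0, V1]].

For any smooth functional of θ (a life-expectancy integral), the gradient G
is obtained by central finite differences, and for the pair
(LE_exp, LE_C) the 2x2 matrix

    Σ = Gᵀ V G,   G = (G_E*; G_C)

holds Var(LE_exp), Var(LE_C) and their covariance, from which

    Var(LLE) = Var(LE_exp) + Var(LE_C) − 2·Cov(LE_exp, LE_C).

The fixed-rates ("modelled w/o uncertainty") variance restricts the gradient
to the excess-model block and uses V1 only; it is simultaneously Var(LE_C)
and Var(LLE) in that mode, and can never exceed the with-uncertainty
variance (the V2 block is positive semi-definite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DomainError

__all__ = [
    "gradient_of",
    "BlockCovariance",
    "sigma",
    "var_lle",
    "var_fixed_rates",
    "rp",
    "confint",
    "se_from",
]


def gradient_of(functional, theta, rel_step: float = 1e-5) -> np.ndarray:
    """Central-finite-difference gradient of a scalar (or vector) functional.

    Step per coordinate: ``rel_step · (1 + |θ_j|)``.  Coordinates the
    functional does not depend on come out exactly zero, because both
    perturbed evaluations return identical values.  A vector-valued
    functional (shape ``(m,)``) yields a ``(p, m)`` Jacobian-transpose.
    """
    theta = np.asarray(theta, dtype=float)
    f0 = np.asarray(functional(theta))
    grad = np.zeros(theta.shape + f0.shape)
    for j in range(theta.size):
        h = rel_step * (1.0 + abs(theta[j]))
        tp = theta.copy()
        tp[j] += h
        tm = theta.copy()
        tm[j] -= h
        fp = np.asarray(functional(tp), dtype=float)
        fm = np.asarray(functional(tm), dtype=float)
        if np.any(~np.isfinite(fp)) or np.any(~np.isfinite(fm)):
            raise DomainError(f"NaN in perturbed evaluation at coordinate {j}")
        grad[j] = (fp - fm) / (2.0 * h)
    return grad


@dataclass
class BlockCovariance:
    """Block-diagonal joint covariance of (β2, γ2, β1, γ1)."""

    V2: np.ndarray  # population (expected) model block, upper-left
    V1: np.ndarray  # excess model block, lower-right

    def __post_init__(self):
        self.V2 = np.atleast_2d(np.asarray(self.V2, dtype=float))
        self.V1 = np.atleast_2d(np.asarray(self.V1, dtype=float))

    @property
    def p2(self) -> int:
        return self.V2.shape[0]

    @property
    def p1(self) -> int:
        return self.V1.shape[0]

    @property
    def dim(self) -> int:
        return self.p2 + self.p1

    @property
    def V(self) -> np.ndarray:
        out = np.zeros((self.dim, self.dim))
        out[: self.p2, : self.p2] = self.V2
        out[self.p2 :, self.p2 :] = self.V1
        return out

    def block1_slice(self) -> slice:
        """Stacked-vector slice of the excess-model parameters."""
        return slice(self.p2, self.dim)


def sigma(grad_le_exp, grad_le_c, V) -> np.ndarray:
    """The 2x2 matrix Σ = Gᵀ·V·G for G = (G_E*; G_C)."""
    Vm = V.V if isinstance(V, BlockCovariance) else np.asarray(V, dtype=float)
    gE = np.asarray(grad_le_exp, dtype=float)
    gC = np.asarray(grad_le_c, dtype=float)
    if gE.size != Vm.shape[0] or gC.size != Vm.shape[0]:
        raise DomainError(
            f"gradient lengths ({gE.size}, {gC.size}) do not match dim(V)={Vm.shape[0]}"
        )
    G = np.column_stack([gE, gC])
    return G.T @ Vm @ G


def var_lle(sig: np.ndarray) -> float:
    """Var(LLE) = Var(LE_exp) + Var(LE_C) − 2·Cov(LE_exp, LE_C)."""
    sig = np.asarray(sig, dtype=float)
    v = sig[0, 0] + sig[1, 1] - sig[0, 1] - sig[1, 0]
    if v < 0:
        if v < -1e-12:
            warnings.warn(f"negative Var(LLE) {v:.3g} clamped to 0", RuntimeWarning)
        v = 0.0
    return float(v)


def var_fixed_rates(grad_block1, V1) -> float:
    """Fixed-rates variance: gradient restricted to the excess-model block.

    When the expected rates are treated as known, the only variance source is
    the excess model, so this single number is both Var(LE_C) and Var(LLE)
    in the fixed-rates mode.
    """
    g = np.asarray(grad_block1, dtype=float)
    V1 = np.atleast_2d(np.asarray(V1, dtype=float))
    return float(g @ V1 @ g)


def rp(se_with: float, se_without: float) -> float:
    """Relative % precision: 100·((SE_with/SE_without)² − 1).

    An RP of 100% means the with-uncertainty variance is twice the
    fixed-rates variance.
    """
    if se_without == 0:
        raise DomainError("rp undefined for se_without = 0")
    return 100.0 * ((se_with / se_without) ** 2 - 1.0)


def confint(value: float, variance: float, level: float = 0.95,
            log_scale: bool = False) -> tuple[float, float]:
    """Normal-based confidence interval on the natural (years) scale.

    ``log_scale=True`` instead builds the interval for ln(value) and
    exponentiates (off by default).
    """
    if variance < 0:
        raise DomainError("negative variance")
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(variance)
    if log_scale:
        if value <= 0:
            raise DomainError("log-scale interval needs a positive value")
        se_log = se / value
        return (value * np.exp(-z * se_log), value * np.exp(z * se_log))
    return (value - z * se, value + z * se)


def se_from(grad, V) -> float:
    """Delta-method standard error √(Gᵀ V G) of a single functional."""
    Vm = V.V if isinstance(V, BlockCovariance) else np.asarray(V, dtype=float)
    g = np.asarray(grad, dtype=float)
    return float(np.sqrt(max(g @ Vm @ g, 0.0)))
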