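"""Restricted cubic spline bases.

The survival models in this package place a restricted cubic spline (RCS) of
log time since diagnosis, or of log attained age, on the log cumulative hazard
scale.  With knots ``k_1 < ... < k_K`` the basis has ``K - 1`` columns: the
first is the identity ``x`` and, for each interior knot ``k_j``
(``j = 2..K-1``),

    v_j(x) = (x - k_j)_+^3 - w_j (x - k_1)_+^3 - (1 - w_j) (x - k_K)_+^3,

with ``w_j = (k_K - k_j) / (k_K - k_1)``.  The weights make every column —
and therefore the whole spline — exactly linear beyond both boundary knots.
That linear tail is the extrapolation contract of the package: survival is
extrapolated to the integration horizon t* by continuing the fitted log
cumulative hazard linearly in log time (or log age).

With exactly two knots the basis degenerates to the single column ``x``, so a
two-knot model on log time is a Weibull model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, InsufficientEventsError

__all__ = ["SplineBasis", "make_knots"]


@dataclass(frozen=True)
class SplineBasis:
    """Knot vector plus evaluation machinery for one RCS basis.

    Parameters
    ----------
    knots
        Strictly increasing knot locations, already on the scale the basis is
        evaluated on (log time, log age, or a natural covariate scale).
    scale_label
        Human-readable description, e.g. ``"log time since diagnosis"``.
    """

    knots: np.ndarray
    scale_label: str = ""

    def __post_init__(self):
        knots = np.asarray(self.knots, dtype=float)
        if knots.ndim != 1 or knots.size < 2:
            raise DomainError("a spline basis needs at least 2 knots")
        if not np.all(np.diff(knots) > 0):
            raise DomainError(f"knots must be strictly increasing, got {knots}")
        object.__setattr__(self, "knots", knots)

    @property
    def n_basis(self) -> int:
        """Number of basis columns (= number of knots - 1)."""
        return self.knots.size - 1

    def eval(self, x) -> np.ndarray:
        """Basis values at ``x``; shape ``x.shape + (n_basis,)``."""
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise DomainError("non-finite input to spline evaluation")
        k = self.knots
        out = np.empty(x.shape + (self.n_basis,))
        out[..., 0] = x
        if self.n_basis > 1:
            kmin, kmax = k[0], k[-1]
            span = kmax - kmin
            lo = np.maximum(x - kmin, 0.0) ** 3
            hi = np.maximum(x - kmax, 0.0) ** 3
            for j in range(1, self.n_basis):
                kj = k[j]
                w = (kmax - kj) / span
                out[..., j] = np.maximum(x - kj, 0.0) ** 3 - w * lo - (1.0 - w) * hi
        return out

    def deriv(self, x) -> np.ndarray:
        """Exact first derivative of each basis column with respect to ``x``."""
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise DomainError("non-finite input to spline derivative")
        k = self.knots
        out = np.empty(x.shape + (self.n_basis,))
        out[..., 0] = 1.0
        if self.n_basis > 1:
            kmin, kmax = k[0], k[-1]
            span = kmax - kmin
            lo = np.maximum(x - kmin, 0.0) ** 2
            hi = np.maximum(x - kmax, 0.0) ** 2
            for j in range(1, self.n_basis):
                kj = k[j]
                w = (kmax - kj) / span
                out[..., j] = 3.0 * (
                    np.maximum(x - kj, 0.0) ** 2 - w * lo - (1.0 - w) * hi
                )
        return out


def make_knots(event_values, df: int, scale_label: str = "", log: bool = True) -> SplineBasis:
    """Place ``df + 1`` knots from observed (uncensored) event values.

    Boundary knots sit at the min and max of the (log) event values; the
    ``df - 1`` interior knots sit at equally spaced centiles of the (log)
    event values — e.g. the 20/40/60/80th centiles for ``df = 5``.

    Parameters
    ----------
    event_values
        Uncensored event times or ages (positive when ``log=True``), or raw
        covariate values when ``log=False``.
    df
        Number of spline coefficients excluding the intercept; the basis gets
        ``df`` columns and ``df + 1`` knots.
    """
    if df < 1:
        raise DomainError(f"df must be >= 1, got {df}")
    vals = np.asarray(event_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if log:
        if np.any(vals <= 0):
            raise DomainError("non-positive event values: log scale undefined")
        x = np.log(vals)
    else:
        x = vals
    distinct = np.unique(x)
    if distinct.size < df + 1:
        raise InsufficientEventsError(
            f"need at least {df + 1} distinct event values for df={df}, "
            f"got {distinct.size}"
        )
    if df == 1:
        knots = np.array([x.min(), x.max()])
    else:
        interior = np.quantile(x, np.arange(1, df) / df)
        knots = np.concatenate([[x.min()], interior, [x.max()]])
    if np.unique(knots).size != knots.size:
        raise InsufficientEventsError(
            f"tied knots {knots}: event values too concentrated for df={df}"
        )
    return SplineBasis(knots=knots, scale_label=scale_label)
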