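"""Mortality models for the general-population (comparator) sample.

Three ways of supplying expected mortality live here:

1. :func:`fit_expected_fpm` — the flexible parametric model on the attained-age
   timescale with delayed entry.  This is the model whose parameter
   uncertainty is later propagated into the life-expectancy variances.
2. :func:`fit_poisson_rates` — an auxiliary Poisson rate model on a Lexis
   expansion of the comparators (attained age x attained calendar year).  Its
   predicted rates populate a :class:`RateTable` and are treated as FIXED when
   plugged into the excess-hazard likelihood.
3. :func:`lookup_life_table` — classical life-table ("popmort") lookup with a
   piecewise-constant hazard along the cohort diagonal, for the conventional
   fixed-rates comparison mode.

Comparator data is a DataFrame with columns ``age_entry, age_exit, died,
year_match`` (ages in fractional years) plus optional extra covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import DomainError, InsufficientEventsError
from .fpm import FPMDesign, LCHFit, build_design, fit_lch
from .splines import make_knots

__all__ = [
    "ExpectedModelFit",
    "RateTable",
    "fit_expected_fpm",
    "predict_expected",
    "lexis_split",
    "fit_poisson_rates",
    "lookup_life_table",
]


class ExpectedModelFit(LCHFit):
    """Fitted attained-age FPM for the comparators (parameters β2, γ2; V2)."""


def _validate_comparators(data: pd.DataFrame):
    required = {"age_entry", "age_exit", "died"}
    missing = required - set(data.columns)
    if missing:
        raise DomainError(f"comparator table missing columns {sorted(missing)}")
    if np.any(data["age_entry"].to_numpy() <= 0):
        raise DomainError("non-positive entry ages: log attained age undefined")
    if np.any(data["age_exit"].to_numpy() <= data["age_entry"].to_numpy()):
        raise DomainError("age_exit must exceed age_entry for every record")


def fit_expected_fpm(
    data: pd.DataFrame,
    df_baseline: int = 5,
    covariate_spec=None,
    tvc_spec=None,
    ortho: bool = True,
    design: FPMDesign | None = None,
) -> ExpectedModelFit:
    """Fit ln H(a|Z2) = s(ln a|γ2,k2) + β2·Z2 with delayed entry.

    The likelihood conditions on survival to the entry age (left truncation):
    each record contributes d·ln h*(a) − [H(a) − H(a0)].  Non-proportional
    covariate effects enter as covariate-spline x age-spline interactions via
    ``tvc_spec``.

    Returns the estimates together with V2, the inverse observed information.
    """
    _validate_comparators(data)
    d = data["died"].to_numpy().astype(bool)
    if d.sum() < 1:
        raise InsufficientEventsError("comparator sample has no deaths")
    a = data["age_exit"].to_numpy(dtype=float)
    a0 = data["age_entry"].to_numpy(dtype=float)
    lna = np.log(a)
    covs = {c: data[c].to_numpy(dtype=float) for c in data.columns
            if c not in ("age_entry", "age_exit", "died", "id")}
    if design is None:
        design = build_design(
            a[d],
            df_baseline,
            covariate_spec,
            tvc_spec,
            data=data,
            timescale_label="log attained age",
            ortho=ortho,
            fit_lnx=lna,
            fit_covariates=covs,
        )
    fit = fit_lch(design, lna, a, d, covariates=covs, entry_lnx=np.log(a0))
    return ExpectedModelFit(**fit.__dict__)


def predict_expected(fit: ExpectedModelFit, a, covariates=None) -> dict:
    """Cumulative hazard H, hazard h*, and survival S* at attained age ``a``.

    The hazard is the analytic derivative h*(a) = H(a) · d s/d ln a / a
    (including any interaction derivative terms); beyond the boundary knots
    the log cumulative hazard continues linearly in log age.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise DomainError("attained age must be positive")
    lna = np.log(a)
    covariates = covariates or {}
    X = fit.design.matrix(lna, covariates)
    Xd = fit.design.deriv_matrix(lna, covariates)
    lnH = X @ fit.theta
    H = np.exp(lnH)
    h = H * (Xd @ fit.theta) / a
    return {"H": H, "hazard": h, "survival": np.exp(-H)}


# ---------------------------------------------------------------------------
# Poisson rate model on a Lexis expansion
# ---------------------------------------------------------------------------


@dataclass
class RateTable:
    """Expected mortality rates on an age x calendar-year grid.

    ``rates[i, j]`` is the rate (events per person-year, not an annual death
    probability) for attained age ``ages[i]`` (one-year band ``[age, age+1)``)
    in calendar year ``years[j]``.
    """

    ages: np.ndarray
    years: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.years = np.asarray(self.years, dtype=int)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (self.ages.size, self.years.size):
            raise DomainError("rate grid shape does not match its axes")
        if np.any(self.rates < 0):
            raise DomainError("negative rates in rate table")

    def rate_at(self, age, year):
        """Rate for the one-year Lexis cell containing (age, year)."""
        age = np.floor(np.asarray(age, dtype=float)).astype(int)
        year = np.floor(np.asarray(year, dtype=float)).astype(int)
        i = np.searchsorted(self.ages, age)
        bad_i = (i >= self.ages.size) | (self.ages[np.minimum(i, self.ages.size - 1)] != age)
        if np.any(bad_i):
            bad = np.atleast_1d(age)[np.atleast_1d(bad_i)]
            raise DomainError(f"age {bad[0]} outside rate table range "
                              f"[{self.ages[0]}, {self.ages[-1]}]")
        j = np.searchsorted(self.years, year)
        bad_j = (j >= self.years.size) | (self.years[np.minimum(j, self.years.size - 1)] != year)
        if np.any(bad_j):
            bad = np.atleast_1d(year)[np.atleast_1d(bad_j)]
            raise DomainError(f"year {bad[0]} outside rate table range "
                              f"[{self.years[0]}, {self.years[-1]}]")
        return self.rates[i, j]

    def to_frame(self) -> pd.DataFrame:
        age_g, year_g = np.meshgrid(self.ages, self.years, indexing="ij")
        return pd.DataFrame(
            {"age": age_g.ravel(), "year": year_g.ravel(), "rate": self.rates.ravel()}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RateTable":
        ages = np.sort(df["age"].unique())
        years = np.sort(df["year"].unique())
        piv = df.pivot_table(index="age", columns="year", values="rate")
        piv = piv.reindex(index=ages, columns=years)
        if piv.isna().any().any():
            raise DomainError("rate table axes are not rectangular/complete")
        return cls(ages=ages, years=years, rates=piv.to_numpy())


def lexis_split(data: pd.DataFrame, age_band: float = 1.0, year_band: float = 1.0) -> pd.DataFrame:
    """Split comparator follow-up into Lexis cells and aggregate.

    Each record runs along the cohort diagonal from (age_entry, year_match) to
    age_exit; follow-up is cut wherever an age-band or year-band boundary is
    crossed.  Returns one row per occupied cell with ``deaths``, ``pyrs`` and
    the cell anchors ``age`` and ``year`` (band lower edges).
    """
    if age_band <= 0 or year_band <= 0:
        raise DomainError("bands must be positive")
    rows = {}
    a0s = data["age_entry"].to_numpy(dtype=float)
    a1s = data["age_exit"].to_numpy(dtype=float)
    y0s = data["year_match"].to_numpy(dtype=float)
    ds = data["died"].to_numpy().astype(bool)
    for a0, a1, y0, died in zip(a0s, a1s, y0s, ds):
        dur = a1 - a0
        cuts_age = np.arange(
            (np.floor(a0 / age_band) + 1) * age_band, a1, age_band
        ) - a0
        y1 = y0 + dur
        cuts_year = np.arange(
            (np.floor(y0 / year_band) + 1) * year_band, y1, year_band
        ) - y0
        cuts = np.unique(np.concatenate([[0.0], cuts_age, cuts_year, [dur]]))
        mids = (cuts[:-1] + cuts[1:]) / 2.0
        widths = np.diff(cuts)
        for m, w, last in zip(mids, widths, np.arange(mids.size) == mids.size - 1):
            key = (
                int(np.floor((a0 + m) / age_band) * age_band),
                int(np.floor((y0 + m) / year_band) * year_band),
            )
            deaths, pyrs = rows.get(key, (0, 0.0))
            rows[key] = (deaths + int(died and last), pyrs + w)
    out = pd.DataFrame(
        [(k[0], k[1], v[0], v[1]) for k, v in sorted(rows.items())],
        columns=["age", "year", "deaths", "pyrs"],
    )
    return out


def fit_poisson_rates(
    data: pd.DataFrame,
    age_band: float = 1.0,
    year_band: float = 1.0,
    df_age: int = 5,
    df_year: int = 3,
    interaction_df: tuple[int, int] | None = (2, 2),
    saturated: bool = False,
    age_range: tuple[int, int] | None = None,
    year_range: tuple[int, int] | None = None,
) -> RateTable:
    """Smooth Poisson rate model for the comparators, tabulated per cell.

    Splits follow-up into Lexis cells, then fits a log-linear rate model with
    RCS effects of attained age and attained calendar year (person-time as
    offset) and tabulates predicted rates on a single-year age x year grid.
    These rates are the fixed expected rates fed to the excess-hazard
    likelihood.  ``saturated=True`` instead returns the cell-wise maximum
    likelihood rates D/Y (only for cells with person-time).
    """
    cells = lexis_split(data, age_band, year_band)
    if cells["deaths"].sum() == 0:
        raise InsufficientEventsError("no deaths in comparator sample: rates degenerate")
    cells = cells[cells["pyrs"] > 0]
    if saturated:
        ages = np.sort(cells["age"].unique())
        years = np.sort(cells["year"].unique())
        rates = np.zeros((ages.size, years.size))
        for _, r in cells.iterrows():
            rates[np.searchsorted(ages, r["age"]), np.searchsorted(years, r["year"])] = (
                r["deaths"] / r["pyrs"]
            )
        return RateTable(ages=ages, years=years, rates=rates)

    age_mid = cells["age"].to_numpy(dtype=float) + age_band / 2.0
    year_mid = cells["year"].to_numpy(dtype=float) + year_band / 2.0

    def _design(av, yv, basis_a, basis_y, basis_ia, basis_iy):
        cols = [np.ones_like(av)[:, None], basis_a.eval(av), basis_y.eval(yv)]
        if basis_ia is not None:
            ia = basis_ia.eval(av)
            iy = basis_iy.eval(yv)
            cols.append((ia[:, :, None] * iy[:, None, :]).reshape(av.size, -1))
        return np.concatenate(cols, axis=1)

    basis_a = make_knots(age_mid, min(df_age, np.unique(age_mid).size - 1),
                         "attained age", log=False)
    basis_y = make_knots(year_mid, min(df_year, np.unique(year_mid).size - 1),
                         "attained year", log=False)
    basis_ia = basis_iy = None
    if interaction_df is not None:
        basis_ia = make_knots(age_mid, min(interaction_df[0], basis_a.n_basis),
                              "attained age", log=False)
        basis_iy = make_knots(year_mid, min(interaction_df[1], basis_y.n_basis),
                              "attained year", log=False)
    X = _design(age_mid, year_mid, basis_a, basis_y, basis_ia, basis_iy)
    model = sm.GLM(
        cells["deaths"].to_numpy(),
        X,
        family=sm.families.Poisson(),
        offset=np.log(cells["pyrs"].to_numpy()),
    )
    res = model.fit()

    if age_range is None:
        age_range = (int(cells["age"].min()), int(cells["age"].max()))
    if year_range is None:
        year_range = (int(cells["year"].min()), int(cells["year"].max()))
    ages = np.arange(age_range[0], age_range[1] + 1)
    years = np.arange(year_range[0], year_range[1] + 1)
    ag, yg = np.meshgrid(ages + 0.5, years + 0.5, indexing="ij")
    Xg = _design(ag.ravel(), yg.ravel(), basis_a, basis_y, basis_ia, basis_iy)
    rates = np.exp(Xg @ res.params).reshape(ages.size, years.size)
    return RateTable(ages=ages, years=years, rates=rates)


def lookup_life_table(table: RateTable, a0: float, year0: float, t) -> dict:
    """Expected hazard and survival along the cohort diagonal from (a0, year0).

    The hazard is piecewise constant over one-year Lexis cells, with age and
    calendar year advancing together: S*(t) = exp(−Σ rate x occupancy time).
    Returns the hazard at ``t`` and the survival to ``t`` (vectorised over t).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    tmax = float(t.max())
    # breakpoints where floor(a0+u) or floor(year0+u) changes
    cuts_a = np.arange(np.floor(a0) + 1, a0 + tmax) - a0
    cuts_y = np.arange(np.floor(year0) + 1, year0 + tmax) - year0
    cuts = np.unique(np.concatenate([[0.0], cuts_a, cuts_y, [tmax]]))
    mids = (cuts[:-1] + cuts[1:]) / 2.0
    seg_rates = table.rate_at(a0 + mids, year0 + mids)
    cumH_at_cuts = np.concatenate([[0.0], np.cumsum(seg_rates * np.diff(cuts))])
    idx = np.clip(np.searchsorted(cuts, t, side="right") - 1, 0, mids.size - 1)
    H = cumH_at_cuts[idx] + seg_rates[idx] * (t - cuts[idx])
    h = table.rate_at(a0 + t, year0 + t)
    out = {"hazard": h, "survival": np.exp(-H), "H": H}
    if np.isscalar(t) or t.size == 1:
        return {k: float(np.asarray(v).ravel()[0]) for k, v in out.items()}
    return out


def merge_expected_rates(patients: pd.DataFrame, table: RateTable) -> pd.DataFrame:
    """Attach each patient's expected rate at exit, h*(a0+t, year_dx+t).

    Looks up the one-year Lexis cell on the cohort diagonal at the exit time,
    exactly the single value per patient the excess-hazard likelihood needs.
    """
    out = patients.copy()
    out["h_star"] = table.rate_at(
        out["age_dx"].to_numpy(dtype=float) + out["t"].to_numpy(dtype=float),
        out["year_dx"].to_numpy(dtype=float) + out["t"].to_numpy(dtype=float),
    )
    return out
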