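"""Mixed-effects Poisson regression for fDRP rates in the observed cohort.

The log rate for a stratum-year-treatment cell is

    log lambda = b0 + b_gender + b_age + b_treatment + b_year
               + b_gender:age + b_treatment:age + b_year:treatment
               + u_region,          u_region ~ Normal(0, sigma_region^2)

with corner (reference-level) constraints: male, the younger age band,
on-treatment and the first declared year are the reference levels, so every
coefficient is a log rate ratio against that cell. The expected number of
*linked* deaths in a cell is

    mu = pmatch * lambda * person_years

where ``pmatch`` is the probability that a death occurring in the cohort was
correctly linked to the mortality register. It thins the observed linked
counts only; the true rate ``lambda`` is already linkage-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_data import Categories, CohortDataset, GroupKey

__all__ = ["RateParams", "RateModelSpec", "log_rate", "rate_linear_predictor",
           "expected_linked_deaths", "rate_loglik", "predicted_off_treatment_rate"]


@dataclass
class RateParams:
    """Coefficients and random effects of the log-rate regression."""

    categories: Categories
    intercept: float = 0.0
    coef_gender: float = 0.0           # non-reference gender (e.g. female)
    coef_age: float = 0.0              # older age band
    coef_treatment: float = 0.0        # off treatment
    coef_year: np.ndarray = None       # one per non-reference year
    coef_gender_x_age: float = 0.0
    coef_treatment_x_age: float = 0.0
    coef_year_x_treatment: np.ndarray = None
    region_effects: np.ndarray = None
    sigma_region: float = 1.0
    pmatch: float = 1.0

    def __post_init__(self) -> None:
        ny = self.categories.n_years - 1
        nr = self.categories.n_regions
        if self.coef_year is None:
            self.coef_year = np.zeros(ny)
        if self.coef_year_x_treatment is None:
            self.coef_year_x_treatment = np.zeros(ny)
        if self.region_effects is None:
            self.region_effects = np.zeros(nr)
        self.coef_year = np.asarray(self.coef_year, dtype=float)
        self.coef_year_x_treatment = np.asarray(self.coef_year_x_treatment, dtype=float)
        self.region_effects = np.asarray(self.region_effects, dtype=float)
        if self.coef_year.shape != (ny,):
            raise ValueError(f"coef_year must have length {ny}")
        if self.coef_year_x_treatment.shape != (ny,):
            raise ValueError(f"coef_year_x_treatment must have length {ny}")
        if self.region_effects.shape != (nr,):
            raise ValueError(f"region_effects must have length {nr}")
        if not self.sigma_region > 0:
            raise ValueError("sigma_region must be positive")
        if not (0.0 < self.pmatch <= 1.0):
            raise ValueError("pmatch must lie in (0, 1]")


@dataclass
class RateModelSpec:
    """Model-variant flags and prior settings for the rate regression.

    ``include_year_x_treatment`` and ``include_gender_x_age`` switch the
    corresponding interaction terms off for sensitivity/DIC comparisons;
    ``fix_pmatch_to_one`` replaces the informative linkage prior with
    perfect-linkage certainty.
    """

    include_year_x_treatment: bool = True
    include_gender_x_age: bool = True
    fix_pmatch_to_one: bool = False
    coef_sd: float = 10.0
    sigma_region_bound: float = 5.0
    pmatch_bounds: tuple[float, float] = (0.74, 0.84)

    def __post_init__(self) -> None:
        lo, hi = self.pmatch_bounds
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("pmatch bounds must satisfy 0 < lower <= upper <= 1")
        if self.coef_sd <= 0 or self.sigma_region_bound <= 0:
            raise ValueError("prior scales must be positive")


def log_rate(key: GroupKey, treatment: str, params: RateParams) -> float:
    """Linear predictor (log true rate per person-year) for one cell.

    Excludes the offsets: neither person-years nor pmatch enter here.
    """
    cats = params.categories
    key.validate(cats)
    if treatment not in ("on", "off"):
        raise ValueError(f"unknown treatment level: {treatment!r}")
    female = cats.index_of("genders", key.gender) > 0
    old = cats.index_of("age_bands", key.age_band) > 0
    off = treatment == "off"
    iy = cats.index_of("years", key.year)
    ir = cats.index_of("regions", key.region)

    eta = params.intercept + params.region_effects[ir]
    if female:
        eta += params.coef_gender
    if old:
        eta += params.coef_age
    if off:
        eta += params.coef_treatment
    if iy > 0:
        eta += params.coef_year[iy - 1]
        if off:
            eta += params.coef_year_x_treatment[iy - 1]
    if female and old:
        eta += params.coef_gender_x_age
    if off and old:
        eta += params.coef_treatment_x_age
    return float(eta)


def rate_linear_predictor(cells: pd.DataFrame, params: RateParams) -> np.ndarray:
    """Vectorised linear predictor over a cells frame (see ``cells_frame``)."""
    cats = params.categories
    female = np.array(
        [cats.index_of("genders", g) > 0 for g in cells["gender"]], dtype=bool
    )
    old = np.array(
        [cats.index_of("age_bands", a) > 0 for a in cells["age_band"]], dtype=bool
    )
    off = cells["treatment"].to_numpy() == "off"
    iy = np.array([cats.index_of("years", y) for y in cells["year"]])
    ir = np.array([cats.index_of("regions", r) for r in cells["region"]])

    year_coef = np.concatenate([[0.0], params.coef_year])
    yxt_coef = np.concatenate([[0.0], params.coef_year_x_treatment])
    eta = (
        params.intercept
        + female * params.coef_gender
        + old * params.coef_age
        + off * params.coef_treatment
        + year_coef[iy]
        + (female & old) * params.coef_gender_x_age
        + (off & old) * params.coef_treatment_x_age
        + off * yxt_coef[iy]
        + params.region_effects[ir]
    )
    return np.asarray(eta, dtype=float)


def expected_linked_deaths(cells: pd.DataFrame, params: RateParams) -> np.ndarray:
    """Poisson means mu = pmatch * exp(eta) * person_years, per cell."""
    eta = rate_linear_predictor(cells, params)
    return params.pmatch * np.exp(eta) * cells["person_years"].to_numpy(dtype=float)


def rate_loglik(data: CohortDataset, params: RateParams) -> float:
    """Poisson log likelihood of the linked death counts.

    Cells with zero person-years contribute 0 unless they record deaths,
    which is a data inconsistency and yields -inf.
    """
    cells = data.cells_frame()
    d = cells["deaths_linked"].to_numpy(dtype=float)
    py = cells["person_years"].to_numpy(dtype=float)
    mu = expected_linked_deaths(cells, params)
    ll = np.zeros_like(mu)
    pos = py > 0
    ll[pos] = stats.poisson.logpmf(d[pos], mu[pos])
    bad = (~pos) & (d > 0)
    if bad.any():
        return float("-inf")
    return float(ll.sum())


def predicted_off_treatment_rate(key: GroupKey, params: RateParams) -> float:
    """True (linkage-corrected) off-treatment fDRP rate per person-year.

    pmatch does not enter: it thins observed linked counts only.
    """
    return float(np.exp(log_rate(key, "off", params)))
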