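"""Logit-linear model for group prevalence and the latent unobserved count.

Prevalence of opioid dependence in group g (gender x age band x region) is

    logit pi_g = alpha_region + c_age + c_gender + c_age:gender
               + v_region * female + w_region * old

with unconstrained region intercepts alpha_region and region interaction
effects v (gender x region) and w (age x region) modelled as exchangeable
Normal random effects. The latent number of dependent people *not* observed
in the cohort follows from the identity pi_g = (n_obs_g + n_miss_g) / P_g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort_data import Categories, GroupKey

__all__ = ["PrevalenceParams", "PrevalencePriors", "prevalence",
           "prevalence_linear_predictor", "n_miss", "national_prevalence",
           "InfeasiblePrevalence"]


class InfeasiblePrevalence(ValueError):
    """pi * population falls below the observed cohort headcount."""


@dataclass
class PrevalenceParams:
    """Coefficients and random effects of the logit-prevalence regression."""

    categories: Categories
    region_intercepts: np.ndarray = None
    coef_age: float = 0.0
    coef_gender: float = 0.0
    coef_age_x_gender: float = 0.0
    gender_x_region_effects: np.ndarray = None
    age_x_region_effects: np.ndarray = None
    sigma_gender_x_region: float = 1.0
    sigma_age_x_region: float = 1.0

    def __post_init__(self) -> None:
        nr = self.categories.n_regions
        if self.region_intercepts is None:
            self.region_intercepts = np.zeros(nr)
        if self.gender_x_region_effects is None:
            self.gender_x_region_effects = np.zeros(nr)
        if self.age_x_region_effects is None:
            self.age_x_region_effects = np.zeros(nr)
        for name in ("region_intercepts", "gender_x_region_effects",
                     "age_x_region_effects"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (nr,):
                raise ValueError(f"{name} must have length {nr}")
        if not (self.sigma_gender_x_region > 0 and self.sigma_age_x_region > 0):
            raise ValueError("random-effect SDs must be positive")


@dataclass
class PrevalencePriors:
    """Prior settings for the prevalence regression (logit scale)."""

    intercept_sd: float = 10.0
    coef_sd: float = 10.0
    sigma_bound: float = 2.0

    def __post_init__(self) -> None:
        if min(self.intercept_sd, self.coef_sd, self.sigma_bound) <= 0:
            raise ValueError("prior scales must be positive")


def _logit_pi(key: GroupKey, params: PrevalenceParams) -> float:
    cats = params.categories
    key.validate(cats)
    female = cats.index_of("genders", key.gender) > 0
    old = cats.index_of("age_bands", key.age_band) > 0
    ir = cats.index_of("regions", key.region)
    eta = params.region_intercepts[ir]
    if old:
        eta += params.coef_age + params.age_x_region_effects[ir]
    if female:
        eta += params.coef_gender + params.gender_x_region_effects[ir]
    if old and female:
        eta += params.coef_age_x_gender
    return float(eta)


def prevalence(key: GroupKey, params: PrevalenceParams) -> float:
    """Group prevalence pi in (0, 1): inverse-logit of the linear predictor."""
    return float(expit(_logit_pi(key, params)))


def prevalence_linear_predictor(groups: pd.DataFrame,
                                params: PrevalenceParams) -> np.ndarray:
    """Vectorised logit prevalence over a frame with gender/age_band/region."""
    cats = params.categories
    female = np.array(
        [cats.index_of("genders", g) > 0 for g in groups["gender"]], dtype=bool
    )
    old = np.array(
        [cats.index_of("age_bands", a) > 0 for a in groups["age_band"]], dtype=bool
    )
    ir = np.array([cats.index_of("regions", r) for r in groups["region"]])
    eta = (
        params.region_intercepts[ir]
        + old * (params.coef_age + params.age_x_region_effects[ir])
        + female * (params.coef_gender + params.gender_x_region_effects[ir])
        + (old & female) * params.coef_age_x_gender
    )
    return np.asarray(eta, dtype=float)


def n_miss(pi: float, population: int, cohort_count: int) -> float:
    """Latent count of dependent people outside the cohort: pi*P - n_obs.

    Raises :class:`InfeasiblePrevalence` when pi * population falls below
    the observed headcount (a state the sampler rejects with -inf).
    """
    if not (0.0 < pi < 1.0):
        raise ValueError("pi must lie in (0, 1)")
    if population <= 0:
        raise ValueError("population must be positive")
    value = pi * population - cohort_count
    if value < 0:
        raise InfeasiblePrevalence(
            f"pi*population = {pi * population:.1f} < cohort_count = {cohort_count}"
        )
    return float(value)


def national_prevalence(pis, populations) -> float:
    """Population-weighted prevalence: sum(pi_g P_g) / sum(P_g)."""
    pis = np.asarray(pis, dtype=float)
    populations = np.asarray(populations, dtype=float)
    if pis.size == 0:
        raise ValueError("empty input")
    if pis.shape != populations.shape:
        raise ValueError("pis and populations must have equal length")
    return float(np.sum(pis * populations) / np.sum(populations))
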