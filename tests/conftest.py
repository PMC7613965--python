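"""Shared fixtures: the packaged national summary table and small scenarios."""

from __future__ import annotations

import numpy as np
import pytest

import mortprev as mp
from mortprev.cohort_data import Categories
from mortprev.prevalence_model import PrevalenceParams
from mortprev.rate_model import RateParams
from mortprev.synthetic import TruthScenario


@pytest.fixture(scope="session")
def table1():
    return mp.load_table1()


@pytest.fixture(scope="session")
def default_scenario():
    return mp.default_scenario()


def make_small_scenario(
    n_regions: int = 2,
    pop_scale: float = 1.0,
    pmatch: float = 0.79,
    homogeneous: bool = False,
    seed: int = 0,
) -> TruthScenario:
    """Compact two-region scenario for fast MCMC tests."""
    regions = tuple(f"r{i}" for i in range(n_regions))
    cats = Categories(regions=regions, years=("y1", "y2"))
    base = 0.016
    prev = PrevalenceParams(
        categories=cats,
        region_intercepts=np.full(n_regions, np.log(base / (1 - base))),
        coef_age=0.0 if homogeneous else -0.8,
        coef_gender=0.0 if homogeneous else -1.1,
        coef_age_x_gender=0.0,
        gender_x_region_effects=np.zeros(n_regions),
        age_x_region_effects=(np.zeros(n_regions) if homogeneous
                              else np.linspace(-0.2, 0.2, n_regions)),
        sigma_gender_x_region=0.07,
        sigma_age_x_region=0.36,
    )
    rate = RateParams(
        categories=cats,
        intercept=float(np.log(2.2e-3)),
        coef_gender=0.0 if homogeneous else -0.7,
        coef_age=0.0 if homogeneous else 0.15,
        coef_treatment=0.0 if homogeneous else 0.5,
        coef_year=np.array([-0.2]),
        coef_gender_x_age=0.0 if homogeneous else 0.4,
        coef_treatment_x_age=0.0 if homogeneous else 0.3,
        coef_year_x_treatment=np.array([0.0]),
        region_effects=(np.zeros(n_regions) if homogeneous
                        else np.linspace(-0.1, 0.1, n_regions)),
        sigma_region=0.15,
        pmatch=pmatch,
    )
    groups = [(g, a, r) for g in cats.genders for a in cats.age_bands
              for r in regions]
    population = {g: int(2_000_000 * pop_scale) for g in groups}
    return TruthScenario(
        categories=cats,
        population=population,
        prevalence_params=prev,
        rate_params=rate,
        treatment_coverage={g: 0.75 for g in groups},
        in_cohort_fraction={g: 0.64 for g in groups},
        year_py_scale={"y1": 0.8, "y2": 1.0},
        seed=seed,
    )


@pytest.fixture()
def small_scenario():
    return make_small_scenario()
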