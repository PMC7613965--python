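"""Synthetic linked-cohort generator with known ground truth.

Emulates the structure of the national linked-cohort summary table: per
demographic group and year, linked fDRP counts and person-years split by
treatment status; for the estimation (final) year, unlinked fDRP counts,
cohort headcounts and population denominators.

Counts are drawn hierarchically in a fixed, documented order (groups in
declaration order, years innermost) from a single seeded stream, so a seed
pins the dataset byte-for-byte:

1. true dependent count     T   ~ Binomial(P, pi)
2. cohort members           C   ~ Binomial(T, in_cohort_fraction)
3. person-time: C * person_time * year_scale, split by treatment coverage
4. true cohort deaths on/off treatment ~ Poisson(rate * person-years)
5. linked deaths ~ Binomial(true cohort deaths, pmatch)
6. estimation year only: deaths among the T - C unobserved people
   (1 person-year each, off-treatment rate) ~ Poisson; unlinked deaths =
   those + the cohort deaths the linkage missed.

Unobserved people contribute off-treatment person-time only, mirroring the
identification assumption that anyone in treatment would have been observed.
``unobserved_rate_multiplier`` (default 1) scales the mortality rate of the
unobserved relative to observed off-treatment people, to probe violations of
the equal-rates assumption.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .cohort_data import (Categories, CohortCell, CohortDataset,
                          GroupKey, GroupObservation, ValidationError)
from .prevalence_model import PrevalenceParams, prevalence
from .rate_model import RateParams, log_rate

__all__ = ["TruthScenario", "simulate_cohort", "default_scenario"]

#: per-member person-time within a year (entries during the year mean < 1)
PERSON_TIME_PER_MEMBER = 0.839


@dataclass
class TruthScenario:
    """Complete generative truth for one synthetic study."""

    categories: Categories
    population: dict[tuple[str, str, str], int]
    prevalence_params: PrevalenceParams
    rate_params: RateParams                 # includes true pmatch
    treatment_coverage: dict[tuple[str, str, str], float]
    in_cohort_fraction: dict[tuple[str, str, str], float]
    year_py_scale: dict[str, float] = None
    person_time_per_member: float = PERSON_TIME_PER_MEMBER
    unobserved_rate_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.year_py_scale is None:
            self.year_py_scale = {y: 1.0 for y in self.categories.years}
        for g, p in self.population.items():
            if p <= 0:
                raise ValidationError(f"population must be positive for {g}")
        for name in ("treatment_coverage", "in_cohort_fraction"):
            table = getattr(self, name)
            for g in self.groups():
                if g not in table:
                    raise ValidationError(f"{name} missing group {g}")
                if not (0.0 <= table[g] <= 1.0):
                    raise ValidationError(f"{name}[{g}] outside [0, 1]")
        for y in self.categories.years:
            if self.year_py_scale.get(y, -1) < 0:
                raise ValidationError(f"year_py_scale missing or negative for {y}")
        if not (0.0 < self.person_time_per_member <= 1.0):
            raise ValidationError("person_time_per_member must lie in (0, 1]")
        if self.unobserved_rate_multiplier < 0:
            raise ValidationError("unobserved_rate_multiplier must be >= 0")

    def groups(self) -> list[tuple[str, str, str]]:
        """Gender/age/region combinations in declaration order."""
        c = self.categories
        return list(itertools.product(c.genders, c.age_bands, c.regions))

    def true_pi(self, group: tuple[str, str, str]) -> float:
        gender, age_band, region = group
        key = GroupKey(gender, age_band, region, self.categories.years[-1])
        return prevalence(key, self.prevalence_params)

    def true_national_prevalence(self) -> float:
        num = sum(self.true_pi(g) * self.population[g] for g in self.groups())
        return num / sum(self.population.values())

    def expected_counts(self) -> dict[str, float]:
        """Analytic expectations of headline totals (estimation year)."""
        est = self.categories.years[-1]
        pm = self.rate_params.pmatch
        cohort = linked = total = 0.0
        for g in self.groups():
            gender, age_band, region = g
            pi = self.true_pi(g)
            dep = self.population[g] * pi
            c = dep * self.in_cohort_fraction[g]
            cohort += c
            key = GroupKey(gender, age_band, region, est)
            r_on = np.exp(log_rate(key, "on", self.rate_params))
            r_off = np.exp(log_rate(key, "off", self.rate_params))
            py = c * self.person_time_per_member * self.year_py_scale[est]
            cov = self.treatment_coverage[g]
            cohort_deaths = r_on * py * cov + r_off * py * (1 - cov)
            unobs_deaths = (dep - c) * r_off * self.unobserved_rate_multiplier
            linked += pm * cohort_deaths
            total += cohort_deaths + unobs_deaths
        return {"cohort_size": cohort, "linked_fdrps": linked,
                "total_fdrps": total}


def simulate_cohort(
    scenario: TruthScenario,
    seed: int | None = None,
) -> tuple[CohortDataset, dict]:
    """Draw one synthetic dataset; returns (dataset, ground-truth record).

    ``seed`` overrides ``scenario.seed`` when given.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    cats = scenario.categories
    est_year = cats.years[-1]
    pm = scenario.rate_params.pmatch

    cells: list[CohortCell] = []
    observations: list[GroupObservation] = []
    truth_groups = []
    for group in scenario.groups():
        gender, age_band, region = group
        pop = scenario.population[group]
        pi = scenario.true_pi(group)
        f_cohort = scenario.in_cohort_fraction[group]
        cov = scenario.treatment_coverage[group]
        for year in cats.years:
            key = GroupKey(gender, age_band, region, year)
            dependent = rng.binomial(pop, pi)
            in_cohort = rng.binomial(dependent, f_cohort)
            py_total = (in_cohort * scenario.person_time_per_member
                        * scenario.year_py_scale[year])
            py_on = py_total * cov
            py_off = py_total - py_on
            r_on = float(np.exp(log_rate(key, "on", scenario.rate_params)))
            r_off = float(np.exp(log_rate(key, "off", scenario.rate_params)))
            deaths_on = rng.poisson(r_on * py_on)
            deaths_off = rng.poisson(r_off * py_off)
            linked_on = rng.binomial(deaths_on, pm)
            linked_off = rng.binomial(deaths_off, pm)
            # zero person-time cannot carry deaths; Poisson(0) guarantees it
            cells.append(CohortCell(key, "on", int(linked_on), float(py_on)))
            cells.append(CohortCell(key, "off", int(linked_off), float(py_off)))
            if year == est_year:
                n_miss_true = dependent - in_cohort
                unobs_deaths = rng.poisson(
                    r_off * scenario.unobserved_rate_multiplier * n_miss_true)
                missed = (deaths_on - linked_on) + (deaths_off - linked_off)
                observations.append(GroupObservation(
                    key=key,
                    deaths_unlinked=int(unobs_deaths + missed),
                    cohort_count=int(in_cohort),
                    population=int(pop),
                ))
                truth_groups.append({
                    "group": group, "pi": pi, "population": pop,
                    "n_dependent": int(dependent), "n_cohort": int(in_cohort),
                    "n_miss": int(n_miss_true),
                    "rate_on": r_on, "rate_off": r_off,
                })
    dataset = CohortDataset(categories=cats, cells=cells,
                            observations=observations)
    truth = {
        "national_prevalence": scenario.true_national_prevalence(),
        "n_total_expected": sum(scenario.true_pi(g) * scenario.population[g]
                                for g in scenario.groups()),
        "pmatch": pm,
        "groups": truth_groups,
        "rate_params": scenario.rate_params,
        "prevalence_params": scenario.prevalence_params,
    }
    return dataset, truth


# ---------------------------------------------------------------------------
# default England-like scenario
#
# Calibrated to the magnitudes of the published 2008/09 national case study:
# ~34.4M population aged 15-64 across nine regions, national prevalence near
# 0.8%, an observed cohort near 176,000, roughly 180 linked and 450 total
# fDRPs in the estimation year, linkage probability 0.79.

_REGIONS = ("north_east", "north_west", "yorkshire_humber", "east_midlands",
            "west_midlands", "east", "london", "south_east", "south_west")

# 15-64 population (thousands) by region, approximate mid-2008 magnitudes
_REGION_POP_K = {
    "north_east": 1700, "north_west": 4600, "yorkshire_humber": 3500,
    "east_midlands": 2900, "west_midlands": 3500, "east": 3700,
    "london": 5600, "south_east": 5500, "south_west": 3400,
}
_AGE_SHARE = {"young": 0.41, "old": 0.59}

# baseline (young male) prevalence by region; NW highest, SE lowest
_REGION_BASE_PREV = {
    "north_east": 0.021, "north_west": 0.026, "yorkshire_humber": 0.020,
    "east_midlands": 0.016, "west_midlands": 0.022, "east": 0.013,
    "london": 0.016, "south_east": 0.011, "south_west": 0.016,
}

# fixed true region deviations (plausible draws at the stated SDs)
_RATE_REGION_EFFECTS = np.array(
    [0.12, 0.18, 0.05, -0.10, 0.08, -0.15, -0.05, -0.18, 0.05])
_PREV_AGE_X_REGION = np.array(
    [0.45, 0.25, 0.10, -0.15, 0.05, -0.30, -0.55, -0.20, 0.35])
_PREV_GENDER_X_REGION = np.array(
    [0.05, 0.08, -0.02, -0.06, 0.03, -0.08, 0.04, -0.05, 0.01])


def default_scenario(seed: int = 0) -> TruthScenario:
    """England-like truth: 36 groups, four years, linkage probability 0.79."""
    cats = Categories(
        genders=("male", "female"),
        age_bands=("young", "old"),
        regions=_REGIONS,
        years=("2005/06", "2006/07", "2007/08", "2008/09"),
    )
    population = {}
    for gender in cats.genders:
        for age_band in cats.age_bands:
            for region in cats.regions:
                population[(gender, age_band, region)] = int(
                    _REGION_POP_K[region] * 1000 * 0.5 * _AGE_SHARE[age_band])

    prev_params = PrevalenceParams(
        categories=cats,
        region_intercepts=np.array(
            [np.log(p / (1 - p)) for p in
             (_REGION_BASE_PREV[r] for r in cats.regions)]),
        coef_age=-0.82,
        coef_gender=-1.14,
        coef_age_x_gender=0.10,
        gender_x_region_effects=_PREV_GENDER_X_REGION.copy(),
        age_x_region_effects=_PREV_AGE_X_REGION.copy(),
        sigma_gender_x_region=0.07,
        sigma_age_x_region=0.36,
    )
    rate_params = RateParams(
        categories=cats,
        intercept=float(np.log(2.292e-3)),
        coef_gender=-0.72,
        coef_age=0.16,
        coef_treatment=0.392,
        coef_year=np.array([-0.20, -0.36, -0.55]),
        coef_gender_x_age=0.47,
        coef_treatment_x_age=0.35,
        coef_year_x_treatment=np.array([-0.21, -0.16, -0.03]),
        region_effects=_RATE_REGION_EFFECTS.copy(),
        sigma_region=0.15,
        pmatch=0.79,
    )
    groups = list(itertools.product(cats.genders, cats.age_bands, cats.regions))
    return TruthScenario(
        categories=cats,
        population=population,
        prevalence_params=prev_params,
        rate_params=rate_params,
        treatment_coverage={g: 0.769 for g in groups},
        in_cohort_fraction={g: 0.6415 for g in groups},
        year_py_scale={"2005/06": 0.706, "2006/07": 0.831,
                       "2007/08": 0.939, "2008/09": 1.0},
        seed=seed,
    )
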