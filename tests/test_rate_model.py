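"""Log-rate linear predictor and Poisson likelihood against brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

import mortprev as mp
from mortprev.cohort_data import Categories, GroupKey
from mortprev.rate_model import (RateModelSpec, RateParams,
                                 expected_linked_deaths, log_rate,
                                 predicted_off_treatment_rate, rate_loglik)

CATS = Categories(regions=("ra", "rb", "rc"), years=("y1", "y2", "y3"))


def random_params(seed: int, pmatch: float = 0.8) -> RateParams:
    rng = np.random.default_rng(seed)
    return RateParams(
        categories=CATS,
        intercept=rng.normal(-6, 1),
        coef_gender=rng.normal(), coef_age=rng.normal(),
        coef_treatment=rng.normal(),
        coef_year=rng.normal(size=2),
        coef_gender_x_age=rng.normal(), coef_treatment_x_age=rng.normal(),
        coef_year_x_treatment=rng.normal(size=2),
        region_effects=rng.normal(size=3),
        sigma_region=1.0,
        pmatch=pmatch,
    )


def oracle_log_rate(key: GroupKey, treatment: str, p: RateParams) -> float:
    """Independent design-matrix dot product (corner constraints)."""
    female = 1.0 * (key.gender == CATS.genders[1])
    old = 1.0 * (key.age_band == CATS.age_bands[1])
    off = 1.0 * (treatment == "off")
    years = [1.0 * (key.year == y) for y in CATS.years[1:]]
    row = np.array([1.0, female, old, off, *years, female * old, off * old,
                    *(off * y for y in years)])
    beta = np.array([p.intercept, p.coef_gender, p.coef_age, p.coef_treatment,
                     *p.coef_year, p.coef_gender_x_age, p.coef_treatment_x_age,
                     *p.coef_year_x_treatment])
    return float(row @ beta + p.region_effects[CATS.regions.index(key.region)])


def all_cells():
    for g in CATS.genders:
        for a in CATS.age_bands:
            for r in CATS.regions:
                for y in CATS.years:
                    for trt in ("on", "off"):
                        yield GroupKey(g, a, r, y), trt


class TestLogRate:
    def test_constant_model(self):
        p = RateParams(categories=CATS, intercept=-5.5)
        for key, trt in all_cells():
            assert log_rate(key, trt, p) == -5.5

    def test_reference_cell_is_intercept_plus_region(self):
        p = random_params(0)
        key = GroupKey("male", "young", "ra", "y1")
        expected = p.intercept + p.region_effects[0]
        assert log_rate(key, "on", p) == pytest.approx(expected, abs=1e-14)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_design_matrix_oracle(self, seed):
        p = random_params(seed)
        for key, trt in all_cells():
            assert log_rate(key, trt, p) == pytest.approx(
                oracle_log_rate(key, trt, p), abs=1e-12)

    def test_unknown_level_rejected(self):
        p = random_params(0)
        with pytest.raises(ValueError, match="region"):
            log_rate(GroupKey("male", "young", "nowhere", "y1"), "on", p)
        with pytest.raises(ValueError, match="treatment"):
            log_rate(GroupKey("male", "young", "ra", "y1"), "sometimes", p)


class TestRateLoglik:
    def _dataset(self, scenario_seed=5):
        from conftest import make_small_scenario
        data, _ = mp.simulate_cohort(make_small_scenario(), seed=scenario_seed)
        return data

    def test_single_cell_zero_deaths(self):
        cats = Categories(regions=("r",), years=("y1",))
        key = GroupKey("male", "young", "r", "y1")
        from mortprev.cohort_data import CohortCell, CohortDataset
        data = CohortDataset(
            categories=cats,
            cells=[CohortCell(key, "on", 0, 1000.0),
                   CohortCell(key, "off", 0, 0.0)])
        p = RateParams(categories=cats, intercept=np.log(0.002), pmatch=1.0)
        # mu = 0.002 * 1000 = 2; Poisson log-pmf at zero is -mu
        assert rate_loglik(data, p) == pytest.approx(-2.0, abs=1e-12)

    def test_matches_term_by_term_oracle(self):
        data = self._dataset()
        p = random_params(7)
        p = RateParams(categories=data.categories, intercept=p.intercept,
                       coef_gender=p.coef_gender, coef_age=p.coef_age,
                       coef_treatment=p.coef_treatment,
                       coef_year=p.coef_year[:1],
                       coef_gender_x_age=p.coef_gender_x_age,
                       coef_treatment_x_age=p.coef_treatment_x_age,
                       coef_year_x_treatment=p.coef_year_x_treatment[:1],
                       region_effects=p.region_effects[:2],
                       pmatch=0.8)
        expected = 0.0
        for cell in data.cells:
            if cell.person_years == 0:
                continue
            eta = mp.log_rate(cell.key, cell.treatment, p)
            mu = p.pmatch * np.exp(eta) * cell.person_years
            expected += stats.poisson.logpmf(cell.deaths_linked, mu)
        assert rate_loglik(data, p) == pytest.approx(expected, abs=1e-10)

    def test_pmatch_scales_means_exactly(self):
        data = self._dataset()
        cells = data.cells_frame()
        cells = cells[cells.person_years > 0]
        rng = np.random.default_rng(11)
        kwargs = dict(
            categories=data.categories, intercept=rng.normal(-6, 1),
            coef_gender=rng.normal(), coef_age=rng.normal(),
            coef_treatment=rng.normal(), coef_year=rng.normal(size=1),
            coef_gender_x_age=rng.normal(),
            coef_treatment_x_age=rng.normal(),
            coef_year_x_treatment=rng.normal(size=1),
            region_effects=rng.normal(size=2))
        p1 = RateParams(pmatch=0.8, **kwargs)
        p2 = RateParams(pmatch=0.4, **kwargs)
        mu1 = expected_linked_deaths(cells, p1)
        mu2 = expected_linked_deaths(cells, p2)
        np.testing.assert_array_equal(mu2 * 2.0, mu1)

    def test_smaller_pmatch_increases_loglik_with_zero_deaths(self):
        cats = Categories(regions=("r",), years=("y1",))
        key = GroupKey("male", "young", "r", "y1")
        from mortprev.cohort_data import CohortCell, CohortDataset
        data = CohortDataset(
            categories=cats,
            cells=[CohortCell(key, "on", 0, 500.0),
                   CohortCell(key, "off", 0, 100.0)])
        base = RateParams(categories=cats, intercept=np.log(0.002), pmatch=0.8)
        half = RateParams(categories=cats, intercept=np.log(0.002), pmatch=0.4)
        assert rate_loglik(data, half) > rate_loglik(data, base)


class TestOffTreatmentRate:
    def test_pure_intercept(self):
        cats = Categories(regions=("r",), years=("y1",))
        p = RateParams(categories=cats, intercept=np.log(0.002))
        key = GroupKey("male", "young", "r", "y1")
        assert predicted_off_treatment_rate(key, p) == pytest.approx(0.002)

    def test_invariant_under_pmatch(self):
        key = GroupKey("female", "old", "rb", "y2")
        lo = random_params(13, pmatch=0.74)
        hi = random_params(13, pmatch=1.0)
        assert predicted_off_treatment_rate(key, lo) == \
            predicted_off_treatment_rate(key, hi)

    @pytest.mark.parametrize("seed", [21, 22])
    def test_matches_exp_oracle(self, seed):
        p = random_params(seed)
        for key, _ in all_cells():
            assert predicted_off_treatment_rate(key, p) == pytest.approx(
                np.exp(oracle_log_rate(key, "off", p)), rel=1e-12)


class TestSpecValidation:
    def test_pmatch_bounds(self):
        with pytest.raises(ValueError):
            RateParams(categories=CATS, pmatch=0.0)
        with pytest.raises(ValueError):
            RateParams(categories=CATS, pmatch=1.2)

    def test_model_spec_bounds(self):
        with pytest.raises(ValueError):
            RateModelSpec(pmatch_bounds=(0.0, 0.5))
        with pytest.raises(ValueError):
            RateModelSpec(coef_sd=-1.0)
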