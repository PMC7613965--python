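"""Sampler correctness: conjugate checks, determinism, summaries and DIC."""

import numpy as np
import pytest
from scipy.special import expit, gammaln

import mortprev as mp
from mortprev.cohort_data import (Categories, CohortCell, CohortDataset,
                                  GroupKey, GroupObservation)
from mortprev.inference import (DicResult, JointModel, McmcConfig,
                                PosteriorSamples, compute_dic, run_mcmc,
                                summarize)
from mortprev.rate_model import RateModelSpec


def single_stratum_dataset(deaths=100, py=50_000.0, d_miss=40,
                           cohort=40_000, population=4_000_000):
    """One gender/age/region/year; all cohort person-time off treatment."""
    cats = Categories(genders=("male",), age_bands=("young",),
                      regions=("r",), years=("y1",))
    key = GroupKey("male", "young", "r", "y1")
    cells = [CohortCell(key, "on", 0, 0.0),
             CohortCell(key, "off", deaths, py)]
    obs = [GroupObservation(key, d_miss, cohort, population)]
    return CohortDataset(categories=cats, cells=cells, observations=obs)


FAST = McmcConfig(chains=2, iterations=3000, burn_in=1500, thin=3, seed=7,
                  rhat_threshold=1.2)


class TestSingleStratum:
    def test_posterior_rate_matches_crude_rate(self):
        """With pmatch = 1 the off-treatment rate posterior must centre on
        deaths/person-years (conjugate Gamma-Poisson behaviour)."""
        data = single_stratum_dataset()
        spec = RateModelSpec(fix_pmatch_to_one=True)
        samples = run_mcmc(data, rate_spec=spec, config=FAST)
        draws = samples.stacked("rate_intercept") + samples.stacked("rate_off")
        rate_draws = np.exp(draws)
        crude = 100 / 50_000.0
        assert abs(np.median(rate_draws) - crude) < 3 * rate_draws.std()
        # relative posterior SD should be near 1/sqrt(deaths)
        assert rate_draws.std() / rate_draws.mean() == pytest.approx(
            0.1, rel=0.5)


class TestDeterminism:
    def test_identical_seeds_identical_chains(self):
        data = single_stratum_dataset()
        s1 = run_mcmc(data, config=FAST)
        s2 = run_mcmc(data, config=FAST)
        np.testing.assert_array_equal(s1.theta, s2.theta)
        np.testing.assert_array_equal(s1.loglik, s2.loglik)

    def test_different_seed_differs(self):
        data = single_stratum_dataset()
        cfg2 = McmcConfig(chains=2, iterations=3000, burn_in=1500, thin=3,
                          seed=8, rhat_threshold=1.2)
        s1 = run_mcmc(data, config=FAST)
        s2 = run_mcmc(data, config=cfg2)
        assert not np.array_equal(s1.theta, s2.theta)

    def test_unknown_sampler_rejected(self):
        with pytest.raises(ValueError, match="sampler"):
            run_mcmc(single_stratum_dataset(),
                     config=McmcConfig(sampler="nuts"))

    def test_observations_required(self, small_scenario):
        data, _ = mp.simulate_cohort(small_scenario, seed=1)
        data.observations = []
        with pytest.raises(ValueError, match="observations"):
            JointModel(data)


class TestSummarize:
    def _samples_from(self, arrays):
        data = single_stratum_dataset()
        model = JointModel(data)
        chains, draws = next(iter(arrays.values())).shape
        theta = np.zeros((chains, draws, model.n_params))
        return PosteriorSamples(
            model=model, config=FAST, theta=theta,
            loglik=np.zeros((chains, draws)), derived=arrays,
            acceptance=np.zeros((chains, 1)))

    def test_constant_samples(self):
        s = self._samples_from({"x": np.full((2, 100), 3.25)})
        row = summarize(s, ["x"]).loc["x"]
        assert row["median"] == row["mean"] == row["lower95"] == \
            row["upper95"] == 3.25

    def test_standard_normal_bounds(self):
        rng = np.random.default_rng(0)
        s = self._samples_from({"x": rng.standard_normal((2, 20_000))})
        row = summarize(s, ["x"]).loc["x"]
        assert row["lower95"] == pytest.approx(-1.96, abs=0.05)
        assert row["upper95"] == pytest.approx(1.96, abs=0.05)
        assert row["rhat"] == pytest.approx(1.0, abs=0.01)

    def test_percentiles_match_sorting_oracle(self):
        rng = np.random.default_rng(1)
        arr = rng.gamma(2.0, 3.0, size=(2, 500))
        s = self._samples_from({"x": arr})
        row = summarize(s, ["x"]).loc["x"]
        assert row["lower95"] == pytest.approx(
            np.quantile(arr.reshape(-1), 0.025), rel=1e-12)
        assert row["upper95"] == pytest.approx(
            np.quantile(arr.reshape(-1), 0.975), rel=1e-12)
        assert row["median"] == pytest.approx(
            np.median(np.sort(arr.reshape(-1))), rel=1e-12)

    def test_single_chain_rhat_unavailable(self):
        s = self._samples_from({"x": np.zeros((1, 50))})
        assert np.isnan(summarize(s, ["x"]).loc["x", "rhat"])

    def test_unknown_quantity_rejected(self):
        s = self._samples_from({"x": np.zeros((2, 50))})
        with pytest.raises(KeyError):
            summarize(s, ["y"])


class TestDic:
    def test_point_mass_posterior_has_zero_complexity(self):
        data = single_stratum_dataset()
        model = JointModel(data)
        rng = np.random.default_rng(3)
        theta = model.initial_theta(rng)
        thetas = np.tile(theta, (2, 50, 1))
        ll = model.log_likelihood(theta)
        s = PosteriorSamples(model=model, config=FAST, theta=thetas,
                             loglik=np.full((2, 50), ll), derived={},
                             acceptance=np.zeros((2, 1)))
        dic = compute_dic(s)
        assert dic.pd == pytest.approx(0.0, abs=1e-9)
        assert dic.dic == pytest.approx(dic.dbar)

    def test_invariants_hold(self):
        r = DicResult(dbar=100.0, d_at_mean=92.5)
        assert r.pd == pytest.approx(7.5)
        assert r.dic == pytest.approx(107.5)

    def test_matches_numerical_integration_oracle(self):
        """Single-stratum model: Dbar and D(theta_bar) from MCMC agree with
        deterministic grid integration over the 3 likelihood-relevant
        parameters (log off-rate via intercept+off, logit prevalence)."""
        deaths, py, d_miss, cohort, population = 80, 40_000.0, 30, 30_000, 3_000_000
        data = single_stratum_dataset(deaths, py, d_miss, cohort, population)
        spec = RateModelSpec(fix_pmatch_to_one=True)
        cfg = McmcConfig(chains=2, iterations=12_000, burn_in=4000, thin=2,
                         seed=11, rhat_threshold=1.2)
        samples = run_mcmc(data, rate_spec=spec, config=cfg)
        dic = compute_dic(samples)

        # oracle: likelihood depends on b = intercept+off and a = logit pi
        lgam = gammaln(deaths + 1) + gammaln(d_miss + 1)

        def loglik(b, a):
            rate = np.exp(b)
            mu1 = rate * py
            nm = expit(a) * population - cohort
            mu2 = rate * np.clip(nm, 0, None)
            ll = (deaths * np.log(mu1) - mu1
                  + d_miss * np.log(np.where(mu2 > 0, mu2, np.nan)) - mu2
                  - lgam)
            return np.where(nm > 0, ll, -np.inf)

        b = np.linspace(np.log(deaths / py) - 1.0, np.log(deaths / py) + 1.0,
                        400)
        crude_pi = (cohort + d_miss / (deaths / py)) / population
        a0 = np.log(crude_pi / (1 - crude_pi))
        a = np.linspace(a0 - 1.5, a0 + 1.5, 400)
        B, A = np.meshgrid(b, a, indexing="ij")
        ll = loglik(B, A)
        # priors: b = intercept+off ~ N(0, 2*10^2); a ~ N(0, 10^2)
        logpost = ll - B**2 / (2 * 200.0) - A**2 / (2 * 100.0)
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        ll_safe = np.where(np.isfinite(ll), ll, 0.0)  # zero-weight region
        dbar_oracle = float(np.sum(w * -2 * ll_safe))
        b_bar, a_bar = float((w * B).sum()), float((w * A).sum())
        d_at_mean_oracle = float(-2 * loglik(b_bar, a_bar))

        assert dic.dbar == pytest.approx(dbar_oracle, abs=1.0)
        assert dic.d_at_mean == pytest.approx(d_at_mean_oracle, abs=1.0)
        assert dic.pd == pytest.approx(dbar_oracle - d_at_mean_oracle,
                                       abs=1.0)
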