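"""Crude Bayesian mortality multiplier — the comparator model.

Estimates the hidden population size as N = D / lambda, where D is the
benchmark count of all fDRPs in the estimation year and lambda is the fDRP
rate estimated from the linked cohort, ignoring heterogeneity, treatment
status and linkage error.

With conjugate vague priors both posteriors are available in closed form:
lambda | cohort data ~ Gamma(a0 + deaths, b0 + person-years) and the Poisson
mean behind the benchmark, mu_D | d ~ Gamma(d + 1, 1) under a flat prior.
The posterior of N is summarised by direct Monte Carlo from these.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_data import CohortDataset, aggregate_counts
from .inference import McmcConfig, _split_rhat

__all__ = ["MultiplierInputs", "plug_in_estimate", "bayesian_multiplier",
           "multiplier_inputs_from_dataset"]


@dataclass(frozen=True)
class MultiplierInputs:
    """Benchmark count plus the cohort data behind the multiplier."""

    benchmark_deaths: int
    cohort_deaths: int
    cohort_person_years: float

    def __post_init__(self) -> None:
        if self.benchmark_deaths < 0 or self.cohort_deaths < 0:
            raise ValueError("death counts must be non-negative")
        if self.benchmark_deaths < self.cohort_deaths:
            raise ValueError("benchmark must include the cohort deaths")
        if self.cohort_person_years <= 0:
            raise ValueError("cohort person-years must be positive")


def multiplier_inputs_from_dataset(data: CohortDataset,
                                   year: str | None = None) -> MultiplierInputs:
    """Derive the three crude inputs from a cohort table's estimation year."""
    year = year or data.estimation_year
    if year is None:
        raise ValueError("dataset has no estimation-year observations")
    linked = aggregate_counts(data, year, "deaths_linked")
    unlinked = aggregate_counts(data, year, "deaths_unlinked")
    py = aggregate_counts(data, year, "person_years")
    return MultiplierInputs(
        benchmark_deaths=int(linked + unlinked),
        cohort_deaths=int(linked),
        cohort_person_years=float(py),
    )


def plug_in_estimate(inputs: MultiplierInputs) -> float:
    """Point estimate N = d * T / d_cohort (benchmark / crude rate)."""
    if inputs.cohort_deaths == 0:
        raise ValueError("multiplier undefined with zero cohort deaths")
    return (inputs.benchmark_deaths * inputs.cohort_person_years
            / inputs.cohort_deaths)


def bayesian_multiplier(
    inputs: MultiplierInputs,
    config: McmcConfig | None = None,
    lambda_prior: tuple[float, float] = (0.001, 0.001),
    fix_lambda: float | None = None,
    fix_benchmark_mean: float | None = None,
) -> pd.DataFrame:
    """Posterior summary of N under the crude multiplier model.

    Parameters
    ----------
    lambda_prior : (a0, b0)
        Gamma prior for the cohort fDRP rate; (0, 0) gives the improper
        limit Gamma(deaths, person-years).
    fix_lambda, fix_benchmark_mean :
        Degenerate (point-mass) overrides, mainly for verification: fixing
        both collapses N to the plug-in estimate.

    Returns a summary table (median/mean/95% CrI/diagnostics) for N, the
    rate lambda, the multiplier 1/lambda and the benchmark mean.
    """
    config = config or McmcConfig(chains=2, iterations=20_000, burn_in=0,
                                  thin=1)
    n_draws = (config.iterations - config.burn_in) // config.thin
    rng = np.random.default_rng(config.seed)
    shape = (config.chains, n_draws)

    a0, b0 = lambda_prior
    if fix_lambda is not None:
        lam = np.full(shape, float(fix_lambda))
    else:
        a = a0 + inputs.cohort_deaths
        if a <= 0:
            raise ValueError("improper posterior: no cohort deaths and a0 = 0")
        lam = rng.gamma(a, 1.0 / (b0 + inputs.cohort_person_years), size=shape)
    if fix_benchmark_mean is not None:
        mu_d = np.full(shape, float(fix_benchmark_mean))
    else:
        mu_d = rng.gamma(inputs.benchmark_deaths + 1.0, 1.0, size=shape)
    n = mu_d / lam

    rows = []
    for name, arr in (("N", n), ("lambda", lam), ("multiplier", 1.0 / lam),
                      ("benchmark_mean", mu_d)):
        flat = arr.reshape(-1)
        rows.append({
            "quantity": name,
            "median": float(np.median(flat)),
            "mean": float(np.mean(flat)),
            "lower95": float(np.percentile(flat, 2.5)),
            "upper95": float(np.percentile(flat, 97.5)),
            "rhat": _split_rhat(arr) if config.chains >= 2 else float("nan"),
            "ess": float(flat.size) if np.ptp(flat) > 0 else float("nan"),
        })
    return pd.DataFrame(rows).set_index("quantity")
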