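"""Likelihood for fDRPs not linked to the cohort.

Unlinked deaths in a group arise from two sources: deaths among the
unobserved dependent population (all of whom are, by definition, out of
treatment) and "leakage" — deaths within the cohort that the record linkage
missed, a fraction (1 - pmatch) of the cohort's true deaths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .cohort_data import GroupObservation

__all__ = ["UnlinkedDeathMean", "expected_unlinked_deaths", "unlinked_loglik"]


@dataclass(frozen=True)
class UnlinkedDeathMean:
    """Poisson mean of one group's unlinked death count, by source."""

    mu_unobserved: float
    mu_leakage: float

    @property
    def total(self) -> float:
        return self.mu_unobserved + self.mu_leakage


def expected_unlinked_deaths(
    rate_off: float,
    rate_on: float,
    n_miss: float,
    py_on: float,
    py_off: float,
    pmatch: float,
) -> UnlinkedDeathMean:
    """Expected unlinked deaths for one group in the estimation year.

    Each unobserved person contributes one person-year at the off-treatment
    rate; leakage applies the linkage miss probability (1 - pmatch) to the
    cohort's expected true deaths on and off treatment.
    """
    if not (0.0 < pmatch <= 1.0):
        raise ValueError("pmatch must lie in (0, 1]")
    if min(rate_off, rate_on) < 0 or min(n_miss, py_on, py_off) < 0:
        raise ValueError("rates, n_miss and person-years must be non-negative")
    mu_unobserved = rate_off * n_miss
    mu_leakage = (1.0 - pmatch) * (rate_on * py_on + rate_off * py_off)
    return UnlinkedDeathMean(mu_unobserved=float(mu_unobserved),
                             mu_leakage=float(mu_leakage))


def unlinked_loglik(
    observations: Sequence[GroupObservation],
    means: Iterable[UnlinkedDeathMean],
) -> float:
    """Sum of Poisson log-pmfs of the unlinked counts at their total means.

    A zero mean with a positive observed count yields -inf (the state is
    inconsistent with the data and is rejected by the sampler).
    """
    counts = np.array([o.deaths_unlinked for o in observations], dtype=float)
    totals = np.array([m.total for m in means], dtype=float)
    if counts.shape != totals.shape:
        raise ValueError("observations and means must align one-to-one")
    if np.any((totals == 0) & (counts > 0)):
        return float("-inf")
    keep = totals > 0
    ll = stats.poisson.logpmf(counts[keep], totals[keep])
    return float(ll.sum())
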