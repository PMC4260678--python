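"""Wright–Fisher drift null test and haploid selection-coefficient estimation.

The null model is neutral Wright–Fisher resampling of ``N`` cytoplasmic
lineages: allele-count states 0..N form a Markov chain whose transition
matrix has entry ``(i, j) = Binom(N, i/N).pmf(j)``. Raising the matrix to
the ``n``-th power gives the exact end-frequency distribution after ``n``
generations conditional on the start count, from which a two-sided tail
p-value for the observed change is read off. Replicates are combined by
multiplying their p-values (the replicates are independent populations);
note that a product of p-values is not itself calibrated as a p-value — it
is reported as the joint null probability of changes at least as extreme,
with Fisher's combined chi-square test available as a calibrated
alternative.

Selection coefficients come from inverting the deterministic haploid
recursion ``p' = p(1+s) / (1 + p s)``: after ``t`` generations the odds
ratio satisfies ``odds(p_t)/odds(p_0) = (1+s)^t``, giving the exact
("discrete") estimator; the continuous-time logit-linear form
``s = [logit(p_t) - logit(p_0)] / t`` is provided for comparison and is
always slightly smaller (it is the log of ``1+s``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import binom, chi2

__all__ = [
    "DriftTestConfig",
    "DriftTestResult",
    "build_transition_matrix",
    "end_distribution",
    "two_sided_pvalue",
    "combine_replicates",
    "fisher_combined",
    "frequency_to_count",
    "drift_test",
    "estimate_selection",
]


def build_transition_matrix(N: int) -> np.ndarray:
    """(N+1)x(N+1) neutral Wright–Fisher transition matrix.

    Entry (i, j) is the binomial probability of j copies among N offspring
    given parental frequency i/N. Rows sum to 1 analytically; states 0 and
    N are absorbing.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    states = np.arange(N + 1)
    return binom.pmf(states[None, :], N, (states / N)[:, None])


def end_distribution(N: int, start_count: int, generations: int) -> np.ndarray:
    """Exact distribution over counts 0..N after ``generations`` neutral steps.

    Row ``start_count`` of the n-th matrix power, computed by repeated
    squaring on the dense matrix (fine for N up to a few thousand).
    ``generations=0`` returns a point mass at the start.
    """
    if not 0 <= start_count <= N:
        raise ValueError(f"start_count must be in [0, {N}], got {start_count}")
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if generations == 0:
        out = np.zeros(N + 1)
        out[start_count] = 1.0
        return out
    M = build_transition_matrix(N)
    return np.linalg.matrix_power(M, generations)[start_count]


def two_sided_pvalue(
    distribution: np.ndarray, observed_count: int, start_count: int
) -> float:
    """Two-sided tail probability of the observed end count under the null.

    Twice the null mass at least as extreme as the observation in its
    direction of change from the start (``2 P(X >= obs)`` for an increase,
    ``2 P(X <= obs)`` for a decrease), capped at 1. No change returns 1.
    Absorbing boundary states contribute to the tails (no conditioning on
    segregation), so the statistic is conservative.
    """
    distribution = np.asarray(distribution, dtype=float)
    n_states = distribution.size
    if not 0 <= observed_count < n_states:
        raise ValueError("observed_count outside the state space")
    if not 0 <= start_count < n_states:
        raise ValueError("start_count outside the state space")
    if observed_count == start_count:
        return 1.0
    if observed_count > start_count:
        tail = distribution[observed_count:].sum()
    else:
        tail = distribution[: observed_count + 1].sum()
    return float(min(1.0, 2.0 * tail))


def combine_replicates(p_values: Sequence[float]) -> float:
    """Product of per-replicate p-values.

    The replicates are independent populations, so the product is the
    joint null probability of all replicates changing at least as
    extremely as observed. It is NOT calibrated as a p-value (the product
    of k uniforms is stochastically smaller than uniform); see
    :func:`fisher_combined` for a calibrated combination.
    """
    if len(p_values) == 0:
        raise ValueError("need at least one p-value")
    if any(not 0.0 <= p <= 1.0 for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    return float(np.prod(p_values))


def fisher_combined(p_values: Sequence[float]) -> float:
    """Fisher's combined probability test: -2 sum(ln p) ~ chi2(2k) under the null."""
    if len(p_values) == 0:
        raise ValueError("need at least one p-value")
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        return 0.0  # -2 ln 0 is infinite; the chi-square tail is exactly 0
    stat = -2.0 * np.log(p).sum()
    return float(chi2.sf(stat, df=2 * len(p)))


def frequency_to_count(frequency: float, N: int) -> int:
    """Map a frequency onto the nearest count state 0..N.

    Rounds half away from zero (18.75 lineages -> 19) so that mapped
    states are symmetric around N/2.
    """
    if not 0.0 <= frequency <= 1.0:
        raise ValueError("frequency must be in [0, 1]")
    return int(math.floor(frequency * N + 0.5))


@dataclass
class DriftTestConfig:
    """Inputs for the drift null test.

    ``replicates`` holds one (start_frequency, end_frequency) pair per
    independent population; frequencies are mapped to integer count states
    by nearest-count rounding.
    """

    effective_size: int
    generations: int
    replicates: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        if self.effective_size < 1:
            raise ValueError("effective_size must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not self.replicates:
            raise ValueError("at least one replicate is required")
        for start, end in self.replicates:
            if not (0.0 <= start <= 1.0 and 0.0 <= end <= 1.0):
                raise ValueError("frequencies must be in [0, 1]")


@dataclass
class DriftTestResult:
    per_replicate_p: list[float]
    combined_p: float
    fisher_p: float
    end_distributions: list[np.ndarray] = field(repr=False)


def drift_test(config: DriftTestConfig) -> DriftTestResult:
    """Run the transition-matrix drift test for every replicate and combine.

    Replicates sharing a start count reuse the same end distribution (one
    matrix power per distinct start).
    """
    N, n = config.effective_size, config.generations
    dist_cache: dict[int, np.ndarray] = {}
    p_values: list[float] = []
    dists: list[np.ndarray] = []
    for start_f, end_f in config.replicates:
        i = frequency_to_count(start_f, N)
        j = frequency_to_count(end_f, N)
        if i not in dist_cache:
            dist_cache[i] = end_distribution(N, i, n)
        dist = dist_cache[i]
        p_values.append(two_sided_pvalue(dist, j, i))
        dists.append(dist)
    return DriftTestResult(
        per_replicate_p=p_values,
        combined_p=combine_replicates(p_values),
        fisher_p=fisher_combined(p_values),
        end_distributions=dists,
    )


def estimate_selection(
    start_frequency: float,
    end_frequency: float,
    generations: int,
    model: str = "discrete",
) -> float:
    """Selection coefficient implied by a frequency change over t generations.

    ``model="discrete"`` inverts the haploid recursion exactly:
    ``s = [odds(p_t)/odds(p_0)]^(1/t) - 1``. ``model="logit"`` is the
    continuous-time logit-linear slope ``[logit(p_t) - logit(p_0)] / t``.
    Both assume the favoured type has the same advantage over every
    competitor.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    for name, f in (("start", start_frequency), ("end", end_frequency)):
        if not 0.0 < f < 1.0:
            raise ValueError(
                f"{name} frequency {f} has undefined odds; frequencies must be "
                "strictly inside (0, 1) — consider a pseudo-frequency such as "
                "1/(2*coverage) for unobserved or fixed alleles"
            )
    odds_ratio = (end_frequency / (1 - end_frequency)) / (
        start_frequency / (1 - start_frequency)
    )
    if model == "discrete":
        return float(odds_ratio ** (1.0 / generations) - 1.0)
    if model == "logit":
        return float(np.log(odds_ratio) / generations)
    raise ValueError(f"unknown model {model!r}; use 'discrete' or 'logit'")
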