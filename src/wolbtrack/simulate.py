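"""Forward simulation of cytoplasmic lineage dynamics with a Pool-Seq observation model.

The population is a fixed number ``N`` of transmitting cytoplasmic lineages
(maternal lines) reproducing in non-overlapping generations. Each lineage
carries an mtDNA clade fixed at generation 0 and an infection state
(Wolbachia present or absent): mtDNA and Wolbachia are completely linked
because both pass only through the egg, so a lineage's clade never changes,
while infection can be lost when maternal transmission is imperfect.

Each generation, ``N`` offspring lineages are drawn by weighted multinomial
resampling — a Wright–Fisher step in which a cytotype's weight is its
frequency times its relative fitness. Optionally, offspring of uninfected
mothers are penalised in proportion to the frequency of infected males
(unidirectional cytoplasmic incompatibility), and infected offspring lose
the infection with probability ``1 - transmission_fidelity``, joining the
uninfected pool but keeping their mtDNA clade.

The observation model (:func:`sample_poolseq_counts`) emulates Pool-Seq of
the experimental populations: per diagnostic SNP, sequencing depth is
Poisson and the diagnostic-allele count is binomial at the owning clade's
frequency, with an optional per-base error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from wolbtrack.sync_io import ALLELE_INDEX, SYNC_ALLELES, SyncRecord

UNINFECTED = "uninfected"

#: Suffix marking lineages that lost their infection but keep their mtDNA clade.
LOST_SUFFIX = ":uninfected"


class DegenerateInputError(ValueError):
    """All surviving cytotypes have zero selective weight; resampling is undefined."""


@dataclass
class SimulationParams:
    """Configuration of the forward simulator.

    Parameters
    ----------
    n_lineages : int
        Number of transmitting cytoplasmic lineages per generation (the N
        of the drift model; for cytoplasmic elements, the count of
        transmitting females).
    generations : int
        Number of Wright–Fisher generations to simulate (>= 0).
    clades : sequence of str
        Ordered clade labels (e.g. ``["VI", "V", "I_II_III"]``).
    initial_frequencies : mapping
        Fraction of lineages per cytotype at generation 0: one entry per
        clade (infected lineages of that clade) plus ``"uninfected"``.
        Must sum to 1.
    selection : mapping
        Relative fitness multiplier per cytotype (``1 + s``); keys as in
        ``initial_frequencies``. Defaults to 1 everywhere (neutral).
    transmission_fidelity : float
        Probability that an infected mother's offspring is infected.
    ci_intensity : float
        Hatch-rate penalty on offspring of uninfected mothers, scaled by
        the current infected-male frequency; 0 disables cytoplasmic
        incompatibility.
    n_replicates : int
        Number of independent replicate populations.
    seed : int
        Seed for the replicate-level random generators.
    """

    n_lineages: int
    generations: int
    clades: Sequence[str]
    initial_frequencies: Mapping[str, float]
    selection: Mapping[str, float] = field(default_factory=dict)
    transmission_fidelity: float = 1.0
    ci_intensity: float = 0.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lineages < 1:
            raise ValueError("n_lineages must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.clades:
            raise ValueError("at least one clade label is required")
        keys = set(self.initial_frequencies)
        expected = set(self.clades) | {UNINFECTED}
        if keys != expected:
            raise ValueError(
                f"initial_frequencies keys {sorted(keys)} must be clades plus "
                f"'{UNINFECTED}' ({sorted(expected)})"
            )
        total = float(sum(self.initial_frequencies.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"initial_frequencies must sum to 1 (got {total})")
        if any(f < 0 for f in self.initial_frequencies.values()):
            raise ValueError("initial_frequencies must be non-negative")
        for key, w in self.selection.items():
            if key not in expected:
                raise ValueError(f"unknown cytotype {key!r} in selection")
            if w <= 0:
                raise ValueError("fitness multipliers must be > 0")
        if not 0.0 <= self.transmission_fidelity <= 1.0:
            raise ValueError("transmission_fidelity must be in [0, 1]")
        if not 0.0 <= self.ci_intensity <= 1.0:
            raise ValueError("ci_intensity must be in [0, 1]")

    def fitness(self, cytotype: str) -> float:
        """Fitness multiplier for a cytotype label; uninfected variants
        (including clade-carrying lineages that lost the infection) use the
        ``"uninfected"`` entry."""
        if cytotype.endswith(LOST_SUFFIX) or cytotype == UNINFECTED:
            return float(self.selection.get(UNINFECTED, 1.0))
        return float(self.selection.get(cytotype, 1.0))

    @property
    def cytotypes(self) -> list[str]:
        """Full cytotype label set: infected clades, clade lineages that lost
        infection, and the founding uninfected pool (unlabelled mtDNA)."""
        return (
            list(self.clades)
            + [c + LOST_SUFFIX for c in self.clades]
            + [UNINFECTED]
        )


@dataclass
class PopulationState:
    """Cytotype counts of one replicate at one generation.

    ``counts`` maps every cytotype label (see
    :attr:`SimulationParams.cytotypes`) to an integer count; counts sum to
    ``n_lineages`` at every generation.
    """

    generation: int
    counts: dict[str, int]

    @property
    def n_lineages(self) -> int:
        return sum(self.counts.values())

    @property
    def infected_count(self) -> int:
        return sum(
            c
            for label, c in self.counts.items()
            if label != UNINFECTED and not label.endswith(LOST_SUFFIX)
        )

    @property
    def infection_rate(self) -> float:
        """Fraction of lineages currently carrying the infection."""
        return self.infected_count / self.n_lineages

    def frequency(self, cytotype: str) -> float:
        return self.counts.get(cytotype, 0) / self.n_lineages

    def wolbachia_clade_frequencies(self, relative: bool = True) -> dict[str, float]:
        """Per-clade frequency of infected lineages.

        With ``relative=True`` (default) frequencies are relative to the
        infected fraction — what Pool-Seq of the symbiont genome measures,
        since only infected hosts contribute symbiont reads.
        """
        infected = {
            label: c
            for label, c in self.counts.items()
            if label != UNINFECTED and not label.endswith(LOST_SUFFIX)
        }
        denom = sum(infected.values()) if relative else self.n_lineages
        if denom == 0:
            return {label: 0.0 for label in infected}
        return {label: c / denom for label, c in infected.items()}

    def mtdna_clade_frequencies(self) -> dict[str, float]:
        """Per-clade mtDNA frequency, pooling infected and infection-lost
        lineages of the same clade (complete cytoplasmic linkage)."""
        out: dict[str, float] = {}
        for label, c in self.counts.items():
            if label == UNINFECTED:
                continue
            clade = label.removesuffix(LOST_SUFFIX)
            out[clade] = out.get(clade, 0.0) + c / self.n_lineages
        return out


def largest_remainder_counts(frequencies: np.ndarray, total: int) -> np.ndarray:
    """Round frequencies to integer counts summing exactly to ``total``.

    Largest-remainder (Hamilton) apportionment: floor everything, then hand
    the leftover units to the largest fractional parts. Ties broken by
    index order for determinism.
    """
    frequencies = np.asarray(frequencies, dtype=float)
    raw = frequencies * total
    counts = np.floor(raw).astype(np.int64)
    remainder = int(total - counts.sum())
    if remainder > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


def apply_selection(
    frequencies: np.ndarray | Sequence[float], fitness: np.ndarray | Sequence[float]
) -> np.ndarray:
    """One deterministic generation of haploid selection.

    Returns ``f_k w_k / sum_j f_j w_j`` — the infinite-population limit of
    the weighted resampling step. With fitness ``1 + s`` for one type
    against 1, this is the classical recursion ``p' = p(1+s) / (1 + p s)``.
    """
    f = np.asarray(frequencies, dtype=float)
    w = np.asarray(fitness, dtype=float)
    if f.shape != w.shape:
        raise ValueError("frequencies and fitness must have the same shape")
    if np.any(w <= 0):
        raise ValueError("fitness multipliers must be > 0")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must sum to 1")
    weighted = f * w
    total = weighted.sum()
    if total <= 0:
        raise DegenerateInputError("total selective weight is zero")
    return weighted / total


def _step(
    counts: np.ndarray, params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    """One generation: selection + CI weighting, multinomial resampling,
    then infection loss."""
    n_clades = len(params.clades)
    cytotypes = params.cytotypes
    freqs = counts / params.n_lineages

    weights = freqs * np.array([params.fitness(c) for c in cytotypes])
    if params.ci_intensity > 0:
        # infected male frequency == infected lineage frequency (equal sex ratio)
        infected_freq = freqs[:n_clades].sum()
        penalty = 1.0 - params.ci_intensity * infected_freq
        weights[n_clades:] *= penalty
    total = weights.sum()
    if total <= 0:
        raise DegenerateInputError(
            "total selective weight is zero; no cytotype can reproduce"
        )

    offspring = rng.multinomial(params.n_lineages, weights / total)

    if params.transmission_fidelity < 1.0:
        loss = rng.binomial(offspring[:n_clades], 1.0 - params.transmission_fidelity)
        offspring[:n_clades] -= loss
        offspring[n_clades : 2 * n_clades] += loss
    return offspring


def simulate_trajectory(params: SimulationParams) -> list[list[PopulationState]]:
    """Simulate all replicates; returns one trajectory (list of states,
    generation 0 .. ``params.generations``) per replicate.

    Generation 0 is the largest-remainder integerisation of
    ``initial_frequencies`` (loss-cytotypes start at 0). Each replicate
    uses an independent stream spawned deterministically from ``seed``, so
    identical parameters reproduce trajectories bit-identically.
    """
    cytotypes = params.cytotypes
    n_clades = len(params.clades)
    init = np.zeros(len(cytotypes))
    for k, clade in enumerate(params.clades):
        init[k] = params.initial_frequencies[clade]
    init[2 * n_clades] = params.initial_frequencies[UNINFECTED]
    counts0 = largest_remainder_counts(init, params.n_lineages)

    seed_seq = np.random.SeedSequence(params.seed)
    trajectories: list[list[PopulationState]] = []
    for child in seed_seq.spawn(params.n_replicates):
        rng = np.random.default_rng(child)
        counts = counts0.copy()
        states = [PopulationState(0, dict(zip(cytotypes, counts0.tolist())))]
        for gen in range(1, params.generations + 1):
            counts = _step(counts, params, rng)
            states.append(PopulationState(gen, dict(zip(cytotypes, counts.tolist()))))
        trajectories.append(states)
    return trajectories


def trajectories_to_rows(
    trajectories: Sequence[Sequence[PopulationState]],
) -> list[dict]:
    """Flatten trajectories to TSV-ready rows
    (replicate, generation, cytotype, count, frequency)."""
    rows = []
    for r, states in enumerate(trajectories, start=1):
        for st in states:
            for cytotype, count in st.counts.items():
                rows.append(
                    {
                        "replicate": f"r{r}",
                        "generation": st.generation,
                        "cytotype": cytotype,
                        "count": int(count),
                        "frequency": count / st.n_lineages,
                    }
                )
    return rows


def sample_poolseq_counts(
    clade_frequencies: Mapping[str, float] | Sequence[Mapping[str, float]],
    snp_table,
    mean_coverage: float,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[SyncRecord]:
    """Draw sync-format read counts at each diagnostic SNP.

    Per site and pool, depth is Poisson(``mean_coverage``); the
    diagnostic-allele count is binomial with success probability equal to
    the owning clade's frequency, perturbed by a symmetric per-base error
    rate (a true diagnostic read miscalls away with probability
    ``error_rate``; each of the three other bases miscalls toward the
    diagnostic allele with probability ``error_rate / 3``). All remaining
    reads carry the reference base.

    Parameters
    ----------
    clade_frequencies : mapping or sequence of mappings
        Clade -> frequency for one pool, or one mapping per pool for a
        multi-replicate sync output. Frequencies may sum to < 1; the
        remainder is reference background.
    snp_table : CladeSNPTable
        Diagnostic SNP positions/alleles (see :mod:`wolbtrack.clades`).
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be > 0")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    if isinstance(clade_frequencies, Mapping):
        pools: list[Mapping[str, float]] = [clade_frequencies]
    else:
        pools = list(clade_frequencies)
    for freqs in pools:
        if sum(freqs.values()) > 1.0 + 1e-9:
            raise ValueError("clade frequencies must sum to <= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    records: list[SyncRecord] = []
    for row in snp_table.rows():
        if row.clade not in pools[0]:
            raise KeyError(f"no frequency provided for clade {row.clade!r}")
        # reference base: any base other than the diagnostic allele
        ref = "A" if row.allele != "A" else "G"
        counts = np.zeros((len(pools), 6), dtype=np.int64)
        for p, freqs in enumerate(pools):
            depth = rng.poisson(mean_coverage)
            f = freqs[row.clade]
            p_eff = f * (1.0 - error_rate) + (1.0 - f) * error_rate / 3.0
            diag = rng.binomial(depth, p_eff)
            counts[p, ALLELE_INDEX[row.allele]] = diag
            counts[p, ALLELE_INDEX[ref]] += depth - diag
        records.append(SyncRecord(row.contig, row.position, ref, counts))
    return records


__all__ = [
    "SimulationParams",
    "PopulationState",
    "DegenerateInputError",
    "UNINFECTED",
    "LOST_SUFFIX",
    "largest_remainder_counts",
    "apply_selection",
    "simulate_trajectory",
    "trajectories_to_rows",
    "sample_poolseq_counts",
]
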