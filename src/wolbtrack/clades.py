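"""Clade-diagnostic SNP discovery and pooled clade-frequency estimation.

A clade-diagnostic SNP is an alignment column where one clade group carries
an allele found in no other group's haplotypes; its pooled allele frequency
then estimates that clade's frequency directly. Per replicate, the clade
frequency is the median of its diagnostic-SNP frequencies after
downsampling every site to a fixed target coverage, which makes estimates
comparable across pools sequenced at different depths and robust to a
minority of misbehaving sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from wolbtrack.sync_io import ALLELE_INDEX, SyncRecord, index_records

logger = logging.getLogger(__name__)

#: IUPAC codes treated as missing/ambiguous; columns containing any are skipped.
AMBIGUOUS = set("NRYSWKMBDHV-?")

VALID_BASES = set("ACGT")


class InsufficientCoverageError(ValueError):
    """Site coverage is below the downsampling target; the site is unusable."""


@dataclass(frozen=True)
class DiagnosticSNP:
    contig: str
    position: int  # 1-based
    allele: str
    clade: str


class CladeSNPTable:
    """Table of clade-diagnostic SNPs.

    Each (contig, position, allele) appears at most once and is assigned to
    exactly one clade label. Two clades may share a position with different
    private alleles (unavoidable in a two-group panel, where every
    diagnostic column carries complementary private alleles).
    """

    def __init__(self, snps: Iterable[DiagnosticSNP]):
        self._snps = list(snps)
        seen: set[tuple[str, int, str]] = set()
        for snp in self._snps:
            key = (snp.contig, snp.position, snp.allele)
            if key in seen:
                raise ValueError(f"duplicate diagnostic site {key}")
            seen.add(key)
            if snp.allele not in VALID_BASES:
                raise ValueError(f"diagnostic allele must be A/C/G/T, got {snp.allele!r}")

    def rows(self) -> Iterator[DiagnosticSNP]:
        return iter(self._snps)

    def __len__(self) -> int:
        return len(self._snps)

    def clades(self) -> list[str]:
        out: list[str] = []
        for snp in self._snps:
            if snp.clade not in out:
                out.append(snp.clade)
        return out

    def for_clade(self, clade: str) -> list[DiagnosticSNP]:
        return [s for s in self._snps if s.clade == clade]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"contig": s.contig, "position": s.position, "allele": s.allele, "clade": s.clade}
                for s in self._snps
            ],
            columns=["contig", "position", "allele", "clade"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CladeSNPTable":
        return cls(
            DiagnosticSNP(str(r.contig), int(r.position), str(r.allele), str(r.clade))
            for r in df.itertuples()
        )


@dataclass
class CladeFrequencyEstimate:
    """Median diagnostic-SNP frequency of one clade in one pool.

    ``median_frequency`` is ``None`` when the clade had no usable SNP in
    the pool (a missing estimate, deliberately distinct from zero).
    """

    replicate: str
    clade: str
    median_frequency: float | None
    n_snps_used: int
    per_snp_frequencies: list[float] = field(default_factory=list)

    @property
    def is_missing(self) -> bool:
        return self.median_frequency is None


def identify_diagnostic_snps(
    haplotypes: Mapping[str, str],
    grouping: Mapping[str, str],
    contig: str = "alignment",
) -> CladeSNPTable:
    """Scan an aligned haplotype panel for clade-private alleles.

    A column is diagnostic for a clade group when every haplotype of that
    group carries the same allele there and no haplotype of any other
    group carries it (the allele is fixed within, and private to, the
    group). Columns containing any N/ambiguity character in any haplotype
    are excluded. Positions are 1-based on the alignment.

    Parameters
    ----------
    haplotypes : mapping
        Haplotype name -> aligned sequence (equal lengths).
    grouping : mapping
        Haplotype name -> clade group label (e.g. clades I, II and III
        mapped to a single ``I_II_III`` group when they share most
        variants).
    """
    if not haplotypes:
        raise ValueError("empty alignment")
    missing = [name for name in haplotypes if name not in grouping]
    if missing:
        raise ValueError(f"haplotypes without a clade label: {missing}")
    names = list(haplotypes)
    seqs = [haplotypes[n].upper() for n in names]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("all haplotypes must have the same aligned length")
    groups = sorted({grouping[n] for n in names})
    if len(groups) < 2:
        raise ValueError("need at least two clade groups to define private alleles")
    by_group: dict[str, list[str]] = {g: [] for g in groups}
    for name, seq in zip(names, seqs):
        by_group[grouping[name]].append(seq)

    snps: list[DiagnosticSNP] = []
    for col in range(length):
        column = [s[col] for s in seqs]
        if any(b not in VALID_BASES for b in column):
            continue  # N or ambiguity code anywhere kills the column
        group_alleles = {g: {s[col] for s in by_group[g]} for g in groups}
        for g in groups:
            alleles = group_alleles[g]
            if len(alleles) != 1:
                continue  # not fixed within the group
            (allele,) = alleles
            others = set().union(*(group_alleles[h] for h in groups if h != g))
            if allele not in others:
                snps.append(DiagnosticSNP(contig, col + 1, allele, g))
    return CladeSNPTable(snps)


def downsample_counts(
    record: SyncRecord,
    replicate: int,
    target_coverage: int,
    rng: int | np.random.Generator = 0,
    with_replacement: bool = False,
) -> SyncRecord:
    """Reduce one pool's counts at a site to exactly ``target_coverage`` reads.

    Default is sampling without replacement (multivariate hypergeometric),
    matching subsample semantics of the standard Pool-Seq toolkits; a
    with-replacement (multinomial) option is provided for comparison. The
    draw treats all six count categories (including N and del) as reads.

    Raises
    ------
    InsufficientCoverageError
        If the site's coverage is below the target; such sites are
        excluded from downstream medians rather than up-sampled.
    """
    if target_coverage < 1:
        raise ValueError("target_coverage must be >= 1")
    counts = record.counts[replicate]
    coverage = int(counts.sum())
    if coverage < target_coverage:
        raise InsufficientCoverageError(
            f"{record.contig}:{record.position} replicate {replicate}: "
            f"coverage {coverage} < target {target_coverage}"
        )
    if coverage == target_coverage:
        new = counts.copy()
    else:
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        if with_replacement:
            new = rng.multinomial(target_coverage, counts / coverage)
        else:
            new = rng.multivariate_hypergeometric(counts, target_coverage)
    return SyncRecord(record.contig, record.position, record.reference, new)


def estimate_clade_frequencies(
    records: Sequence[SyncRecord],
    table: CladeSNPTable,
    target_coverage: int,
    seed: int | np.random.Generator = 0,
    replicates: Sequence[str] | None = None,
) -> list[CladeFrequencyEstimate]:
    """Estimate per-pool clade frequencies from pooled counts.

    For every pool and clade, each diagnostic SNP present in ``records``
    is downsampled to ``target_coverage`` and its diagnostic-allele
    frequency computed as count / target coverage; the clade estimate is
    the median over usable SNPs (even counts average the two central
    values). Sites missing from ``records`` or below target coverage are
    skipped with a warning; a clade with zero usable SNPs in a pool is
    reported as missing, never as zero.
    """
    if not records:
        raise ValueError("no sync records given")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_pos = index_records(records)
    n_reps = records[0].n_replicates
    if replicates is None:
        replicates = [f"r{i + 1}" for i in range(n_reps)]
    if len(replicates) != n_reps:
        raise ValueError("replicate names do not match sync column count")

    estimates: list[CladeFrequencyEstimate] = []
    for rep_idx, rep_name in enumerate(replicates):
        for clade in table.clades():
            freqs: list[float] = []
            for snp in table.for_clade(clade):
                rec = by_pos.get((snp.contig, snp.position))
                if rec is None:
                    logger.warning(
                        "diagnostic SNP %s:%d absent from sync records; skipped",
                        snp.contig,
                        snp.position,
                    )
                    continue
                try:
                    down = downsample_counts(rec, rep_idx, target_coverage, rng)
                except InsufficientCoverageError as exc:
                    logger.warning("excluded: %s", exc)
                    continue
                freqs.append(down.allele_count(0, snp.allele) / target_coverage)
            if freqs:
                estimates.append(
                    CladeFrequencyEstimate(
                        rep_name, clade, float(np.median(freqs)), len(freqs), freqs
                    )
                )
            else:
                estimates.append(CladeFrequencyEstimate(rep_name, clade, None, 0, []))
    return estimates


def cumulative_frequency_check(
    estimates: Sequence[CladeFrequencyEstimate],
    band: tuple[float, float] = (0.9, 1.1),
) -> pd.DataFrame:
    """Per-pool sum of clade medians with a pass/warn flag.

    When the diagnostic panel captures every major lineage, the clade
    medians should sum to ~1; a sum well below 1 means a major variant is
    unaccounted for, well above 1 suggests misassigned SNPs. Missing
    estimates make the pool's check fail-safe (warn).
    """
    lo, hi = band
    rows = []
    for rep in dict.fromkeys(e.replicate for e in estimates):
        rep_est = [e for e in estimates if e.replicate == rep]
        if any(e.is_missing for e in rep_est):
            rows.append({"replicate": rep, "cumulative_frequency": np.nan, "status": "warn"})
            continue
        total = sum(e.median_frequency for e in rep_est)
        rows.append(
            {
                "replicate": rep,
                "cumulative_frequency": total,
                "status": "pass" if lo <= total <= hi else "warn",
            }
        )
    return pd.DataFrame(rows, columns=["replicate", "cumulative_frequency", "status"])


def estimates_to_frame(estimates: Sequence[CladeFrequencyEstimate]) -> pd.DataFrame:
    """Tabulate estimates (replicate, clade, median_frequency, n_snps_used)."""
    return pd.DataFrame(
        [
            {
                "replicate": e.replicate,
                "clade": e.clade,
                "median_frequency": np.nan if e.is_missing else e.median_frequency,
                "n_snps_used": e.n_snps_used,
            }
            for e in estimates
        ],
        columns=["replicate", "clade", "median_frequency", "n_snps_used"],
    )


__all__ = [
    "DiagnosticSNP",
    "CladeSNPTable",
    "CladeFrequencyEstimate",
    "InsufficientCoverageError",
    "identify_diagnostic_snps",
    "downsample_counts",
    "estimate_clade_frequencies",
    "cumulative_frequency_check",
    "estimates_to_frame",
]
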