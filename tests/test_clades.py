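"""Diagnostic-SNP discovery, coverage downsampling, and median clade-frequency estimation."""

import numpy as np
import pytest

from wolbtrack.clades import (
    CladeSNPTable,
    DiagnosticSNP,
    InsufficientCoverageError,
    cumulative_frequency_check,
    downsample_counts,
    estimate_clade_frequencies,
    identify_diagnostic_snps,
)
from wolbtrack.sync_io import ALLELE_INDEX, SyncRecord


def record(counts, contig="wolb", position=1, ref="A"):
    return SyncRecord(contig, position, ref, np.array(counts))


def deterministic_record(position, allele, freq, coverage=100, ref="A"):
    """Counts exactly proportional to freq at exactly the target coverage,
    so downsampling is the identity and the frequency is noise-free."""
    counts = np.zeros(6, dtype=int)
    diag = round(freq * coverage)
    counts[ALLELE_INDEX[allele]] = diag
    counts[ALLELE_INDEX[ref]] += coverage - diag
    return SyncRecord("wolb", position, ref, counts)


class TestIdentifyDiagnosticSnps:
    def test_single_mismatch_diagnostic_for_both_groups(self):
        table = identify_diagnostic_snps(
            {"h1": "AAAT", "h2": "AAAC"}, {"h1": "g1", "h2": "g2"}
        )
        found = {(s.position, s.allele, s.clade) for s in table.rows()}
        assert found == {(4, "T", "g1"), (4, "C", "g2")}

    def test_shared_allele_diagnostic_only_for_odd_group(self):
        # groups 1 and 2 share G; only group 3's T is private
        table = identify_diagnostic_snps(
            {"a": "AG", "b": "AG", "c": "AT"},
            {"a": "g1", "b": "g2", "c": "g3"},
        )
        found = {(s.position, s.allele, s.clade) for s in table.rows()}
        assert found == {(2, "T", "g3")}

    def test_ambiguous_columns_excluded(self):
        table = identify_diagnostic_snps(
            {"a": "ANT", "b": "AGC"}, {"a": "g1", "b": "g2"}
        )
        assert {s.position for s in table.rows()} == {3}

    def test_allele_not_fixed_within_group_is_not_diagnostic(self):
        table = identify_diagnostic_snps(
            {"a1": "T", "a2": "G", "b": "G"}, {"a1": "g1", "a2": "g1", "b": "g2"}
        )
        assert len(table) == 0

    @pytest.mark.parametrize(
        "haplotypes,grouping",
        [({}, {}), ({"a": "ACGT", "b": "ACGT"}, {"a": "g1", "b": "g1"})],
    )
    def test_degenerate_panels_rejected(self, haplotypes, grouping):
        with pytest.raises(ValueError):
            identify_diagnostic_snps(haplotypes, grouping)

    def test_planted_variants_recovered_exactly(self):
        """Random 1 kb alignment with planted private variants: the scan must
        agree with an independent brute-force column oracle."""
        rng = np.random.default_rng(17)
        length, groups = 1000, {"g1": 3, "g2": 3, "g3": 2}
        backbone = rng.choice(list("ACGT"), size=length)
        seqs = {}
        grouping = {}
        for g, n in groups.items():
            for i in range(n):
                name = f"{g}_{i}"
                seqs[name] = backbone.copy()
                grouping[name] = g
        # plant fixed private variants (distinct columns, allele differing from backbone)
        planted = {}
        for g, col in [("g1", 10), ("g1", 500), ("g2", 250), ("g3", 999)]:
            alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[backbone[col]]
            for name, grp in grouping.items():
                if grp == g:
                    seqs[name][col] = alt
            planted[(col + 1, alt)] = g
        # sprinkle non-diagnostic noise: a variant in a single haplotype of a
        # multi-member group (breaks fixation, so never diagnostic)
        seqs["g1_0"][700] = {"A": "C", "C": "G", "G": "T", "T": "A"}[backbone[700]]
        haplotypes = {k: "".join(v) for k, v in seqs.items()}

        table = identify_diagnostic_snps(haplotypes, grouping)
        found = {(s.position, s.allele): s.clade for s in table.rows()}
        assert found == planted

        # independent oracle: exhaustive per-column allele bookkeeping
        oracle = {}
        for col in range(length):
            col_alleles = {g: set() for g in groups}
            for name, seq in haplotypes.items():
                col_alleles[grouping[name]].add(seq[col])
            if any(a - set("ACGT") for a in col_alleles.values()):
                continue
            for g in groups:
                if len(col_alleles[g]) == 1:
                    (allele,) = col_alleles[g]
                    if all(allele not in col_alleles[h] for h in groups if h != g):
                        oracle[(col + 1, allele)] = g
        assert found == oracle


class TestDownsampling:
    def test_exact_coverage_returned_unchanged(self):
        rec = record([60, 40, 0, 0, 0, 0])
        out = downsample_counts(rec, 0, 100, rng=1)
        assert out.counts[0].tolist() == [60, 40, 0, 0, 0, 0]

    def test_insufficient_coverage_raises(self):
        with pytest.raises(InsufficientCoverageError):
            downsample_counts(record([30, 0, 0, 0, 0, 0]), 0, 50)

    def test_never_exceeds_target_and_preserves_expectation(self):
        """Hypergeometric draw: coverage is exactly the target and the allele
        frequency is unbiased over seeds."""
        rec = record([100, 100, 0, 0, 0, 0])
        rng = np.random.default_rng(23)
        draws = np.array(
            [downsample_counts(rec, 0, 100, rng).counts[0, 0] for _ in range(10_000)]
        )
        # hypergeometric variance: n*p*(1-p)*(N-n)/(N-1)
        var = 100 * 0.5 * 0.5 * 100 / 199
        assert abs(draws.mean() - 50.0) < 3 * np.sqrt(var / 10_000)
        assert all(
            downsample_counts(rec, 0, 100, rng).coverage(0) == 100 for _ in range(20)
        )

    def test_del_and_n_reads_count_toward_coverage(self):
        rec = record([40, 0, 0, 0, 30, 30])
        out = downsample_counts(rec, 0, 50, rng=5)
        assert out.coverage(0) == 50
        assert out.counts[0, 4:].sum() > 0  # N/del reads survive the draw

    def test_with_replacement_option(self):
        rec = record([10, 10, 0, 0, 0, 0])
        out = downsample_counts(rec, 0, 15, rng=9, with_replacement=True)
        assert out.coverage(0) == 15


class TestEstimateCladeFrequencies:
    def test_single_snp_direct_frequency(self):
        table = CladeSNPTable([DiagnosticSNP("wolb", 1, "A", "V")])
        recs = [record([80, 20, 0, 0, 0, 0], ref="T")]
        (est,) = estimate_clade_frequencies(recs, table, 100, seed=1)
        assert est.median_frequency == pytest.approx(0.80)
        assert est.n_snps_used == 1

    def test_median_robust_to_outlier_snp(self):
        table = CladeSNPTable(
            [DiagnosticSNP("wolb", p, "C", "V") for p in (1, 2, 3)]
        )
        recs = [
            deterministic_record(1, "C", 0.20),
            deterministic_record(2, "C", 0.25),
            deterministic_record(3, "C", 0.90),  # aberrant site
        ]
        (est,) = estimate_clade_frequencies(recs, table, 100, seed=1)
        assert est.median_frequency == pytest.approx(0.25)

    def test_even_count_averages_central_values(self):
        table = CladeSNPTable(
            [DiagnosticSNP("wolb", p, "C", "V") for p in (1, 2, 3, 4)]
        )
        recs = [deterministic_record(p, "C", f) for p, f in zip((1, 2, 3, 4), (0.1, 0.2, 0.4, 0.9))]
        (est,) = estimate_clade_frequencies(recs, table, 100, seed=1)
        assert est.median_frequency == pytest.approx(0.3)

    def test_zero_noise_counts_return_truth_exactly(self):
        truth = {"VI": 0.55, "V": 0.25, "I_II_III": 0.20}
        table = CladeSNPTable(
            [DiagnosticSNP("wolb", p, "C", c) for p, c in zip((1, 2, 3), truth)]
        )
        recs = [deterministic_record(p, "C", f) for p, f in zip((1, 2, 3), truth.values())]
        ests = estimate_clade_frequencies(recs, table, 100, seed=1)
        assert {e.clade: e.median_frequency for e in ests} == pytest.approx(truth)

    def test_snp_order_permutation_invariant(self):
        rng = np.random.default_rng(3)
        positions = list(range(1, 12))
        freqs = rng.uniform(0.1, 0.9, len(positions))
        recs = [deterministic_record(p, "C", f) for p, f in zip(positions, freqs)]
        fwd = CladeSNPTable([DiagnosticSNP("wolb", p, "C", "V") for p in positions])
        rev = CladeSNPTable([DiagnosticSNP("wolb", p, "C", "V") for p in reversed(positions)])
        (a,) = estimate_clade_frequencies(recs, fwd, 100, seed=1)
        (b,) = estimate_clade_frequencies(recs, rev, 100, seed=1)
        assert a.median_frequency == b.median_frequency

    def test_corruption_of_minority_of_snps_leaves_median(self):
        positions = list(range(1, 8))
        recs = [deterministic_record(p, "C", 0.4) for p in positions]
        for p in (1, 2, 3):  # corrupt 3 of 7
            recs[p - 1] = deterministic_record(p, "C", 0.99)
        table = CladeSNPTable([DiagnosticSNP("wolb", p, "C", "V") for p in positions])
        (est,) = estimate_clade_frequencies(recs, table, 100, seed=1)
        assert est.median_frequency == pytest.approx(0.4)

    def test_unusable_clade_reported_missing_not_zero(self):
        table = CladeSNPTable(
            [DiagnosticSNP("wolb", 1, "C", "V"), DiagnosticSNP("wolb", 2, "C", "VI")]
        )
        recs = [deterministic_record(1, "C", 0.5)]  # VI's site absent
        ests = {e.clade: e for e in estimate_clade_frequencies(recs, table, 100, seed=1)}
        assert ests["V"].median_frequency == pytest.approx(0.5)
        assert ests["VI"].is_missing
        assert ests["VI"].median_frequency is None

    def test_low_coverage_sites_excluded(self):
        table = CladeSNPTable(
            [DiagnosticSNP("wolb", 1, "C", "V"), DiagnosticSNP("wolb", 2, "C", "V")]
        )
        recs = [
            deterministic_record(1, "C", 0.5, coverage=100),
            deterministic_record(2, "C", 0.5, coverage=30),  # below target
        ]
        (est,) = estimate_clade_frequencies(recs, table, 100, seed=1)
        assert est.n_snps_used == 1

    def test_recovery_from_sampled_counts_at_fifty_fold(self, snp_table):
        """Pool-Seq sampling at ~50x then median estimation recovers the truth
        within the binomial error bound at that depth."""
        import wolbtrack as w

        truth = {"VI": 0.55, "V": 0.25, "I_II_III": 0.20}
        recs = w.sample_poolseq_counts(truth, snp_table, 80, 0.001, seed=29)
        ests = estimate_clade_frequencies(recs, snp_table, 50, seed=30)
        for est in ests:
            assert est.median_frequency == pytest.approx(truth[est.clade], abs=0.08)


class TestCumulativeCheck:
    def _estimates(self, medians):
        from wolbtrack.clades import CladeFrequencyEstimate

        return [
            CladeFrequencyEstimate("r1", c, m, 5, [m]) for c, m in medians.items()
        ]

    def test_complete_panel_passes(self):
        df = cumulative_frequency_check(self._estimates({"VI": 0.55, "V": 0.25, "I_II_III": 0.20}))
        assert df.loc[0, "status"] == "pass"
        assert df.loc[0, "cumulative_frequency"] == pytest.approx(1.0)

    def test_missing_major_lineage_warns(self):
        df = cumulative_frequency_check(self._estimates({"VI": 0.30, "V": 0.20, "I_II_III": 0.10}))
        assert df.loc[0, "status"] == "warn"
        assert df.loc[0, "cumulative_frequency"] == pytest.approx(0.60)
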