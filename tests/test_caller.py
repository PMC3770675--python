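import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polymine.caller import (
    CallerConfig,
    PolymorphismCall,
    call_indels,
    call_snps,
    summarize_calls,
    window_filter,
)

from conftest import make_alignment, random_alignment
from oracles import brute_force_indels, brute_force_snps


class TestSnpCriteria:
    def test_supported_biallelic_column_is_called(self):
        aln = make_alignment(
            ["AAGAA", "AAGAA", "AATAA", "AATAA", "AATAA"],
            varieties=["A", "A", "B", "B", "B"],
        )
        (call,) = call_snps(aln)
        assert call.contig_col == 2
        assert call.alleles == ("G", "T")
        assert call.variety_alleles == {"A": ("G", 2), "B": ("T", 3)}

    def test_within_variety_mismatch_blocks_call(self):
        aln = make_alignment(
            ["AAGAA", "AAGAA", "AATAA", "AAGAA"],
            varieties=["A", "A", "B", "B"],
        )
        assert call_snps(aln) == []

    def test_three_base_types_block_call(self):
        aln = make_alignment(
            ["AAGAA", "AAGAA", "AATAA", "AATAA", "AACAA", "AACAA"],
            varieties=["A", "A", "B", "B", "C", "C"],
        )
        assert call_snps(aln) == []

    def test_n_at_site_blocks_call(self):
        aln = make_alignment(
            ["AAGAA", "AAGAA", "AATAA", "AATAA", "AANAA"],
            varieties=["A", "A", "B", "B", "C"],
        )
        assert call_snps(aln) == []

    def test_singleton_allele_blocks_call(self):
        # allele T appears twice but split across two varieties
        aln = make_alignment(
            ["AAGAA", "AAGAA", "AATAA", "AATAA"],
            varieties=["A", "A", "B", "C"],
        )
        assert call_snps(aln) == []

    def test_unknown_reads_cannot_provide_support(self):
        aln = make_alignment(
            ["AAGAA", "AAGAA", "AATAA", "AATAA"],
            varieties=["A", "A", "unknown", "unknown"],
        )
        assert call_snps(aln) == []

    def test_identical_alignment_yields_nothing(self):
        aln = make_alignment(["ACGT"] * 4, varieties=["A", "A", "B", "B"])
        assert call_snps(aln) == []
        assert call_indels(aln) == []

    def test_gap_containing_column_left_to_indel_path(self):
        aln = make_alignment(
            ["AAGAA", "AAGAA", "AATAA", "AATAA", "AA-AA", "AA-AA"],
            varieties=["A", "A", "B", "B", "C", "C"],
        )
        assert call_snps(aln) == []


def _alignment_with_flank_snps(flank_cols):
    """40-column alignment: candidate SNP at col 20, extra SNPs at the
    given columns."""
    varieties = ["A", "A", "B", "B"]
    cols = {20: ("G", "T")}
    for c in flank_cols:
        cols[c] = ("C", "A")
    out = []
    for i in range(4):
        row = list("A" * 40)
        for c, (a, b) in cols.items():
            row[c] = a if varieties[i] == "A" else b
        out.append("".join(row))
    return make_alignment(out, varieties=varieties)


class TestWindowFilter:
    def _with_flank_snps(self, flank_cols):
        return _alignment_with_flank_snps(flank_cols)

    def test_clean_flanks_pass(self):
        aln = self._with_flank_snps([])
        assert window_filter(aln, 20)
        assert len(call_snps(aln)) == 1

    def test_three_discontinuous_flank_polymorphisms_fail(self):
        aln = self._with_flank_snps([16, 18, 23])
        assert not window_filter(aln, 20)
        # the candidate at 20 is suppressed
        assert all(c.contig_col != 20 for c in call_snps(aln))

    def test_adjacent_run_collapses_to_one_cluster(self):
        aln = self._with_flank_snps([22, 23, 24])
        assert window_filter(aln, 20)

    def test_two_separated_clusters_pass(self):
        aln = self._with_flank_snps([16, 23, 24])
        assert window_filter(aln, 20)

    def test_out_of_range_column_raises(self):
        aln = self._with_flank_snps([])
        with pytest.raises(IndexError):
            window_filter(aln, 99)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(st.sets(st.integers(min_value=10, max_value=30).filter(lambda c: c != 20),
                   max_size=10))
    def test_cluster_collapse_matches_enumeration_oracle(self, flank_cols):
        """For arbitrary flank-polymorphism patterns, the pass/fail verdict
        equals the independent cluster-counting enumeration."""
        from oracles import _window_clusters

        aln = _alignment_with_flank_snps(flank_cols)
        poly_cols = set(flank_cols) | {20}
        expected = _window_clusters(poly_cols, 20, 5) < 3
        assert window_filter(aln, 20) is expected


class TestIndels:
    def test_two_nt_deletion_called(self):
        aln = make_alignment(
            ["ACGTACGTAC", "ACGTACGTAC", "ACG--CGTAC", "ACG--CGTAC",
             "ACG--CGTAC"],
            varieties=["A", "A", "B", "B", "B"],
        )
        (call,) = call_indels(aln)
        assert call.contig_col == 3
        assert call.alleles == ("TA", "--")
        assert call.variety_alleles == {"A": ("TA", 2), "B": ("--", 3)}

    def test_run_longer_than_max_is_skipped(self):
        aln = make_alignment(
            ["ACGTACGTAC", "ACGTACGTAC", "AC----GTAC", "AC----GTAC"],
            varieties=["A", "A", "B", "B"],
        )
        assert call_indels(aln) == []
        cfg = CallerConfig(max_indel_len=4)
        assert len(call_indels(aln, cfg)) == 1

    def test_singleton_gap_is_rejected(self):
        aln = make_alignment(
            ["ACGTACGTAC", "ACGTACGTAC", "ACG-ACGTAC"],
            varieties=["A", "A", "B"],
        )
        assert call_indels(aln) == []


class TestOracleEquivalence:
    def test_matches_brute_force_criteria_checker(self, rng):
        """Vectorized caller equals an independent per-column
        re-implementation of the discovery criteria on random alignments."""
        for _ in range(60):
            contig = random_alignment(rng, max_reads=20, max_cols=200)
            got = [(c.contig_col, c.alleles, c.variety_alleles)
                   for c in call_snps(contig)]
            assert got == brute_force_snps(contig)
            got_indels = [(c.contig_col, c.alleles, c.variety_alleles)
                          for c in call_indels(contig)]
            assert got_indels == brute_force_indels(contig)

    def test_monotonicity_in_support_and_window(self, rng):
        """Raising min_support or widening the window never adds calls."""
        for _ in range(25):
            contig = random_alignment(rng)
            base = {c.contig_col for c in call_snps(contig)}
            stricter = {c.contig_col
                        for c in call_snps(contig, CallerConfig(min_support=3))}
            wider = {c.contig_col
                     for c in call_snps(contig, CallerConfig(window_halfwidth=8))}
            assert stricter <= base
            assert wider <= base

    def test_output_contract_two_alleles_no_n(self, rng):
        for _ in range(20):
            contig = random_alignment(rng)
            for call in call_snps(contig):
                assert len(set(call.alleles)) == 2
                assert all(a in "ACGT" for a in call.alleles)
                for allele, count in call.variety_alleles.values():
                    assert count >= 1


class TestSummaries:
    def test_per_gene_averages(self):
        calls = (
            [PolymorphismCall("SNP", "c", i, ("A", "G"), gene_id=f"g{i % 3}")
             for i in range(10)]
            + [PolymorphismCall("InDel", "c", 50 + i, ("AT", "--"),
                                gene_id="g0") for i in range(2)]
        )
        s = summarize_calls(calls)
        assert (s.n_snp, s.n_indel) == (10, 2)
        assert s.n_genes_snp == 3 and s.n_genes_indel == 1
        assert s.snps_per_gene == 3.3
        assert s.indels_per_gene == 2.0

    def test_interval_math(self):
        calls = [PolymorphismCall("SNP", "c", i, ("A", "G"), gene_id="g")
                 for i in range(4)]
        s = summarize_calls(calls, total_bases=1350)
        assert s.snp_interval_bp == 337.5

    def test_empty_call_list_reports_absent_averages(self):
        s = summarize_calls([])
        assert s.n_snp == 0 and s.n_indel == 0
        assert s.snps_per_gene is None
        assert s.polymorphisms_per_gene is None


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        CallerConfig(min_support=0)
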