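import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from polymine.alignment import ContigAlignment, SequenceRead, revcomp
from polymine.annotate import (
    GoTransferRule,
    anchor,
    classify_region,
    codon_effect,
    substitution_effect,
    transfer_go,
)
from polymine.caller import PolymorphismCall
from polymine.genemodels import GeneModel, GeneModelSet


def _single_exon_setup():
    """Forward-strand single-exon gene at scaffold positions 101-400."""
    rng = np.random.default_rng(7)
    scaffold = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
    # CDS 161..340 (180 nt), UTRs on either side, all one exon
    cds = "ATG" + "GCT" * 58 + "TGA"  # 180 nt
    scaffold = scaffold[:160] + cds + scaffold[340:]
    model = GeneModel(
        gene_id="g1", transcript_id="t1", scaffold="s1", strand="+",
        exons=[(101, 400)], cds_segments=[(161, 340)],
        utr5=[(101, 160)], utr3=[(341, 400)],
    )
    return {"s1": scaffold}, GeneModelSet([model])


def _contig_for(model, genome, flip=False):
    transcript = model.transcript_seq(genome)
    seq = revcomp(transcript) if flip else transcript
    reads = [
        SequenceRead(read_id=model.transcript_id, aligned_seq=seq,
                     variety="AM560-2", orientation="-" if flip else "+"),
        SequenceRead(read_id="r1", aligned_seq=seq, variety="KU50"),
    ]
    return ContigAlignment(contig_id="c1", n_columns=len(seq), reads=reads,
                           reference_member=model.transcript_id)


class TestAnchor:
    def test_forward_single_exon_offset_identity(self):
        genome, models = _single_exon_setup()
        contig = _contig_for(models["g1"], genome)
        anc = anchor(contig, genome, models)
        assert anc is not None and not anc.flip_to_coding
        assert anc.position_of(0) == 101
        assert anc.position_of(299) == 400

    def test_reverse_placed_reference_member(self):
        genome, models = _single_exon_setup()
        contig = _contig_for(models["g1"], genome, flip=True)
        anc = anchor(contig, genome, models)
        assert anc is not None and anc.flip_to_coding
        # last contig column is the transcript's first base
        assert anc.position_of(contig.n_columns - 1) == 101

    def test_pullback_consistency_on_simulated_cohort(self, sim):
        """Every anchored position, read back from the genome on the plus
        strand, equals the reference member's base after orientation
        transforms — including multi-exon minus-strand models."""
        for contig in sim.contigs:
            anc = anchor(contig, sim.scaffolds, sim.models)
            assert anc is not None
            ref = contig.reference_read
            scaffold = sim.scaffolds[anc.scaffold]
            for col in range(contig.n_columns):
                pos = anc.position_of(col)
                assert pos is not None  # full-length ungapped reference
                assert anc.to_plus_strand(ref.symbol_at(col)) == scaffold[pos - 1]

    def test_unannotated_contig_is_unanchored(self):
        genome, models = _single_exon_setup()
        reads = [SequenceRead(read_id=f"r{i}", aligned_seq="ACGTACGTAC",
                              variety="KU50") for i in range(2)]
        contig = ContigAlignment(contig_id="cx", n_columns=10, reads=reads)
        assert anchor(contig, genome, models) is None


class TestRegions:
    def test_point_classification(self):
        genome, models = _single_exon_setup()
        assert classify_region("s1", 200, models) == [("CDS", "g1")]
        assert classify_region("s1", 120, models) == [("UTR5", "g1")]
        assert classify_region("s1", 380, models) == [("UTR3", "g1")]
        assert classify_region("s1", 50, models) == [("intergenic", None)]

    def test_strand_flip_swaps_utr_sides(self):
        """The same genomic layout annotated on the minus strand turns the
        left exon segment into 3'-UTR."""
        plus = GeneModel("g", "t", "s", "+", exons=[(101, 400)],
                         cds_segments=[(161, 340)], utr5=[(101, 160)],
                         utr3=[(341, 400)])
        minus = GeneModel("g", "t", "s", "-", exons=[(101, 400)],
                          cds_segments=[(161, 340)], utr5=[(341, 400)],
                          utr3=[(101, 160)])
        assert plus.region_of(120) == "UTR5"
        assert minus.region_of(120) == "UTR3"
        assert plus.region_of(380) == "UTR3"
        assert minus.region_of(380) == "UTR5"

    def test_derived_utr_without_explicit_records(self):
        model = GeneModel("g", "t", "s", "-", exons=[(101, 400)],
                          cds_segments=[(161, 340)])
        assert model.region_of(120) == "UTR3"
        assert model.region_of(380) == "UTR5"

    def test_intron_classification(self):
        model = GeneModel("g", "t", "s", "+", exons=[(101, 200), (301, 400)],
                          cds_segments=[(101, 200), (301, 400)])
        assert model.region_of(250) == "intron"

    def test_region_partition_on_simulated_cohort(self, sim):
        """Every genic position gets exactly one region label and the
        labels agree with the generator's interval structure."""
        for model in sim.models:
            for pos in range(model.span[0], model.span[1] + 1, 7):
                region = model.region_of(pos)
                in_cds = any(s <= pos <= e for s, e in model.cds_segments)
                in_u5 = any(s <= pos <= e for s, e in model.utr5)
                in_u3 = any(s <= pos <= e for s, e in model.utr3)
                expected = ("CDS" if in_cds else "UTR5" if in_u5
                            else "UTR3" if in_u3 else "intron")
                assert region == expected


class TestCodonEffects:
    def test_enumeration_matches_codon_table(self):
        """All 576 single-base codon substitutions labeled identically to a
        direct enumeration over the standard genetic code."""
        bases = "ACGT"
        n_checked = 0
        for codon in map("".join, itertools.product(bases, repeat=3)):
            for pos in (1, 2, 3):
                for alt in bases:
                    if alt == codon[pos - 1]:
                        continue
                    alt_codon, ref_aa, alt_aa, effect = substitution_effect(
                        codon, pos, alt)
                    # independent oracle: Biopython translation
                    exp_ref = str(Seq(codon).translate())
                    exp_alt = str(Seq(alt_codon).translate())
                    assert ref_aa == exp_ref and alt_aa == exp_alt
                    if exp_ref != "*" and exp_alt == "*":
                        expected = "premature_stop"
                    elif exp_ref == "*" and exp_alt != "*":
                        expected = "read_through"
                    elif exp_ref == exp_alt:
                        expected = "synonymous"
                    else:
                        expected = "nonsynonymous"
                    assert effect == expected, (codon, pos, alt)
                    n_checked += 1
        assert n_checked == 576

    def test_canonical_examples(self):
        assert substitution_effect("GGA", 3, "G")[3] == "synonymous"
        assert substitution_effect("TGG", 3, "A")[3] == "premature_stop"
        assert substitution_effect("TGA", 3, "G")[3] == "read_through"
        assert substitution_effect("GCT", 1, "T")[3] == "nonsynonymous"

    def test_codon_effect_positions_on_fixture_gene(self):
        genome, models = _single_exon_setup()
        model = models["g1"]
        # CDS starts at 161: position 165 is codon 2, codon position 2
        call = PolymorphismCall("SNP", "c1", 0, ("C", "A"),
                                scaffold="s1", genome_pos=165)
        ann = codon_effect(call, model, genome)
        assert (ann.codon_index, ann.codon_position) == (1, 2)
        assert ann.ref_codon == "GCT"
        assert ann.effect == "nonsynonymous"  # GCT(Ala) -> GAT(Asp)
        assert ann.alt_codon == "GAT"

    def test_read_through_at_annotated_stop(self):
        genome, models = _single_exon_setup()
        # stop codon TGA at 338-340; G->C at codon position 3: TGA->TGC
        call = PolymorphismCall("SNP", "c1", 0, ("A", "C"),
                                scaffold="s1", genome_pos=340)
        ann = codon_effect(call, models["g1"], genome)
        assert ann.ref_aa == "*" and ann.effect == "read_through"

    def test_strand_convention_invariance(self):
        """A gene and its reverse-complemented mirror yield identical
        codon effects for the corresponding substitution."""
        genome, models = _single_exon_setup()
        fwd = models["g1"]
        L = len(genome["s1"])
        mirror_scaffold = revcomp(genome["s1"])
        mirror = GeneModel(
            gene_id="g1m", transcript_id="t1m", scaffold="s1", strand="-",
            exons=[(L - 399, L - 100)], cds_segments=[(L - 339, L - 160)],
            utr5=[(L - 399, L - 340)], utr3=[(L - 159, L - 100)],
        )
        pos = 165
        call = PolymorphismCall("SNP", "c", 0, ("C", "A"),
                                scaffold="s1", genome_pos=pos)
        ann_fwd = codon_effect(call, fwd, genome)
        mpos = L - pos + 1
        mcall = PolymorphismCall("SNP", "c", 0, ("C", "A"),
                                 scaffold="s1", genome_pos=mpos)
        ann_rev = codon_effect(mcall, mirror, {"s1": mirror_scaffold},
                               coding_alleles=("C", "A"))
        for field in ("codon_index", "codon_position", "ref_codon",
                      "alt_codon", "ref_aa", "alt_aa", "effect"):
            assert getattr(ann_fwd, field) == getattr(ann_rev, field)


class TestGoTransfer:
    @staticmethod
    def _hits(rows):
        return pd.DataFrame(
            [r + (0, 0, 1, 10, 1, 10) + (r[-1],) for r in []] or rows,
            columns=["qseqid", "sseqid", "pident", "length", "mismatch",
                     "gapopen", "qstart", "qend", "sstart", "send",
                     "evalue", "bitscore"],
        )

    def test_threshold_boundaries(self):
        hits = self._hits([
            ("q1", "AT1", 90.0, 80, 0, 0, 1, 80, 1, 80, 1e-10, 200.0),
            ("q2", "AT2", 90.0, 65, 0, 0, 1, 65, 1, 65, 1e-30, 200.0),
        ])
        lengths = {"AT1": 100, "AT2": 100}
        go = {"AT1": ["GO:0006950"], "AT2": ["GO:0009058"]}
        out = transfer_go(hits, lengths, go)
        assert out == {"q1": ["GO:0006950"]}  # q2 fails 70% coverage

    def test_missing_subject_length_skips_hit(self, caplog):
        hits = self._hits([("q1", "ATX", 90.0, 80, 0, 0, 1, 80, 1, 80,
                            1e-10, 200.0)])
        assert transfer_go(hits, {}, {"ATX": ["GO:1"]}) == {}

    def test_random_table_matches_filter_then_argmin_oracle(self, rng):
        subjects = [f"AT{i}" for i in range(12)]
        lengths = {s: int(rng.integers(80, 200)) for s in subjects}
        go = {s: [f"GO:{i:07d}"] for i, s in enumerate(subjects)}
        rows = []
        for _ in range(100):
            q = f"q{int(rng.integers(0, 15))}"
            s = subjects[int(rng.integers(0, len(subjects)))]
            length = int(rng.integers(30, 200))
            evalue = float(10.0 ** -rng.integers(0, 40))
            rows.append((q, s, 90.0, length, 0, 0, 1, length, 1, length,
                         evalue, 100.0))
        hits = self._hits(rows)
        rule = GoTransferRule()
        got = transfer_go(hits, lengths, go, rule)
        # brute force: filter then pick (evalue, -coverage, subject) min
        expected = {}
        for q in {r[0] for r in rows}:
            keep = [
                r for r in rows
                if r[0] == q
                and r[3] / lengths[r[1]] > rule.min_coverage
                and r[10] < rule.max_evalue
            ]
            if keep:
                best = min(keep, key=lambda r: (r[10], -r[3] / lengths[r[1]], r[1]))
                expected[q] = go[best[1]]
        assert got == expected
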