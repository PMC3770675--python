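"""Genome anchoring, region classification and codon-level effect calls.

Anchoring realizes discovery criterion (i): a contig only yields reportable
polymorphisms if it can be placed on the draft genome.  Placement goes
through the contig's *reference member* — the annotated transcript included
in the assembly input — whose ungapped sequence is matched against the
spliced exon sequence of its gene model; alignment columns then map
through the exon structure to 1-based scaffold positions, strand-aware.

Effects use the standard nuclear genetic code.  A CDS substitution is
synonymous when the encoded amino acid is unchanged, nonsynonymous
otherwise; the two open-reading-frame-breaking classes are singled out:
premature stop (coding codon -> stop) and read-through (stop codon ->
coding codon).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .alignment import ContigAlignment, revcomp
from .caller import PolymorphismCall
from .genemodels import GeneModel, GeneModelSet, _fetch

logger = logging.getLogger(__name__)

STOP = "*"
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}


def translate_codon(codon: str) -> str:
    """Amino acid (one-letter) or ``*`` for a stop codon."""
    if codon in _STANDARD_TABLE.stop_codons:
        return STOP
    return _STANDARD_TABLE.forward_table[codon]


@dataclass
class EffectAnnotation:
    """Gene-context annotation of one call.

    ``codon_position`` is 1-based within the codon; codon fields are only
    present for CDS SNPs.  ``effect`` is one of synonymous / nonsynonymous /
    premature_stop / read_through / none.
    """

    call: PolymorphismCall | None
    region: str  # CDS|UTR5|UTR3|intron|intergenic
    gene_id: str | None = None
    codon_index: int | None = None
    codon_position: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    effect: str = "none"
    multi_gene: bool = False
    frame_warning: bool = False
    family: str | None = None


@dataclass
class ContigAnchor:
    """Column-wise placement of a contig on the genome via its reference
    member transcript.

    ``positions[col]`` is the 1-based scaffold position of alignment column
    ``col`` (None where the reference member is absent or gapped).
    ``flip_to_coding`` is True when the reference member was placed
    reverse-complemented, i.e. contig-orientation symbols must be
    complemented to read them on the transcript's coding strand.
    """

    contig_id: str
    model: GeneModel
    positions: list[int | None]
    flip_to_coding: bool

    @property
    def scaffold(self) -> str:
        return self.model.scaffold

    def position_of(self, col: int) -> int | None:
        return self.positions[col]

    def to_coding(self, symbol: str) -> str:
        return _COMP[symbol] if self.flip_to_coding else symbol

    def to_coding_allele(self, allele: str) -> str:
        """Multi-base allele in coding orientation (gap runs unchanged)."""
        if set(allele) == {"-"}:
            return allele
        if self.flip_to_coding:
            return "".join(_COMP[b] for b in reversed(allele))
        return allele

    def to_plus_strand(self, symbol: str) -> str:
        coding = self.to_coding(symbol)
        return _COMP[coding] if self.model.strand == "-" else coding


def anchor(
    contig: ContigAlignment, genome, models: GeneModelSet
) -> ContigAnchor | None:
    """Place a contig on the genome through its reference member.

    Returns None (criterion-(i) failure) when the contig has no reference
    member, the member's id matches no gene model transcript, or its
    ungapped sequence does not match the model's spliced transcript in
    either orientation.
    """
    ref = contig.reference_read
    if ref is None:
        return None
    model = models.by_transcript(ref.read_id)
    if model is None:
        return None
    transcript = model.transcript_seq(genome)
    ungapped = ref.ungapped()
    if ungapped == transcript:
        flip = False
    elif revcomp(ungapped) == transcript:
        flip = True
    else:
        logger.warning(
            "contig %s: reference member %s does not match transcript sequence",
            contig.contig_id, ref.read_id,
        )
        return None

    positions: list[int | None] = [None] * contig.n_columns
    t = 0  # offset along the reference member's ungapped sequence
    n = len(ungapped)
    for col in range(ref.contig_offset, ref.end):
        if ref.symbol_at(col) == "-":
            continue
        # transcript offset in coding orientation
        offset = (n - 1 - t) if flip else t
        positions[col] = model.transcript_offset_to_genome(offset)
        t += 1
    return ContigAnchor(
        contig_id=contig.contig_id, model=model, positions=positions, flip_to_coding=flip
    )


def classify_region(
    scaffold: str, pos: int, models: GeneModelSet
) -> list[tuple[str, str]]:
    """(region, gene_id) for every gene model overlapping the position;
    [("intergenic", None)] when none does."""
    hits = models.overlapping(scaffold, pos)
    if not hits:
        return [("intergenic", None)]
    return [(m.region_of(pos), m.gene_id) for m in hits]


def substitution_effect(ref_codon: str, codon_position: int, alt_base: str):
    """Effect of replacing base ``codon_position`` (1-based) of
    ``ref_codon`` with ``alt_base``.

    Returns (alt_codon, ref_aa, alt_aa, effect).
    """
    if not 1 <= codon_position <= 3:
        raise ValueError("codon_position must be 1, 2 or 3")
    alt_codon = (
        ref_codon[: codon_position - 1] + alt_base + ref_codon[codon_position:]
    )
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa != STOP and alt_aa == STOP:
        effect = "premature_stop"
    elif ref_aa == STOP and alt_aa != STOP:
        effect = "read_through"
    elif ref_aa == alt_aa:
        effect = "synonymous"
    else:
        effect = "nonsynonymous"
    return alt_codon, ref_aa, alt_aa, effect


def _pick_ref_alt(alleles: tuple[str, str], genome_base: str) -> tuple[str, str]:
    """Reference allele is the one matching the genome (reference-member)
    base; if neither matches, the lexicographically smaller allele is REF
    for determinism."""
    a, b = alleles
    if a == genome_base:
        return a, b
    if b == genome_base:
        return b, a
    return (a, b) if a < b else (b, a)


def codon_effect(
    call: PolymorphismCall,
    model: GeneModel,
    genome,
    coding_alleles: tuple[str, str] | None = None,
    multi_gene: bool = False,
) -> EffectAnnotation:
    """Codon-level annotation for an anchored CDS SNP.

    ``coding_alleles`` are the call's two alleles expressed on the coding
    strand (anchor.to_coding applied); they default to the stored alleles.
    """
    if call.kind != "SNP":
        raise ValueError("codon effects are defined for SNPs only")
    if call.genome_pos is None:
        raise ValueError("call must be anchored before effect annotation")
    pos = call.genome_pos
    cds_offset = model.cds_offset_of(pos)
    if cds_offset is None:
        raise ValueError(f"position {pos} is not in the CDS of {model.gene_id}")
    cds = model.cds_seq(genome)
    frame_warning = len(cds) % 3 != 0
    codon_index = cds_offset // 3
    codon_position = cds_offset % 3 + 1
    if 3 * codon_index + 3 > len(cds):
        # partial trailing codon on a frame-damaged model: no effect call
        return EffectAnnotation(
            call=call, region="CDS", gene_id=model.gene_id,
            codon_index=codon_index, codon_position=codon_position,
            frame_warning=True, effect="none", multi_gene=multi_gene,
        )
    ref_codon = cds[3 * codon_index : 3 * codon_index + 3]
    alleles = coding_alleles or call.alleles
    genome_base = cds[cds_offset]
    ref_allele, alt_allele = _pick_ref_alt(tuple(alleles), genome_base)
    if ref_allele != genome_base:
        # reference member unreadable at the site; evaluate against the
        # genome codon with the deterministic REF choice substituted in
        ref_codon = (
            ref_codon[: codon_position - 1] + ref_allele + ref_codon[codon_position:]
        )
    alt_codon, ref_aa, alt_aa, effect = substitution_effect(
        ref_codon, codon_position, alt_allele
    )
    return EffectAnnotation(
        call=call,
        region="CDS",
        gene_id=model.gene_id,
        codon_index=codon_index,
        codon_position=codon_position,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        effect=effect,
        multi_gene=multi_gene,
        frame_warning=frame_warning,
    )


def annotate_calls(
    calls: Iterable[PolymorphismCall],
    anchors: Mapping[str, ContigAnchor],
    genome,
    models: GeneModelSet,
    require_genome_anchor: bool = True,
) -> tuple[list[EffectAnnotation], list[PolymorphismCall]]:
    """Anchor and annotate a call set.

    Fills each call's scaffold/genome_pos/gene_id in place, classifies its
    region against every overlapping gene model (one annotation per model,
    flagged multi-gene when >1) and computes codon effects for CDS SNPs.
    Returns (annotations, unanchored_calls); unanchored calls are dropped
    from the annotation list when ``require_genome_anchor``.
    """
    annotations: list[EffectAnnotation] = []
    unanchored: list[PolymorphismCall] = []
    for call in calls:
        anc = anchors.get(call.contig_id)
        pos = anc.position_of(call.contig_col) if anc is not None else None
        if pos is None:
            unanchored.append(call)
            if not require_genome_anchor:
                annotations.append(EffectAnnotation(call=call, region="unanchored"))
            continue
        call.scaffold = anc.scaffold
        call.genome_pos = pos
        regions = classify_region(anc.scaffold, pos, models)
        multi = len(regions) > 1
        for region, gene_id in regions:
            if call.gene_id is None and gene_id is not None:
                call.gene_id = gene_id
            if region == "CDS" and call.kind == "SNP":
                coding = tuple(anc.to_coding(a) for a in call.alleles)
                ann = codon_effect(
                    call, models[gene_id], genome, coding_alleles=coding, multi_gene=multi
                )
            else:
                ann = EffectAnnotation(
                    call=call, region=region, gene_id=gene_id, multi_gene=multi
                )
            annotations.append(ann)
    return annotations, unanchored


# ---------------------------------------------------------------------------
# GO-term transfer from protein-alignment best hits


@dataclass(frozen=True)
class GoTransferRule:
    """Best-hit GO transfer thresholds: coverage is alignment length over
    *subject* protein length; defaults keep hits with >70% coverage and
    E-value < 1e-5."""

    min_coverage: float = 0.70
    max_evalue: float = 1e-5
    best_hit_only: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")


BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hit_table(path) -> pd.DataFrame:
    """12-column tab-separated pairwise-alignment hit table."""
    return pd.read_csv(path, sep="\t", names=BLAST_COLUMNS, header=None)


def read_go_map(path) -> dict[str, list[str]]:
    """2-column TSV: subject_id <TAB> pipe-separated GO terms."""
    out: dict[str, list[str]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            subject, terms = line.split("\t")[:2]
            out[subject] = [t for t in terms.split("|") if t]
    return out


def transfer_go(
    hits: pd.DataFrame,
    subject_lengths: Mapping[str, int],
    go_map: Mapping[str, list[str]],
    rule: GoTransferRule | None = None,
) -> dict[str, list[str]]:
    """Assign GO terms to each query gene from its best qualifying hit.

    A hit qualifies when alignment_length / subject_protein_length exceeds
    ``min_coverage`` and its E-value is below ``max_evalue``.  The best hit
    per query is the lowest E-value, ties broken by higher coverage then
    subject id.  Hits whose subject length is unknown are skipped with a
    warning.
    """
    rule = rule or GoTransferRule()
    best: dict[str, tuple[float, float, str]] = {}
    for row in hits.itertuples(index=False):
        slen = subject_lengths.get(row.sseqid)
        if slen is None:
            logger.warning("no protein length for subject %r; hit skipped", row.sseqid)
            continue
        coverage = row.length / slen
        if coverage <= rule.min_coverage or row.evalue >= rule.max_evalue:
            continue
        key = (row.evalue, -coverage, row.sseqid)
        if row.qseqid not in best or key < best[row.qseqid]:
            best[row.qseqid] = key
    result: dict[str, list[str]] = {}
    for query, (_, _, subject) in best.items():
        result[query] = list(go_map.get(subject, []))
    return result
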