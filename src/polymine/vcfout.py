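"""Serialization of call sets: VCF v4.2 (via pysam) and flat TSV.

The VCF carries anchored calls only (unanchored calls have no genomic
coordinate and go to a TSV sidecar).  REF is always the draft-genome base
run at the position; per-variety allele support is packed into the VA INFO
field as ``variety:allele:count`` triples.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping

import pysam

from .annotate import ContigAnchor, EffectAnnotation
from .caller import PolymorphismCall

TSV_COLUMNS = [
    "contig_id", "contig_col", "kind", "allele_a", "allele_b",
    "allele_a_coding", "allele_b_coding", "scaffold", "genome_pos",
    "gene_id", "variety_alleles",
]


def _pack_va(call: PolymorphismCall) -> str:
    return ";".join(
        f"{v}:{allele}:{count}"
        for v, (allele, count) in sorted(call.variety_alleles.items())
    )


def _unpack_va(text: str) -> dict[str, tuple[str, int]]:
    out: dict[str, tuple[str, int]] = {}
    for chunk in text.split(";"):
        if not chunk:
            continue
        variety, allele, count = chunk.rsplit(":", 2)
        out[variety] = (allele, int(count))
    return out


def write_calls_tsv(
    calls: Iterable[PolymorphismCall],
    path: str | Path,
    anchors: Mapping[str, ContigAnchor] | None = None,
) -> None:
    anchors = anchors or {}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for call in calls:
            anc = anchors.get(call.contig_id)
            coding = [
                anc.to_coding_allele(a) if anc else a for a in call.alleles
            ]
            writer.writerow([
                call.contig_id, call.contig_col, call.kind,
                call.alleles[0], call.alleles[1],
                coding[0], coding[1],
                call.scaffold or "", call.genome_pos or "",
                call.gene_id or "", _pack_va(call),
            ])


def read_calls_tsv(path: str | Path) -> list[tuple[PolymorphismCall, tuple[str, str]]]:
    """Read back (call, coding_alleles) pairs."""
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            call = PolymorphismCall(
                kind=row["kind"],
                contig_id=row["contig_id"],
                contig_col=int(row["contig_col"]),
                alleles=(row["allele_a"], row["allele_b"]),
                variety_alleles=_unpack_va(row["variety_alleles"]),
                scaffold=row["scaffold"] or None,
                genome_pos=int(row["genome_pos"]) if row["genome_pos"] else None,
                gene_id=row["gene_id"] or None,
            )
            out.append((call, (row["allele_a_coding"], row["allele_b_coding"])))
    return out


def _plus_strand_alleles(
    call: PolymorphismCall, anc: ContigAnchor
) -> tuple[list[int], list[str]]:
    """Run positions (ascending) and plus-strand single-column symbols."""
    length = call.length
    cols = list(range(call.contig_col, call.contig_col + length))
    positions = [anc.position_of(c) for c in cols]
    return positions, cols


def write_vcf(
    calls: Iterable[PolymorphismCall],
    anchors: Mapping[str, ContigAnchor],
    scaffolds: Mapping[str, str],
    path: str | Path,
    effects: Mapping[int, EffectAnnotation] | None = None,
) -> int:
    """Write anchored calls as VCF v4.2; returns the record count.

    ``effects`` optionally maps ``id(call)`` to an annotation whose REGION/
    EFFECT/CODON fields are appended to INFO.
    """
    header = pysam.VariantHeader()
    header.add_line('##source=polymine')
    for name in scaffolds.keys():
        header.contigs.add(str(name), length=len(str(scaffolds[name])))
    header.add_line('##INFO=<ID=KIND,Number=1,Type=String,Description="SNP or InDel">')
    header.add_line('##INFO=<ID=CONTIG,Number=1,Type=String,Description="Source contig">')
    header.add_line('##INFO=<ID=COL,Number=1,Type=Integer,Description="0-based contig column">')
    header.add_line('##INFO=<ID=VA,Number=1,Type=String,Description="variety:allele:count support">')
    header.add_line('##INFO=<ID=REGION,Number=1,Type=String,Description="Gene-model region">')
    header.add_line('##INFO=<ID=EFFECT,Number=1,Type=String,Description="Codon-level effect">')
    header.add_line('##INFO=<ID=CODON,Number=1,Type=String,Description="ref>alt codon">')

    records = []
    for call in calls:
        anc = anchors.get(call.contig_id)
        if anc is None or not call.anchored:
            continue
        scaffold_seq = str(scaffolds[call.scaffold])
        if call.kind == "SNP":
            pos = call.genome_pos
            ref = scaffold_seq[pos - 1]
            plus = {anc.to_plus_strand(a) for a in call.alleles}
            alts = sorted(plus - {ref}) or ["."]
            start0 = pos - 1
            alleles = (ref, *alts)
        else:
            positions, _cols = _plus_strand_alleles(call, anc)
            mapped = [p for p in positions if p is not None]
            if mapped:  # deletion relative to the genome
                lo = min(mapped)
                anchor_base = scaffold_seq[lo - 2] if lo > 1 else scaffold_seq[lo - 1]
                start0 = lo - 2 if lo > 1 else lo - 1
                deleted = scaffold_seq[lo - 1 : lo - 1 + call.length]
                alleles = (anchor_base + deleted, anchor_base)
            else:  # insertion relative to the genome: anchor to the left
                left = [
                    anc.position_of(c)
                    for c in range(call.contig_col - 1, -1, -1)
                    if anc.position_of(c) is not None
                ]
                if not left:
                    continue
                lo = left[0]
                anchor_base = scaffold_seq[lo - 1]
                inserted = next(a for a in call.alleles if set(a) != {"-"})
                inserted = "".join(anc.to_plus_strand(b) for b in inserted)
                start0 = lo - 1
                alleles = (anchor_base, anchor_base + inserted)
        info = dict(
            KIND=call.kind, CONTIG=call.contig_id,
            COL=call.contig_col, VA=_pack_va(call),
        )
        if effects and id(call) in effects:
            ann = effects[id(call)]
            info["REGION"] = ann.region
            info["EFFECT"] = ann.effect
            if ann.ref_codon:
                info["CODON"] = f"{ann.ref_codon}>{ann.alt_codon}"
        records.append((call.scaffold, start0, alleles, info))

    records.sort(key=lambda r: (r[0], r[1]))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for scaffold, start0, alleles, info in records:
            rec = vcf.new_record(contig=scaffold, start=start0, alleles=alleles)
            for key, value in info.items():
                rec.info[key] = value
            vcf.write(rec)
    return len(records)


def write_effects_tsv(annotations: Iterable[EffectAnnotation], path: str | Path) -> int:
    n = 0
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([
            "contig_id", "contig_col", "kind", "scaffold", "genome_pos",
            "region", "gene_id", "codon_index", "codon_position",
            "ref_codon", "alt_codon", "ref_aa", "alt_aa", "effect", "multi_gene",
        ])
        for ann in annotations:
            call = ann.call
            writer.writerow([
                call.contig_id if call else "", call.contig_col if call else "",
                call.kind if call else "", call.scaffold if call else "",
                call.genome_pos if call else "",
                ann.region, ann.gene_id or "",
                ann.codon_index if ann.codon_index is not None else "",
                ann.codon_position if ann.codon_position is not None else "",
                ann.ref_codon or "", ann.alt_codon or "",
                ann.ref_aa or "", ann.alt_aa or "", ann.effect,
                int(ann.multi_gene),
            ])
            n += 1
    return n
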