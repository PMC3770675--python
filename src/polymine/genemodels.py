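"""Gene models (exon/CDS/UTR geometry) loaded from GFF3, plus the
coordinate arithmetic between transcript space, CDS space and genome space.

All genomic intervals are 1-based inclusive (GFF3/VCF convention);
transcript and CDS offsets are 0-based.  Minus-strand genes read their
transcript from the highest genomic coordinate downward.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import gffutils

from .alignment import revcomp

Interval = tuple[int, int]  # 1-based inclusive


def _fetch(genome, scaffold: str, start: int, end: int) -> str:
    """Plus-strand slice [start, end] (1-based inclusive) from a pyfaidx
    Fasta or a plain mapping of scaffold -> sequence string."""
    seq = genome[scaffold]
    piece = seq[start - 1 : end]
    return str(piece).upper()


@dataclass
class GeneModel:
    """One protein-coding gene model on a scaffold."""

    gene_id: str
    transcript_id: str
    scaffold: str
    strand: str  # "+" | "-"
    exons: list[Interval]
    cds_segments: list[Interval]
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        for name in ("exons", "cds_segments", "utr5", "utr3"):
            ivs = sorted(getattr(self, name))
            setattr(self, name, ivs)
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"{self.gene_id}: overlapping {name} intervals")

    @property
    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    # ---- sequence extraction -------------------------------------------

    def spliced(self, genome, which: str = "exons") -> str:
        """Spliced sequence in transcription (coding) orientation."""
        parts = [
            _fetch(genome, self.scaffold, s, e) for s, e in getattr(self, which)
        ]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq

    def transcript_seq(self, genome) -> str:
        return self.spliced(genome, "exons")

    def cds_seq(self, genome) -> str:
        return self.spliced(genome, "cds_segments")

    # ---- coordinate maps -----------------------------------------------

    def _offset_to_pos(self, offset: int, intervals: list[Interval]) -> int:
        """Map a 0-based offset along the spliced (coding-orientation)
        concatenation of ``intervals`` to a 1-based genome position."""
        total = sum(e - s + 1 for s, e in intervals)
        if not 0 <= offset < total:
            raise IndexError(f"offset {offset} outside spliced length {total}")
        walk = intervals if self.strand == "+" else intervals[::-1]
        for s, e in walk:
            length = e - s + 1
            if offset < length:
                return s + offset if self.strand == "+" else e - offset
            offset -= length
        raise AssertionError("unreachable")

    def _pos_to_offset(self, pos: int, intervals: list[Interval]) -> int | None:
        """Inverse of :meth:`_offset_to_pos`; None when pos not in intervals."""
        offset = 0
        walk = intervals if self.strand == "+" else intervals[::-1]
        for s, e in walk:
            if s <= pos <= e:
                return offset + (pos - s if self.strand == "+" else e - pos)
            offset += e - s + 1
        return None

    def transcript_offset_to_genome(self, offset: int) -> int:
        return self._offset_to_pos(offset, self.exons)

    def genome_to_transcript_offset(self, pos: int) -> int | None:
        return self._pos_to_offset(pos, self.exons)

    def cds_offset_of(self, pos: int) -> int | None:
        """0-based offset of a genome position within the spliced CDS."""
        return self._pos_to_offset(pos, self.cds_segments)

    # ---- region classification -----------------------------------------

    def region_of(self, pos: int) -> str:
        """CDS / UTR5 / UTR3 / intron / intergenic for a genome position."""
        lo, hi = self.span
        if not lo <= pos <= hi:
            return "intergenic"
        for s, e in self.cds_segments:
            if s <= pos <= e:
                return "CDS"
        for s, e in self.utr5:
            if s <= pos <= e:
                return "UTR5"
        for s, e in self.utr3:
            if s <= pos <= e:
                return "UTR3"
        for s, e in self.exons:
            if s <= pos <= e:
                # exonic but not covered by explicit CDS/UTR records:
                # derive the UTR side from position relative to the CDS
                return self._derived_utr(pos)
        return "intron"

    def _derived_utr(self, pos: int) -> str:
        cds_lo = self.cds_segments[0][0]
        cds_hi = self.cds_segments[-1][1]
        upstream = pos < cds_lo
        if self.strand == "-":
            upstream = pos > cds_hi
        return "UTR5" if upstream else "UTR3"


class GeneModelSet:
    """Gene models indexed by scaffold for point queries."""

    def __init__(self, models: list[GeneModel]):
        self.models = {m.gene_id: m for m in models}
        self._by_transcript = {m.transcript_id: m for m in models}
        self._by_scaffold: dict[str, list[GeneModel]] = {}
        for m in models:
            self._by_scaffold.setdefault(m.scaffold, []).append(m)
        for ms in self._by_scaffold.values():
            ms.sort(key=lambda m: m.span)

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.models[gene_id]

    def by_transcript(self, transcript_id: str) -> GeneModel | None:
        return self._by_transcript.get(transcript_id)

    def overlapping(self, scaffold: str, pos: int) -> list[GeneModel]:
        return [
            m
            for m in self._by_scaffold.get(scaffold, [])
            if m.span[0] <= pos <= m.span[1]
        ]


def load_gene_models(gff3_path: str | Path) -> GeneModelSet:
    """Load protein-coding gene models from GFF3 (via gffutils, in-memory).

    UTR intervals come from explicit five_prime_UTR/three_prime_UTR
    features when present, otherwise they are derived later from exon/CDS
    geometry during region classification.  GFF3 phase is trusted as
    written; CDS frame is recomputed only when the column is absent.
    """
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        utr5 = [(f.start, f.end) for f in db.children(mrna, featuretype="five_prime_UTR")]
        utr3 = [(f.start, f.end) for f in db.children(mrna, featuretype="three_prime_UTR")]
        if not cds:
            continue
        if not exons:
            exons = sorted(cds + utr5 + utr3)
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                scaffold=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_segments=cds,
                utr5=utr5,
                utr3=utr3,
            )
        )
    return GeneModelSet(models)
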