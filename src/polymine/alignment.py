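"""Data model and I/O for multi-variety contig alignments.

A contig alignment is the discovery substrate for EST-based polymorphism
mining: a gap-padded multiple alignment of reads, each tagged with the
cassava variety (or library) it came from, optionally containing one
*reference member* — an annotated transcript predicted from the draft
genome — used later to anchor alignment columns to genome coordinates.

Internal conventions: columns are 0-based half-open; the alignment alphabet
is ``{A, C, G, T, N, -}`` (ACE pads ``*`` and lowercase input are
normalized on read); read sequences are stored in *contig orientation*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Sequencing import Ace

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN-")
UNKNOWN_VARIETY = "unknown"

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def revcomp(seq: str) -> str:
    """Reverse complement over the alignment alphabet (gaps map to gaps)."""
    return seq.translate(_COMPLEMENT)[::-1]


class AceParseError(ValueError):
    """Raised on a structurally invalid ACE file."""


@dataclass
class SequenceRead:
    """One read placed in a contig alignment.

    ``aligned_seq`` is gap-padded and already in contig orientation;
    ``orientation`` records how the assembler placed the read ("+" as-is,
    "-" reverse-complemented).  ``contig_offset`` is the 0-based alignment
    column of the read's first base.
    """

    read_id: str
    aligned_seq: str
    contig_offset: int = 0
    variety: str = UNKNOWN_VARIETY
    orientation: str = "+"

    def __post_init__(self) -> None:
        self.aligned_seq = self.aligned_seq.upper().replace("*", "-")
        bad = set(self.aligned_seq) - ALPHABET
        if bad:
            raise ValueError(
                f"read {self.read_id!r}: illegal symbols {sorted(bad)} in aligned sequence"
            )
        if self.contig_offset < 0:
            raise ValueError(f"read {self.read_id!r}: negative contig offset")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"read {self.read_id!r}: orientation must be '+' or '-'")

    @property
    def end(self) -> int:
        """One past the last alignment column covered by this read."""
        return self.contig_offset + len(self.aligned_seq)

    def spans(self, col: int) -> bool:
        return self.contig_offset <= col < self.end

    def symbol_at(self, col: int) -> str:
        """Symbol at alignment column ``col`` (read must span it)."""
        return self.aligned_seq[col - self.contig_offset]

    def ungapped(self) -> str:
        return self.aligned_seq.replace("-", "")


@dataclass
class ContigAlignment:
    """A padded multiple alignment of ≥2 reads (singlets carry no signal)."""

    contig_id: str
    n_columns: int
    reads: list[SequenceRead] = field(default_factory=list)
    reference_member: str | None = None

    def __post_init__(self) -> None:
        for read in self.reads:
            if read.end > self.n_columns:
                raise ValueError(
                    f"read {read.read_id!r} extends past column {self.n_columns} "
                    f"of contig {self.contig_id!r}"
                )

    def __len__(self) -> int:
        return self.n_columns

    @property
    def reference_read(self) -> SequenceRead | None:
        if self.reference_member is None:
            return None
        for read in self.reads:
            if read.read_id == self.reference_member:
                return read
        return None

    def contributing(self, col: int) -> list[SequenceRead]:
        """Reads whose span covers alignment column ``col``."""
        if not 0 <= col < self.n_columns:
            raise IndexError(
                f"column {col} out of range for contig {self.contig_id!r} "
                f"({self.n_columns} columns)"
            )
        return [r for r in self.reads if r.spans(col)]

    def column_profile(self, col: int) -> dict[str, list[str]]:
        """Observed symbols at ``col``, grouped by variety.

        Only reads spanning the column contribute; varieties with no
        spanning read are absent from the mapping.  Symbols are reported in
        contig orientation.
        """
        profile: dict[str, list[str]] = {}
        for read in self.contributing(col):
            profile.setdefault(read.variety, []).append(read.symbol_at(col))
        return profile


class VarietyMap(dict):
    """read_id -> variety label; externalizes the per-variety read grouping."""

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VarietyMap":
        mapping = cls()
        with open(path) as handle:
            header = handle.readline().rstrip("\n").split("\t")
            if header[:2] != ["read_id", "variety"]:
                raise ValueError(
                    f"{path}: expected header 'read_id<TAB>variety', got {header!r}"
                )
            for lineno, line in enumerate(handle, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 2 or not fields[1]:
                    raise ValueError(f"{path}:{lineno}: malformed variety-map row")
                read_id, variety = fields[0], fields[1]
                if read_id in mapping:
                    raise ValueError(f"{path}:{lineno}: duplicate read_id {read_id!r}")
                mapping[read_id] = variety
        return mapping

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write("read_id\tvariety\n")
            for read_id, variety in self.items():
                handle.write(f"{read_id}\t{variety}\n")

    def variety_of(self, read_id: str) -> str:
        variety = self.get(read_id)
        if variety is None:
            logger.warning("read %r has no variety assignment; using %r",
                           read_id, UNKNOWN_VARIETY)
            return UNKNOWN_VARIETY
        return variety


def read_ace(
    path: str | Path, variety_map: Mapping[str, str] | None = None
) -> list[ContigAlignment]:
    """Parse an assembler ACE file into contig alignments.

    Pads (``*``) are normalized to ``-``; reads flagged "C" in their AF
    record are stored reverse-complemented, so every alignment column
    addresses the same position in every read.  Varieties are attached from
    ``variety_map`` when given.
    """
    path = Path(path)
    try:
        with open(path) as handle:
            record = Ace.read(handle)
    except (ValueError, IndexError) as exc:
        raise AceParseError(f"{path}: malformed ACE file: {exc}") from exc

    contigs: list[ContigAlignment] = []
    for co in record.contigs:
        placements = {af.name: af for af in co.af}
        reads: list[SequenceRead] = []
        for rd in co.reads:
            af = placements.get(rd.rd.name)
            if af is None:
                raise AceParseError(
                    f"{path}: contig {co.name!r}: RD {rd.rd.name!r} has no AF placement"
                )
            seq = rd.rd.sequence.upper().replace("*", "-")
            reverse = af.coru == "C"
            if reverse:
                seq = revcomp(seq)
            variety = UNKNOWN_VARIETY
            if variety_map is not None:
                variety = variety_map.get(rd.rd.name, UNKNOWN_VARIETY)
                if rd.rd.name not in variety_map:
                    logger.warning("read %r absent from variety map", rd.rd.name)
            reads.append(
                SequenceRead(
                    read_id=rd.rd.name,
                    aligned_seq=seq,
                    contig_offset=af.padded_start - 1,
                    variety=variety,
                    orientation="-" if reverse else "+",
                )
            )
        missing = set(placements) - {r.read_id for r in reads}
        if missing:
            raise AceParseError(
                f"{path}: contig {co.name!r}: AF reads without RD records: {sorted(missing)}"
            )
        contigs.append(
            ContigAlignment(
                contig_id=co.name,
                n_columns=len(co.sequence),
                reads=reads,
            )
        )
    return contigs


def write_ace(
    alignments: ContigAlignment | Iterable[ContigAlignment], path: str | Path
) -> None:
    """Serialize contig alignments as an ACE file parseable by :func:`read_ace`.

    The consensus written to CO is the per-column majority symbol; pads are
    rendered as ``*``; "-"-oriented reads are written back in read
    orientation with an AF "C" flag.
    """
    if isinstance(alignments, ContigAlignment):
        alignments = [alignments]
    alignments = list(alignments)
    n_reads = sum(len(a.reads) for a in alignments)
    lines: list[str] = [f"AS {len(alignments)} {n_reads}", ""]
    for contig in alignments:
        if any(not r.aligned_seq for r in contig.reads):
            raise ValueError(f"contig {contig.contig_id!r}: empty read sequence")
        consensus = _consensus(contig)
        lines.append(
            f"CO {contig.contig_id} {contig.n_columns} {len(contig.reads)} 1 U"
        )
        lines.extend(_wrap(consensus.replace("-", "*")))
        lines.append("")
        lines.append("BQ")
        lines.append("")
        for read in contig.reads:
            flag = "C" if read.orientation == "-" else "U"
            lines.append(f"AF {read.read_id} {flag} {read.contig_offset + 1}")
        lines.append("")
        for read in contig.reads:
            seq = read.aligned_seq
            if read.orientation == "-":
                seq = revcomp(seq)
            lines.append(f"RD {read.read_id} {len(seq)} 0 0")
            lines.extend(_wrap(seq.replace("-", "*")))
            lines.append("")
            lines.append(f"QA 1 {len(seq)} 1 {len(seq)}")
            lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def _consensus(contig: ContigAlignment) -> str:
    out = []
    for col in range(contig.n_columns):
        tally: dict[str, int] = {}
        for read in contig.reads:
            if read.spans(col):
                sym = read.symbol_at(col)
                tally[sym] = tally.get(sym, 0) + 1
        if not tally:
            out.append("N")
        else:
            # deterministic majority: count desc, then alphabet order
            out.append(min(tally, key=lambda s: (-tally[s], s)))
    return "".join(out)


def _wrap(seq: str, width: int = 50) -> list[str]:
    return [seq[i : i + width] for i in range(0, len(seq), width)] or [""]


def read_aligned_fasta(
    path: str | Path,
    variety_map: Mapping[str, str] | None = None,
    contig_id: str | None = None,
    reference_member: str | None = None,
) -> ContigAlignment:
    """Read a gap-padded aligned FASTA as a single contig alignment.

    All sequences must be equal length; every read sits at offset 0.  This
    is the assembler-independent input path.
    """
    from Bio import SeqIO

    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no sequences")
    lengths = {len(rec.seq) for rec in records}
    if len(lengths) > 1:
        offenders = sorted(
            rec.id for rec in records if len(rec.seq) != len(records[0].seq)
        )
        raise ValueError(
            f"{path}: aligned FASTA sequences differ in length (e.g. {offenders})"
        )
    n_columns = lengths.pop()
    reads = []
    for rec in records:
        variety = UNKNOWN_VARIETY
        if variety_map is not None:
            if rec.id in variety_map:
                variety = variety_map[rec.id]
            else:
                logger.warning("read %r absent from variety map", rec.id)
        reads.append(SequenceRead(read_id=rec.id, aligned_seq=str(rec.seq), variety=variety))
    return ContigAlignment(
        contig_id=contig_id or path.stem,
        n_columns=n_columns,
        reads=reads,
        reference_member=reference_member,
    )


def column_profile(contig: ContigAlignment, col: int) -> dict[str, list[str]]:
    """Functional alias for :meth:`ContigAlignment.column_profile`."""
    return contig.column_profile(col)
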