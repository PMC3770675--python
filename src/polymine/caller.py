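"""SNP and InDel discovery from contig alignments.

A column (or gap run) becomes a call only if it survives the full filter
stack used for EST-derived alignments, where sequencing error, paralog
cross-contamination and low-quality stretches are the dominant artifacts:

(ii)  no contributing symbol is N;
(iii) exactly two allele types segregate (a third base type at the column
      is taken as evidence of cross-contamination between loci and kills
      the site);
(iv)  each allele is supported by at least ``min_support`` reads within a
      single variety — singleton observations are treated as sequencing
      errors;
(v)   every variety is internally monomorphic at the site (heterozygosity
      is not modelled; within-variety disagreement is treated as error);
(vi)  fewer than ``max_flank_polys`` *discontinuous* other polymorphic
      columns lie within ``window_halfwidth`` columns of the site (dense
      local polymorphism flags a low-quality alignment region).

Criterion (i) — the contig must anchor to the draft genome — is applied
after calling (see :mod:`polymine.annotate`), so the caller is testable
without a genome.

Reads labelled with the sentinel variety "unknown" contribute observations
(they can veto a site via (ii)/(iii)/(v)) but cannot by themselves satisfy
the per-variety support rule (iv).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .alignment import ContigAlignment, UNKNOWN_VARIETY

BASES = ("A", "C", "G", "T")
GAP = "-"

# numeric codes for the vectorized column scan
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
_OUT = 6  # column outside a read's span


@dataclass(frozen=True)
class CallerConfig:
    """Tunables of the discovery criteria (defaults follow the filter stack
    described above: support 2, ±5 bp window, <3 discontinuous flank
    polymorphisms, InDels of 1–3 bp)."""

    min_support: int = 2
    window_halfwidth: int = 5
    max_flank_polys: int = 3
    max_indel_len: int = 3
    require_genome_anchor: bool = True

    def __post_init__(self) -> None:
        for name in ("min_support", "window_halfwidth", "max_flank_polys", "max_indel_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PolymorphismCall:
    """One SNP or InDel with its per-variety allele evidence.

    ``alleles`` holds the two segregating forms: single bases for a SNP;
    for an InDel the spanned bases versus a ``-`` run of equal length.
    ``variety_alleles`` maps each observing variety to its (allele,
    supporting-read-count) pair.  Genome fields are filled by anchoring.
    """

    kind: str  # "SNP" | "InDel"
    contig_id: str
    contig_col: int
    alleles: tuple[str, str]
    variety_alleles: dict[str, tuple[str, int]] = field(default_factory=dict)
    scaffold: str | None = None
    genome_pos: int | None = None  # 1-based
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.alleles)) != 2:
            raise ValueError("a call must have exactly 2 distinct alleles")
        if self.kind == "SNP" and any(a in ("N", GAP) for a in self.alleles):
            raise ValueError("SNP alleles cannot be N or gap")

    @property
    def length(self) -> int:
        return max(len(a) for a in self.alleles)

    @property
    def anchored(self) -> bool:
        return self.scaffold is not None and self.genome_pos is not None


def _code_matrix(contig: ContigAlignment) -> np.ndarray:
    """(n_reads, n_columns) symbol-code matrix, _OUT outside read spans."""
    mat = np.full((len(contig.reads), contig.n_columns), _OUT, dtype=np.uint8)
    for i, read in enumerate(contig.reads):
        codes = [_CODE[s] for s in read.aligned_seq]
        mat[i, read.contig_offset : read.end] = codes
    return mat


def _polymorphic_mask(mat: np.ndarray) -> np.ndarray:
    """True for columns with ≥2 distinct symbol types (gaps and N count)."""
    present = np.stack([(mat == c).any(axis=0) for c in range(6)])
    return present.sum(axis=0) >= 2


def _cluster_count(mask: np.ndarray, col: int, halfwidth: int) -> int:
    """Discontinuous polymorphic clusters within ±halfwidth of ``col``.

    Runs of adjacent polymorphic columns collapse to a single cluster; the
    candidate column itself never counts.
    """
    lo = max(0, col - halfwidth)
    hi = min(len(mask), col + halfwidth + 1)
    clusters = 0
    in_run = False
    for c in range(lo, hi):
        if c == col:
            in_run = False
            continue
        if mask[c]:
            if not in_run:
                clusters += 1
            in_run = True
        else:
            in_run = False
    return clusters


def window_filter(contig: ContigAlignment, col: int, config: CallerConfig | None = None) -> bool:
    """Flanking-window check: True (pass) iff fewer than
    ``max_flank_polys`` discontinuous other polymorphic columns lie within
    ``window_halfwidth`` of ``col``."""
    config = config or CallerConfig()
    if not 0 <= col < contig.n_columns:
        raise IndexError(f"column {col} out of range")
    mask = _polymorphic_mask(_code_matrix(contig))
    return _cluster_count(mask, col, config.window_halfwidth) < config.max_flank_polys


def _allele_support(
    groups: Mapping[str, list[str]], allele: str, min_support: int
) -> bool:
    """Does some *known* variety carry ``allele`` in ≥ min_support reads?"""
    for variety, symbols in groups.items():
        if variety == UNKNOWN_VARIETY:
            continue
        if symbols and symbols[0] == allele and len(symbols) >= min_support:
            return True
    return False


def call_snps(contig: ContigAlignment, config: CallerConfig | None = None) -> list[PolymorphismCall]:
    """Apply criteria (ii)–(vi) column by column and emit SNP calls."""
    config = config or CallerConfig()
    if len(contig.reads) < 2:
        return []
    mat = _code_matrix(contig)
    mask = _polymorphic_mask(mat)

    # candidate pruning: a SNP column has no gap, no N, exactly 2 base types
    has_gap = (mat == _CODE[GAP]).any(axis=0)
    has_n = (mat == _CODE["N"]).any(axis=0)
    base_types = np.stack([(mat == _CODE[b]).any(axis=0) for b in BASES]).sum(axis=0)
    candidates = np.flatnonzero(~has_gap & ~has_n & (base_types == 2))

    calls: list[PolymorphismCall] = []
    for col in candidates:
        col = int(col)
        profile = contig.column_profile(col)
        # (v) every variety internally monomorphic
        if any(len(set(sym)) > 1 for sym in profile.values()):
            continue
        observed = sorted({sym[0] for sym in profile.values()})
        if len(observed) != 2:
            continue  # the 2 base types are not fixed between varieties
        # (iv) each allele backed by >=min_support reads in some variety
        if not all(_allele_support(profile, a, config.min_support) for a in observed):
            continue
        # (vi) flanking window
        if _cluster_count(mask, col, config.window_halfwidth) >= config.max_flank_polys:
            continue
        calls.append(
            PolymorphismCall(
                kind="SNP",
                contig_id=contig.contig_id,
                contig_col=col,
                alleles=(observed[0], observed[1]),
                variety_alleles={
                    v: (sym[0], len(sym)) for v, sym in sorted(profile.items())
                },
            )
        )
    return calls


def _gap_runs(mat: np.ndarray, max_len: int) -> list[tuple[int, int]]:
    """Maximal runs of columns where gap and base symbols co-occur.

    Returns (start, end) inclusive; runs longer than ``max_len`` are
    still returned (the caller rejects them) so that run maximality is
    preserved.
    """
    has_gap = (mat == _CODE[GAP]).any(axis=0)
    has_base = np.stack([(mat == _CODE[b]).any(axis=0) for b in BASES]).any(axis=0)
    seg = has_gap & has_base
    runs: list[tuple[int, int]] = []
    start = None
    for c, flag in enumerate(seg):
        if flag and start is None:
            start = c
        elif not flag and start is not None:
            runs.append((start, c - 1))
            start = None
    if start is not None:
        runs.append((start, len(seg) - 1))
    return runs


def call_indels(contig: ContigAlignment, config: CallerConfig | None = None) -> list[PolymorphismCall]:
    """Find short (≤ ``max_indel_len``) InDels segregating between varieties.

    A maximal gap run is called when every read spanning it is internally
    consistent (all-gap or all-base), based reads agree on the spanned
    bases, no N contributes, each allele has per-variety support, and every
    variety is monomorphic across the run.
    """
    config = config or CallerConfig()
    if len(contig.reads) < 2:
        return []
    mat = _code_matrix(contig)
    calls: list[PolymorphismCall] = []
    for start, end in _gap_runs(mat, config.max_indel_len):
        length = end - start + 1
        if length > config.max_indel_len:
            continue
        by_variety: dict[str, list[str]] = {}
        base_forms: set[str] = set()
        ok = True
        for read in contig.reads:
            if not (read.contig_offset <= start and end < read.end):
                continue  # only reads spanning the whole run contribute
            segment = read.aligned_seq[start - read.contig_offset : end - read.contig_offset + 1]
            if "N" in segment:
                ok = False
                break
            if GAP in segment:
                if set(segment) != {GAP}:
                    ok = False  # read partially gapped across the run
                    break
                allele = GAP * length
            else:
                allele = segment
                base_forms.add(segment)
            by_variety.setdefault(read.variety, []).append(allele)
        if not ok or len(base_forms) != 1 or not by_variety:
            continue
        if any(len(set(alleles)) > 1 for alleles in by_variety.values()):
            continue  # variety not monomorphic across the run
        gap_allele = GAP * length
        base_allele = base_forms.pop()
        observed = {a for alleles in by_variety.values() for a in alleles}
        if observed != {gap_allele, base_allele}:
            continue  # both forms must actually segregate
        if not (
            _allele_support(by_variety, gap_allele, config.min_support)
            and _allele_support(by_variety, base_allele, config.min_support)
        ):
            continue
        calls.append(
            PolymorphismCall(
                kind="InDel",
                contig_id=contig.contig_id,
                contig_col=start,
                alleles=(base_allele, gap_allele),
                variety_alleles={
                    v: (alleles[0], len(alleles)) for v, alleles in sorted(by_variety.items())
                },
            )
        )
    return calls


def call_polymorphisms(
    contig: ContigAlignment, config: CallerConfig | None = None
) -> list[PolymorphismCall]:
    """SNPs and InDels for one contig, in column order."""
    calls = call_snps(contig, config) + call_indels(contig, config)
    return sorted(calls, key=lambda c: (c.contig_col, c.kind))


# ---------------------------------------------------------------------------
# summaries


def per_unit_average(total: float, units: int, ndigits: int = 1) -> float | None:
    """Report-style average (e.g. polymorphisms per gene), rounded."""
    if units == 0:
        return None
    return round(total / units, ndigits)


@dataclass
class CallSummary:
    n_snp: int
    n_indel: int
    n_genes_snp: int
    n_genes_indel: int
    n_genes_total: int
    snps_per_gene: float | None
    indels_per_gene: float | None
    polymorphisms_per_gene: float | None
    snp_interval_bp: float | None = None
    indel_interval_bp: float | None = None


def summarize_calls(
    calls: Iterable[PolymorphismCall],
    gene_of=None,
    total_bases: int | None = None,
) -> CallSummary:
    """Tabulate call counts, genes hit, per-gene averages and (optionally)
    mean polymorphism interval = total transcribed bases / n calls.

    ``gene_of`` maps a call to its gene id (callable, or None to use the
    call's own ``gene_id`` field); unassigned calls count toward totals but
    not toward gene averages.
    """
    calls = list(calls)
    if gene_of is None:
        gene_of = lambda call: call.gene_id  # noqa: E731
    snp_genes, indel_genes = set(), set()
    n_snp = n_indel = 0
    for call in calls:
        gene = gene_of(call)
        if call.kind == "SNP":
            n_snp += 1
            if gene is not None:
                snp_genes.add(gene)
        else:
            n_indel += 1
            if gene is not None:
                indel_genes.add(gene)
    summary = CallSummary(
        n_snp=n_snp,
        n_indel=n_indel,
        n_genes_snp=len(snp_genes),
        n_genes_indel=len(indel_genes),
        n_genes_total=len(snp_genes | indel_genes),
        snps_per_gene=per_unit_average(n_snp, len(snp_genes)),
        indels_per_gene=per_unit_average(n_indel, len(indel_genes)),
        polymorphisms_per_gene=per_unit_average(n_snp + n_indel, len(snp_genes | indel_genes)),
    )
    if total_bases is not None:
        summary.snp_interval_bp = per_unit_average(total_bases, n_snp)
        summary.indel_interval_bp = per_unit_average(total_bases, n_indel)
    return summary
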