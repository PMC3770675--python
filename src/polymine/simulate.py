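"""Seeded synthetic fixtures: toy genomes, gene models and multi-variety
EST read sets with planted polymorphisms.

The generator emulates the discovery substrate of an EST-mining study: a
draft genome with annotated protein-coding gene models (proper start/stop
codons, UTRs on both sides, introns, mixed strands), one annotated
transcript per gene acting as the contig's reference member, and per-
variety transcript reads carrying planted SNPs and short deletions
(1–3 bp, weighted like the observed 612:42:20 length distribution).
Sequencing errors and N bases are injected as within-variety singletons,
which is exactly the artifact class the per-variety support criterion is
meant to reject.

Every planted event is recorded in a plant log together with a
*detectability* flag: whether the event satisfies the discovery criteria
given the simulated coverage (≥2 carrier reads in one variety, ≥2
reference reads in a non-carrier variety, two alleles only).  Running the
caller on an error-free simulation must recover exactly the detectable
subset — that is the ground-truth contract the recovery tests check.

All randomness flows from ``SimConfig.seed`` via one generator, so every
output is a pure function of the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignment import ContigAlignment, SequenceRead, VarietyMap, revcomp, write_ace
from .annotate import ContigAnchor
from .caller import PolymorphismCall
from .genemodels import GeneModel, GeneModelSet

__all__ = [
    "SimConfig", "PlantedEvent", "PlantLog", "Simulation",
    "generate_genome", "simulate_reads", "simulate", "evaluate_recovery",
    "write_genome_fasta", "write_gff3", "write_ace",
]

BASES = "ACGT"
STOPS = ("TAA", "TAG", "TGA")
REFERENCE_VARIETY = "AM560-2"

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the synthetic cohort.

    ``varieties`` maps variety name to read depth per gene; the reference
    variety contributes exactly one annotated-transcript read per contig on
    top of these.  Event counts are per gene.  ``indel_length_weights``
    gives the relative frequency of 1/2/3-bp deletions.
    """

    n_scaffolds: int = 2
    genes_per_scaffold: int = 3
    exons_per_gene: int = 2
    varieties: tuple[tuple[str, int], ...] = (
        ("CM523-7", 3), ("MCol22", 3), ("KU50", 3), ("MBra685", 3),
        ("MPer183", 3), ("SG107-35", 3), ("Mirassol", 1), ("unknown", 2),
    )
    n_snps_per_gene: int = 3
    n_lowdepth_snps_per_gene: int = 1
    n_contaminated_per_gene: int = 1
    n_indels_per_gene: int = 1
    indel_length_weights: tuple[float, float, float] = (612.0, 42.0, 20.0)
    error_rate: float = 0.0
    n_rate: float = 0.0
    min_event_spacing: int = 13
    reverse_contig_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scaffolds < 1 or self.genes_per_scaffold < 1:
            raise ValueError("need at least one scaffold and one gene")
        if any(depth < 0 for _, depth in self.varieties):
            raise ValueError("depths must be non-negative")

    @property
    def known_varieties(self) -> list[str]:
        return [v for v, _ in self.varieties if v != "unknown"]

    def depth(self, variety: str) -> int:
        return dict(self.varieties)[variety]


@dataclass
class PlantedEvent:
    """One planted polymorphism with its plus-strand ground truth."""

    event_id: str
    contig_id: str
    scaffold: str
    genome_pos: int  # 1-based; for deletions, smallest deleted position
    kind: str  # "SNP" | "InDel"
    ref_allele: str  # plus-strand
    alt_allele: str  # plus-strand ("-"*len for a deletion)
    transcript_offset: int
    length: int
    carriers: tuple[str, ...]
    detectable: bool
    note: str = ""

    @property
    def key(self):
        if self.kind == "SNP":
            return (self.scaffold, self.genome_pos, "SNP",
                    frozenset((self.ref_allele, self.alt_allele)))
        return (self.scaffold, self.genome_pos, "InDel", self.length)


class PlantLog(list):
    """List of :class:`PlantedEvent` with TSV round-trip."""

    COLUMNS = [
        "event_id", "contig_id", "scaffold", "genome_pos", "kind",
        "ref_allele", "alt_allele", "transcript_offset", "length",
        "carriers", "detectable", "note",
    ]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(self.COLUMNS) + "\n")
            for ev in self:
                fh.write("\t".join([
                    ev.event_id, ev.contig_id, ev.scaffold, str(ev.genome_pos),
                    ev.kind, ev.ref_allele, ev.alt_allele,
                    str(ev.transcript_offset), str(ev.length),
                    ",".join(ev.carriers), str(int(ev.detectable)), ev.note,
                ]) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PlantLog":
        log = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                log.append(PlantedEvent(
                    event_id=row["event_id"], contig_id=row["contig_id"],
                    scaffold=row["scaffold"], genome_pos=int(row["genome_pos"]),
                    kind=row["kind"], ref_allele=row["ref_allele"],
                    alt_allele=row["alt_allele"],
                    transcript_offset=int(row["transcript_offset"]),
                    length=int(row["length"]),
                    carriers=tuple(c for c in row["carriers"].split(",") if c),
                    detectable=bool(int(row["detectable"])), note=row["note"],
                ))
        return log


# ---------------------------------------------------------------------------
# genome generation


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + internal non-stop codons + one stop codon."""
    internal = []
    while len(internal) < n_codons - 2:
        codon = _random_seq(rng, 3)
        if codon not in STOPS:
            internal.append(codon)
    stop = STOPS[rng.integers(0, len(STOPS))]
    return "ATG" + "".join(internal) + stop


def _runs(positions: Sequence[int]) -> list[tuple[int, int]]:
    """Merge sorted 1-based positions into inclusive intervals."""
    runs: list[tuple[int, int]] = []
    for p in sorted(positions):
        if runs and p == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], p)
        else:
            runs.append((p, p))
    return runs


def generate_genome(config: SimConfig) -> tuple[dict[str, str], GeneModelSet]:
    """Deterministic toy genome: scaffold sequences + gene models.

    Every gene has a CDS divisible by 3 starting with ATG and ending in a
    stop codon, UTRs on both sides, ``exons_per_gene`` exons with canonical
    GT..AG introns, and strands alternate so any multi-gene simulation
    carries at least one minus-strand model.
    """
    rng = np.random.default_rng(config.seed)
    scaffolds: dict[str, str] = {}
    models: list[GeneModel] = []
    gene_counter = 0
    for s in range(config.n_scaffolds):
        scaffold_id = f"scaffold_{s + 1}"
        parts: list[str] = [_random_seq(rng, int(rng.integers(150, 300)))]
        offset = len(parts[0])
        for g in range(config.genes_per_scaffold):
            gene_counter += 1
            gene_id = f"gene_{gene_counter:03d}"
            strand = "+" if gene_counter % 2 == 1 else "-"
            utr5_len = int(rng.integers(50, 91))
            utr3_len = int(rng.integers(50, 91))
            n_codons = int(rng.integers(80, 141))
            cds = _random_cds(rng, n_codons)
            transcript = _random_seq(rng, utr5_len) + cds + _random_seq(rng, utr3_len)
            T = len(transcript)

            # split the transcript into exons, insert canonical introns
            n_exons = max(1, config.exons_per_gene)
            cuts = sorted(rng.choice(np.arange(20, T - 20), size=n_exons - 1,
                                     replace=False)) if n_exons > 1 else []
            bounds = [0, *map(int, cuts), T]
            coding_parts: list[tuple[str, str]] = []  # (kind, seq)
            for i in range(n_exons):
                coding_parts.append(("exon", transcript[bounds[i]:bounds[i + 1]]))
                if i < n_exons - 1:
                    intron = "GT" + _random_seq(rng, int(rng.integers(56, 117))) + "AG"
                    coding_parts.append(("intron", intron))
            gene_coding = "".join(seq for _, seq in coding_parts)
            L = len(gene_coding)

            # transcript offset -> 0-based offset within the coding-strand
            # gene sequence
            t2g: list[int] = []
            cursor = 0
            for kind, seq in coding_parts:
                if kind == "exon":
                    t2g.extend(range(cursor, cursor + len(seq)))
                cursor += len(seq)

            gene_start = offset  # 0-based on the scaffold
            segment = gene_coding if strand == "+" else revcomp(gene_coding)
            parts.append(segment)
            spacer = _random_seq(rng, int(rng.integers(200, 400)))
            parts.append(spacer)
            offset += len(segment) + len(spacer)

            def genome_pos(t_off: int) -> int:
                g_off = t2g[t_off]
                if strand == "+":
                    return gene_start + g_off + 1
                return gene_start + L - g_off

            exon_pos = [genome_pos(t) for t in range(T)]
            utr5_pos = [genome_pos(t) for t in range(utr5_len)]
            cds_pos = [genome_pos(t) for t in range(utr5_len, utr5_len + len(cds))]
            utr3_pos = [genome_pos(t) for t in range(utr5_len + len(cds), T)]
            models.append(GeneModel(
                gene_id=gene_id,
                transcript_id=f"mRNA_{gene_counter:03d}",
                scaffold=scaffold_id,
                strand=strand,
                exons=_runs(exon_pos),
                cds_segments=_runs(cds_pos),
                utr5=_runs(utr5_pos),
                utr3=_runs(utr3_pos),
            ))
        scaffolds[scaffold_id] = "".join(parts)
    return scaffolds, GeneModelSet(models)


def write_genome_fasta(scaffolds: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in scaffolds.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_gff3(models: GeneModelSet, path: str | Path) -> None:
    """GFF3 with gene/mRNA/exon/CDS/UTR features; CDS phase computed in
    transcription order."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo, hi = m.span
            base = f"{m.scaffold}\tpolymine\t"
            tail = f"\t.\t{m.strand}\t"
            fh.write(f"{base}gene\t{lo}\t{hi}{tail}.\tID={m.gene_id}\n")
            fh.write(f"{base}mRNA\t{lo}\t{hi}{tail}.\tID={m.transcript_id};Parent={m.gene_id}\n")
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(f"{base}exon\t{s}\t{e}{tail}.\t"
                         f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}\n")
            cds_walk = m.cds_segments if m.strand == "+" else m.cds_segments[::-1]
            cum = 0
            phases = {}
            for s, e in cds_walk:
                phases[(s, e)] = (3 - cum % 3) % 3
                cum += e - s + 1
            for i, (s, e) in enumerate(m.cds_segments, 1):
                fh.write(f"{base}CDS\t{s}\t{e}{tail}{phases[(s, e)]}\t"
                         f"ID={m.transcript_id}.cds{i};Parent={m.transcript_id}\n")
            for kind, ivs in (("five_prime_UTR", m.utr5), ("three_prime_UTR", m.utr3)):
                for i, (s, e) in enumerate(ivs, 1):
                    fh.write(f"{base}{kind}\t{s}\t{e}{tail}.\t"
                             f"ID={m.transcript_id}.{kind}{i};Parent={m.transcript_id}\n")


# ---------------------------------------------------------------------------
# read simulation with planted events


@dataclass
class Simulation:
    config: SimConfig
    scaffolds: dict[str, str]
    models: GeneModelSet
    contigs: list[ContigAlignment]
    variety_map: VarietyMap
    plant_log: PlantLog


def _pick_positions(rng, n: int, transcript_len: int, spacing: int) -> list[int]:
    """n positions ≥ spacing apart, away from transcript edges."""
    chosen: list[int] = []
    candidates = np.arange(8, transcript_len - 8)
    rng.shuffle(candidates)
    for pos in candidates:
        if all(abs(int(pos) - c) >= spacing for c in chosen):
            chosen.append(int(pos))
            if len(chosen) == n:
                break
    if len(chosen) < n:
        raise ValueError("transcript too short for requested event count")
    return chosen


def simulate_reads(
    scaffolds: Mapping[str, str],
    models: GeneModelSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ContigAlignment], VarietyMap, PlantLog]:
    """Per-gene contig alignments with planted events, plus ground truth.

    One contig per gene: the reference-member transcript (variety
    AM560-2), then ``depth`` full-length transcript copies per variety.
    Deletion carriers show a gap run; errors/N are singleton substitutions
    per variety.  A random fraction of contigs is stored reverse-
    complemented relative to the transcript, exercising orientation
    handling downstream.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    contigs: list[ContigAlignment] = []
    variety_map = VarietyMap()
    plant_log = PlantLog()
    deep_varieties = [v for v in config.known_varieties
                      if v != REFERENCE_VARIETY and config.depth(v) >= 2]
    shallow_varieties = [v for v in config.known_varieties
                         if v != REFERENCE_VARIETY and config.depth(v) == 1]
    event_counter = 0

    for model in models:
        transcript = model.transcript_seq(scaffolds)
        T = len(transcript)
        contig_id = f"contig_{model.gene_id.split('_')[-1]}"
        n_events = (config.n_snps_per_gene + config.n_lowdepth_snps_per_gene
                    + config.n_contaminated_per_gene + config.n_indels_per_gene)
        positions = _pick_positions(rng, n_events, T, config.min_event_spacing)
        pos_iter = iter(positions)

        # per-variety alternative haplotypes, as transcript edits
        edits: dict[str, dict[int, str]] = {v: {} for v, _ in config.varieties}
        events: list[PlantedEvent] = []

        def plus_strand(allele: str) -> str:
            if model.strand == "+":
                return allele
            return "".join(_COMP[b] for b in reversed(allele))

        def new_event(kind, t, ref, alt, length, carriers, detectable, note=""):
            nonlocal event_counter
            event_counter += 1
            gpos = min(model.transcript_offset_to_genome(t + i) for i in range(length))
            events.append(PlantedEvent(
                event_id=f"ev_{event_counter:04d}", contig_id=contig_id,
                scaffold=model.scaffold, genome_pos=gpos, kind=kind,
                ref_allele=plus_strand(ref),
                alt_allele=alt if alt.startswith("-") else plus_strand(alt),
                transcript_offset=t, length=length,
                carriers=tuple(carriers), detectable=detectable, note=note,
            ))

        def alt_base(ref: str, exclude: str = "") -> str:
            choices = [b for b in BASES if b != ref and b not in exclude]
            return choices[rng.integers(0, len(choices))]

        for _ in range(config.n_snps_per_gene):
            t = next(pos_iter)
            ref = transcript[t]
            alt = alt_base(ref)
            n_carriers = int(rng.integers(1, len(deep_varieties)))
            carriers = list(rng.choice(deep_varieties, size=n_carriers, replace=False))
            for v in carriers:
                edits[v][t] = alt
            new_event("SNP", t, ref, alt, 1, carriers, detectable=True)

        for _ in range(config.n_lowdepth_snps_per_gene):
            if not shallow_varieties:
                break
            t = next(pos_iter)
            ref = transcript[t]
            alt = alt_base(ref)
            carrier = shallow_varieties[rng.integers(0, len(shallow_varieties))]
            edits[carrier][t] = alt
            new_event("SNP", t, ref, alt, 1, [carrier],
                      detectable=False, note="carrier_depth_1")

        for _ in range(config.n_contaminated_per_gene):
            t = next(pos_iter)
            ref = transcript[t]
            alt1 = alt_base(ref)
            alt2 = alt_base(ref, exclude=alt1)
            v1, v2 = rng.choice(deep_varieties, size=2, replace=False)
            edits[v1][t] = alt1
            edits[v2][t] = alt2
            new_event("SNP", t, ref, alt1, 1, [v1, v2],
                      detectable=False, note="three_alleles")

        for _ in range(config.n_indels_per_gene):
            t = next(pos_iter)
            weights = np.asarray(config.indel_length_weights, dtype=float)
            length = int(rng.choice([1, 2, 3], p=weights / weights.sum()))
            n_carriers = int(rng.integers(1, len(deep_varieties)))
            carriers = list(rng.choice(deep_varieties, size=n_carriers, replace=False))
            for v in carriers:
                for i in range(length):
                    edits[v][t + i] = "-"
            new_event("InDel", t, transcript[t : t + length], "-" * length,
                      length, carriers, detectable=True)

        # build reads
        flip = rng.random() < config.reverse_contig_fraction
        reads = [SequenceRead(
            read_id=model.transcript_id, aligned_seq=transcript,
            variety=REFERENCE_VARIETY, orientation="+",
        )]
        variety_map[model.transcript_id] = REFERENCE_VARIETY
        for variety, depth in config.varieties:
            hap = list(transcript)
            for t, sym in edits[variety].items():
                hap[t] = sym
            used_cols: set[int] = set()
            for i in range(depth):
                copy = hap[:]
                for col, sym in _singleton_noise(rng, T, config, used_cols, copy):
                    copy[col] = sym
                read_id = f"{contig_id}.{variety}.{i + 1}".replace(" ", "_")
                reads.append(SequenceRead(
                    read_id=read_id, aligned_seq="".join(copy),
                    variety=variety, orientation="+",
                ))
                variety_map[read_id] = variety
        if flip:
            for read in reads:
                read.aligned_seq = revcomp(read.aligned_seq)
                read.orientation = "-" if read.orientation == "+" else "+"
        contigs.append(ContigAlignment(
            contig_id=contig_id, n_columns=T, reads=reads,
            reference_member=model.transcript_id,
        ))
        plant_log.extend(events)
    return contigs, variety_map, plant_log


def _singleton_noise(rng, T, config, used_cols, haplotype) -> list[tuple[int, str]]:
    """Error/N substitutions for one read, never reusing a column already
    perturbed within the same variety (keeps artifacts singleton)."""
    out: list[tuple[int, str]] = []
    for rate, n_symbol in ((config.error_rate, False), (config.n_rate, True)):
        if rate <= 0:
            continue
        n = rng.binomial(T, rate)
        for _ in range(n):
            for _attempt in range(20):
                col = int(rng.integers(0, T))
                if col in used_cols or haplotype[col] == "-":
                    continue
                used_cols.add(col)
                if n_symbol:
                    out.append((col, "N"))
                else:
                    choices = [b for b in BASES if b != haplotype[col]]
                    out.append((col, choices[rng.integers(0, 3)]))
                break
    return out


def simulate(config: SimConfig) -> Simulation:
    """Full fixture: genome + models + contigs + variety map + plant log."""
    scaffolds, models = generate_genome(config)
    rng = np.random.default_rng(config.seed + 1)
    contigs, variety_map, plant_log = simulate_reads(scaffolds, models, config, rng)
    return Simulation(
        config=config, scaffolds=scaffolds, models=models,
        contigs=contigs, variety_map=variety_map, plant_log=plant_log,
    )


# ---------------------------------------------------------------------------
# recovery scoring


def evaluate_recovery(
    calls: Iterable[PolymorphismCall],
    anchors: Mapping[str, ContigAnchor],
    plant_log: PlantLog,
) -> dict[str, float | int]:
    """Recall/precision of anchored calls against detectable planted events.

    Calls are keyed by plus-strand (scaffold, position, kind, alleles |
    length); a call matching a non-detectable planted event (e.g. one with
    singleton carrier depth) counts as a false positive.
    """
    call_keys = set()
    for call in calls:
        anc = anchors.get(call.contig_id)
        if anc is None or not call.anchored:
            continue
        if call.kind == "SNP":
            pair = frozenset(anc.to_plus_strand(a) for a in call.alleles)
            call_keys.add((call.scaffold, call.genome_pos, "SNP", pair))
        else:
            length = call.length
            cols = range(call.contig_col, call.contig_col + length)
            positions = [anc.position_of(c) for c in cols]
            gpos = min(p for p in positions if p is not None)
            call_keys.add((call.scaffold, gpos, "InDel", length))
    truth = {ev.key for ev in plant_log if ev.detectable}
    tp = len(call_keys & truth)
    fp = len(call_keys - truth)
    fn = len(truth - call_keys)
    return {
        "n_calls": len(call_keys),
        "n_detectable": len(truth),
        "true_positives": tp,
        "false_positives": fp,
        "false_negatives": fn,
        "recall": tp / len(truth) if truth else float("nan"),
        "precision": tp / len(call_keys) if call_keys else float("nan"),
    }
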