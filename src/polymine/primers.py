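"""Flanking PCR primer design around polymorphism sites.

Candidate primer pairs are enumerated directly on the genomic template and
filtered against hard constraints — primer length 18–25 bp, product length
150–200 bp, GC content 45–65%, melting temperature 58–72 °C, pair Tm
difference ≤ 5 °C, and a minimum gap between each primer's 3' end and the
polymorphism — then ranked deterministically: smallest pair Tm difference
first, then product length closest to the middle of the allowed range,
then leftmost placement.

Melting temperatures use nearest-neighbor thermodynamics (unified DNA
parameters of Allawi & SantaLucia 1997 with terminal-end corrections and
the entropic salt correction of SantaLucia 1998) at 50 mM monovalent
cation and 50 nM total strand concentration.  Boulder-IO records (the
tag=value input format of standard primer-design tools, records terminated
by ``=``) can be emitted for external cross-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .alignment import revcomp

R_GAS = 1.987  # cal / (mol K)

# Unified nearest-neighbor parameters, 5'->3' dinucleotide on one strand:
# (delta-H kcal/mol, delta-S cal/(mol K))
_NN = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
# a dinucleotide and its reverse complement share parameters
for _d, _v in list(_NN.items()):
    _NN[revcomp(_d)] = _v

_INIT_AT = (2.3, 4.1)  # terminal A/T pair
_INIT_GC = (0.1, -2.8)  # terminal G/C pair


def melting_temperature(
    seq: str,
    monovalent_mM: float = 50.0,
    total_strand_nM: float = 50.0,
) -> float:
    """Nearest-neighbor duplex Tm in °C for a primer annealing to its
    perfect complement (non-self-complementary assumption, CT/4 term).

    Deterministic; raises on ambiguous bases or primers shorter than 8 nt.
    """
    seq = seq.upper()
    if len(seq) < 8:
        raise ValueError("primer too short for nearest-neighbor Tm (<8 nt)")
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguous bases in primer: {seq!r}")
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        inith, inits = _INIT_AT if end in "AT" else _INIT_GC
        dh += inith
        ds += inits
    for i in range(len(seq) - 1):
        nh, ns = _NN[seq[i : i + 2]]
        dh += nh
        ds += ns
    # entropic salt correction: 0.368 * (N-1) * ln[mon+]
    ds += 0.368 * (len(seq) - 1) * math.log(monovalent_mM / 1000.0)
    ct = total_strand_nM * 1e-9
    return (1000.0 * dh) / (ds + R_GAS * math.log(ct / 4.0)) - 273.15


def gc_percent(seq: str) -> float:
    return 100.0 * sum(1 for b in seq.upper() if b in "GC") / len(seq)


@dataclass(frozen=True)
class PrimerConstraints:
    primer_len: tuple[int, int] = (18, 25)
    product_len: tuple[int, int] = (150, 200)
    gc_percent: tuple[float, float] = (45.0, 65.0)
    tm_celsius: tuple[float, float] = (58.0, 72.0)
    max_tm_diff: float = 5.0
    min_flank: int = 10

    def __post_init__(self) -> None:
        for lo, hi in (self.primer_len, self.product_len, self.gc_percent, self.tm_celsius):
            if lo > hi:
                raise ValueError("constraint range is empty")


@dataclass
class PrimerPair:
    """A designed pair: left primer on the plus strand, right primer given
    5'->3' on the minus strand; positions are 1-based on the template
    (``right_start`` is the right primer's 5' end, i.e. the rightmost
    template base of the amplicon)."""

    left_seq: str
    right_seq: str
    left_start: int
    right_start: int
    left_tm: float
    right_tm: float
    left_gc: float
    right_gc: float
    product_length: int
    product_seq: str


@dataclass
class DesignResult:
    pair: PrimerPair | None
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.pair is not None


def _primer_candidates(
    template: str,
    constraints: PrimerConstraints,
    start_lo: int,
    start_hi: int,
) -> list[tuple[int, int, float, float]]:
    """(start0, length, tm, gc) for every in-bounds window passing the
    per-primer constraints, with 0-based start in [start_lo, start_hi]."""
    lo_len, hi_len = constraints.primer_len
    gc_lo, gc_hi = constraints.gc_percent
    tm_lo, tm_hi = constraints.tm_celsius
    out = []
    for start in range(max(0, start_lo), min(len(template), start_hi + 1)):
        for length in range(lo_len, hi_len + 1):
            if start + length > len(template):
                break
            window = template[start : start + length]
            if set(window) - set("ACGT"):
                continue  # degenerate/soft-masked bases disqualify the window
            gc = gc_percent(window)
            if not gc_lo <= gc <= gc_hi:
                continue
            tm = melting_temperature(window)
            if not tm_lo <= tm <= tm_hi:
                continue
            out.append((start, length, tm, gc))
    return out


def design_pair(
    template: str,
    target_pos: int,
    constraints: PrimerConstraints | None = None,
) -> DesignResult:
    """Best primer pair amplifying across ``target_pos`` (1-based within
    the template), or a reason code when no pair satisfies the constraints.

    Ranking among valid pairs: |Tm_left - Tm_right| ascending, then product
    length closest to the middle of the product range, then leftmost
    product, then shortest product; fully deterministic.
    """
    constraints = constraints or PrimerConstraints()
    template = template.upper()
    if not 1 <= target_pos <= len(template):
        raise ValueError("target_pos outside template")
    prod_lo, prod_hi = constraints.product_len
    flank = constraints.min_flank
    t0 = target_pos - 1  # 0-based target index

    # geometric bounds: left primer must end >= flank+1 before the target,
    # right primer must start >= flank+1 after it, product within range
    if t0 - flank < constraints.primer_len[0] or (
        len(template) - t0 - 1 - flank
    ) < constraints.primer_len[0]:
        return DesignResult(None, "target_too_close_to_edge")

    left_start_lo = t0 - (prod_hi - 1)
    left_start_hi = t0 - flank - constraints.primer_len[0]
    lefts = _primer_candidates(template, constraints, left_start_lo, left_start_hi)
    # right primer plus-strand window [rs, re]; its 3' end is rs
    rights: list[tuple[int, int, float, float]] = []
    rs_lo = t0 + flank + 1
    rs_hi = t0 + (prod_hi - 1)
    lo_len, hi_len = constraints.primer_len
    for rs in range(rs_lo, min(len(template), rs_hi + 1)):
        for length in range(lo_len, hi_len + 1):
            if rs + length > len(template):
                break
            window = template[rs : rs + length]
            if set(window) - set("ACGT"):
                continue
            primer = revcomp(window)
            gc = gc_percent(primer)
            if not constraints.gc_percent[0] <= gc <= constraints.gc_percent[1]:
                continue
            tm = melting_temperature(primer)
            if not constraints.tm_celsius[0] <= tm <= constraints.tm_celsius[1]:
                continue
            rights.append((rs, length, tm, gc))
    if not lefts or not rights:
        return DesignResult(None, "no_valid_primer_window")

    midpoint = (prod_lo + prod_hi) / 2.0
    best = None
    best_key = None
    for ls, llen, ltm, lgc in lefts:
        # left primer 3' end at ls+llen-1; enforce flank before target
        if ls + llen - 1 > t0 - flank - 1:
            continue
        for rs, rlen, rtm, rgc in rights:
            re = rs + rlen - 1
            product_length = re - ls + 1
            if not prod_lo <= product_length <= prod_hi:
                continue
            if abs(ltm - rtm) > constraints.max_tm_diff:
                continue
            key = (
                abs(ltm - rtm),
                abs(product_length - midpoint),
                ls,
                product_length,
                rlen,
                llen,
            )
            if best_key is None or key < best_key:
                best_key = key
                best = (ls, llen, ltm, lgc, rs, rlen, rtm, rgc, product_length)
    if best is None:
        return DesignResult(None, "no_valid_pair")
    ls, llen, ltm, lgc, rs, rlen, rtm, rgc, product_length = best
    re = rs + rlen - 1
    return DesignResult(
        PrimerPair(
            left_seq=template[ls : ls + llen],
            right_seq=revcomp(template[rs : rs + rlen]),
            left_start=ls + 1,
            right_start=re + 1,
            left_tm=ltm,
            right_tm=rtm,
            left_gc=lgc,
            right_gc=rgc,
            product_length=product_length,
            product_seq=template[ls : re + 1],
        )
    )


# ---------------------------------------------------------------------------
# Boulder-IO interchange


def write_boulder(
    targets: Sequence[tuple[str, int]] | Sequence[tuple[str, str, int]],
    constraints: PrimerConstraints | None = None,
) -> str:
    """Boulder-IO records for external primer tools: one record per
    (template, target_pos) or (id, template, target_pos), each closed by
    a lone ``=`` line.  SEQUENCE_TARGET uses the 0-based start,length
    convention."""
    constraints = constraints or PrimerConstraints()
    if not targets:
        raise ValueError("no targets")
    records = []
    for i, target in enumerate(targets):
        if len(target) == 3:
            seq_id, template, pos = target
        else:
            template, pos = target
            seq_id = f"target_{i + 1}"
        lines = [
            f"SEQUENCE_ID={seq_id}",
            f"SEQUENCE_TEMPLATE={template}",
            f"SEQUENCE_TARGET={pos - 1},1",
            f"PRIMER_MIN_SIZE={constraints.primer_len[0]}",
            f"PRIMER_MAX_SIZE={constraints.primer_len[1]}",
            f"PRIMER_PRODUCT_SIZE_RANGE={constraints.product_len[0]}-{constraints.product_len[1]}",
            f"PRIMER_MIN_GC={constraints.gc_percent[0]:g}",
            f"PRIMER_MAX_GC={constraints.gc_percent[1]:g}",
            f"PRIMER_MIN_TM={constraints.tm_celsius[0]:g}",
            f"PRIMER_MAX_TM={constraints.tm_celsius[1]:g}",
            f"PRIMER_PAIR_MAX_DIFF_TM={constraints.max_tm_diff:g}",
            "=",
        ]
        records.append("\n".join(lines))
    return "\n".join(records) + "\n"


def parse_boulder(text: str) -> list[dict[str, str]]:
    """Parse Boulder-IO text back into one tag->value dict per record."""
    records: list[dict[str, str]] = []
    current: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line == "=":
            records.append(current)
            current = {}
            continue
        tag, _, value = line.partition("=")
        current[tag] = value
    if current:
        records.append(current)
    return records
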