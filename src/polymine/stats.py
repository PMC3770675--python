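"""Characterization statistics for a mined polymorphism set.

Covers the transition/transversion spectrum, codon-position distribution
and nonsynonymous fraction, per-family nonsynonymous:synonymous ratios,
pairwise-variety polymorphism ratios, and the Pearson chi-square test with
adjusted standardized residuals used to localize which categories (e.g. GO
terms) drive a significant difference between two gene groups.

For an r x c contingency table with observed counts O_ij, row margins
n_i., column margins n_.j and grand total N:

    E_ij = n_i. * n_.j / N
    d_ij = (O_ij - E_ij) / sqrt(E_ij * (1 - n_i./N) * (1 - n_.j/N))

Under independence the d_ij are approximately standard normal, so |d| >
1.96 flags a cell at the 0.05 level and |d| > 2.575 at the 0.01 level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotate import EffectAnnotation
from .caller import PolymorphismCall

TRANSITION_PAIRS = (frozenset("CT"), frozenset("GA"))
SNP_PAIR_ORDER = ("C/T", "G/A", "A/C", "A/T", "C/G", "T/G")
_PAIR_KEY = {frozenset(p.split("/")): p for p in SNP_PAIR_ORDER}


@dataclass
class SnpSpectrum:
    """Counts of the six unordered single-base changes and the Ts/Tv ratio."""

    counts: dict[str, int]

    @property
    def transitions(self) -> int:
        return self.counts["C/T"] + self.counts["G/A"]

    @property
    def transversions(self) -> int:
        return sum(self.counts[p] for p in ("A/C", "A/T", "C/G", "T/G"))

    @property
    def total(self) -> int:
        return self.transitions + self.transversions

    @property
    def ts_tv_ratio(self) -> float | None:
        """Transitions/transversions, 2 decimals; None when no
        transversions were observed (degenerate all-transition input)."""
        if self.transversions == 0:
            return None
        return round(self.transitions / self.transversions, 2)


def snp_spectrum(calls: Iterable[PolymorphismCall | tuple[str, str]]) -> SnpSpectrum:
    """Classify SNP calls by their unordered allele pair."""
    counts = {p: 0 for p in SNP_PAIR_ORDER}
    for call in calls:
        alleles = call.alleles if isinstance(call, PolymorphismCall) else tuple(call)
        pair = _PAIR_KEY.get(frozenset(alleles))
        if pair is None:
            raise ValueError(f"not a two-base SNP allele pair: {alleles!r}")
        counts[pair] += 1
    return SnpSpectrum(counts=counts)


@dataclass
class CodonPositionDistribution:
    position_counts: tuple[int, int, int]
    n_synonymous: int
    n_nonsynonymous: int

    @property
    def total(self) -> int:
        return sum(self.position_counts)

    @property
    def pct_nonsynonymous(self) -> float | None:
        """Nonsynonymous share of classified CDS SNPs, in %, 1 decimal."""
        denom = self.n_synonymous + self.n_nonsynonymous
        if denom == 0:
            return None
        return round(100 * self.n_nonsynonymous / denom, 1)


def codon_position_distribution(
    annotations: Iterable[EffectAnnotation],
) -> CodonPositionDistribution:
    """Tally CDS SNP annotations by codon position and syn/nonsyn class.

    Premature-stop and read-through substitutions count as nonsynonymous
    (the amino acid sequence changes) in the fraction.
    """
    pos = [0, 0, 0]
    syn = nonsyn = 0
    for ann in annotations:
        if ann.region != "CDS" or ann.codon_position is None:
            continue
        pos[ann.codon_position - 1] += 1
        if ann.effect == "synonymous":
            syn += 1
        elif ann.effect in ("nonsynonymous", "premature_stop", "read_through"):
            nonsyn += 1
    return CodonPositionDistribution(
        position_counts=(pos[0], pos[1], pos[2]),
        n_synonymous=syn,
        n_nonsynonymous=nonsyn,
    )


def family_ns_ratio(
    annotations: Iterable[EffectAnnotation],
    family_of: Mapping[str, str] | None = None,
    min_count: int = 30,
) -> pd.DataFrame:
    """Per-family nonsynonymous and synonymous counts and their ratio.

    Families (e.g. protein-domain labels) with fewer than ``min_count``
    classified SNPs are excluded.  A family with zero synonymous SNPs keeps
    its row with ratio NaN (sentinel) rather than being dropped.
    """
    rows = []
    for ann in annotations:
        if ann.effect not in ("synonymous", "nonsynonymous", "premature_stop", "read_through"):
            continue
        family = ann.family
        if family is None and family_of is not None and ann.gene_id is not None:
            family = family_of.get(ann.gene_id)
        if family is None:
            continue
        rows.append((family, ann.effect == "synonymous"))
    if not rows:
        return pd.DataFrame(columns=["family", "nonsyn", "syn", "ratio"]).set_index("family")
    df = pd.DataFrame(rows, columns=["family", "is_syn"])
    grouped = df.groupby("family")["is_syn"].agg(syn="sum", total="count")
    grouped["nonsyn"] = grouped["total"] - grouped["syn"]
    grouped = grouped[grouped["total"] >= min_count]
    with np.errstate(divide="ignore", invalid="ignore"):
        grouped["ratio"] = np.where(
            grouped["syn"] > 0, grouped["nonsyn"] / grouped["syn"], np.nan
        )
    return grouped[["nonsyn", "syn", "ratio"]].sort_index()


def pairwise_variety_ratio(
    calls: Sequence[PolymorphismCall],
    variety_a: str,
    variety_b: str,
    gene_of=None,
) -> float | None:
    """Fraction of co-covered polymorphic genes at which two varieties
    carry different alleles.

    Numerator: genes containing ≥1 SNP where both varieties observed an
    allele and the alleles differ.  Denominator: genes containing ≥1 SNP
    (across all varieties) at which both varieties have observed alleles.
    None when the denominator is empty.
    """
    if gene_of is None:
        gene_of = lambda call: call.gene_id  # noqa: E731
    covered: set[str] = set()
    differing: set[str] = set()
    for call in calls:
        if call.kind != "SNP":
            continue
        gene = gene_of(call)
        if gene is None:
            continue
        va = call.variety_alleles.get(variety_a)
        vb = call.variety_alleles.get(variety_b)
        if va is None or vb is None:
            continue
        covered.add(gene)
        if va[0] != vb[0]:
            differing.add(gene)
    if not covered:
        return None
    return round(len(differing) / len(covered), 2)


def pairwise_variety_matrix(
    calls: Sequence[PolymorphismCall],
    varieties: Sequence[str],
    gene_of=None,
) -> pd.DataFrame:
    """Lower-triangle matrix of pairwise polymorphism ratios."""
    mat = pd.DataFrame(index=list(varieties), columns=list(varieties), dtype=float)
    for i, va in enumerate(varieties):
        for vb in varieties[:i]:
            mat.loc[va, vb] = pairwise_variety_ratio(calls, va, vb, gene_of=gene_of)
    return mat


# ---------------------------------------------------------------------------
# chi-square with adjusted standardized residuals


@dataclass
class ContingencyTable:
    observed: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        if self.observed.ndim != 2:
            raise ValueError("contingency table must be 2-dimensional")

    @classmethod
    def from_tsv(cls, path) -> "ContingencyTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)), list(df.columns.astype(str)))

    @property
    def row_margins(self) -> np.ndarray:
        return self.observed.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.observed.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.observed.sum())


@dataclass
class ResidualResult:
    table: ContingencyTable
    expected: np.ndarray
    residuals: np.ndarray
    chi_square: float
    dof: int
    p_value: float
    alpha_05_cutoff: float = 1.96
    alpha_01_cutoff: float = 2.575
    significant_05: np.ndarray = field(init=False)
    significant_01: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.significant_05 = np.abs(self.residuals) > self.alpha_05_cutoff
        self.significant_01 = np.abs(self.residuals) > self.alpha_01_cutoff

    def to_frame(self) -> pd.DataFrame:
        t = self.table
        rows = []
        for i, r in enumerate(t.row_labels):
            for j, c in enumerate(t.col_labels):
                rows.append(
                    dict(
                        category=r,
                        group=c,
                        observed=t.observed[i, j],
                        expected=self.expected[i, j],
                        residual=self.residuals[i, j],
                        sig_05=bool(self.significant_05[i, j]),
                        sig_01=bool(self.significant_01[i, j]),
                    )
                )
        return pd.DataFrame(rows)


def residual_test(
    table: ContingencyTable | np.ndarray,
    alpha_05_cutoff: float = 1.96,
    alpha_01_cutoff: float = 2.575,
) -> ResidualResult:
    """Pearson chi-square with per-cell adjusted standardized residuals.

    Residuals are (O-E)/sqrt(E(1-n_i./N)(1-n_.j/N)), approximately N(0,1)
    under independence; per-cell significance flags use the two cutoff
    values.  Raises on a zero row or column margin (the residual is
    undefined there).
    """
    if not isinstance(table, ContingencyTable):
        arr = np.asarray(table, dtype=float)
        table = ContingencyTable(
            arr,
            [f"row{i}" for i in range(arr.shape[0])],
            [f"col{j}" for j in range(arr.shape[1])],
        )
    O = table.observed
    ni = table.row_margins
    nj = table.col_margins
    N = table.total
    if (ni == 0).any():
        empty = [table.row_labels[i] for i in np.flatnonzero(ni == 0)]
        raise ValueError(f"zero row margin for {empty}")
    if (nj == 0).any():
        empty = [table.col_labels[j] for j in np.flatnonzero(nj == 0)]
        raise ValueError(f"zero column margin for {empty}")
    E = np.outer(ni, nj) / N
    chi_square = float(((O - E) ** 2 / E).sum())
    dof = (O.shape[0] - 1) * (O.shape[1] - 1)
    p_value = float(sps.chi2.sf(chi_square, dof)) if dof > 0 else float("nan")
    denom = np.sqrt(E * (1 - ni / N)[:, None] * (1 - nj / N)[None, :])
    residuals = (O - E) / denom
    return ResidualResult(
        table=table,
        expected=E,
        residuals=residuals,
        chi_square=chi_square,
        dof=dof,
        p_value=p_value,
        alpha_05_cutoff=alpha_05_cutoff,
        alpha_01_cutoff=alpha_01_cutoff,
    )


def go_group_comparison(
    group_counts: Mapping[str, int],
    background_counts: Mapping[str, int],
    group_label: str = "group",
    background_label: str = "all_genes",
    gate_alpha: float = 0.05,
    bonferroni: bool = False,
) -> tuple[ResidualResult, pd.DataFrame]:
    """Category-vs-group residual analysis gated on the global chi-square.

    Builds a (categories x 2) table from per-GO-term gene counts for a
    focal group and the background, runs :func:`residual_test`, and
    reports per-term flags only when the global test passes ``gate_alpha``
    (no multiple-testing correction by default; ``bonferroni`` divides the
    gate and the per-cell alpha by the number of categories).
    """
    terms = sorted(set(group_counts) | set(background_counts))
    observed = np.array(
        [[group_counts.get(t, 0), background_counts.get(t, 0)] for t in terms],
        dtype=float,
    )
    keep = observed.sum(axis=1) > 0
    observed = observed[keep]
    terms = [t for t, k in zip(terms, keep) if k]
    table = ContingencyTable(observed, terms, [group_label, background_label])
    cutoff_05, cutoff_01 = 1.96, 2.575
    if bonferroni and terms:
        cutoff_05 = float(sps.norm.ppf(1 - 0.025 / len(terms)))
        cutoff_01 = float(sps.norm.ppf(1 - 0.005 / len(terms)))
    result = residual_test(table, cutoff_05, cutoff_01)
    frame = result.to_frame()
    if result.p_value >= gate_alpha:
        frame["sig_05"] = False
        frame["sig_01"] = False
    return result, frame
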