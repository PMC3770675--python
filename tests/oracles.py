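"""Independent brute-force re-implementations of the discovery criteria,
used only as test oracles.  Deliberately written column-by-column in plain
Python, without sharing code paths with the package implementation."""

from polymine.alignment import ContigAlignment


def _spanning_symbols(contig: ContigAlignment, col: int):
    out = []
    for read in contig.reads:
        if read.contig_offset <= col < read.contig_offset + len(read.aligned_seq):
            out.append((read.variety, read.aligned_seq[col - read.contig_offset]))
    return out


def _polymorphic_columns(contig: ContigAlignment) -> set[int]:
    cols = set()
    for col in range(contig.n_columns):
        symbols = {s for _, s in _spanning_symbols(contig, col)}
        if len(symbols) >= 2:
            cols.add(col)
    return cols


def _window_clusters(poly_cols: set[int], col: int, halfwidth: int) -> int:
    flagged = sorted(c for c in poly_cols
                     if c != col and abs(c - col) <= halfwidth)
    # a run interrupted by the candidate column itself splits in two
    clusters = 0
    prev = None
    for c in flagged:
        if prev is None or c - prev > 1 or prev < col < c:
            clusters += 1
        prev = c
    return clusters


def _variety_support(groups: dict, allele: str, min_support: int) -> bool:
    for variety, symbols in groups.items():
        if variety == "unknown":
            continue
        if all(s == allele for s in symbols) and len(symbols) >= min_support:
            return True
    return False


def brute_force_snps(contig: ContigAlignment, min_support=2, halfwidth=5,
                     max_flank=3):
    poly_cols = _polymorphic_columns(contig)
    found = []
    for col in range(contig.n_columns):
        observed = _spanning_symbols(contig, col)
        if not observed:
            continue
        symbols = [s for _, s in observed]
        if "N" in symbols or "-" in symbols:
            continue
        bases = set(symbols)
        if len(bases) != 2:
            continue
        groups: dict[str, list[str]] = {}
        for variety, s in observed:
            groups.setdefault(variety, []).append(s)
        if any(len(set(ss)) != 1 for ss in groups.values()):
            continue
        a, b = sorted(bases)
        if not (_variety_support(groups, a, min_support)
                and _variety_support(groups, b, min_support)):
            continue
        if _window_clusters(poly_cols, col, halfwidth) >= max_flank:
            continue
        found.append((col, (a, b),
                      {v: (ss[0], len(ss)) for v, ss in sorted(groups.items())}))
    return found


def brute_force_indels(contig: ContigAlignment, min_support=2, max_len=3):
    # columns where gap and base symbols co-occur among spanning reads
    seg = []
    for col in range(contig.n_columns):
        symbols = [s for _, s in _spanning_symbols(contig, col)]
        seg.append("-" in symbols and any(s in "ACGT" for s in symbols))
    runs = []
    col = 0
    while col < contig.n_columns:
        if seg[col]:
            start = col
            while col < contig.n_columns and seg[col]:
                col += 1
            runs.append((start, col - 1))
        else:
            col += 1
    found = []
    for start, end in runs:
        length = end - start + 1
        if length > max_len:
            continue
        groups: dict[str, list[str]] = {}
        base_forms = set()
        valid = True
        for read in contig.reads:
            if not (read.contig_offset <= start
                    and end < read.contig_offset + len(read.aligned_seq)):
                continue
            piece = read.aligned_seq[start - read.contig_offset:
                                     end - read.contig_offset + 1]
            if "N" in piece:
                valid = False
                break
            if "-" in piece:
                if piece != "-" * length:
                    valid = False
                    break
            else:
                base_forms.add(piece)
            groups.setdefault(read.variety, []).append(
                "-" * length if "-" in piece else piece)
        if not valid or len(base_forms) != 1 or not groups:
            continue
        if any(len(set(ss)) != 1 for ss in groups.values()):
            continue
        gap_form = "-" * length
        base_form = base_forms.pop()
        alleles_seen = {a for ss in groups.values() for a in ss}
        if alleles_seen != {gap_form, base_form}:
            continue
        if not (_variety_support(groups, gap_form, min_support)
                and _variety_support(groups, base_form, min_support)):
            continue
        found.append((start, (base_form, gap_form),
                      {v: (ss[0], len(ss)) for v, ss in sorted(groups.items())}))
    return found
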