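import numpy as np
import pytest

from polymine.alignment import ContigAlignment, SequenceRead
from polymine.simulate import SimConfig, simulate


def make_alignment(rows, varieties=None, offsets=None, contig_id="c1",
                   reference_member=None):
    """Build a ContigAlignment from aligned row strings (test helper)."""
    n_columns = max(
        (offsets[i] if offsets else 0) + len(row) for i, row in enumerate(rows)
    )
    reads = []
    for i, row in enumerate(rows):
        reads.append(SequenceRead(
            read_id=f"r{i}",
            aligned_seq=row,
            contig_offset=offsets[i] if offsets else 0,
            variety=varieties[i] if varieties else "unknown",
        ))
    return ContigAlignment(contig_id=contig_id, n_columns=n_columns,
                           reads=reads, reference_member=reference_member)


def random_alignment(rng, max_reads=20, max_cols=200, varieties=("V1", "V2", "V3", "V4", "unknown")):
    """Random multi-variety alignment with variety-level haplotype changes,
    gaps, errors and N bases — input generator for oracle-equivalence tests."""
    n_cols = int(rng.integers(40, max_cols + 1))
    n_reads = int(rng.integers(4, max_reads + 1))
    reference = "".join("ACGT"[i] for i in rng.integers(0, 4, n_cols))
    # variety haplotypes: a few columns where a variety deviates
    haplotypes = {}
    for v in varieties:
        hap = list(reference)
        for _ in range(int(rng.integers(0, 6))):
            col = int(rng.integers(0, n_cols))
            choice = rng.random()
            if choice < 0.6:
                hap[col] = "ACGT"[int(rng.integers(0, 4))]
            elif choice < 0.85:
                run = int(rng.integers(1, 5))
                for c in range(col, min(n_cols, col + run)):
                    hap[c] = "-"
            else:
                hap[col] = "N"
        haplotypes[v] = hap
    reads = []
    for i in range(n_reads):
        v = varieties[int(rng.integers(0, len(varieties)))]
        seq = list(haplotypes[v])
        for _ in range(int(rng.integers(0, 3))):  # singleton noise
            col = int(rng.integers(0, n_cols))
            seq[col] = "ACGTN-"[int(rng.integers(0, 6))]
        offset = int(rng.integers(0, max(1, n_cols // 4)))
        end = int(rng.integers(offset + 10, n_cols + 1))
        reads.append(SequenceRead(
            read_id=f"r{i}", aligned_seq="".join(seq[offset:end]),
            contig_offset=offset, variety=v,
        ))
    return ContigAlignment(contig_id="rand", n_columns=n_cols, reads=reads)


@pytest.fixture(scope="session")
def sim():
    """Default error-free synthetic cohort."""
    return simulate(SimConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
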