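import numpy as np
import pytest

from overlapenrich.intervals import GenomeDefinition, IntervalSet


@pytest.fixture
def toy_genome():
    return GenomeDefinition("toy", {"chr1": 100_000, "chr2": 80_000})


def random_interval_set(
    rng: np.random.Generator,
    genome: GenomeDefinition,
    n: int,
    max_len: int = 500,
    build_label: str | None = None,
) -> IntervalSet:
    """Random (possibly overlapping, unmerged) intervals on a genome."""
    chrom_names = list(genome.chromosomes)
    rows = []
    for _ in range(n):
        chrom = chrom_names[rng.integers(0, len(chrom_names))]
        L = genome.chromosomes[chrom]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, L - length + 1))
        rows.append((chrom, start, start + length))
    return IntervalSet.from_intervals(
        rows, build_label=build_label or genome.build_label
    )


# ---------------------------------------------------------------------------
# brute-force oracles, O(n*m) over all pairs; independent of the package's
# sweep/searchsorted implementations
# ---------------------------------------------------------------------------

def brute_intersect(a: IntervalSet, b: IntervalSet) -> list[tuple]:
    out = []
    for ai in a:
        for bi in b:
            if ai.chrom == bi.chrom and ai.start < bi.end and bi.start < ai.end:
                out.append((ai.chrom, max(ai.start, bi.start), min(ai.end, bi.end)))
    return sorted(out)


def brute_covered_bp(intervals) -> int:
    by_chrom = {}
    for iv in intervals:
        by_chrom.setdefault(iv[0] if isinstance(iv, tuple) else iv.chrom, set()).update(
            range(iv[1], iv[2]) if isinstance(iv, tuple) else range(iv.start, iv.end)
        )
    return sum(len(s) for s in by_chrom.values())


def brute_subtract_bp(a: IntervalSet, b: IntervalSet) -> int:
    """Base pairs of (merged) a not covered by b, by explicit position sets."""
    a_pos = {}
    for iv in a:
        a_pos.setdefault(iv.chrom, set()).update(range(iv.start, iv.end))
    for iv in b:
        if iv.chrom in a_pos:
            a_pos[iv.chrom] -= set(range(iv.start, iv.end))
    return sum(len(s) for s in a_pos.values())


def brute_count_overlapping(a: IntervalSet, b: IntervalSet) -> int:
    count = 0
    for ai in a:
        if any(
            ai.chrom == bi.chrom and ai.start < bi.end and bi.start < ai.end
            for bi in b
        ):
            count += 1
    return count
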