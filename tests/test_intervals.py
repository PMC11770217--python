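"""Interval engine: parsing contracts, bedtools-default semantics, and
exact agreement with brute-force all-pairs oracles."""

import numpy as np
import pytest

from overlapenrich.intervals import (
    BedParseError,
    BuildMismatchError,
    GenomeDefinition,
    GenomicInterval,
    IntervalSet,
    count_elements_with_overlap,
    intersect,
    merge,
    overlap_proportion,
    read_bed,
    read_chrom_sizes,
    subtract,
    write_bed,
)

from conftest import (
    brute_count_overlapping,
    brute_covered_bp,
    brute_intersect,
    brute_subtract_bp,
    random_interval_set,
)


def iv_tuples(s: IntervalSet) -> list[tuple]:
    return [(i.chrom, i.start, i.end) for i in s]


class TestGenomeDefinition:
    def test_natural_chromosome_order(self):
        g = GenomeDefinition("b", {"chr10": 5, "chr2": 5, "chr1": 5, "chrX": 5})
        assert list(g.chromosomes) == ["chr1", "chr2", "chr10", "chrX"]
        assert g.total_bp == 20

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            GenomeDefinition("b", {"chr1": 0})


class TestBedIO:
    def test_read_sorts_intervals(self, tmp_path, toy_genome):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\nchr1\t5\t8\n")
        s = read_bed(p, toy_genome)
        assert iv_tuples(s) == [("chr1", 5, 8), ("chr1", 10, 20)]

    def test_empty_file(self, tmp_path, toy_genome):
        p = tmp_path / "empty.bed"
        p.write_text("")
        s = read_bed(p, toy_genome)
        assert len(s) == 0 and s.total_bp == 0

    @pytest.mark.parametrize(
        "content,fragment",
        [
            ("chr1\t20\t10\n", "line 1"),
            ("chr1\t10\t20\nchr1\tx\t30\n", "line 2"),
            ("chr9\t10\t20\n", "chr9"),
            ("chr1\t10\t200000\n", "exceeds"),
        ],
    )
    def test_malformed_input_raises_with_context(
        self, tmp_path, toy_genome, content, fragment
    ):
        p = tmp_path / "bad.bed"
        p.write_text(content)
        with pytest.raises(BedParseError, match=fragment):
            read_bed(p, toy_genome)

    def test_roundtrip(self, tmp_path, toy_genome):
        rng = np.random.default_rng(0)
        s = random_interval_set(rng, toy_genome, 50)
        path = tmp_path / "rt.bed"
        write_bed(s, path)
        assert read_bed(path, toy_genome) == s

    def test_chrom_sizes_reader(self, tmp_path):
        p = tmp_path / "g.sizes"
        p.write_text("chr2\t500\nchr1\t1000\n")
        g = read_chrom_sizes(p, "toy")
        assert list(g.chromosomes) == ["chr1", "chr2"]
        assert g.length_of("chr2") == 500


class TestMerge:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([("chr1", 10, 20), ("chr1", 15, 30)], [("chr1", 10, 30)]),
            # book-ended intervals join (bedtools merge default)
            ([("chr1", 10, 20), ("chr1", 20, 30)], [("chr1", 10, 30)]),
            (
                [("chr1", 10, 20), ("chr2", 10, 20)],
                [("chr1", 10, 20), ("chr2", 10, 20)],
            ),
        ],
    )
    def test_union_semantics(self, raw, expected):
        s = merge(IntervalSet.from_intervals(raw))
        assert iv_tuples(s) == expected and s.merged

    def test_idempotent_and_order_insensitive(self, toy_genome):
        rng = np.random.default_rng(1)
        s = random_interval_set(rng, toy_genome, 200)
        m = merge(s)
        assert merge(m) == m
        perm = rng.permutation(len(s))
        shuffled = IntervalSet(
            s.build_label, s.chroms[perm], s.starts[perm], s.ends[perm]
        )
        assert merge(shuffled) == m
        assert m.total_bp <= s.total_bp

    def test_total_bp_matches_position_set_oracle(self, toy_genome):
        rng = np.random.default_rng(2)
        s = random_interval_set(rng, toy_genome, 100, max_len=300)
        assert merge(s).total_bp == brute_covered_bp(list(s))


class TestIntersectSubtract:
    def test_partial_overlap(self):
        a = IntervalSet.from_intervals([("chr1", 0, 100)])
        b = IntervalSet.from_intervals([("chr1", 50, 150)])
        assert iv_tuples(intersect(a, b)) == [("chr1", 50, 100)]
        assert iv_tuples(subtract(a, b)) == [("chr1", 0, 50)]

    def test_disjoint_and_identity(self):
        a = IntervalSet.from_intervals([("chr1", 0, 10)], merged=True)
        b = IntervalSet.from_intervals([("chr1", 20, 30)], merged=True)
        assert len(intersect(a, b)) == 0
        assert subtract(a, IntervalSet.empty()) == a

    def test_subset_relations(self):
        a = merge(IntervalSet.from_intervals([("chr1", 10, 20)]))
        b = merge(IntervalSet.from_intervals([("chr1", 0, 100)]))
        assert intersect(a, b) == a
        assert len(subtract(a, b)) == 0

    def test_build_mismatch_rejected(self, toy_genome):
        a = IntervalSet.from_intervals([("chr1", 0, 10)], build_label="hg19")
        b = IntervalSet.from_intervals([("chr1", 0, 10)], build_label="hg38")
        with pytest.raises(BuildMismatchError):
            intersect(a, b)
        with pytest.raises(BuildMismatchError):
            subtract(a, b)

    def test_symmetric_overlap_bp(self, toy_genome):
        rng = np.random.default_rng(3)
        a = random_interval_set(rng, toy_genome, 80)
        b = random_interval_set(rng, toy_genome, 80)
        assert intersect(merge(a), merge(b)).total_bp == intersect(merge(b), merge(a)).total_bp

    def test_intersect_subtract_partition_merged_a(self, toy_genome):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = merge(random_interval_set(rng, toy_genome, 60))
            b = merge(random_interval_set(rng, toy_genome, 60))
            assert (
                intersect(a, b).total_bp + subtract(a, b).total_bp == a.total_bp
            )


class TestOverlapProportion:
    def test_half_identity_disjoint(self):
        a = merge(IntervalSet.from_intervals([("chr1", 0, 100)]))
        b = merge(IntervalSet.from_intervals([("chr1", 50, 150)]))
        assert overlap_proportion(a, b) == 0.5
        assert overlap_proportion(a, a) == 1.0
        c = merge(IntervalSet.from_intervals([("chr1", 500, 600)]))
        assert overlap_proportion(a, c) == 0.0

    def test_requires_merged_and_nonempty(self):
        a = IntervalSet.from_intervals([("chr1", 0, 10), ("chr1", 5, 15)])
        b = merge(a)
        with pytest.raises(ValueError, match="merged"):
            overlap_proportion(a, b)
        with pytest.raises(ValueError, match="empty"):
            overlap_proportion(IntervalSet.empty(), b)

    def test_monotone_in_b(self, toy_genome):
        rng = np.random.default_rng(5)
        a = merge(random_interval_set(rng, toy_genome, 50))
        b1 = merge(random_interval_set(rng, toy_genome, 30))
        extra = random_interval_set(rng, toy_genome, 30)
        b2 = merge(
            IntervalSet.from_intervals(
                [(i.chrom, i.start, i.end) for i in b1] + [(i.chrom, i.start, i.end) for i in extra],
                build_label=toy_genome.build_label,
            )
        )
        assert overlap_proportion(a, b2) >= overlap_proportion(a, b1)


class TestOverlapCounting:
    def test_elements_spanning_annotation(self):
        elements = IntervalSet.from_intervals([("chr1", 0, 10), ("chr1", 100, 110)])
        annot = merge(IntervalSet.from_intervals([("chr1", 5, 105)]))
        assert count_elements_with_overlap(elements, annot) == 2

    def test_empty_annotation(self):
        elements = IntervalSet.from_intervals([("chr1", 0, 10)])
        assert count_elements_with_overlap(elements, IntervalSet.empty()) == 0

    def test_requires_merged_annotation(self):
        elements = IntervalSet.from_intervals([("chr1", 0, 10)])
        annot = IntervalSet.from_intervals([("chr1", 0, 5), ("chr1", 3, 8)])
        with pytest.raises(ValueError, match="merged"):
            count_elements_with_overlap(elements, annot)

    def test_matches_brute_force_on_random_fixtures(self, toy_genome):
        rng = np.random.default_rng(6)
        for _ in range(10):
            elements = random_interval_set(rng, toy_genome, 200, max_len=400)
            annot = merge(random_interval_set(rng, toy_genome, 100, max_len=800))
            assert count_elements_with_overlap(elements, annot) == brute_count_overlapping(
                elements, annot
            )

    def test_pair_counting_mode(self):
        elements = IntervalSet.from_intervals([("chr1", 0, 100)])
        annot = merge(
            IntervalSet.from_intervals([("chr1", 10, 20), ("chr1", 50, 60), ("chr1", 200, 210)])
        )
        assert count_elements_with_overlap(elements, annot, mode="pairs") == 2
        assert count_elements_with_overlap(elements, annot, mode="unique") == 1


from hypothesis import given, settings
from hypothesis import strategies as st

interval_lists = st.lists(
    st.tuples(
        st.sampled_from(["chr1", "chr2"]),
        st.integers(min_value=0, max_value=9_000),
        st.integers(min_value=1, max_value=500),
    ).map(lambda t: (t[0], t[1], t[1] + t[2])),
    min_size=1,
    max_size=60,
)


@settings(max_examples=60, derandomize=True)
@given(raw=interval_lists)
def test_merge_invariants_hold_for_arbitrary_inputs(raw):
    """merge is idempotent, order-insensitive, and conserves covered bp."""
    s = IntervalSet.from_intervals(raw)
    m = merge(s)
    assert merge(m) == m
    assert m.total_bp == brute_covered_bp(raw)
    assert m.total_bp <= s.total_bp
    starts = m.starts
    ends = m.ends
    same_chrom = m.chroms[1:] == m.chroms[:-1]
    # strictly separated (book-ended pairs must have merged)
    assert np.all(starts[1:][same_chrom] > ends[:-1][same_chrom])


@settings(max_examples=60, derandomize=True)
@given(raw_a=interval_lists, raw_b=interval_lists)
def test_intersect_subtract_partition_for_arbitrary_inputs(raw_a, raw_b):
    a = merge(IntervalSet.from_intervals(raw_a))
    b = IntervalSet.from_intervals(raw_b)
    assert intersect(a, b).total_bp + subtract(a, b).total_bp >= a.total_bp
    bm = merge(b)
    assert intersect(a, bm).total_bp + subtract(a, bm).total_bp == a.total_bp


def test_engine_agrees_with_allpairs_oracle(toy_genome):
    """intersect/subtract/count all reproduce the brute-force oracle exactly
    on random unmerged fixtures."""
    rng = np.random.default_rng(7)
    for _ in range(25):
        a = random_interval_set(rng, toy_genome, int(rng.integers(1, 120)))
        b = random_interval_set(rng, toy_genome, int(rng.integers(1, 120)))
        assert iv_tuples(intersect(a, b)) == brute_intersect(a, b)
        am = merge(a)
        assert subtract(am, b).total_bp == brute_subtract_bp(am, b)
        bm = merge(b)
        assert count_elements_with_overlap(a, bm) == brute_count_overlapping(a, bm)
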