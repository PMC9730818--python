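"""Interval model and algebra: overlap counting, nearest gaps, shuffling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from episcan import (
    Genome,
    GenomicInterval,
    GenomeMismatchError,
    InputError,
    IntervalSet,
    count_overlapping,
    nearest_gap,
    shuffle_intervals,
)

from conftest import brute_count_overlapping, make_set, random_set


class TestGenomeAndIntervals:
    def test_genome_rejects_nonpositive_lengths(self):
        with pytest.raises(InputError):
            Genome({"chr1": 0})

    def test_interval_rejects_inverted_coordinates(self):
        with pytest.raises(InputError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(InputError):
            GenomicInterval("chr1", -1, 5)

    def test_set_bound_to_genome_rejects_out_of_bounds(self, toy_genome):
        with pytest.raises(InputError):
            make_set([("chr1", 0, 200_000)], genome=toy_genome)

    def test_duplicates_are_kept_but_warned(self, toy_genome):
        with pytest.warns(UserWarning, match="duplicated"):
            s = make_set([("chr1", 0, 10), ("chr1", 0, 10)], genome=toy_genome)
        assert len(s) == 2


class TestCountOverlapping:
    @pytest.mark.parametrize(
        "query,reference,expected",
        [
            # containment overlaps
            ([("chr1", 100, 200)], [("chr1", 150, 160)], 1),
            # half-open adjacency is not overlap
            ([("chr1", 100, 200)], [("chr1", 200, 300)], 0),
            # each query counted at most once despite two reference hits
            ([("chr1", 100, 200)], [("chr1", 90, 110), ("chr1", 150, 400)], 1),
            # chromosomes partition the search
            ([("chr2", 100, 200)], [("chr1", 100, 200)], 0),
        ],
    )
    def test_examples(self, toy_genome, query, reference, expected):
        q = make_set(query, genome=toy_genome)
        r = make_set(reference, genome=toy_genome)
        assert count_overlapping(q, r) == expected

    def test_empty_reference_returns_zero(self, toy_genome):
        q = make_set([("chr1", 0, 10)], genome=toy_genome)
        assert count_overlapping(q, IntervalSet(genome=toy_genome)) == 0

    def test_mismatched_genomes_raise(self, toy_genome):
        q = make_set([("chr1", 0, 10)], genome=toy_genome)
        r = make_set([("chr1", 0, 10)], genome=Genome({"chr1": 10}))
        with pytest.raises(GenomeMismatchError):
            count_overlapping(q, r)

    def test_min_overlap_threshold(self, toy_genome):
        q = make_set([("chr1", 100, 200)], genome=toy_genome)
        r = make_set([("chr1", 195, 300)], genome=toy_genome)
        assert count_overlapping(q, r, min_overlap_bp=5) == 1
        assert count_overlapping(q, r, min_overlap_bp=6) == 0

    def test_min_overlap_against_individual_not_merged_references(self, toy_genome):
        # two abutting 1-bp overlaps must not merge into a 2-bp overlap
        q = make_set([("chr1", 99, 101)], genome=toy_genome)
        r = make_set([("chr1", 90, 100), ("chr1", 100, 110)], genome=toy_genome)
        assert count_overlapping(q, r, min_overlap_bp=2) == 0

    @pytest.mark.parametrize("min_ov", [1, 3])
    def test_brute_force_equivalence(self, toy_genome, min_ov):
        rng = np.random.default_rng(42)
        for _ in range(25):
            q = random_set(rng, toy_genome, int(rng.integers(0, 60)))
            r = random_set(rng, toy_genome, int(rng.integers(0, 60)))
            assert count_overlapping(q, r, min_ov) == brute_count_overlapping(q, r, min_ov)

    def test_monotone_in_reference(self, toy_genome):
        rng = np.random.default_rng(7)
        q = random_set(rng, toy_genome, 50)
        r = random_set(rng, toy_genome, 40)
        df = r.to_dataframe()
        prev = 0
        for k in range(0, len(df) + 1, 10):
            sub = IntervalSet.from_dataframe(df.iloc[:k], genome=toy_genome) if k else IntervalSet(genome=toy_genome)
            c = count_overlapping(q, sub)
            assert prev <= c <= len(q)
            prev = c


class TestNearestGap:
    def test_overlap_gives_zero(self, toy_genome):
        r = make_set([("chr1", 150, 160)], genome=toy_genome)
        assert nearest_gap(GenomicInterval("chr1", 100, 200), r) == 0

    def test_gap_to_the_right(self, toy_genome):
        r = make_set([("chr1", 250, 260)], genome=toy_genome)
        assert nearest_gap(GenomicInterval("chr1", 100, 200), r) == 50

    def test_no_feature_on_chromosome_is_none(self, toy_genome):
        r = make_set([("chr1", 250, 260)], genome=toy_genome)
        assert nearest_gap(GenomicInterval("chr2", 0, 10), r) is None

    def test_adjacent_interval_gap_is_zero(self, toy_genome):
        r = make_set([("chr1", 200, 300)], genome=toy_genome)
        assert nearest_gap(GenomicInterval("chr1", 100, 200), r) == 0

    @given(
        qs=st.integers(0, 900),
        qlen=st.integers(1, 100),
        rs=st.integers(0, 900),
        rlen=st.integers(1, 100),
    )
    def test_reflection_symmetry(self, qs, qlen, rs, rlen):
        """Mirroring all coordinates across the chromosome preserves gaps."""
        L = 1000
        genome = Genome({"c": L})
        fwd = nearest_gap(
            GenomicInterval("c", qs, qs + qlen),
            make_set([("c", rs, rs + rlen)], genome=genome),
        )
        rev = nearest_gap(
            GenomicInterval("c", L - qs - qlen, L - qs),
            make_set([("c", L - rs - rlen, L - rs)], genome=genome),
        )
        assert fwd == rev


class TestShuffle:
    def test_single_placement_chromosome(self):
        genome = Genome({"c": 10})
        s = make_set([("c", 0, 10)], genome=genome)
        out = shuffle_intervals(s, genome, seed=3)
        iv = next(iter(out))
        assert (iv.start, iv.end) == (0, 10)

    def test_preserves_chrom_and_length_multiset(self, toy_genome):
        rng = np.random.default_rng(11)
        s = random_set(rng, toy_genome, 80)
        out = shuffle_intervals(s, toy_genome, seed=5)
        orig = sorted(zip(s.chroms, s.lengths))
        shuf = sorted(zip(out.chroms, out.lengths))
        assert orig == shuf
        assert s.counts_per_chrom() == out.counts_per_chrom()

    def test_deterministic_given_seed(self, toy_genome):
        rng = np.random.default_rng(12)
        s = random_set(rng, toy_genome, 30)
        a = shuffle_intervals(s, toy_genome, seed=9)
        b = shuffle_intervals(s, toy_genome, seed=9)
        assert (a.starts == b.starts).all()

    def test_interval_longer_than_chromosome_raises(self):
        big = Genome({"c": 100})
        small = Genome({"c": 5})
        s = make_set([("c", 0, 50)], genome=big)
        with pytest.raises(InputError):
            shuffle_intervals(s, small, seed=0)

    def test_start_positions_uniform_on_enumerable_chromosome(self):
        """Length-2 interval on a length-4 chromosome: starts {0,1,2}
        equiprobable (chi-square at alpha = 0.01 over 3000 draws)."""
        genome = Genome({"c": 4})
        s = make_set([("c", 0, 2)], genome=genome)
        starts = [next(iter(shuffle_intervals(s, genome, seed=k))).start for k in range(3000)]
        counts = np.bincount(starts, minlength=3)
        assert counts.sum() == 3000
        _, p = stats.chisquare(counts)
        assert p > 0.01
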