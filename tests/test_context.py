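"""Condition set algebra, genic fraction, densities, gene size classes."""

import numpy as np
import pytest

from episcan import (
    GeneModel,
    Genome,
    GenomicInterval,
    InputError,
    IntervalSet,
    chromosome_density,
    condition_sets,
    gene_size_stats,
    genes_from_intervals,
    genic_fraction,
)

from conftest import make_set


class TestConditionSets:
    def test_disjoint_sets_are_all_unique(self, toy_genome):
        a = make_set([("chr1", 0, 10), ("chr1", 100, 110)], genome=toy_genome)
        other = make_set([("chr1", 50, 60)], genome=toy_genome)
        shared, unique = condition_sets(a, [other])
        assert len(shared) == 0 and len(unique) == 2

    def test_partition_property(self, toy_genome):
        rng = np.random.default_rng(17)
        from conftest import random_set

        a = random_set(rng, toy_genome, 60)
        others = [random_set(rng, toy_genome, 30) for _ in range(2)]
        shared, unique = condition_sets(a, others)
        assert len(shared) + len(unique) == len(a)
        # every shared interval overlaps some other set; unique overlaps none
        from episcan import count_overlapping

        union = IntervalSet(
            [iv for o in others for iv in o], genome=toy_genome
        )
        assert count_overlapping(shared, union) == len(shared)
        assert count_overlapping(unique, union) == 0


class TestGenicFraction:
    def test_bounds(self, toy_genome):
        genes = make_set([("chr1", 0, 50_000)], genome=toy_genome)
        inside = make_set([("chr1", 10, 20)], genome=toy_genome)
        outside = make_set([("chr1", 60_000, 60_100)], genome=toy_genome)
        assert genic_fraction(inside, genes) == 1.0
        assert genic_fraction(outside, genes) == 0.0

    def test_empty_dsbs_raise(self, toy_genome):
        genes = make_set([("chr1", 0, 50_000)], genome=toy_genome)
        with pytest.raises(InputError):
            genic_fraction(IntervalSet(genome=toy_genome), genes)

    def test_invariant_to_merging_overlapping_genes(self, toy_genome):
        dsbs = make_set([("chr1", 100, 200), ("chr1", 5_000, 5_100)], genome=toy_genome)
        split = make_set([("chr1", 0, 150), ("chr1", 120, 1_000)], genome=toy_genome)
        merged = make_set([("chr1", 0, 1_000)], genome=toy_genome)
        assert genic_fraction(dsbs, split) == genic_fraction(dsbs, merged)


class TestChromosomeDensity:
    def test_count_per_mb(self):
        genome = Genome({"c": 2_000_000})
        dsbs = make_set([("c", i * 1000, i * 1000 + 10) for i in range(10)], genome=genome)
        assert chromosome_density(dsbs, genome) == {"c": 5.0}

    def test_empty_chromosome_is_zero(self, toy_genome):
        dsbs = make_set([("chr1", 0, 10)], genome=toy_genome)
        dens = chromosome_density(dsbs, toy_genome)
        assert dens["chr2"] == 0.0 and dens["chr1"] == 10.0


class TestGeneSizeStats:
    def make_gene(self, chrom, start, length, gid):
        return GeneModel(GenomicInterval(chrom, start, start + length), gid)

    def test_boundary_rules(self):
        cases = [(999, None), (1_000, "1-100"), (99_999, "1-100"),
                 (150_000, "100-300"), (300_000, "300-800"),
                 (799_999, "300-800"), (800_000, ">800")]
        genome = Genome({"c": 10_000_000})
        for length, expected in cases:
            g = self.make_gene("c", 0, length, "g")
            assert g.size_class == expected

    def test_density_math(self):
        genome = Genome({"c": 10_000_000})
        # two 1-Mb genes in the 300-800 kb class? no: use 1 Mb -> >800 class
        genes = [self.make_gene("c", 0, 1_000_000, "g1"),
                 self.make_gene("c", 2_000_000, 1_000_000, "g2")]
        hits = make_set([("c", int(p), int(p) + 100) for p in
                         np.linspace(0, 900_000, 5).astype(int)] +
                        [("c", 2_500_000, 2_500_100) for _ in range(5)],
                        genome=genome)
        summary = gene_size_stats(hits, genes)
        assert summary.n_genes[">800"] == 2
        assert summary.total_gene_mb[">800"] == pytest.approx(2.0)
        assert summary.density_per_mb[">800"] == pytest.approx(10 / 2.0)

    def test_hit_spanning_two_classes_counts_in_each(self):
        genome = Genome({"c": 10_000_000})
        genes = [self.make_gene("c", 0, 50_000, "small"),
                 self.make_gene("c", 50_000, 200_000, "medium")]
        hit = make_set([("c", 49_000, 51_000)], genome=genome)
        summary = gene_size_stats(hit, genes)
        assert summary.n_hits["1-100"] == 1 and summary.n_hits["100-300"] == 1

    def test_empty_class_density_is_none(self):
        genes = [self.make_gene("c", 0, 50_000, "g")]
        hits = make_set([("c", 0, 100)], genome=Genome({"c": 10_000_000}))
        summary = gene_size_stats(hits, genes)
        assert summary.density_per_mb[">800"] is None

    def test_doubling_hits_doubles_density(self):
        genome = Genome({"c": 10_000_000})
        genes = [self.make_gene("c", 0, 50_000, "g")]
        hits1 = make_set([("c", 100, 200)], genome=genome)
        with pytest.warns(UserWarning):
            hits2 = make_set([("c", 100, 200), ("c", 100, 200)], genome=genome)
        d1 = gene_size_stats(hits1, genes).density_per_mb["1-100"]
        d2 = gene_size_stats(hits2, genes).density_per_mb["1-100"]
        assert d2 == pytest.approx(2 * d1)


def test_longest_isoform_per_gene_symbol(toy_genome):
    ivs = IntervalSet(
        [GenomicInterval("chr1", 0, 2_000, "geneA"),
         GenomicInterval("chr1", 0, 5_000, "geneA"),
         GenomicInterval("chr2", 0, 3_000, "geneB")],
        genome=toy_genome,
    )
    models = genes_from_intervals(ivs)
    by_id = {m.gene_id: m for m in models}
    assert len(models) == 2
    assert by_id["geneA"].interval.length == 5_000
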