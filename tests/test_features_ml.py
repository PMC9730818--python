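"""Matched-null sampling, feature matrices, and classifier sanity."""

import numpy as np
import pytest

from episcan import (
    Genome,
    GenomicInterval,
    InputError,
    IntervalSet,
    SignalTrack,
    build_feature_matrix,
    sample_matched_nulls,
    train_evaluate,
)
from episcan.features_ml import FeatureMatrix

from conftest import make_set, random_set


class TestMatchedNulls:
    def test_preserves_chrom_and_length_distributions(self, toy_genome):
        rng = np.random.default_rng(1)
        dsbs = random_set(rng, toy_genome, 50)
        nulls = sample_matched_nulls(dsbs, toy_genome, dsbs, seed=4)
        assert sorted(zip(dsbs.chroms, dsbs.lengths)) == sorted(zip(nulls.chroms, nulls.lengths))

    def test_nulls_avoid_exclusion_set(self, toy_genome):
        rng = np.random.default_rng(2)
        dsbs = random_set(rng, toy_genome, 50)
        nulls = sample_matched_nulls(dsbs, toy_genome, dsbs, seed=4)
        from episcan import count_overlapping

        assert count_overlapping(nulls, dsbs) == 0

    def test_forced_single_placement(self):
        genome = Genome({"c": 100})
        dsbs = make_set([("c", 20, 30)], genome=genome)
        exclude = make_set([("c", 0, 90)], genome=genome)
        nulls = sample_matched_nulls(dsbs, genome, exclude, seed=0)
        iv = next(iter(nulls))
        assert (iv.start, iv.end) == (90, 100)

    def test_impossible_placement_raises_with_region_name(self):
        genome = Genome({"c": 100})
        dsbs = make_set([("c", 20, 30)], genome=genome)
        exclude = make_set([("c", 0, 100)], genome=genome)
        with pytest.raises(InputError, match="region 0"):
            sample_matched_nulls(dsbs, genome, exclude, seed=0, max_attempts=50)

    def test_deterministic_given_seed(self, toy_genome):
        rng = np.random.default_rng(3)
        dsbs = random_set(rng, toy_genome, 30)
        a = sample_matched_nulls(dsbs, toy_genome, dsbs, seed=9)
        b = sample_matched_nulls(dsbs, toy_genome, dsbs, seed=9)
        assert (a.starts == b.starts).all()


class TestFeatureMatrix:
    def test_signal_mode_values(self, toy_genome):
        real = make_set([("chr1", 0, 10)], genome=toy_genome)
        null = make_set([("chr1", 500, 510)], genome=toy_genome)
        track = SignalTrack([("chr1", 0, 4, 1.0), ("chr1", 4, 10, 2.5)], genome=toy_genome)
        const = SignalTrack([("chr1", 0, 100_000, 1.0)], genome=toy_genome)
        m = build_feature_matrix(real, null, tracks={"t": track, "one": const}, mode="signal")
        assert m.values.loc[0, "t"] == pytest.approx(1.9)   # hand-computed mean
        assert m.values.loc[1, "t"] == 0.0
        assert (m.values["one"] == 1.0).all()
        assert list(m.labels) == ["real", "null"]

    def test_distance_mode_with_sentinel(self, toy_genome):
        real = make_set([("chr1", 100, 200)], genome=toy_genome)
        null = make_set([("chr2", 100, 200)], genome=toy_genome)
        feats = make_set([("chr1", 150, 160)], genome=toy_genome)
        m = build_feature_matrix(real, null, feature_sets={"f": feats}, mode="distance")
        assert m.values.loc[0, "f"] == 0.0
        # chr2 has no feature: encoded as the chromosome length
        assert m.values.loc[1, "f"] == toy_genome["chr2"]

    def test_tsv_round_trip(self, tmp_path, toy_genome):
        real = make_set([("chr1", 0, 10)], genome=toy_genome)
        null = make_set([("chr1", 500, 510)], genome=toy_genome)
        track = SignalTrack([("chr1", 0, 1000, 2.0)], genome=toy_genome)
        m = build_feature_matrix(real, null, tracks={"t": track}, mode="signal")
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        back = FeatureMatrix.from_tsv(path)
        assert back.values.equals(m.values) and (back.labels == m.labels).all()


def _toy_matrix(rng, n_per_class=60, separable=False, seed_label_perm=None):
    """Noise features plus one optionally separable feature."""
    n = 2 * n_per_class
    X = rng.normal(size=(n, 4))
    y = np.array(["real"] * n_per_class + ["null"] * n_per_class)
    if separable:
        X[:n_per_class, 0] += 10.0
    if seed_label_perm is not None:
        y = np.random.default_rng(seed_label_perm).permutation(y)
    import pandas as pd

    return FeatureMatrix(
        values=pd.DataFrame(X, columns=["f0", "f1", "f2", "f3"]),
        labels=y,
        mode="signal",
    )


class TestClassifier:
    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        m = _toy_matrix(rng)
        m.labels[:] = "real"
        with pytest.raises(InputError):
            train_evaluate(m, n_trees=20, seed=0)

    def test_perfectly_separable_feature(self):
        rng = np.random.default_rng(5)
        m = _toy_matrix(rng, separable=True)
        report = train_evaluate(m, n_trees=200, seed=1)
        assert report.auroc >= 0.99
        assert max(report.class_errors.values()) < 0.1
        # the separating feature dominates both importance measures
        assert max(report.importance_impurity, key=report.importance_impurity.get) == "f0"
        assert max(report.importance_permutation, key=report.importance_permutation.get) == "f0"

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        m = _toy_matrix(rng, separable=True)
        a = train_evaluate(m, n_trees=50, seed=2)
        b = train_evaluate(m, n_trees=50, seed=2)
        assert a.to_dict() == b.to_dict()

    def test_holdout_evaluation_option(self):
        rng = np.random.default_rng(7)
        m = _toy_matrix(rng, separable=True, n_per_class=100)
        report = train_evaluate(m, n_trees=100, seed=3, holdout_fraction=0.3)
        assert report.evaluation.startswith("holdout")
        assert report.auroc >= 0.95

    def test_auroc_invariant_to_monotone_feature_transform(self):
        rng = np.random.default_rng(8)
        m = _toy_matrix(rng, separable=True)
        r1 = train_evaluate(m, n_trees=100, seed=4)
        m2 = FeatureMatrix(values=m.values.copy(), labels=m.labels.copy(), mode="signal")
        m2.values["f0"] = np.exp(m2.values["f0"] / 3.0)  # strictly increasing
        r2 = train_evaluate(m2, n_trees=100, seed=4)
        assert r1.auroc == pytest.approx(r2.auroc, abs=1e-9)
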