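"""Matched-null sampling, feature matrices, and the DSB classifier.

The classification contract mirrors the field's standard recipe: for each
real DSB draw one random genomic region with the same chromosome and
length (rejection-sampled away from an exclusion set, normally the DSBs
themselves), describe both groups by per-region feature values (mean
signal over the region, or edge distance to the nearest feature), and
train a bagged decision-tree ensemble (random forest, 700 trees, default
mtry = sqrt(p)) evaluated out-of-bag.  Reported: AUROC, PR-AUC, per-class
error rates, and both permutation (mean-decrease-accuracy analog) and
impurity (mean-decrease-Gini analog) variable importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import train_test_split

from .core import (
    Genome,
    GenomicInterval,
    InputError,
    IntervalSet,
    as_rng,
    nearest_gap,
)
from .tracks import SignalTrack, _region_sums, mean_signal_over_region

REAL, NULL = "real", "null"


@dataclass
class FeatureMatrix:
    values: pd.DataFrame        # rows = regions, columns = features
    labels: np.ndarray          # "real" / "null" per row
    mode: str                   # "signal" | "distance"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.values) != len(self.labels):
            raise InputError("labels must match matrix rows")
        if self.values.isna().any().any():
            raise InputError("feature matrix must have no missing values")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "label", self.labels)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, mode: str = "signal") -> "FeatureMatrix":
        # keep_default_na=False so the literal label "null" survives parsing
        df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
        labels = df.pop("label").to_numpy()
        return cls(values=df, labels=labels, mode=mode)


@dataclass
class ClassifierReport:
    auroc: float
    pr_auc: float
    class_errors: dict[str, float]
    importance_permutation: dict[str, float]
    importance_impurity: dict[str, float]
    n_trees: int
    seed: int
    evaluation: str = "oob"

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "pr_auc": self.pr_auc,
            "class_errors": self.class_errors,
            "importance_permutation": self.importance_permutation,
            "importance_impurity": self.importance_impurity,
            "n_trees": self.n_trees,
            "seed": self.seed,
            "evaluation": self.evaluation,
        }


def sample_matched_nulls(
    dsbs: IntervalSet,
    genome: Genome,
    exclude: IntervalSet,
    seed,
    max_attempts: int = 1000,
) -> IntervalSet:
    """One uniformly placed non-excluded region per DSB, matching its
    chromosome and length.  Raises when a region cannot be placed within
    ``max_attempts`` rejection draws."""
    rng = as_rng(seed)
    rows = []
    df = dsbs.to_dataframe()
    for i, row in enumerate(df.itertuples(index=False)):
        length = int(row.end - row.start)
        chrom_len = genome[row.chrom]
        if length > chrom_len:
            raise InputError(f"region {i} ({row.chrom}) longer than its chromosome")
        ms, me = exclude.merged_by_chrom(row.chrom)
        placed = None
        for _ in range(max_attempts):
            start = int(rng.integers(0, chrom_len - length + 1))
            end = start + length
            pos = int(np.searchsorted(me, start, side="right"))
            if pos < ms.size and ms[pos] < end:
                continue
            placed = (start, end)
            break
        if placed is None:
            raise InputError(
                f"could not place a matched null for region {i} "
                f"({row.chrom}:{row.start}-{row.end}) within {max_attempts} attempts"
            )
        rows.append((row.chrom, placed[0], placed[1], f"null_{i}", None, None))
    frame = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    label = f"{dsbs.label}|matched_null" if dsbs.label else "matched_null"
    if not rows:
        return IntervalSet(genome=genome, label=label)
    return IntervalSet.from_dataframe(frame, genome=genome, label=label)


def build_feature_matrix(
    real: IntervalSet,
    null: IntervalSet,
    tracks: Optional[dict[str, SignalTrack]] = None,
    feature_sets: Optional[dict[str, IntervalSet]] = None,
    mode: str = "signal",
    agg: str = "mean",
) -> FeatureMatrix:
    """Region-by-feature matrix for the classifier.

    ``signal`` mode: one column per track, mean (or sum) signal over the
    region, uncovered bases as zero.  ``distance`` mode: one column per
    feature set, edge gap in bp to the nearest feature on the same
    chromosome; chromosomes carrying no feature are encoded with the
    chromosome length as an order-preserving sentinel.
    """
    if mode == "signal":
        if not tracks:
            raise InputError("signal mode requires at least one track")
        columns = tracks
    elif mode == "distance":
        if not feature_sets:
            raise InputError("distance mode requires at least one feature set")
        columns = feature_sets
    else:
        raise InputError(f"unknown mode {mode!r}")
    if len(set(columns)) != len(columns):
        raise InputError("feature column names must be unique")
    if agg not in ("mean", "sum"):
        raise InputError(f"unknown aggregation {agg!r}")

    genome = real.genome or null.genome

    def region_rows(iset: IntervalSet) -> list[list[float]]:
        rows = []
        for iv in iset:
            row = []
            for name, source in columns.items():
                if mode == "signal":
                    if agg == "mean":
                        row.append(mean_signal_over_region(source, iv))
                    else:
                        row.append(_region_sums(source, iv.chrom, iv.start, iv.end)[0])
                else:
                    gap = nearest_gap(iv, source)
                    if gap is None:
                        if genome is None or iv.chrom not in genome:
                            raise InputError(
                                f"no feature on {iv.chrom} and no genome to supply a sentinel"
                            )
                        gap = genome[iv.chrom]
                    row.append(float(gap))
            rows.append(row)
        return rows

    data = region_rows(real) + region_rows(null)
    labels = np.array([REAL] * len(real) + [NULL] * len(null))
    values = pd.DataFrame(data, columns=list(columns))
    return FeatureMatrix(
        values=values,
        labels=labels,
        mode=mode,
        provenance={
            "real": real.label,
            "null": null.label,
            "columns": list(columns),
            "agg": agg if mode == "signal" else None,
        },
    )


def train_evaluate(
    matrix: FeatureMatrix,
    n_trees: int = 700,
    seed: int = 0,
    holdout_fraction: Optional[float] = None,
    n_permutation_repeats: int = 10,
) -> ClassifierReport:
    """Fit the random-forest classifier and report its metrics.

    Default evaluation is out-of-bag (each sample scored by the trees that
    did not see it); ``holdout_fraction`` switches to a stratified
    train/test split.  Deterministic given ``seed``.
    """
    y = (matrix.labels == REAL).astype(int)
    if len(np.unique(y)) < 2:
        raise InputError("both real and null labels must be present")
    if min(np.bincount(y)) < 10:
        raise InputError("need at least 10 rows per class")
    X = matrix.values.to_numpy(float)
    rs = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))

    if holdout_fraction:
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=holdout_fraction, stratify=y, random_state=rs
        )
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=rs, n_jobs=1)
        clf.fit(X_tr, y_tr)
        prob = clf.predict_proba(X_te)[:, 1]
        y_eval, X_eval = y_te, X_te
        evaluation = f"holdout({holdout_fraction:g})"
    else:
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=rs, oob_score=True, n_jobs=1
        )
        clf.fit(X, y)
        prob = clf.oob_decision_function_[:, 1]
        # with hundreds of trees every row is out-of-bag for some tree,
        # but guard against the degenerate tiny-n case
        prob = np.nan_to_num(prob, nan=0.5)
        y_eval, X_eval = y, X
        evaluation = "oob"

    pred = (prob >= 0.5).astype(int)
    class_errors = {
        REAL: float(np.mean(pred[y_eval == 1] != 1)),
        NULL: float(np.mean(pred[y_eval == 0] != 0)),
    }
    perm = permutation_importance(
        clf,
        X_eval,
        y_eval,
        n_repeats=n_permutation_repeats,
        random_state=rs,
        scoring="accuracy",
    )
    names = matrix.feature_names
    return ClassifierReport(
        auroc=float(roc_auc_score(y_eval, prob)),
        pr_auc=float(average_precision_score(y_eval, prob)),
        class_errors=class_errors,
        importance_permutation=dict(zip(names, perm.importances_mean.tolist())),
        importance_impurity=dict(zip(names, clf.feature_importances_.tolist())),
        n_trees=n_trees,
        seed=seed,
        evaluation=evaluation,
    )
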