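"""Permutation test for DSB-feature overlap enrichment.

The observed statistic is the number of query (DSB) intervals sharing at
least one base with the feature set.  The null redraws every DSB uniformly
on its own chromosome, preserving length and per-chromosome counts
(shuffleBed-style), and the empirical one-sided p-value is

    p = #(iterations with null count >= observed) / n_iterations

with no +1 correction; when no iteration reaches the observed count the
result is displayed as the resolution bound ``p < 1/n_iterations``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import (
    Genome,
    InputError,
    IntervalSet,
    count_overlapping,
    shuffle_starts,
    _require_common_genome,
)


@dataclass
class EnrichmentResult:
    observed: int
    null_counts: list[int]
    n_iterations: int
    p_value: float
    p_display: str
    seed: int
    query_label: Optional[str] = None
    reference_label: Optional[str] = None

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_counts)) if self.null_counts else float("nan")

    def to_dict(self) -> dict:
        return {
            "query": self.query_label,
            "reference": self.reference_label,
            "observed": self.observed,
            "n_iterations": self.n_iterations,
            "p_value": self.p_value,
            "p_display": self.p_display,
            "null_mean": self.null_mean,
            "seed": self.seed,
            "null_counts": self.null_counts,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def _null_overlap_count(
    iset: IntervalSet,
    genome: Genome,
    merged_ref: dict[str, tuple[np.ndarray, np.ndarray]],
    chrom_rows: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> int:
    """One shuffle iteration without materializing an IntervalSet.

    Consumes the random stream exactly like ``shuffle_intervals`` followed by
    ``count_overlapping`` would (one vectorized draw in set order).
    """
    starts = shuffle_starts(iset, genome, rng)
    lens = iset.lengths
    total = 0
    for chrom, rows in chrom_rows.items():
        ms, me = merged_ref[chrom]
        if ms.size == 0:
            continue
        qs = starts[rows]
        qe = qs + lens[rows]
        pos = np.searchsorted(me, qs, side="right")
        hit = (pos < ms.size) & (ms[np.minimum(pos, ms.size - 1)] < qe)
        total += int(hit.sum())
    return total


def permutation_enrichment(
    dsbs: IntervalSet,
    feature: IntervalSet,
    genome: Genome,
    n_iterations: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """One-sided permutation enrichment of ``dsbs`` in ``feature``.

    Each iteration draws from an iteration-specific substream of ``seed``
    (``SeedSequence(seed).spawn``), so iterations are order-independent.
    """
    if n_iterations < 1:
        raise InputError("n_iterations must be >= 1")
    _require_common_genome(dsbs, feature)
    labels = dict(query_label=dsbs.label, reference_label=feature.label)
    if len(dsbs) == 0:
        warnings.warn("empty DSB set: enrichment is undefined, returning p = 1.0")
        return EnrichmentResult(
            observed=0,
            null_counts=[0] * n_iterations,
            n_iterations=n_iterations,
            p_value=1.0,
            p_display="1",
            seed=seed,
            **labels,
        )
    observed = count_overlapping(dsbs, feature)
    merged_ref = {c: feature.merged_by_chrom(c) for c in dsbs._indices_by_chrom()}
    chrom_rows = dsbs._indices_by_chrom()
    children = np.random.SeedSequence(seed).spawn(n_iterations)
    null_counts = [
        _null_overlap_count(dsbs, genome, merged_ref, chrom_rows, np.random.default_rng(child))
        for child in children
    ]
    exceed = int(sum(c >= observed for c in null_counts))
    p_value = exceed / n_iterations
    p_display = f"p < {1 / n_iterations:g}" if exceed == 0 else f"{p_value:g}"
    return EnrichmentResult(
        observed=observed,
        null_counts=null_counts,
        n_iterations=n_iterations,
        p_value=p_value,
        p_display=p_display,
        seed=seed,
        **labels,
    )
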