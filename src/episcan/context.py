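"""Condition set algebra and gene-context statistics.

Covers the descriptive layer of the analysis: DSBs shared with / unique to
a condition, the fraction of DSBs in genic regions, per-chromosome DSB
density, and counts/densities of hits stratified by gene size class.

Gene size classes are half-open in kb: [1, 100), [100, 300), [300, 800),
[800, inf).  Genes shorter than 1 kb enter no class.  A hit spanning genes
of two classes is tallied once in each class, so stacked class totals can
exceed the number of hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    Genome,
    GenomicInterval,
    InputError,
    IntervalSet,
    count_overlapping,
    overlap_mask,
)

SIZE_CLASS_BOUNDS_KB: tuple[tuple[float, float], ...] = (
    (1, 100),
    (100, 300),
    (300, 800),
    (800, float("inf")),
)
SIZE_CLASS_LABELS: tuple[str, ...] = ("1-100", "100-300", "300-800", ">800")


@dataclass(frozen=True)
class GeneModel:
    """A gene-level span with its size class."""

    interval: GenomicInterval
    gene_id: str

    @property
    def length_kb(self) -> float:
        return self.interval.length / 1000.0

    @property
    def size_class(self) -> Optional[str]:
        kb = self.length_kb
        for (lo, hi), label in zip(SIZE_CLASS_BOUNDS_KB, SIZE_CLASS_LABELS):
            if lo <= kb < hi:
                return label
        return None  # < 1 kb


@dataclass
class SizeClassSummary:
    """Per-class gene counts, total genic Mb, hit counts and per-Mb density."""

    n_genes: dict[str, int]
    total_gene_mb: dict[str, float]
    n_hits: dict[str, int]
    density_per_mb: dict[str, Optional[float]]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size_class": list(SIZE_CLASS_LABELS),
                "n_genes": [self.n_genes[c] for c in SIZE_CLASS_LABELS],
                "total_gene_mb": [self.total_gene_mb[c] for c in SIZE_CLASS_LABELS],
                "n_hits": [self.n_hits[c] for c in SIZE_CLASS_LABELS],
                "density_per_mb": [self.density_per_mb[c] for c in SIZE_CLASS_LABELS],
            }
        )


def genes_from_intervals(genes: IntervalSet) -> list[GeneModel]:
    """Wrap an interval set as gene models, one per interval.

    When several intervals share a name (isoforms), only the longest is
    kept, giving one span per gene symbol.
    """
    best: dict[str, GenomicInterval] = {}
    anon = 0
    for iv in genes:
        gid = iv.name
        if gid is None:
            gid = f"gene{anon}"
            anon += 1
        if gid not in best or iv.length > best[gid].length:
            best[gid] = iv
    return [GeneModel(iv, gid) for gid, iv in best.items()]


def condition_sets(
    a: IntervalSet, others: Sequence[IntervalSet]
) -> tuple[IntervalSet, IntervalSet]:
    """Split ``a`` into (shared, unique) against the union of ``others``.

    unique = intervals of ``a`` overlapping (>= 1 bp) nothing in any other
    set; shared = the rest.  |shared| + |unique| == |a|.
    """
    hit = np.zeros(len(a), dtype=bool)
    for other in others:
        hit |= overlap_mask(a, other)
    label = a.label or "set"
    return (
        a.subset(hit, label=f"{label}|shared"),
        a.subset(~hit, label=f"{label}|unique"),
    )


def genic_fraction(dsbs: IntervalSet, genes: IntervalSet) -> float:
    """Fraction of DSB intervals overlapping >= 1 gene."""
    if len(dsbs) == 0:
        raise InputError("genic fraction is undefined for an empty DSB set")
    return count_overlapping(dsbs, genes) / len(dsbs)


def chromosome_density(dsbs: IntervalSet, genome: Genome) -> dict[str, float]:
    """DSB count per Mb for every chromosome of the genome."""
    counts = dsbs.counts_per_chrom()
    return {
        chrom: 1e6 * counts.get(chrom, 0) / genome[chrom] for chrom in genome
    }


def gene_size_stats(hits: IntervalSet, genes: Sequence[GeneModel]) -> SizeClassSummary:
    """Hit counts and per-Mb densities stratified by gene size class."""
    n_genes = {c: 0 for c in SIZE_CLASS_LABELS}
    total_mb = {c: 0.0 for c in SIZE_CLASS_LABELS}
    per_class_ivs: dict[str, list[GenomicInterval]] = {c: [] for c in SIZE_CLASS_LABELS}
    for gene in genes:
        cls = gene.size_class
        if cls is None:
            continue
        n_genes[cls] += 1
        total_mb[cls] += gene.interval.length / 1e6
        per_class_ivs[cls].append(gene.interval)
    n_hits = {}
    density = {}
    for cls in SIZE_CLASS_LABELS:
        class_set = IntervalSet(per_class_ivs[cls], genome=hits.genome)
        n = count_overlapping(hits, class_set) if len(class_set) else 0
        n_hits[cls] = n
        density[cls] = (n / total_mb[cls]) if total_mb[cls] > 0 else None
    return SizeClassSummary(
        n_genes=n_genes, total_gene_mb=total_mb, n_hits=n_hits, density_per_mb=density
    )
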