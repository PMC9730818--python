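"""Genomic interval data model and interval algebra.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  Adjacency (``end == start`` of the neighbour) is *not*
overlap, but it is a zero-base gap for distance purposes.  Strand is carried
for provenance only and ignored by every overlap/distance computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Union

import numpy as np
import pandas as pd


class EpiscanError(Exception):
    """Base class for all package errors."""


class InputError(EpiscanError):
    """Malformed or out-of-contract input data."""


class GenomeMismatchError(EpiscanError):
    """Two objects bound to different genomes were combined."""


SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


def as_rng(seed: SeedLike) -> np.random.Generator:
    """Return a numpy Generator from an int seed, SeedSequence, or Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class Genome:
    """Chromosome name -> length (bp) mapping.

    Names must be unique (guaranteed by the dict) and lengths positive.
    """

    def __init__(self, sizes: Mapping[str, int]):
        if not sizes:
            raise InputError("genome must contain at least one chromosome")
        for name, length in sizes.items():
            if int(length) < 1:
                raise InputError(f"chromosome {name!r} has non-positive length {length}")
        self._sizes = {str(k): int(v) for k, v in sizes.items()}

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self._sizes == other._sizes

    def __repr__(self) -> str:
        return f"Genome({len(self._sizes)} chromosomes, {self.total_bp:,} bp)"

    @property
    def chromosomes(self) -> list[str]:
        return list(self._sizes)

    @property
    def total_bp(self) -> int:
        return sum(self._sizes.values())

    def sizes(self) -> dict[str, int]:
        return dict(self._sizes)


@dataclass(frozen=True)
class GenomicInterval:
    """A single half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: Optional[str] = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise InputError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in (None, "+", "-", "."):
            raise InputError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Representative point, floor((start + end) / 2)."""
        return (self.start + self.end) // 2


def _merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping intervals into sorted disjoint blocks."""
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s = starts[order]
    e = np.maximum.accumulate(ends[order])
    # a new block begins where a start exceeds the running max end so far
    new_block = np.empty(s.size, dtype=bool)
    new_block[0] = True
    new_block[1:] = s[1:] > e[:-1]
    idx = np.flatnonzero(new_block)
    ms = s[idx]
    me = e[np.append(idx[1:], s.size) - 1]
    return ms, me


class IntervalSet:
    """Ordered collection of :class:`GenomicInterval`, optionally genome-bound.

    Duplicated intervals are permitted but flagged with a warning, mirroring
    how peak/DSB call files occasionally carry duplicate rows.
    """

    _COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome: Optional[Genome] = None,
        label: Optional[str] = None,
        _frame: Optional[pd.DataFrame] = None,
    ):
        if _frame is not None:
            df = _frame
        else:
            rows = [
                (iv.chrom, iv.start, iv.end, iv.name, iv.score, iv.strand)
                for iv in intervals
            ]
            df = pd.DataFrame(rows, columns=self._COLUMNS)
            if df.empty:
                df = pd.DataFrame(
                    {
                        "chrom": pd.Series(dtype=object),
                        "start": pd.Series(dtype=np.int64),
                        "end": pd.Series(dtype=np.int64),
                        "name": pd.Series(dtype=object),
                        "score": pd.Series(dtype=float),
                        "strand": pd.Series(dtype=object),
                    }
                )
        df = df.reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
            bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])][0]
            raise InputError(f"invalid interval at row {bad}: require 0 <= start < end")
        self._df = df
        self.genome = genome
        self.label = label
        self._by_chrom_cache: Optional[dict[str, np.ndarray]] = None
        self._merged_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if genome is not None:
            self._validate_bounds()
        if len(df) and df.duplicated(subset=["chrom", "start", "end"]).any():
            n_dup = int(df.duplicated(subset=["chrom", "start", "end"]).sum())
            warnings.warn(
                f"IntervalSet {label or ''!s} contains {n_dup} duplicated interval(s)",
                stacklevel=2,
            )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        genome: Optional[Genome] = None,
        label: Optional[str] = None,
    ) -> "IntervalSet":
        frame = pd.DataFrame(index=range(len(df)))
        frame["chrom"] = df["chrom"].astype(str).to_numpy()
        frame["start"] = df["start"].to_numpy()
        frame["end"] = df["end"].to_numpy()
        for col in ("name", "score", "strand"):
            frame[col] = df[col].to_numpy() if col in df.columns else None
        return cls(genome=genome, label=label, _frame=frame)

    def _validate_bounds(self):
        assert self.genome is not None
        for chrom, idx in self._indices_by_chrom().items():
            if chrom not in self.genome:
                raise InputError(f"chromosome {chrom!r} not in genome")
            ends = self._df["end"].to_numpy()[idx]
            if (ends > self.genome[chrom]).any():
                raise InputError(
                    f"interval on {chrom} exceeds chromosome length {self.genome[chrom]}"
                )

    # ---- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self._df.itertuples(index=False):
            yield GenomicInterval(
                row.chrom,
                int(row.start),
                int(row.end),
                None if pd.isna(row.name) else row.name,
                None if row.score is None or (isinstance(row.score, float) and np.isnan(row.score)) else float(row.score),
                None if pd.isna(row.strand) else row.strand,
            )

    def __repr__(self) -> str:
        return f"IntervalSet({self.label or 'unlabeled'}, n={len(self)})"

    def to_dataframe(self) -> pd.DataFrame:
        return self._df.copy()

    # ---- derived views ------------------------------------------------------

    @property
    def chroms(self) -> np.ndarray:
        return self._df["chrom"].to_numpy()

    @property
    def starts(self) -> np.ndarray:
        return self._df["start"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self._df["end"].to_numpy()

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def _indices_by_chrom(self) -> dict[str, np.ndarray]:
        if self._by_chrom_cache is None:
            chroms = self._df["chrom"].to_numpy()
            self._by_chrom_cache = {
                str(c): np.flatnonzero(chroms == c) for c in pd.unique(chroms)
            }
        return self._by_chrom_cache

    def counts_per_chrom(self) -> dict[str, int]:
        return {c: int(idx.size) for c, idx in self._indices_by_chrom().items()}

    def merged_by_chrom(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted, disjoint union blocks for one chromosome (cached)."""
        if chrom not in self._merged_cache:
            idx = self._indices_by_chrom().get(chrom)
            if idx is None or idx.size == 0:
                empty = np.empty(0, dtype=np.int64)
                self._merged_cache[chrom] = (empty, empty)
            else:
                self._merged_cache[chrom] = _merge(self.starts[idx], self.ends[idx])
        return self._merged_cache[chrom]

    def total_bp(self) -> int:
        """Total covered bases after merging overlaps."""
        total = 0
        for chrom in self._indices_by_chrom():
            ms, me = self.merged_by_chrom(chrom)
            total += int((me - ms).sum())
        return total

    def subset(self, mask: np.ndarray, label: Optional[str] = None) -> "IntervalSet":
        return IntervalSet(
            genome=self.genome,
            label=label if label is not None else self.label,
            _frame=self._df.loc[np.asarray(mask)].reset_index(drop=True),
        )

    def sorted(self) -> "IntervalSet":
        df = self._df.sort_values(["chrom", "start", "end"], kind="stable")
        return IntervalSet(genome=self.genome, label=self.label, _frame=df.reset_index(drop=True))


def _require_common_genome(a: IntervalSet, b: IntervalSet):
    if a.genome is not None and b.genome is not None and a.genome != b.genome:
        raise GenomeMismatchError("interval sets are bound to different genomes")


def overlap_mask(
    query: IntervalSet, reference: IntervalSet, min_overlap_bp: int = 1
) -> np.ndarray:
    """Boolean mask over ``query`` rows: True where the interval shares at
    least ``min_overlap_bp`` bases with at least one ``reference`` interval."""
    if min_overlap_bp < 1:
        raise InputError("min_overlap_bp must be a positive integer")
    _require_common_genome(query, reference)
    out = np.zeros(len(query), dtype=bool)
    if len(reference) == 0 or len(query) == 0:
        return out
    ref_idx = reference._indices_by_chrom()
    for chrom, qidx in query._indices_by_chrom().items():
        if chrom not in ref_idx:
            continue
        qs = query.starts[qidx]
        qe = query.ends[qidx]
        if min_overlap_bp == 1:
            ms, me = reference.merged_by_chrom(chrom)
            pos = np.searchsorted(me, qs, side="right")
            ok = pos < ms.size
            hit = ok & (ms[np.minimum(pos, ms.size - 1)] < qe)
            out[qidx] = hit
        else:
            # min-overlap against *individual* reference intervals, so no merge
            ridx = ref_idx[chrom]
            order = np.argsort(reference.starts[ridx], kind="stable")
            rs = reference.starts[ridx][order]
            re_ = reference.ends[ridx][order]
            cummax_e = np.maximum.accumulate(re_)
            hit = np.zeros(qidx.size, dtype=bool)
            for i in range(qidx.size):
                hi = np.searchsorted(rs, qe[i], side="left")
                lo = np.searchsorted(cummax_e[:hi], qs[i], side="right")
                if lo >= hi:
                    continue
                ov = np.minimum(re_[lo:hi], qe[i]) - np.maximum(rs[lo:hi], qs[i])
                hit[i] = bool((ov >= min_overlap_bp).any())
            out[qidx] = hit
    return out


def count_overlapping(
    query: IntervalSet, reference: IntervalSet, min_overlap_bp: int = 1
) -> int:
    """Number of query intervals overlapping >= 1 reference interval by at
    least ``min_overlap_bp`` shared bases; each query counted at most once."""
    return int(overlap_mask(query, reference, min_overlap_bp).sum())


def nearest_gap(query: GenomicInterval, reference: IntervalSet) -> Optional[int]:
    """Edge-to-edge base gap from ``query`` to the closest reference interval
    on the same chromosome; 0 on overlap (or exact adjacency); None when the
    chromosome carries no reference interval."""
    ms, me = reference.merged_by_chrom(query.chrom)
    if ms.size == 0:
        return None
    pos = int(np.searchsorted(me, query.start, side="right"))
    if pos < ms.size and ms[pos] < query.end:
        return 0
    best = None
    if pos < ms.size:  # nearest block to the right (or adjacent)
        best = int(ms[pos] - query.end)
    if pos >= 1:
        left = int(query.start - me[pos - 1])
        best = left if best is None else min(best, left)
    return best


def shuffle_intervals(
    iset: IntervalSet, genome: Genome, seed: SeedLike
) -> IntervalSet:
    """Uniform same-chromosome, length-preserving shuffle (shuffleBed-style
    null with per-chromosome counts fixed).  Output intervals may overlap
    one another; deterministic given ``seed``."""
    rng = as_rng(seed)
    starts = shuffle_starts(iset, genome, rng)
    df = iset.to_dataframe()
    df["start"] = starts
    df["end"] = starts + iset.lengths
    label = f"{iset.label}|shuffled" if iset.label else "shuffled"
    return IntervalSet(genome=genome, label=label, _frame=df)


def shuffle_starts(
    iset: IntervalSet, genome: Genome, rng: np.random.Generator
) -> np.ndarray:
    """Draw one uniform start per interval over {0 .. chrom_len - len}.

    Single vectorized draw in set order, so a full shuffle consumes the
    random stream identically whether built through :func:`shuffle_intervals`
    or the enrichment fast path.
    """
    lens = iset.lengths
    chrom_lens = np.array([genome[c] for c in iset.chroms], dtype=np.int64)
    highs = chrom_lens - lens + 1
    if (highs < 1).any():
        bad = int(np.flatnonzero(highs < 1)[0])
        raise InputError(
            f"interval row {bad} ({iset.chroms[bad]}) longer than its chromosome"
        )
    return rng.integers(0, highs, dtype=np.int64)
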