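"""Stepwise-constant signal tracks and region summarization.

A :class:`SignalTrack` models bedGraph/bigWig semantics: within each
chromosome, a sorted list of disjoint half-open segments each carrying one
finite value; bases not covered by any segment have no value.  Region
summaries follow the two conventions of bigWigAverageOverBed: ``mean0``
(uncovered bases count as zero, the default here) and ``mean`` (divide by
covered bases only).
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .core import Genome, GenomicInterval, InputError, IntervalSet


class SignalTrack:
    """Per-chromosome disjoint (start, end, value) segments."""

    def __init__(
        self,
        segments: Iterable[tuple[str, int, int, float]] = (),
        genome: Optional[Genome] = None,
        label: Optional[str] = None,
    ):
        rows = [(str(c), int(s), int(e), float(v)) for c, s, e, v in segments]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        if df.empty:
            df = df.astype({"start": np.int64, "end": np.int64, "value": float})
        if len(df):
            if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
                raise InputError("track segments require 0 <= start < end")
            if not np.isfinite(df["value"].to_numpy()).all():
                raise InputError("track values must be finite")
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        self._per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            s = sub["start"].to_numpy(np.int64)
            e = sub["end"].to_numpy(np.int64)
            v = sub["value"].to_numpy(float)
            if (s[1:] < e[:-1]).any():
                raise InputError(f"overlapping segments on {chrom}")
            if genome is not None:
                if chrom not in genome:
                    raise InputError(f"chromosome {chrom!r} not in genome")
                if e[-1] > genome[chrom]:
                    raise InputError(f"segment on {chrom} exceeds chromosome length")
            self._per_chrom[str(chrom)] = (s, e, v)
        self.genome = genome
        self.label = label

    def __repr__(self) -> str:
        return f"SignalTrack({self.label or 'unlabeled'}, {self.n_segments} segments)"

    @property
    def n_segments(self) -> int:
        return sum(s.size for s, _, _ in self._per_chrom.values())

    @property
    def chromosomes(self) -> list[str]:
        return list(self._per_chrom)

    def chrom_arrays(self, chrom: str):
        """(starts, ends, values) for one chromosome, or empty arrays."""
        if chrom in self._per_chrom:
            return self._per_chrom[chrom]
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, np.empty(0, dtype=float)

    def segments(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom, (s, e, v) in self._per_chrom.items():
            for i in range(s.size):
                yield chrom, int(s[i]), int(e[i]), float(v[i])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.segments()), columns=["chrom", "start", "end", "value"]
        )

    def segment_values(self) -> np.ndarray:
        """The multiset of all segment values (genomic background for
        bin-level score comparisons)."""
        if not self._per_chrom:
            return np.empty(0, dtype=float)
        return np.concatenate([v for _, _, v in self._per_chrom.values()])


def _region_sums(
    track: SignalTrack, chrom: str, start: int, end: int
) -> tuple[float, int]:
    """(sum of value*bases, covered bases) over [start, end)."""
    s, e, v = track.chrom_arrays(chrom)
    if s.size == 0:
        return 0.0, 0
    lo = int(np.searchsorted(e, start, side="right"))
    hi = int(np.searchsorted(s, end, side="left"))
    if lo >= hi:
        return 0.0, 0
    bases = np.minimum(e[lo:hi], end) - np.maximum(s[lo:hi], start)
    bases = np.clip(bases, 0, None)
    return float((bases * v[lo:hi]).sum()), int(bases.sum())


def mean_signal_over_region(
    track: SignalTrack, interval: GenomicInterval, uncovered_as_zero: bool = True
) -> float:
    """Mean track value over ``interval``.

    ``uncovered_as_zero=True`` divides the per-base sum by the interval
    length (mean0); ``False`` divides by covered bases only (0.0 when the
    interval is entirely uncovered).
    """
    total, covered = _region_sums(track, interval.chrom, interval.start, interval.end)
    if uncovered_as_zero:
        return total / interval.length
    return total / covered if covered else 0.0


def region_coverage(track: SignalTrack, interval: GenomicInterval) -> int:
    """Covered bases of ``interval`` (0 when the track misses it entirely)."""
    return _region_sums(track, interval.chrom, interval.start, interval.end)[1]


def binned_track_from_intervals(bins: IntervalSet) -> SignalTrack:
    """Lossless conversion of scored, non-overlapping bins into a track."""
    scores = bins.to_dataframe()["score"]
    if len(bins) and scores.isna().any():
        raise InputError("all bins must carry a score")
    segs = zip(bins.chroms, bins.starts, bins.ends, scores.to_numpy(float))
    try:
        return SignalTrack(segs, genome=bins.genome, label=bins.label)
    except InputError as exc:
        if "overlapping" in str(exc):
            raise InputError("bins must be non-overlapping") from exc
        raise
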