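"""Feature-centered aggregation profiles of DSBs.

For each DSB (represented by its interval midpoint) the signed offset to a
feature center is binned over a fixed window, producing the classic
metafeature plot: counts per bin against distance from the marker center.
Two modes: ``nearest`` uses only the closest feature center on the same
chromosome (ties broken toward the leftmost feature); ``all`` counts the
DSB once for every feature whose center lies within the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import InputError, IntervalSet


@dataclass
class AggregationProfile:
    window_bp: int
    n_bins: int
    bin_counts: np.ndarray  # length n_bins, nonnegative ints
    mode: str
    query_label: Optional[str] = None
    feature_label: Optional[str] = None

    @property
    def bin_width(self) -> int:
        return self.window_bp // self.n_bins

    def bin_edges(self) -> np.ndarray:
        """Offset edges, length n_bins + 1, from -window/2 to +window/2."""
        half = self.window_bp // 2
        return np.arange(self.n_bins + 1) * self.bin_width - half

    def to_dataframe(self) -> pd.DataFrame:
        edges = self.bin_edges()
        return pd.DataFrame(
            {
                "bin": np.arange(self.n_bins),
                "offset_start": edges[:-1],
                "offset_end": edges[1:],
                "count": self.bin_counts,
            }
        )

    def total(self) -> int:
        return int(self.bin_counts.sum())


def feature_centers(features: IntervalSet) -> dict[str, np.ndarray]:
    """Sorted feature centers (floor midpoint) per chromosome."""
    out = {}
    for chrom, rows in features._indices_by_chrom().items():
        centers = (features.starts[rows] + features.ends[rows]) // 2
        out[chrom] = np.sort(centers)
    return out


def aggregate_profile(
    dsbs: IntervalSet,
    features: IntervalSet,
    window_bp: int = 20_000,
    n_bins: int = 50,
    mode: str = "nearest",
) -> AggregationProfile:
    if len(features) == 0:
        raise InputError("feature set must be nonempty")
    if window_bp <= 0 or window_bp % 2 or window_bp % n_bins:
        raise InputError("window_bp must be even, positive, and divisible by n_bins")
    if mode not in ("nearest", "all"):
        raise InputError(f"unknown mode {mode!r}")
    half = window_bp // 2
    bin_width = window_bp // n_bins
    centers = feature_centers(features)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom, rows in dsbs._indices_by_chrom().items():
        if chrom not in centers:
            continue
        c = centers[chrom]
        mids = (dsbs.starts[rows] + dsbs.ends[rows]) // 2
        if mode == "nearest":
            pos = np.searchsorted(c, mids, side="right")
            left = np.clip(pos - 1, 0, c.size - 1)
            right = np.clip(pos, 0, c.size - 1)
            d_left = np.abs(mids - c[left])
            d_right = np.abs(c[right] - mids)
            # tie -> leftmost feature
            use_left = (d_left <= d_right) | (right == left)
            chosen = np.where(use_left, c[left], c[right])
            offsets = mids - chosen
            idx = (offsets + half) // bin_width
            ok = (idx >= 0) & (idx < n_bins)
            np.add.at(counts, idx[ok].astype(np.int64), 1)
        else:
            for m in mids:
                lo = np.searchsorted(c, m - half, side="left")
                hi = np.searchsorted(c, m + half, side="right")
                offsets = m - c[lo:hi]
                idx = (offsets + half) // bin_width
                ok = (idx >= 0) & (idx < n_bins)
                np.add.at(counts, idx[ok].astype(np.int64), 1)
    return AggregationProfile(
        window_bp=window_bp,
        n_bins=n_bins,
        bin_counts=counts,
        mode=mode,
        query_label=dsbs.label,
        feature_label=features.label,
    )
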