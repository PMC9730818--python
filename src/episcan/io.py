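"""Readers and writers for the BED-family plain-text formats.

Supported: chrom.sizes (two-column TSV), BED3/BED6, ENCODE narrowPeak
(BED6+4; the four extra columns are parsed but unused downstream), and
4-column bedGraph.  All region readers validate coordinates against the
bound genome and report offending line numbers.  A bigWig reader is
available when pyBigWig is importable; bedGraph is the canonical
interchange so nothing else depends on a binary format.
"""

from __future__ import annotations

import os
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import Genome, InputError, IntervalSet
from .tracks import SignalTrack

PathLike = Union[str, os.PathLike]


def read_chrom_sizes(path: PathLike) -> Genome:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise InputError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise InputError(f"{path}:{lineno}: length {fields[1]!r} is not an integer")
            if name in sizes:
                raise InputError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            if length < 1:
                raise InputError(f"{path}:{lineno}: non-positive length {length}")
            sizes[name] = length
    if not sizes:
        raise InputError(f"{path}: no chromosomes found")
    return Genome(sizes)


def write_chrom_sizes(genome: Genome, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f"{chrom}\t{genome[chrom]}\n")


def _data_lines(path: PathLike):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            yield lineno, stripped.split("\t")


def _parse_coords(path, lineno, fields, genome: Optional[Genome]):
    if len(fields) < 3:
        raise InputError(f"{path}:{lineno}: expected at least 3 columns")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise InputError(f"{path}:{lineno}: non-integer coordinates")
    if not (0 <= start < end):
        raise InputError(f"{path}:{lineno}: require 0 <= start < end, got {start}-{end}")
    if genome is not None:
        if chrom not in genome:
            raise InputError(f"{path}:{lineno}: chromosome {chrom!r} not in genome")
        if end > genome[chrom]:
            raise InputError(
                f"{path}:{lineno}: end {end} exceeds {chrom} length {genome[chrom]}"
            )
    return chrom, start, end


def read_bed(
    path: PathLike, genome: Optional[Genome] = None, label: Optional[str] = None
) -> IntervalSet:
    """Read BED3/BED6 (or wider; extra columns ignored)."""
    rows = []
    for lineno, fields in _data_lines(path):
        chrom, start, end = _parse_coords(path, lineno, fields, genome)
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score = None
        if len(fields) > 4 and fields[4] not in (".", ""):
            try:
                score = float(fields[4])
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-numeric score {fields[4]!r}")
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-", ".") else None
        rows.append((chrom, start, end, name, score, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    if df.empty:
        return IntervalSet(genome=genome, label=label or _stem(path))
    return IntervalSet.from_dataframe(df, genome=genome, label=label or _stem(path))


def read_narrowpeak(
    path: PathLike, genome: Optional[Genome] = None, label: Optional[str] = None
) -> IntervalSet:
    """Read ENCODE narrowPeak (BED6+4).  signalValue/pValue/qValue/summit
    are validated as numeric but not retained."""
    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 10:
            raise InputError(f"{path}:{lineno}: narrowPeak requires 10 columns")
        chrom, start, end = _parse_coords(path, lineno, fields, genome)
        name = fields[3] if fields[3] != "." else None
        score = float(fields[4]) if fields[4] not in (".", "") else None
        strand = fields[5] if fields[5] in ("+", "-", ".") else None
        try:
            [float(x) for x in fields[6:9]]
            int(fields[9])
        except ValueError:
            raise InputError(f"{path}:{lineno}: malformed narrowPeak statistics columns")
        rows.append((chrom, start, end, name, score, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    if df.empty:
        return IntervalSet(genome=genome, label=label or _stem(path))
    return IntervalSet.from_dataframe(df, genome=genome, label=label or _stem(path))


def write_bed(iset: IntervalSet, path: PathLike) -> None:
    """Write BED6 when any name/score/strand is present, else BED3."""
    df = iset.to_dataframe()
    bed6 = df[["name", "score", "strand"]].notna().any().any()
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            if bed6:
                name = row.name if not pd.isna(row.name) else "."
                score = "0" if pd.isna(row.score) else f"{row.score:g}"
                strand = row.strand if not pd.isna(row.strand) else "."
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t{score}\t{strand}\n")
            else:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")


def read_bedgraph(
    path: PathLike, genome: Optional[Genome] = None, label: Optional[str] = None
) -> SignalTrack:
    segs = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise InputError(f"{path}:{lineno}: bedGraph requires 4 columns")
        chrom, start, end = _parse_coords(path, lineno, fields, genome)
        try:
            value = float(fields[3])
        except ValueError:
            raise InputError(f"{path}:{lineno}: non-numeric value {fields[3]!r}")
        segs.append((chrom, start, end, value))
    return SignalTrack(segs, genome=genome, label=label or _stem(path))


def write_bedgraph(track: SignalTrack, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.segments():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_bigwig(
    path: PathLike, genome: Optional[Genome] = None, label: Optional[str] = None
) -> SignalTrack:
    """Convert a bigWig file to a SignalTrack (requires pyBigWig)."""
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover
        raise InputError("bigWig support requires the pyBigWig package") from exc
    segs = []
    with pyBigWig.open(str(path)) as bw:
        for chrom in bw.chroms():
            ivs = bw.intervals(chrom)
            if ivs:
                for start, end, value in ivs:
                    if not np.isnan(value):
                        segs.append((chrom, start, end, float(value)))
    return SignalTrack(segs, genome=genome, label=label or _stem(path))


def _stem(path: PathLike) -> str:
    return os.path.splitext(os.path.basename(os.fspath(path)))[0]
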