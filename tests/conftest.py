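import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from episcan import Genome, GenomicInterval, IntervalSet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_genome():
    return Genome({"chr1": 100_000, "chr2": 50_000})


def make_set(intervals, genome=None, label=None):
    """Build an IntervalSet from (chrom, start, end[, name]) tuples."""
    ivs = [GenomicInterval(*t) for t in intervals]
    return IntervalSet(ivs, genome=genome, label=label)


def random_set(rng, genome, n, max_len=500, label=None):
    """Uniform random intervals for oracle-equivalence checks."""
    chroms = list(genome)
    rows = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, genome[chrom] - length + 1))
        rows.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(rows, genome=genome, label=label)


def brute_count_overlapping(query, reference, min_overlap_bp=1):
    """All-pairs scan: number of query intervals sharing >= min_overlap_bp
    bases with at least one reference interval."""
    refs = [(iv.chrom, iv.start, iv.end) for iv in reference]
    count = 0
    for q in query:
        for chrom, s, e in refs:
            if chrom != q.chrom:
                continue
            if min(e, q.end) - max(s, q.start) >= min_overlap_bp:
                count += 1
                break
    return count


def brute_mean_signal(track, interval, uncovered_as_zero=True):
    """Per-base accumulation over a (small) interval."""
    per_base = {}
    for chrom, s, e, v in track.segments():
        if chrom != interval.chrom:
            continue
        for pos in range(max(s, interval.start), min(e, interval.end)):
            per_base[pos] = v
    total = sum(per_base.values())
    if uncovered_as_zero:
        return total / interval.length
    return total / len(per_base) if per_base else 0.0


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared across tests (seed 0)."""
    from episcan import generate_dataset

    return generate_dataset()
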