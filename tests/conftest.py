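import numpy as np
import pytest

from caplocus.intervals import GenomicInterval, IntervalSet


def brute_force_overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """O(1) reference predicate, written independently of the interval-tree path."""
    if a.chrom != b.chrom:
        return False
    lo, hi = max(a.start, b.start), min(a.end, b.end)
    return hi - lo >= min_bp


def brute_force_count_overlapping(predicted, reference, min_bp: int = 1) -> int:
    """O(n*m) all-pairs count of predicted intervals hitting the reference."""
    return sum(
        1
        for p in predicted
        if any(brute_force_overlaps(p, r, min_bp) for r in reference)
    )


def random_interval_set(rng: np.random.Generator, n: int, n_chroms: int = 3,
                        span: int = 10_000, max_len: int = 500) -> IntervalSet:
    ivs = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len + 1))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(ivs)


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)
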