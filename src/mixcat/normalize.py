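"""Digital normalization of pooled reads by k-mer depth.

Before co-assembling many samples, reads from highly abundant genomes are
downsampled to a target depth and reads whose k-mers look like sequencing
errors (depth below a minimum) are discarded.  The depth of a read is the
median count of its canonical k-mers in an exact count table built from the
full pooled input; a read of depth *d* is then kept with probability
``min(1, target_depth / d)`` when ``d >= min_depth`` and dropped otherwise.

Counting happens in a single pass over the complete input before any read is
filtered, so the depth estimates are deterministic and independent of the
filtering order; the kept/dropped decisions use one uniform draw per read (or
read pair), which makes the kept set monotone in ``target_depth`` under
common random numbers.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .records import Read, ReadSet

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NormalizeConfig:
    """Depth-normalization parameters (defaults: target 70x, error floor 2x)."""

    k: int = 31
    target_depth: int = 70
    min_depth: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 15 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 15")
        if not 1 <= self.min_depth <= self.target_depth:
            raise ValueError("need 1 <= min_depth <= target_depth")


def canonical_kmers(seq: str, k: int) -> list[str]:
    """Canonical (lexicographic min of strand pair) k-mers of a sequence."""
    rc = reverse_complement(seq)
    n = len(seq)
    return [min(seq[i : i + k], rc[n - k - i : n - i]) for i in range(n - k + 1)]


def count_kmers(reads: Iterable[Read], k: int) -> Counter:
    counts: Counter = Counter()
    for read in reads:
        if len(read.sequence) >= k:
            counts.update(canonical_kmers(read.sequence, k))
    return counts


def kmer_depth_profile(
    reads: Sequence[Read], k: int, counts: Counter | None = None
) -> list[float | None]:
    """Per-read depth: median count of the read's k-mers in the pooled table.

    Reads shorter than *k* have undefined depth (``None``); they are passed
    through by normalization and logged.
    """
    if not reads:
        raise ValueError("empty read list")
    if counts is None:
        counts = count_kmers(reads, k)
    depths: list[float | None] = []
    for read in reads:
        if len(read.sequence) < k:
            logger.warning(
                "read %s shorter than k=%d: depth undefined, passed through",
                read.read_id,
                k,
            )
            depths.append(None)
        else:
            kmer_counts = [counts[km] for km in canonical_kmers(read.sequence, k)]
            depths.append(float(np.median(kmer_counts)))
    return depths


def normalize_reads(readset: ReadSet, config: NormalizeConfig) -> ReadSet:
    """Filter a read set to the target depth; returns a subset in input order.

    Paired reads (same read_id, mates 1 and 2) are kept or dropped as a unit
    using the lower of the two mates' depths, so no mate is orphaned.
    """
    reads = readset.reads
    if not reads:
        return ReadSet(sample_id=readset.sample_id, reads=[])
    counts = count_kmers(reads, config.k)
    depths = kmer_depth_profile(reads, config.k, counts)

    # group mates into units sharing one keep/drop decision
    unit_of: dict[str, list[int]] = {}
    for i, read in enumerate(reads):
        unit_of.setdefault(read.read_id, []).append(i)

    rng = np.random.default_rng(config.seed)
    keep = [False] * len(reads)
    for read_id in unit_of:  # insertion order = input order of first mate
        idxs = unit_of[read_id]
        unit_depths = [depths[i] for i in idxs if depths[i] is not None]
        u = rng.random()
        if not unit_depths:  # all mates shorter than k: pass through
            decision = True
        else:
            d = min(unit_depths)
            if d < config.min_depth:
                decision = False
            else:
                decision = u < min(1.0, config.target_depth / d)
        for i in idxs:
            keep[i] = decision
    kept = [r for r, k_ in zip(reads, keep) if k_]
    logger.info(
        "normalized %s: kept %d / %d reads (target=%dx, min_depth=%dx, k=%d)",
        readset.sample_id,
        len(kept),
        len(reads),
        config.target_depth,
        config.min_depth,
        config.k,
    )
    return ReadSet(sample_id=readset.sample_id, reads=kept)
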