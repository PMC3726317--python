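"""Quality trimming and construction of equalized, subsampled read sets.

Trimming removes low-quality bases iteratively from both read ends at a
fixed phred threshold (default Q20); interior low-quality bases are
kept. Libraries of unequal size and read length are made comparable by
hard-clipping every read to a common length and subsampling each
library, without replacement, down to the size of the smallest one —
repeated over many seeded replicates so that downstream statistics can
be checked for subsampling artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import ReadRecord

__all__ = ["trim_read", "trim_library", "hard_clip", "equalize_libraries", "ReplicateSet"]


def trim_read(read: ReadRecord, q_min: int = 20) -> ReadRecord | None:
    """Trim bases below ``q_min`` from both ends; None if nothing survives."""
    q = read.qualities
    lo, hi = 0, len(q)
    while lo < hi and q[lo] < q_min:
        lo += 1
    while hi > lo and q[hi - 1] < q_min:
        hi -= 1
    if hi == lo:
        return None
    if lo == 0 and hi == len(q):
        return read
    return ReadRecord(
        read.read_id, read.sequence[lo:hi], q[lo:hi], read.mate, read.library_id
    )


def trim_library(reads: list[ReadRecord], q_min: int = 20) -> list[ReadRecord]:
    """Trim every read, dropping those that trim to nothing."""
    out = []
    for r in reads:
        t = trim_read(r, q_min)
        if t is not None:
            out.append(t)
    return out


def hard_clip(read: ReadRecord, target_length: int) -> ReadRecord | None:
    """Keep the first ``target_length`` bases; None if the read is shorter."""
    if len(read) < target_length:
        return None
    if len(read) == target_length:
        return read
    return ReadRecord(
        read.read_id,
        read.sequence[:target_length],
        read.qualities[:target_length],
        read.mate,
        read.library_id,
    )


@dataclass
class ReplicateSet:
    """One equalized subsampling replicate across libraries."""

    replicate_index: int
    reads: dict[str, list[ReadRecord]]  # library_id -> subsampled reads
    target_read_length: int
    target_read_count: int


def equalize_libraries(
    libraries: dict[str, list[ReadRecord]],
    target_length: int = 60,
    n_replicates: int = 49,
    seed: int = 0,
) -> list[ReplicateSet]:
    """Build length- and depth-equalized replicate datasets.

    Every read is clipped to ``target_length`` (shorter reads dropped);
    the smallest post-clipping library sets the per-library read count.
    Each replicate subsamples every larger library without replacement
    down to that count and passes the smallest library through intact.
    Replicate ``r`` under seed ``s`` is reproducible from ``(s, r)``
    alone.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    clipped: dict[str, list[ReadRecord]] = {}
    for lib, reads in libraries.items():
        kept = [c for r in reads if (c := hard_clip(r, target_length)) is not None]
        if not kept:
            raise ValueError(f"library {lib} has no reads of length >= {target_length}")
        clipped[lib] = kept
    target_count = min(len(v) for v in clipped.values())

    replicates = []
    for rep in range(1, n_replicates + 1):
        rng = np.random.default_rng([seed, rep])
        subset: dict[str, list[ReadRecord]] = {}
        for lib in sorted(clipped):
            reads = clipped[lib]
            if len(reads) == target_count:
                subset[lib] = list(reads)
            else:
                idx = rng.choice(len(reads), size=target_count, replace=False)
                idx.sort()
                subset[lib] = [reads[i] for i in idx]
        replicates.append(ReplicateSet(rep, subset, target_length, target_count))
    return replicates
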