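"""Seed-and-extend read mapping onto repeat and UCOS reference contigs.

This is a deliberately small alignment stage tuned for coverage-based
copy-number estimation from short (60/80 bp) reads: exact k-mer seeds
on both strands, ungapped extension over the full read, a mismatch
ceiling expressed as a fraction of read length, and — crucially —
*random* placement among equally good hits. Reads from a multi-copy
family must land somewhere on that family's consensus for its coverage
to add up; discarding multi-mappers would systematically deflate repeat
coverage.

Externally produced alignments can be imported from SAM (text) and
mapped reads exported to SAM, both through pysam.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .records import ReadRecord, revcomp
from .synthetic import seq_to_idx

__all__ = [
    "ReferenceContig",
    "AlignmentRecord",
    "SeedIndex",
    "build_index",
    "map_read",
    "map_reads",
    "brute_force_best_mismatches",
    "export_sam",
    "import_alignments",
    "Pileup",
    "PileupColumn",
    "pileup",
]


@dataclass
class ReferenceContig:
    """A reference contig: a TE family consensus, a UCOS gene, or other."""

    contig_id: str
    sequence: str
    category: str = "TE"  # "TE", "UCOS" or "other"
    te_class: str = "NA"  # "I", "II", "satellite" or "NA"
    superfamily: str = "NA"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id} has empty sequence")
        if self.category == "TE" and self.superfamily in ("NA", ""):
            raise ValueError(f"TE contig {self.contig_id} needs a superfamily label")
        self._arr = seq_to_idx(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def arr(self) -> np.ndarray:
        return self._arr


@dataclass
class AlignmentRecord:
    """An ungapped read placement on a reference contig.

    ``aligned_seq``/``aligned_quals`` are stored in contig orientation
    (reverse-complemented/reversed for minus-strand placements), which
    makes pileup construction orientation-free. ``mismatch_offsets`` are
    offsets from ``start`` along the contig.
    """

    read_id: str
    contig_id: str
    start: int
    strand: str  # "+" or "-"
    aligned_length: int
    mismatch_offsets: tuple[int, ...]
    score: int
    mapq_proxy: int
    aligned_seq: str = ""
    aligned_quals: np.ndarray | None = None

    @property
    def end(self) -> int:
        return self.start + self.aligned_length

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_offsets)


class SeedIndex:
    """Exact k-mer index over both strands of a contig set."""

    def __init__(self, contigs: Sequence[ReferenceContig], k: int):
        if k < 8:
            raise ValueError("seed length k must be >= 8")
        self.k = k
        self.contigs = list(contigs)
        self.by_id = {c.contig_id: i for i, c in enumerate(self.contigs)}
        if len(self.by_id) != len(self.contigs):
            raise ValueError("duplicate contig ids")
        # kmer -> list of (contig_index, strand, fwd_start_of_kmer_alignment_anchor)
        # '+' entries anchor the k-mer at its forward-strand start; '-'
        # entries store the start of the k-mer on the reverse-complemented
        # contig, pre-converted so a read offset o yields a forward start
        # directly (see map_read).
        self.kmers: dict[str, list[tuple[int, str, int]]] = {}
        for ci, c in enumerate(self.contigs):
            seq = c.sequence
            n = len(seq)
            for p in range(n - k + 1):
                self.kmers.setdefault(seq[p : p + k], []).append((ci, "+", p))
            rc = revcomp(seq)
            for p in range(n - k + 1):
                self.kmers.setdefault(rc[p : p + k], []).append((ci, "-", p))

    def lookup(self, kmer: str) -> list[tuple[int, str, int]]:
        return self.kmers.get(kmer, [])


def build_index(contigs: Sequence[ReferenceContig], k: int = 13) -> SeedIndex:
    """Build the exact k-mer seed index (both strands)."""
    return SeedIndex(contigs, k)


def _seed_offsets(L: int, k: int) -> list[int]:
    offs = list(range(0, L - k + 1, k))
    if offs[-1] != L - k:
        offs.append(L - k)
    return offs


def map_read(
    read: ReadRecord,
    index: SeedIndex,
    max_mismatch_rate: float = 0.08,
    rng: np.random.Generator | None = None,
) -> AlignmentRecord | None:
    """Place one read; None if no placement clears the mismatch ceiling.

    Non-overlapping k-mer seeds of the read are looked up on both
    strands; every candidate diagonal is extended ungapped across the
    full read. The fewest-mismatch placement wins if its mismatch count
    is at most ``ceil(max_mismatch_rate * len(read))``; ties are broken
    uniformly at random (mapq_proxy 0).
    """
    if rng is None:
        rng = np.random.default_rng()
    seq = read.sequence
    L = len(seq)
    k = index.k
    if L < k:
        return None
    ridx = seq_to_idx(seq)
    rc_ridx = None

    candidates: set[tuple[int, str, int]] = set()
    for o in _seed_offsets(L, k):
        for ci, strand, p in index.lookup(seq[o : o + k]):
            if strand == "+":
                candidates.add((ci, "+", p - o))
            else:
                clen = len(index.contigs[ci])
                # k-mer sits at p on rc(contig); alignment start on rc is
                # p - o; convert to forward coordinates of the contig.
                candidates.add((ci, "-", clen - (p - o) - L))
    if not candidates:
        return None

    max_mm = math.ceil(max_mismatch_rate * L)
    best_mm = max_mm + 1
    best: list[tuple[int, str, int]] = []
    for ci, strand, start in candidates:
        carr = index.contigs[ci].arr
        if start < 0 or start + L > len(carr):
            continue
        if strand == "+":
            qarr = ridx
        else:
            if rc_ridx is None:
                rc_ridx = (3 - ridx)[::-1] if ridx.max() < 4 else seq_to_idx(revcomp(seq))
            qarr = rc_ridx
        mm = int(np.count_nonzero(carr[start : start + L] != qarr))
        if mm < best_mm:
            best_mm = mm
            best = [(ci, strand, start)]
        elif mm == best_mm:
            best.append((ci, strand, start))
    if not best or best_mm > max_mm:
        return None

    if len(best) > 1:
        best.sort()
        ci, strand, start = best[int(rng.integers(len(best)))]
        mapq = 0
    else:
        ci, strand, start = best[0]
        mapq = 60
    contig = index.contigs[ci]
    if strand == "+":
        aseq, aqual, qarr = seq, read.qualities, ridx
    else:
        aseq = revcomp(seq)
        aqual = read.qualities[::-1]
        qarr = rc_ridx if rc_ridx is not None else seq_to_idx(aseq)
    offs = tuple(int(x) for x in np.nonzero(contig.arr[start : start + L] != qarr)[0])
    return AlignmentRecord(
        read_id=read.read_id,
        contig_id=contig.contig_id,
        start=start,
        strand=strand,
        aligned_length=L,
        mismatch_offsets=offs,
        score=L - 2 * best_mm,
        mapq_proxy=mapq,
        aligned_seq=aseq,
        aligned_quals=aqual,
    )


def map_reads(
    reads: Iterable[ReadRecord],
    index: SeedIndex,
    max_mismatch_rate: float = 0.08,
    seed: int = 0,
) -> list[AlignmentRecord]:
    """Map a read set with one seeded tie-breaking generator."""
    rng = np.random.default_rng(seed)
    out = []
    for r in reads:
        a = map_read(r, index, max_mismatch_rate, rng)
        if a is not None:
            out.append(a)
    return out


def brute_force_best_mismatches(read: ReadRecord, contigs: Sequence[ReferenceContig]) -> int | None:
    """Exhaustive best mismatch count over every position and strand.

    Independent oracle for the seeded mapper; O(total contig length x
    read length), test use only.
    """
    L = len(read)
    ridx = seq_to_idx(read.sequence)
    rc = seq_to_idx(revcomp(read.sequence))
    best = None
    for c in contigs:
        if len(c) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(c.arr, L)
        for qarr in (ridx, rc):
            mm = int((windows != qarr).sum(axis=1).min())
            if best is None or mm < best:
                best = mm
    return best


# ---------------------------------------------------------------------------
# SAM interoperability


def _sam_header(contigs: Sequence[ReferenceContig]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": c.contig_id, "LN": len(c)} for c in contigs],
        }
    )


def _md_string(ref_slice: str, aln_seq: str) -> str:
    md = []
    run = 0
    for r, q in zip(ref_slice, aln_seq):
        if r == q:
            run += 1
        else:
            md.append(str(run))
            md.append(r)
            run = 0
    md.append(str(run))
    return "".join(md)


def export_sam(
    alignments: Iterable[AlignmentRecord],
    contigs: Sequence[ReferenceContig],
    path: str | Path,
) -> None:
    """Write alignments as SAM text with NM and MD tags."""
    by_id = {c.contig_id: i for i, c in enumerate(contigs)}
    header = _sam_header(contigs)
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for a in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = a.read_id.replace("/", "_")
            seg.reference_id = by_id[a.contig_id]
            seg.reference_start = a.start
            seg.flag = 16 if a.strand == "-" else 0
            seg.mapping_quality = a.mapq_proxy
            seg.cigarstring = f"{a.aligned_length}M"
            seg.query_sequence = a.aligned_seq or None
            if a.aligned_quals is not None:
                seg.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(int(q) + 33) for q in a.aligned_quals)
                )
            ref = contigs[by_id[a.contig_id]].sequence[a.start : a.end]
            seg.set_tag("NM", a.n_mismatches)
            if a.aligned_seq:
                seg.set_tag("MD", _md_string(ref, a.aligned_seq))
            fh.write(seg)


def _md_offsets(md: str) -> tuple[int, ...]:
    offs = []
    pos = 0
    num = ""
    i = 0
    while i < len(md):
        ch = md[i]
        if ch.isdigit():
            num += ch
            i += 1
        elif ch == "^":  # deletion: skip ref bases (not produced by this mapper)
            pos += int(num or 0)
            num = ""
            i += 1
            while i < len(md) and md[i].isalpha():
                i += 1
        else:
            pos += int(num or 0)
            num = ""
            offs.append(pos)
            pos += 1
            i += 1
    return tuple(offs)


@dataclass
class ImportStats:
    imported: int = 0
    skipped_unmapped: int = 0
    skipped_secondary: int = 0


def import_alignments(
    path: str | Path, contigs: Sequence[ReferenceContig]
) -> tuple[list[AlignmentRecord], ImportStats]:
    """Import primary mapped records from a SAM text file.

    CIGAR is consumed for the aligned length; MD gives mismatch offsets
    when present (falling back to an offset-less NM count); unmapped and
    secondary/supplementary records are skipped and counted.
    """
    known = {c.contig_id for c in contigs}
    stats = ImportStats()
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                stats.skipped_unmapped += 1
                continue
            if seg.is_secondary or seg.is_supplementary:
                stats.skipped_secondary += 1
                continue
            if seg.reference_name not in known:
                raise ValueError(f"unknown reference {seg.reference_name!r} in SAM")
            if seg.has_tag("MD"):
                offs = _md_offsets(str(seg.get_tag("MD")))
            elif seg.has_tag("NM"):
                offs = tuple(range(int(seg.get_tag("NM"))))  # count only; positions unknown
            else:
                offs = ()
            quals = (
                np.asarray(seg.query_alignment_qualities, dtype=np.uint8)
                if seg.query_alignment_qualities is not None
                else None
            )
            out.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    contig_id=seg.reference_name,
                    start=seg.reference_start,
                    strand="-" if seg.is_reverse else "+",
                    aligned_length=seg.query_alignment_length,
                    mismatch_offsets=offs,
                    score=seg.query_alignment_length - 2 * len(offs),
                    mapq_proxy=seg.mapping_quality,
                    aligned_seq=seg.query_alignment_sequence or "",
                    aligned_quals=quals,
                )
            )
            stats.imported += 1
    return out, stats


# ---------------------------------------------------------------------------
# pileups


@dataclass
class PileupColumn:
    """One reference position: depth and the allele/quality tally."""

    contig_id: str
    pos: int
    ref_base: str
    depth: int
    hq_depth: int  # bases with quality >= the pileup's hq threshold
    alt_tally: dict[str, list[int]]  # non-reference base -> supporting quals

    def ref_support_hq(self, min_quality: int) -> int:
        alt_hq = sum(1 for quals in self.alt_tally.values() for q in quals if q >= min_quality)
        return self.hq_depth - alt_hq


class Pileup:
    """Per-contig coverage arrays plus allele tallies at mismatch sites.

    Coverage is exact for every position; individual base qualities are
    kept only where a read disagrees with the reference, while
    reference-supporting bases contribute to the aggregate high-quality
    depth (``hq_depth``, counting bases with quality >=
    ``hq_threshold``). This keeps memory linear in the number of
    variant-supporting bases rather than in total coverage.
    """

    def __init__(self, contigs: Sequence[ReferenceContig], hq_threshold: int = 20):
        self.hq_threshold = hq_threshold
        self.contigs = {c.contig_id: c for c in contigs}
        self.depth = {c.contig_id: np.zeros(len(c), dtype=np.int32) for c in contigs}
        self.hq_depth = {c.contig_id: np.zeros(len(c), dtype=np.int32) for c in contigs}
        self.alts: dict[str, dict[int, dict[str, list[int]]]] = {
            c.contig_id: {} for c in contigs
        }
        self.n_alignments = 0
        self.total_aligned = 0

    def add(self, a: AlignmentRecord) -> None:
        d = self.depth[a.contig_id]
        d[a.start : a.end] += 1
        if a.aligned_quals is not None:
            hq = np.asarray(a.aligned_quals) >= self.hq_threshold
            self.hq_depth[a.contig_id][a.start : a.end] += hq
        else:
            self.hq_depth[a.contig_id][a.start : a.end] += 1
        if a.mismatch_offsets and a.aligned_seq:
            contig_alts = self.alts[a.contig_id]
            for off in a.mismatch_offsets:
                pos = a.start + off
                base = a.aligned_seq[off]
                q = int(a.aligned_quals[off]) if a.aligned_quals is not None else 40
                contig_alts.setdefault(pos, {}).setdefault(base, []).append(q)
        self.n_alignments += 1
        self.total_aligned += a.aligned_length

    def column(self, contig_id: str, pos: int) -> PileupColumn:
        return PileupColumn(
            contig_id=contig_id,
            pos=pos,
            ref_base=self.contigs[contig_id].sequence[pos],
            depth=int(self.depth[contig_id][pos]),
            hq_depth=int(self.hq_depth[contig_id][pos]),
            alt_tally=self.alts[contig_id].get(pos, {}),
        )

    def coverage(self, contig_id: str) -> np.ndarray:
        return self.depth[contig_id]


def pileup(
    alignments: Iterable[AlignmentRecord],
    contigs: Sequence[ReferenceContig],
    hq_threshold: int = 20,
) -> Pileup:
    """Accumulate alignments into per-position coverage and allele tallies."""
    p = Pileup(contigs, hq_threshold)
    for a in alignments:
        p.add(a)
    return p
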