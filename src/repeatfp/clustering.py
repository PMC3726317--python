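"""De novo graph-based clustering of shotgun reads into repeat families.

Reads are vertices; an edge connects two reads whose best ungapped
overlap (found via shared k-mers, both orientations) reaches a minimum
identity over a minimum fraction of the shorter read, with weight
identity x overlap fraction. Louvain community detection partitions the
graph, and each community's size as a fraction of all reads used is its
"genome percentage" — repeats occupy genome space in proportion to the
reads they emit.

Because the method never touches a reference, it is insensitive to how
far the genome's repeat copies have drifted from any particular
consensus — the property that makes de novo estimates preferable to
mapping across species boundaries.

Clusters are annotated against a user-supplied repeat library by k-mer
containment of representative reads, with a DUST-like triplet score
flagging low-complexity (satellite-like) clusters first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .mapping import ReferenceContig
from .records import ReadRecord, revcomp
from .synthetic import seq_to_idx

__all__ = [
    "build_read_graph",
    "louvain_clusters",
    "cluster_report",
    "subsample_reads",
    "dust_score",
]


def subsample_reads(
    reads: list[ReadRecord], max_vertices: int, seed: int = 0
) -> list[ReadRecord]:
    """Seeded subsample applied when a read set exceeds the vertex budget.

    Genome percentages downstream remain ratios of the reads actually
    used, so subsampling changes variance, not scale.
    """
    if len(reads) <= max_vertices:
        return list(reads)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=max_vertices, replace=False)
    idx.sort()
    return [reads[i] for i in idx]


def _overlap(
    a: np.ndarray, b: np.ndarray, diag: int, min_identity: float, min_overlap_fraction: float
) -> float | None:
    """Score the ungapped alignment a[x] ~ b[x - diag]; None if it fails."""
    start = max(0, diag)
    end = min(len(a), len(b) + diag)
    ovl = end - start
    shorter = min(len(a), len(b))
    if ovl < math.ceil(min_overlap_fraction * shorter):
        return None
    matches = int(np.count_nonzero(a[start:end] == b[start - diag : end - diag]))
    identity = matches / ovl
    if identity < min_identity:
        return None
    return identity * min(ovl / shorter, 1.0)


def build_read_graph(
    reads: list[ReadRecord],
    k: int = 17,
    min_identity: float = 0.90,
    min_overlap_fraction: float = 0.55,
    max_candidates_per_read: int = 30,
    kmer_stride: int = 3,
    bucket_sample: int = 64,
    per_lookup_candidates: int = 8,
    seed: int = 0,
) -> nx.Graph:
    """Build the weighted read-overlap graph.

    Candidate partners come from shared canonical k-mers (so both
    orientations are found); each shared k-mer votes for an (orientation,
    diagonal) and the top-voted diagonal per partner is verified by the
    ungapped overlap test. The k-mer index samples every
    ``kmer_stride``-th position of each read while queries scan every
    position, so candidate discovery does not depend on the relative
    offset of a read pair. Very popular k-mers (deep repeats) are
    down-sampled to ``bucket_sample`` entries with a seeded generator,
    which bounds the work per read without disconnecting large
    clusters. Every read is a vertex; vertices keep their read id in
    the ``read_id`` attribute.
    """
    if reads and k > min(len(r) for r in reads):
        raise ValueError("k exceeds the shortest read length")
    n = len(reads)
    G = nx.Graph()
    for i, r in enumerate(reads):
        G.add_node(i, read_id=r.read_id)
    if n < 2:
        return G

    arrs = [seq_to_idx(r.sequence) for r in reads]
    rcs = [seq_to_idx(revcomp(r.sequence)) for r in reads]

    buckets: dict[str, list[tuple[int, int, int]]] = {}
    for i, r in enumerate(reads):
        s = r.sequence
        L = len(s)
        positions = list(range(0, L - k + 1, kmer_stride))
        if positions and positions[-1] != L - k:
            positions.append(L - k)
        for p in positions:
            km = s[p : p + k]
            rkm = revcomp(km)
            if km <= rkm:
                buckets.setdefault(km, []).append((i, p, 1))
            else:
                buckets.setdefault(rkm, []).append((i, p, -1))

    rng = np.random.default_rng(seed)
    for km, entries in buckets.items():
        if len(entries) > bucket_sample:
            pick = rng.choice(len(entries), size=bucket_sample, replace=False)
            pick.sort()
            buckets[km] = [entries[x] for x in pick]

    for i, r in enumerate(reads):
        s = r.sequence
        L = len(s)
        votes: dict[tuple[int, int, int], int] = {}
        for p in range(L - k + 1):
            km = s[p : p + k]
            rkm = revcomp(km)
            can, strand_i = (km, 1) if km <= rkm else (rkm, -1)
            entries = buckets.get(can)
            if not entries:
                continue
            taken = 0
            for j, q, strand_j in entries:
                if j == i:
                    continue
                if taken >= per_lookup_candidates:
                    break
                taken += 1
                orient = strand_i * strand_j
                if orient == 1:
                    diag = p - q
                else:
                    diag = p - (len(reads[j]) - k - q)
                key = (j, orient, diag)
                votes[key] = votes.get(key, 0) + 1
        best_by_j: dict[int, tuple[int, int, int]] = {}
        for (j, orient, diag), c in votes.items():
            cur = best_by_j.get(j)
            if cur is None or c > cur[2]:
                best_by_j[j] = (orient, diag, c)
        ranked = sorted(best_by_j.items(), key=lambda kv: (-kv[1][2], kv[0]))
        for j, (orient, diag, _c) in ranked[:max_candidates_per_read]:
            b = arrs[j] if orient == 1 else rcs[j]
            w = _overlap(arrs[i], b, diag, min_identity, min_overlap_fraction)
            if w is None:
                continue
            if G.has_edge(i, j):
                if w > G[i][j]["weight"]:
                    G[i][j]["weight"] = w
            else:
                G.add_edge(i, j, weight=w)
    return G


def louvain_clusters(
    G: nx.Graph,
    resolution: float = 1.0,
    seed: int = 0,
    merge_cross_degree: float = 0.2,
) -> list[set]:
    """Louvain community partition with supercluster merging, largest first.

    Louvain tends to shatter a single dense repeat (a satellite blob,
    or the positional segments of a long element) into several
    communities; a merge pass reunites communities whose cross-edge
    count *exceeds* ``merge_cross_degree`` times the smaller
    community's size. Genuinely distinct repeat families share no edges
    and are never merged, and a single bridge edge between two
    five-read communities sits exactly at the default threshold and
    does not merge them. Set ``merge_cross_degree`` to 0/None to
    disable.
    """
    if G.number_of_nodes() == 0:
        return []
    comms = nx.community.louvain_communities(
        G, weight="weight", resolution=resolution, seed=seed
    )
    parts = [set(c) for c in comms]
    if merge_cross_degree:
        parts = _merge_superclusters(G, parts, merge_cross_degree)
    return sorted(parts, key=lambda c: (-len(c), min(c)))


def _merge_superclusters(G: nx.Graph, parts: list[set], threshold: float) -> list[set]:
    comm_of = {}
    for ci, members in enumerate(parts):
        for v in members:
            comm_of[v] = ci
    cross: dict[tuple[int, int], int] = {}
    for u, v in G.edges():
        a, b = comm_of[u], comm_of[v]
        if a != b:
            key = (a, b) if a < b else (b, a)
            cross[key] = cross.get(key, 0) + 1
    parent = list(range(len(parts)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), n_edges in sorted(cross.items()):
        if n_edges > threshold * min(len(parts[a]), len(parts[b])):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    merged: dict[int, set] = {}
    for ci, members in enumerate(parts):
        merged.setdefault(find(ci), set()).update(members)
    return list(merged.values())


def dust_score(seq: str) -> float:
    """DUST-style low-complexity score (higher = simpler sequence)."""
    if len(seq) < 4:
        return 0.0
    counts: dict[str, int] = {}
    for i in range(len(seq) - 2):
        t = seq[i : i + 3]
        counts[t] = counts.get(t, 0) + 1
    return sum(c * (c - 1) / 2 for c in counts.values()) / (len(seq) - 3)


def _containment(read_kmers: set[str], lib_kmers: set[str]) -> float:
    if not read_kmers:
        return 0.0
    return len(read_kmers & lib_kmers) / len(read_kmers)


def _canonical_kmers(seq: str, k: int) -> set[str]:
    out = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        out.add(min(km, revcomp(km)))
    return out


def cluster_report(
    partition: list[set],
    total_reads_used: int,
    reads: list[ReadRecord] | None = None,
    repeat_library: list[ReferenceContig] | None = None,
    graph: nx.Graph | None = None,
    cutoff: float = 0.0001,
    annotation_k: int = 13,
    min_containment: float = 0.30,
    low_complexity_threshold: float = 1.5,
    max_representatives: int = 30,
) -> pd.DataFrame:
    """Summarise a cluster partition with sizes and annotations.

    ``genome_percentage`` is cluster reads / ``total_reads_used`` x 100;
    clusters below ``cutoff`` (a fraction; the 0.01% default, boundary
    inclusive) are omitted. Representative reads (highest graph degree
    when a graph is given) are classified as "low complexity" by mean
    DUST score, otherwise by best k-mer containment against the repeat
    library's contigs (label = that contig's superfamily), else
    "unknown".
    """
    if total_reads_used <= 0:
        raise ValueError("total_reads_used must be > 0")
    lib_kmers: list[tuple[ReferenceContig, set[str]]] = []
    if repeat_library:
        lib_kmers = [
            (c, _canonical_kmers(c.sequence, annotation_k)) for c in repeat_library
        ]
    rows = []
    for cid, members in enumerate(partition, start=1):
        pct = 100.0 * len(members) / total_reads_used
        if pct / 100.0 < cutoff:
            continue
        annotation, best_match, mean_dust = "unknown", "", float("nan")
        if reads is not None:
            if graph is not None:
                reps = sorted(members, key=lambda v: (-graph.degree(v), v))
            else:
                reps = sorted(members)
            reps = reps[:max_representatives]
            rep_seqs = [reads[v].sequence for v in reps]
            mean_dust = float(np.mean([dust_score(s) for s in rep_seqs]))
            if mean_dust >= low_complexity_threshold:
                annotation = "low complexity"
            elif lib_kmers:
                best_c, best_frac = None, 0.0
                for contig, kms in lib_kmers:
                    frac = float(
                        np.mean(
                            [
                                _containment(_canonical_kmers(s, annotation_k), kms)
                                for s in rep_seqs
                            ]
                        )
                    )
                    if frac > best_frac:
                        best_c, best_frac = contig, frac
                if best_c is not None and best_frac >= min_containment:
                    annotation = best_c.superfamily
                    best_match = best_c.contig_id
        rows.append(
            {
                "cluster_id": cid,
                "n_reads": len(members),
                "genome_percentage": pct,
                "annotation": annotation,
                "best_match": best_match,
                "mean_complexity": mean_dust,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "n_reads",
            "genome_percentage",
            "annotation",
            "best_match",
            "mean_complexity",
        ],
    ).set_index("cluster_id")
    df.attrs["total_reads_used"] = total_reads_used
    return df
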