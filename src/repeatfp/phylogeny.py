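"""Species-tree estimation from single-copy (UCOS) loci.

Per-sample consensus sequences are called from read pileups on each
UCOS contig under conservative rules (minimum high-quality depth,
majority fraction; ambiguous positions become N). Columns containing
any N/gap are removed, short loci discarded, and the survivors provide
both a concatenated matrix (NEXUS, with a partition table) and
individual locus alignments for gene trees.

Gene trees are neighbor joining on JC69-corrected distances. The
species tree is STAR: within each gene tree rooted on the outgroup,
internal nodes receive ranks (root = number of taxa, child = parent -
1), a pair's distance is twice the rank of its MRCA, distances are
averaged over gene trees, and neighbor joining of the averaged matrix
gives the topology. Branch lengths on the species tree are therefore in
rank units, not substitutions. Support comes from a multilocus
bootstrap: loci are resampled with replacement, a STAR tree is built
per replicate, and each internal edge of the point-estimate tree is
annotated with the percentage of replicates containing its bipartition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .mapping import Pileup

__all__ = [
    "consensus_sequences",
    "LocusAlignment",
    "filter_columns_and_loci",
    "write_nexus",
    "jc69_distance_matrix",
    "neighbor_joining",
    "nj_gene_tree",
    "star_species_tree",
    "multilocus_bootstrap",
    "BootstrapResult",
    "tree_from_newick",
    "bipartitions",
]


# ---------------------------------------------------------------------------
# consensus matrix construction


def consensus_sequences(
    pile: Pileup,
    contig_ids: list[str] | None = None,
    min_depth: int = 6,
    min_base_quality: int = 20,
    majority_fraction: float = 0.8,
) -> dict[str, str]:
    """Call a consensus sequence per contig for one sample.

    At each position only bases with quality >= ``min_base_quality``
    count. Filtered depth below ``min_depth`` ("6 or more" at the
    default) gives N; otherwise the top allele is emitted when it holds
    at least ``majority_fraction`` of the filtered depth, and N (an
    ambiguous/heterozygous position) when it does not.
    """
    if min_base_quality != pile.hq_threshold:
        raise ValueError("min_base_quality must match the pileup's hq_threshold")
    ids = contig_ids if contig_ids is not None else [
        c.contig_id for c in pile.contigs.values() if c.category == "UCOS"
    ]
    out: dict[str, str] = {}
    for cid in ids:
        ref = pile.contigs[cid].sequence
        hq = pile.hq_depth[cid]
        chars = np.frombuffer(ref.encode(), dtype=np.uint8).copy()
        chars[hq < min_depth] = ord("N")
        for pos, tally in pile.alts[cid].items():
            depth = int(hq[pos])
            if depth < min_depth:
                continue
            alt_hq = {b: sum(1 for q in quals if q >= min_base_quality) for b, quals in tally.items()}
            ref_hq = depth - sum(alt_hq.values())
            counts = dict(alt_hq)
            counts[ref[pos]] = counts.get(ref[pos], 0) + ref_hq
            top_base, top_n = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
            chars[pos] = ord(top_base) if top_n / depth >= majority_fraction else ord("N")
        out[cid] = chars.tobytes().decode()
    return out


@dataclass
class LocusAlignment:
    """Gap-free alignment of one locus over the retained columns."""

    locus_id: str
    sequences: dict[str, str]  # sample -> sequence, all equal length
    retained_length: int


def filter_columns_and_loci(
    loci: dict[str, dict[str, str]],
    min_length: int = 50,
) -> tuple[list[LocusAlignment], dict[str, str], pd.DataFrame]:
    """Remove gapped columns, drop short loci, concatenate the rest.

    Ns are treated as gaps; every column with at least one gap is
    removed entirely, so the retained matrix has no missing data. Loci
    retaining fewer than ``min_length`` columns are excluded. Returns
    the per-locus alignments, the concatenated per-sample sequences and
    a partition table with each locus's (1-based, inclusive) coordinate
    range in the concatenation.
    """
    samples: list[str] | None = None
    kept: list[LocusAlignment] = []
    for locus_id in sorted(loci):
        seqs = loci[locus_id]
        if not seqs:
            warnings.warn(f"locus {locus_id}: no samples covered, dropped", stacklevel=2)
            continue
        if samples is None:
            samples = sorted(seqs)
        elif sorted(seqs) != samples:
            raise ValueError(f"locus {locus_id} has a different sample set")
        arr = np.array([list(seqs[s]) for s in samples])
        good = ~((arr == "N") | (arr == "-")).any(axis=0)
        retained = int(good.sum())
        if retained < min_length:
            continue
        sub = arr[:, good]
        kept.append(
            LocusAlignment(
                locus_id,
                {s: "".join(sub[i]) for i, s in enumerate(samples)},
                retained,
            )
        )
    concat: dict[str, str] = {}
    rows = []
    pos = 0
    if samples is None:
        samples = []
    for la in kept:
        rows.append({"locus": la.locus_id, "start": pos + 1, "end": pos + la.retained_length})
        for s in samples:
            concat[s] = concat.get(s, "") + la.sequences[s]
        pos += la.retained_length
    return kept, concat, pd.DataFrame(rows)


def write_nexus(concat: dict[str, str], partitions: pd.DataFrame, path: str | Path) -> None:
    """Write the concatenated matrix as NEXUS with a charset block per locus."""
    samples = sorted(concat)
    nchar = len(next(iter(concat.values()))) if concat else 0
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={len(samples)} NCHAR={nchar};\n")
        fh.write("    FORMAT DATATYPE=DNA MISSING=N GAP=-;\n    MATRIX\n")
        for s in samples:
            fh.write(f"    {s}  {concat[s]}\n")
        fh.write("    ;\nEND;\n\nBEGIN SETS;\n")
        for _, row in partitions.iterrows():
            fh.write(f"    CHARSET {row['locus']} = {row['start']}-{row['end']};\n")
        fh.write("END;\n")


# ---------------------------------------------------------------------------
# distances and neighbor joining


def jc69_distance_matrix(alignment: LocusAlignment) -> pd.DataFrame:
    """Pairwise JC69-corrected distances of a gap-free alignment."""
    samples = sorted(alignment.sequences)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for a gene tree")
    arrs = {s: np.frombuffer(alignment.sequences[s].encode(), dtype=np.uint8) for s in samples}
    n = len(samples)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = float(np.mean(arrs[samples[i]] != arrs[samples[j]]))
            if p >= 0.75:
                raise ValueError(
                    f"saturated distance (p={p:.2f}) between {samples[i]} and {samples[j]}"
                )
            d = -0.75 * math.log(1.0 - 4.0 * p / 3.0) if p > 0 else 0.0
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=samples, columns=samples)


def neighbor_joining(dist: pd.DataFrame) -> str:
    """Neighbor joining; returns a Newick string with branch lengths.

    Ties in the Q criterion are broken by lexicographic order of the
    joined labels, so the output is deterministic. On an additive
    distance matrix the generating tree is recovered exactly.
    """
    labels = list(dist.index)
    D: dict[tuple[str, str], float] = {}
    for a in labels:
        for b in labels:
            if a != b:
                D[(a, b)] = float(dist.loc[a, b])
    newick: dict[str, str] = {lbl: lbl for lbl in labels}
    active = sorted(labels)

    def d(a: str, b: str) -> float:
        return D[(a, b)]

    node_counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        best_q = math.inf
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (n - 2) * d(a, b) - r[a] - r[b]
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12 and best is not None and (a, b) < best):
                    best_q = q
                    best = (a, b)
        a, b = best
        la = 0.5 * d(a, b) + (r[a] - r[b]) / (2 * (n - 2))
        lb = d(a, b) - la
        node_counter += 1
        new = f"@node{node_counter}"
        newick[new] = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g})"
        for c in active:
            if c not in (a, b):
                D[(new, c)] = D[(c, new)] = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        active = sorted([c for c in active if c not in (a, b)] + [new])

    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
        lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
        lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        return f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g},{newick[c]}:{lc:.10g});"
    if len(active) == 2:
        a, b = active
        half = d(a, b) / 2
        return f"({newick[a]}:{half:.10g},{newick[b]}:{half:.10g});"
    return f"{newick[active[0]]};"


def tree_from_newick(newick: str, tns: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick,
        schema="newick",
        taxon_namespace=tns,
        preserve_underscores=True,
    )


def nj_gene_tree(
    alignment: LocusAlignment, tns: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """NJ/JC69 gene tree for one locus alignment."""
    return tree_from_newick(neighbor_joining(jc69_distance_matrix(alignment)), tns)


# ---------------------------------------------------------------------------
# STAR species tree


def _rank_distances(tree: dendropy.Tree, outgroup: str) -> dict[frozenset, int] | None:
    """Pairwise rank distances (2 x MRCA rank) of one rooted gene tree.

    Returns None when the outgroup is absent. Root rank equals the
    number of taxa in the tree; each child internal node's rank is its
    parent's minus one (all children of a non-binary node share the
    same rank).
    """
    t = tree.clone(depth=1)
    leaves = {nd.taxon.label: nd for nd in t.leaf_node_iter()}
    if outgroup not in leaves:
        return None
    t.reroot_at_edge(leaves[outgroup].edge, update_bipartitions=False)
    n_taxa = len(leaves)
    t.seed_node.rank = n_taxa
    for nd in t.preorder_node_iter():
        if nd is t.seed_node or nd.is_leaf():
            continue
        nd.rank = nd.parent_node.rank - 1

    dist: dict[frozenset, int] = {}
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            nd.leafset = [nd.taxon.label]
            continue
        child_sets = [c.leafset for c in nd.child_nodes()]
        for i in range(len(child_sets)):
            for j in range(i + 1, len(child_sets)):
                for a, b in product(child_sets[i], child_sets[j]):
                    dist[frozenset((a, b))] = 2 * nd.rank
        nd.leafset = [x for s in child_sets for x in s]
    return dist


def star_species_tree(
    gene_trees: list[dendropy.Tree],
    outgroup: str,
    tns: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """STAR species tree from a set of gene trees.

    Per-pair rank distances are averaged over the gene trees containing
    both taxa; neighbor joining of the averaged matrix gives the
    topology, which is then rooted on the outgroup. Branch lengths are
    in rank units (not substitutions).
    """
    if not gene_trees:
        raise ValueError("no gene trees given")
    sums: dict[frozenset, float] = {}
    counts: dict[frozenset, int] = {}
    used = 0
    for gt in gene_trees:
        dd = _rank_distances(gt, outgroup)
        if dd is None:
            warnings.warn("gene tree missing the outgroup; skipped", stacklevel=2)
            continue
        used += 1
        for pair, v in dd.items():
            sums[pair] = sums.get(pair, 0.0) + v
            counts[pair] = counts.get(pair, 0) + 1
    if used == 0:
        raise ValueError("no gene tree contains the outgroup")
    taxa = sorted({x for pair in sums for x in pair})
    D = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for pair, s in sums.items():
        a, b = sorted(pair)
        D.loc[a, b] = D.loc[b, a] = s / counts[pair]
    tree = tree_from_newick(neighbor_joining(D), tns)
    _root_on(tree, outgroup)
    return tree


def _root_on(tree: dendropy.Tree, outgroup: str) -> None:
    for nd in tree.leaf_node_iter():
        if nd.taxon.label == outgroup:
            tree.reroot_at_edge(nd.edge, update_bipartitions=False)
            return


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions as canonical leaf-label sets.

    Each bipartition is represented by the side *not* containing the
    lexicographically smallest taxon, so topologies can be compared as
    plain sets regardless of rooting.
    """
    labels = sorted(nd.taxon.label for nd in tree.leaf_node_iter())
    ref = labels[0]
    n = len(labels)
    out: set[frozenset] = set()
    for nd in tree.postorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        side = frozenset(set(labels) - below) if ref in below else below
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


@dataclass
class BootstrapResult:
    point_tree: dendropy.Tree  # internal nodes labelled with % support
    support: dict[frozenset, float]  # bipartition -> % of replicates
    consensus_tree: dendropy.Tree
    n_replicates: int


def clade_support(result: BootstrapResult, clade: set[str]) -> float:
    """Bootstrap % for the bipartition separating ``clade`` from the rest."""
    labels = sorted(nd.taxon.label for nd in result.point_tree.leaf_node_iter())
    ref = labels[0]
    side = frozenset(set(labels) - set(clade)) if ref in clade else frozenset(clade)
    return result.support.get(side, 0.0)


def multilocus_bootstrap(
    loci: list[LocusAlignment] | None,
    outgroup: str,
    B: int = 1000,
    seed: int = 0,
    gene_trees: list[dendropy.Tree] | None = None,
) -> BootstrapResult:
    """Multilocus bootstrap support for the STAR species tree.

    Loci (not sites) are resampled with replacement; per replicate the
    resampled gene trees feed STAR, and the point-estimate tree's
    internal edges are annotated with the percentage of replicate trees
    containing each bipartition. A majority-rule consensus of the
    replicate STAR trees is returned alongside. Gene trees per locus
    are deterministic, so they are estimated once and reused across
    replicates. Pre-estimated gene trees (e.g. imported Newick) may be
    supplied instead of alignments.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    tns = dendropy.TaxonNamespace()
    if gene_trees is None:
        if not loci or len(loci) < 2:
            raise ValueError("need at least 2 loci")
        gene_trees = [nj_gene_tree(la, tns) for la in loci]
    else:
        gene_trees = [
            tree_from_newick(gt.as_string(schema="newick"), tns) for gt in gene_trees
        ]
    n = len(gene_trees)
    point = star_species_tree(gene_trees, outgroup, tns)

    rng = np.random.default_rng(seed)
    bip_counts: dict[frozenset, int] = {}
    replicate_trees = dendropy.TreeList(taxon_namespace=tns)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        rep_trees = [gene_trees[i] for i in idx]
        rep_star = star_species_tree(rep_trees, outgroup, tns)
        replicate_trees.append(rep_star)
        for bip in bipartitions(rep_star):
            bip_counts[bip] = bip_counts.get(bip, 0) + 1

    support = {bip: 100.0 * c / B for bip, c in bip_counts.items()}
    labels = sorted(nd.taxon.label for nd in point.leaf_node_iter())
    ref = labels[0]
    for nd in point.postorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        side = frozenset(set(labels) - below) if ref in below else below
        if 2 <= len(side) <= len(labels) - 2:
            nd.label = f"{support.get(side, 0.0):.0f}"
    consensus = replicate_trees.consensus(min_freq=0.5)
    return BootstrapResult(point, support, consensus, B)
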