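"""Standard simulation designs used to validate the pipeline.

Each scenario fixes the synthetic study conditions — genome composition,
family copy numbers and divergences, sequencing depth and read length —
and provides runners that execute the relevant pipeline stages and
score recovery against the recorded truth. The designs are part of the
package, not test fixtures: they define the conditions under which the
method's properties (copy-number recovery, the mapping-vs-de-novo
divergence effect, the class I/class II diversity gap, PCA separation,
species-tree recovery) are demonstrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from . import abundance, clustering, diversity, fingerprint, mapping, phylogeny, readprep
from .mapping import AlignmentRecord, Pileup, ReferenceContig
from .records import ReadRecord
from .synthetic import (
    FamilySpec,
    LibraryProfile,
    ReferenceBuild,
    TruthSet,
    build_reference,
    class_i_layout,
    class_ii_layout,
    mutate,
    seq_to_idx,
    idx_to_seq,
    simulate_reads,
    source_interval,
)

__all__ = [
    "reference_contigs",
    "copy_number_design",
    "diversity_design",
    "partition_design",
    "pca_design",
    "species_tree_design",
    "run_mapping",
    "read_true_family",
    "clustering_family_fractions",
    "mapping_family_fractions",
]


def reference_contigs(build: ReferenceBuild) -> list[ReferenceContig]:
    """Reference contig set (family consensus + UCOS) for a synthetic build."""
    contigs = [
        ReferenceContig(
            contig_id=fid,
            sequence=seq,
            category="TE",
            te_class=build.truth.families[fid].te_class,
            superfamily=build.truth.families[fid].superfamily,
        )
        for fid, seq in build.consensus.items()
    ]
    contigs += [
        ReferenceContig(contig_id=uid, sequence=seq, category="UCOS")
        for uid, seq in build.ucos.items()
    ]
    return contigs


def run_mapping(
    build: ReferenceBuild,
    reads: list[ReadRecord],
    contigs: list[ReferenceContig] | None = None,
    q_min: int = 20,
    k: int = 13,
    max_mismatch_rate: float = 0.08,
    seed: int = 0,
) -> tuple[list[AlignmentRecord], Pileup]:
    """Trim, map and pile reads against a build's reference contigs."""
    if contigs is None:
        contigs = reference_contigs(build)
    trimmed = readprep.trim_library(reads, q_min)
    index = mapping.build_index(contigs, k)
    alns = mapping.map_reads(trimmed, index, max_mismatch_rate, seed=seed)
    pile = mapping.pileup(alns, contigs)
    return alns, pile


# ---------------------------------------------------------------------------
# scenario designs


def copy_number_design(seed: int = 0, drift: float = 0.0) -> tuple[ReferenceBuild, LibraryProfile]:
    """~2 Mb genome, 6 TE families at copy numbers {1, 5, 20, 100}, 6x depth.

    ``drift`` additionally mutates every family consensus by that
    substitution fraction *before* planting copies, while the mapping
    reference keeps the undrifted consensus — emulating mapping a
    related species' reads onto the focal species' repeat library.
    """
    specs = [
        FamilySpec("GYPSY1", "I", "LTR/Gypsy", 3000, 100, 0.05),
        FamilySpec("COPIA1", "I", "LTR/Copia", 3000, 20, 0.03),
        FamilySpec("GYPSY2", "I", "LTR/Gypsy", 3000, 5, 0.02),
        FamilySpec("HAT1", "II", "DNA/hAT", 3000, 20, 0.01),
        FamilySpec("MUTATOR1", "II", "DNA/Mutator", 3000, 5, 0.005),
        FamilySpec("HARBINGER1", "II", "DNA/Harbinger", 3000, 1, 0.0),
    ]
    build = build_reference(
        specs, n_ucos=20, ucos_length=1500, background_length=1_500_000, seed=seed
    )
    if drift > 0:
        rng = np.random.default_rng([seed, 915_001])
        drifted_specs = []
        for s in specs:
            arr, _, _ = mutate(rng, seq_to_idx(build.consensus[s.family_id]), drift)
            drifted_specs.append(
                FamilySpec(
                    s.family_id,
                    s.te_class,
                    s.superfamily,
                    s.consensus_length,
                    s.copy_number,
                    s.per_copy_divergence,
                    sequence=idx_to_seq(arr),
                )
            )
        drifted = build_reference(
            drifted_specs,
            n_ucos=20,
            ucos_length=1500,
            background_length=1_500_000,
            seed=seed,
        )
        # keep the *undrifted* consensus as the mapping reference
        drifted.consensus = dict(build.consensus)
        build = drifted
    profile = LibraryProfile(
        read_length=60, mean_depth=6.0, base_error_rate=0.002, seed=seed + 7, library_id="sim"
    )
    return build, profile


def diversity_design(seed: int = 0) -> tuple[ReferenceBuild, LibraryProfile]:
    """Class I families at 5% inter-copy divergence vs class II at 0.5%.

    Five families per class, five copies each (so a variant carried by
    a single copy sits at the 20% allele-fraction threshold in both
    classes and the class contrast is driven by the divergence rates).
    """
    specs = []
    for i in range(5):
        sf = "LTR/Gypsy" if i % 2 == 0 else "LTR/Copia"
        specs.append(FamilySpec(f"CL1F{i}", "I", sf, 3000, 5, 0.05))
    for i in range(5):
        sf = "DNA/hAT" if i % 2 == 0 else "DNA/Mutator"
        specs.append(FamilySpec(f"CL2F{i}", "II", sf, 3000, 5, 0.005))
    build = build_reference(
        specs, n_ucos=10, ucos_length=1500, background_length=300_000, seed=seed
    )
    profile = LibraryProfile(
        read_length=60, mean_depth=6.0, base_error_rate=0.002, seed=seed + 11, library_id="div"
    )
    return build, profile


def partition_design(seed: int = 0) -> tuple[ReferenceBuild, LibraryProfile]:
    """One annotated LTR element under uniform per-site divergence."""
    layout = class_i_layout(6000, ltr_len=700)
    specs = [
        FamilySpec("LTRELEM", "I", "LTR/Gypsy", 6000, 5, 0.05, feature_layout=layout)
    ]
    build = build_reference(
        specs, n_ucos=5, ucos_length=1500, background_length=100_000, seed=seed
    )
    profile = LibraryProfile(
        read_length=60, mean_depth=8.0, base_error_rate=0.001, seed=seed + 13, library_id="part"
    )
    return build, profile


def pca_design(
    seed: int = 0, n_per_group: int = 3
) -> tuple[dict[str, tuple[ReferenceBuild, LibraryProfile]], list[str], list[str]]:
    """Two planted accession groups differing 2x in DNA/hAT and LTR/Copia.

    Returns per-sample (build, profile) pairs plus the two group member
    lists. All samples share family consensus sequences (same build
    seed); group B doubles the copy number of the two marker families.
    Reads are 80 bp so that length equalization to 60 bp has work to do.
    """

    def specs(double: bool) -> list[FamilySpec]:
        m = 2 if double else 1
        return [
            FamilySpec("GYPSY1", "I", "LTR/Gypsy", 1500, 10, 0.03),
            FamilySpec("COPIA1", "I", "LTR/Copia", 2000, 12 * m, 0.03),
            FamilySpec("HAT1", "II", "DNA/hAT", 2000, 12 * m, 0.01),
            FamilySpec("MUTATOR1", "II", "DNA/Mutator", 1500, 8, 0.01),
            FamilySpec("HARBINGER1", "II", "DNA/Harbinger", 1500, 6, 0.01),
        ]

    samples: dict[str, tuple[ReferenceBuild, LibraryProfile]] = {}
    group_a = [f"A{i + 1}" for i in range(n_per_group)]
    group_b = [f"B{i + 1}" for i in range(n_per_group)]
    for gi, (group, double) in enumerate(((group_a, False), (group_b, True))):
        for si, name in enumerate(group):
            build = build_reference(
                specs(double),
                n_ucos=40,
                ucos_length=1500,
                background_length=250_000,
                seed=seed,  # same consensus/background across samples
            )
            profile = LibraryProfile(
                read_length=80,
                mean_depth=6.0,
                base_error_rate=0.002,
                seed=seed + 101 + 10 * gi + si,
                library_id=name,
            )
            samples[name] = (build, profile)
    return samples, group_a, group_b


def species_tree_design(
    seed: int = 0, n_trees: int = 100, discordant_fraction: float = 0.2
) -> tuple[list[dendropy.Tree], str, frozenset, str]:
    """Gene trees concordant with a known 6-taxon species tree plus noise.

    Returns (gene_trees, species_topology_newick, planted_clade,
    outgroup). ``discordant_fraction`` of the trees get a random
    topology over the ingroup instead.
    """
    taxa = ["A", "B", "C", "D", "E"]
    outgroup = "OUT"
    species_newick = "((((A,B),C),D),E,OUT);"
    planted = frozenset({"A", "B"})
    rng = np.random.default_rng(seed)
    n_disc = int(round(discordant_fraction * n_trees))
    trees: list[dendropy.Tree] = []
    for i in range(n_trees):
        if i < n_trees - n_disc:
            nwk = species_newick
        else:
            nwk = f"({_random_topology(rng, list(taxa))},{outgroup});"
        trees.append(phylogeny.tree_from_newick(nwk))
    return trees, species_newick, planted, outgroup


def _random_topology(rng: np.random.Generator, labels: list[str]) -> str:
    nodes = list(labels)
    order = rng.permutation(len(nodes))
    nodes = [nodes[i] for i in order]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [n for x, n in enumerate(nodes) if x not in (i, j)] + [merged]
    return nodes[0]


# ---------------------------------------------------------------------------
# scenario runners (shared by the test suite and the acceptance script)


def run_copy_number_scenario(seed: int = 0) -> dict:
    """Copy-number recovery under the standard design; returns metrics."""
    build, profile = copy_number_design(seed)
    reads = simulate_reads(build.genome, profile)
    _, pile = run_mapping(build, reads, seed=seed + 1)
    table = abundance.copy_number_table(pile, "sim")
    truth_cn = {f: build.truth.copy_number(f) for f in build.truth.families}
    rel_err = [
        abs(table.loc[f, "relative_copy_number"] - cn) / cn for f, cn in truth_cn.items()
    ]
    return {
        "build": build,
        "table": table,
        "truth_copy_numbers": truth_cn,
        "median_relative_error": float(np.median(rel_err)),
        "genome_size": build.truth.genome_size,
    }


def run_divergence_scenario(seed: int = 0, cluster_vertices: int = 15000) -> dict:
    """Mapping-vs-de-novo contrast at 25% consensus drift.

    The same families are simulated twice — copies drawn from the
    focal consensus, then from a 25%-drifted consensus — and both read
    sets are mapped against the *undrifted* reference. De novo
    clustering runs on the drifted reads and its per-family fractions
    are scored against true genome occupancy.
    """
    base_build, base_profile = copy_number_design(seed)
    base_reads = simulate_reads(base_build.genome, base_profile)
    _, base_pile = run_mapping(base_build, base_reads, seed=seed + 1)
    base_tab = abundance.copy_number_table(base_pile, "base")
    base_frac = mapping_family_fractions(base_tab, base_build.truth.genome_size)

    drift_build, drift_profile = copy_number_design(seed, drift=0.25)
    drift_reads = simulate_reads(drift_build.genome, drift_profile)
    _, drift_pile = run_mapping(drift_build, drift_reads, seed=seed + 1)
    drift_tab = abundance.copy_number_table(drift_pile, "drift")
    drift_frac = mapping_family_fractions(drift_tab, drift_build.truth.genome_size)

    total_base = sum(base_frac.values())
    total_drift = sum(drift_frac.values())
    drop = (total_base - total_drift) / total_base if total_base else float("nan")

    trimmed = readprep.trim_library(drift_reads)
    sub = clustering.subsample_reads(trimmed, cluster_vertices, seed=seed + 2)
    G = clustering.build_read_graph(sub, seed=seed + 3)
    parts = clustering.louvain_clusters(G, seed=seed + 4)
    cl_frac = clustering_family_fractions(parts, sub, drift_build.truth)
    occupancy = {f: drift_build.truth.occupancy(f) for f in drift_build.truth.families}
    cluster_err_pp = {
        f: 100.0 * abs(cl_frac.get(f, 0.0) - occupancy[f]) for f in occupancy
    }
    return {
        "mapping_fraction_base": base_frac,
        "mapping_fraction_drifted": drift_frac,
        "relative_drop": float(drop),
        "clustering_fractions": cl_frac,
        "true_occupancy": occupancy,
        "cluster_error_pp": cluster_err_pp,
        "max_cluster_error_pp": float(max(cluster_err_pp.values())),
    }


def run_diversity_scenario(seed: int = 0) -> dict:
    """Class I vs class II called-diversity contrast."""
    build, profile = diversity_design(seed)
    reads = simulate_reads(build.genome, profile)
    _, pile = run_mapping(build, reads, seed=seed + 1)
    te_ids = sorted(build.consensus)
    variants = diversity.call_variant_sites(pile, contig_ids=te_ids)
    dtab = diversity.diversity_table(pile, variants)
    med = dtab.groupby("te_class")["diversity"].median()
    ratio = float(med["I"] / med["II"]) if med.get("II", 0) > 0 else float("inf")
    return {"table": dtab, "median_class_I": float(med["I"]),
            "median_class_II": float(med.get("II", float("nan"))), "ratio": ratio}


def run_partition_scenario(seed: int = 0) -> dict:
    """Feature partitioning of an LTR element under uniform divergence."""
    build, profile = partition_design(seed)
    reads = simulate_reads(build.genome, profile)
    _, pile = run_mapping(build, reads, seed=seed + 1)
    variants = diversity.call_variant_sites(pile, contig_ids=["LTRELEM"])
    lengths = {"LTRELEM": len(build.consensus["LTRELEM"])}
    report = diversity.partition_variants(variants, build.annotations, lengths)
    features = [f for f in ("LTR", "RT", "IT", "GAG", "AP", "RH") if f in report.index]
    feat = report.loc[features]
    pooled = feat["variant_count"].sum() / feat["total_feature_length"].sum()
    z = {}
    for f in features:
        L = feat.loc[f, "total_feature_length"]
        exp = L * pooled
        sd = math.sqrt(L * pooled * (1 - pooled))
        z[f] = float((feat.loc[f, "variant_count"] - exp) / sd) if sd else 0.0
    return {
        "report": report,
        "percent_sum": float(report["percent_of_total"].sum()),
        "pooled_rate": float(pooled),
        "feature_z": z,
        "max_abs_z": float(max(abs(v) for v in z.values())),
    }


def run_pca_scenario(seed: int = 0, n_replicates: int = 49) -> dict:
    """Planted 2-group PCA fingerprint with equalized subsample replicates.

    Libraries are mapped once after length equalization; each
    replicate's abundances are accumulated from the alignments of that
    replicate's read subset (a read's placement does not depend on the
    other reads in the subsample).
    """
    samples, group_a, group_b = pca_design(seed)
    first_build = next(iter(samples.values()))[0]
    contigs = reference_contigs(first_build)
    index = mapping.build_index(contigs, 13)
    te_meta = {
        c.contig_id: (c.superfamily, len(c)) for c in contigs if c.category == "TE"
    }
    ucos_ids = [c.contig_id for c in contigs if c.category == "UCOS"]
    clen = {c.contig_id: len(c) for c in contigs}

    clipped: dict[str, list[ReadRecord]] = {}
    aln_by_read: dict[str, dict[str, AlignmentRecord]] = {}
    for i, (name, (build, profile)) in enumerate(sorted(samples.items())):
        reads = simulate_reads(build.genome, profile)
        trimmed = readprep.trim_library(reads)
        clip = [c for r in trimmed if (c := readprep.hard_clip(r, 60)) is not None]
        clipped[name] = clip
        alns = mapping.map_reads(clip, index, seed=seed + 500 + i)
        aln_by_read[name] = {a.read_id: a for a in alns}

    def abundance_series(names_to_alns: dict[str, list[AlignmentRecord]]) -> dict[str, pd.Series]:
        out = {}
        for name, alns in names_to_alns.items():
            totals: dict[str, int] = {}
            for a in alns:
                totals[a.contig_id] = totals.get(a.contig_id, 0) + a.aligned_length
            baseline = float(np.mean([totals.get(u, 0) / clen[u] for u in ucos_ids]))
            sf: dict[str, float] = {}
            for cid, (superfam, length) in te_meta.items():
                rel = (totals.get(cid, 0) / length) / baseline
                sf[superfam] = sf.get(superfam, 0.0) + rel
            out[name] = pd.Series(sf).sort_index()
        return out

    full_series = abundance_series(
        {name: list(aln_by_read[name].values()) for name in clipped}
    )
    full_matrix = fingerprint.assemble_matrix(full_series)
    full_result = fingerprint.run_pca(full_matrix)

    replicates = readprep.equalize_libraries(clipped, 60, n_replicates, seed)
    rep_matrices = []
    for rep in replicates:
        series = abundance_series(
            {
                name: [
                    aln_by_read[name][r.read_id]
                    for r in rep.reads[name]
                    if r.read_id in aln_by_read[name]
                ]
                for name in rep.reads
            }
        )
        rep_matrices.append(fingerprint.assemble_matrix(series))
    rep_results, stability = fingerprint.replicate_pca(rep_matrices, full_matrix)

    def separated(result: fingerprint.PCAResult) -> bool:
        pc1 = result.scores["PC1"]
        a = pc1.loc[[s for s in group_a if s in pc1.index]]
        b = pc1.loc[[s for s in group_b if s in pc1.index]]
        return bool(a.max() < b.min() or b.max() < a.min())

    rep_sep = [separated(r) for r in rep_results]
    return {
        "full_matrix": full_matrix,
        "full_result": full_result,
        "replicate_results": rep_results,
        "stability": stability,
        "group_a": group_a,
        "group_b": group_b,
        "full_separated": separated(full_result),
        "replicate_separation_fraction": float(np.mean(rep_sep)),
    }


def run_species_tree_scenario(seed: int = 0, B: int = 100) -> dict:
    """STAR + multilocus bootstrap on the planted 6-taxon design."""
    trees, species_newick, planted, outgroup = species_tree_design(seed)
    true_bips = phylogeny.bipartitions(phylogeny.tree_from_newick(species_newick))
    star = phylogeny.star_species_tree(trees, outgroup)
    boot = phylogeny.multilocus_bootstrap(
        None, outgroup, B=B, seed=seed + 1, gene_trees=trees
    )
    return {
        "species_tree": star,
        "recovered": phylogeny.bipartitions(star) == true_bips,
        "bootstrap": boot,
        "planted_clade": planted,
        "planted_support": phylogeny.clade_support(boot, planted),
    }


# ---------------------------------------------------------------------------
# truth attribution


def read_true_family(read_id: str, truth: TruthSet, read_length: int) -> str | None:
    """Planted family a simulated read originates from (by read midpoint)."""
    start, flen, mate = source_interval(read_id)
    if mate == 2:
        lo = start + flen - read_length
    else:
        lo = start
    mid = lo + read_length // 2
    for p in truth.placements:
        if p.start <= mid < p.end:
            return p.family_id
    return None


def clustering_family_fractions(
    partition: list[set],
    reads: list[ReadRecord],
    truth: TruthSet,
    min_majority: float = 0.5,
) -> dict[str, float]:
    """De novo genome fraction per planted family.

    Each cluster is attributed to the planted family that the majority
    of its reads originate from (ground-truth read provenance); a
    family's fraction is the summed size of its clusters over all reads
    used. This scores cluster *sizes* while sidestepping annotation.
    """
    total = len(reads)
    fractions: dict[str, float] = {f: 0.0 for f in truth.families}
    for members in partition:
        labels: dict[str, int] = {}
        for v in members:
            fam = read_true_family(reads[v].read_id, truth, len(reads[v]))
            if fam is not None:
                labels[fam] = labels.get(fam, 0) + 1
        if not labels:
            continue
        fam, n = max(labels.items(), key=lambda kv: (kv[1], kv[0]))
        if n / len(members) >= min_majority:
            fractions[fam] += len(members) / total
    return fractions


def mapping_family_fractions(table: pd.DataFrame, genome_size: int) -> dict[str, float]:
    """Mapping-based genome fraction per family: rel_cn x length / genome."""
    return {
        fid: float(row["relative_copy_number"] * row["length"] / genome_size)
        for fid, row in table.iterrows()
    }
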