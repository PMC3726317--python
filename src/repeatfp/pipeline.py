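"""End-to-end pipeline orchestration: config, stages, run manifest.

A single YAML config describes the synthetic study (families, samples,
stage parameters); ``run_pipeline`` executes a requested subset of
stages in dependency order, writes every table with a commented
metadata header (tool version, config hash, seed), and records a run
manifest with SHA-256 checksums so that determinism can be verified by
re-running. Stages communicate in memory; requesting a stage whose
upstream never ran raises :class:`DependencyError`.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, abundance, clustering, diversity, fingerprint, mapping, phylogeny, readprep
from .annotations import write_gff3
from .records import write_fasta, write_fastq
from .scenarios import reference_contigs
from .synthetic import (
    FamilySpec,
    LibraryProfile,
    build_reference,
    idx_to_seq,
    mutate,
    seq_to_idx,
    simulate_reads,
    write_truth,
)

STAGES = ["simulate", "prep", "map", "abundance", "diversity", "fingerprint", "cluster", "phylo"]

_DEPS = {
    "simulate": [],
    "prep": ["simulate"],
    "map": ["prep"],
    "abundance": ["map"],
    "diversity": ["map"],
    "fingerprint": ["abundance"],
    "cluster": ["prep"],
    "phylo": ["map"],
}


class ValidationError(ValueError):
    """Invalid configuration or inputs (CLI exit code 2)."""


class DependencyError(RuntimeError):
    """A requested stage is missing an upstream artifact (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    output_dir: Path
    seed: int = 0
    simulate: dict[str, Any] = field(default_factory=dict)
    prep: dict[str, Any] = field(default_factory=dict)
    mapping: dict[str, Any] = field(default_factory=dict)
    abundance: dict[str, Any] = field(default_factory=dict)
    diversity: dict[str, Any] = field(default_factory=dict)
    fingerprint: dict[str, Any] = field(default_factory=dict)
    cluster: dict[str, Any] = field(default_factory=dict)
    phylo: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, output_dir: str | Path | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        out = Path(output_dir or raw.get("output_dir", "repeatfp_out"))
        kwargs = {k: raw.get(k, {}) for k in ("simulate", "prep", "abundance", "diversity", "fingerprint", "cluster", "phylo")}
        kwargs["mapping"] = raw.get("mapping", raw.get("map", {}))
        return cls(output_dir=out, seed=int(raw.get("seed", 0)), **kwargs)

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.__dict__.items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, meta: dict[str, Any]) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict[str, Any]:
    """Run the requested stages; returns the run manifest (also written).

    The manifest lists every output with its SHA-256 checksum; two runs
    with identical config and seed produce identical checksums.
    """
    stages = stages or STAGES
    for s in stages:
        if s not in STAGES:
            raise ValidationError(f"unknown stage {s!r}")
        for dep in _DEPS[s]:
            if dep not in stages:
                raise DependencyError(f"stage {s!r} requires stage {dep!r}")
    ordered = [s for s in STAGES if s in stages]

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "tool": f"repeatfp {__version__}",
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    manifest: dict[str, Any] = {"config_hash": config.config_hash(), "seed": config.seed,
                                "stages": ordered, "outputs": {}, "timings_s": {}}
    state: dict[str, Any] = {}

    def record(path: Path) -> None:
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)

    for stage in ordered:
        t0 = time.time()
        _run_stage(stage, config, out, state, meta, record)
        manifest["timings_s"][stage] = round(time.time() - t0, 3)

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _families_from_config(sim: dict[str, Any]) -> list[FamilySpec]:
    fams = []
    for f in sim.get("families", []):
        fams.append(
            FamilySpec(
                family_id=f["family_id"],
                te_class=str(f.get("te_class", "I")),
                superfamily=f.get("superfamily", "LTR/Gypsy"),
                consensus_length=int(f.get("consensus_length", 3000)),
                copy_number=int(f.get("copy_number", 10)),
                per_copy_divergence=float(f.get("per_copy_divergence", 0.0)),
            )
        )
    if not fams:
        raise ValidationError("simulate.families must list at least one family")
    return fams


def _run_stage(stage, config, out, state, meta, record) -> None:  # noqa: C901
    sim = config.simulate
    if stage == "simulate":
        specs = _families_from_config(sim)
        build = build_reference(
            specs,
            n_ucos=int(sim.get("n_ucos", 10)),
            ucos_length=int(sim.get("ucos_length", 1500)),
            background_length=int(sim.get("background_length", 300_000)),
            seed=config.seed,
        )
        refdir = out / "refs"
        refdir.mkdir(exist_ok=True)
        write_fasta({"genome": build.genome}, refdir / "genome.fa")
        write_fasta(build.consensus, refdir / "te_consensus.fa")
        write_fasta(build.ucos, refdir / "ucos.fa")
        write_gff3(build.annotations, refdir / "features.gff3")
        write_truth(build.truth, out / "truth.tsv")
        for p in ("genome.fa", "te_consensus.fa", "ucos.fa", "features.gff3"):
            record(refdir / p)
        record(out / "truth.tsv")

        readdir = out / "reads"
        readdir.mkdir(exist_ok=True)
        libraries: dict[str, list] = {}
        sample_cfgs = sim.get("samples", [{"sample_id": "S1"}])
        for i, sc in enumerate(sample_cfgs):
            sid = sc.get("sample_id", f"S{i + 1}")
            genome = build.genome
            gdiv = float(sc.get("genome_divergence", 0.0))
            if gdiv > 0:
                rng = np.random.default_rng([config.seed, 77_000 + i])
                arr, _, _ = mutate(rng, seq_to_idx(genome), gdiv)
                genome = idx_to_seq(arr)
            profile = LibraryProfile(
                read_length=int(sc.get("read_length", 60)),
                mean_depth=float(sc.get("mean_depth", 5.0)),
                base_error_rate=float(sc.get("base_error_rate", 0.002)),
                seed=int(sc.get("seed", config.seed + 1000 + i)),
                library_id=sid,
            )
            reads = simulate_reads(genome, profile)
            write_fastq(reads, readdir / f"{sid}.fastq")
            record(readdir / f"{sid}.fastq")
            libraries[sid] = reads
        state["build"] = build
        state["libraries"] = libraries

    elif stage == "prep":
        if "libraries" not in state:
            raise DependencyError("stage 'prep' is missing output of stage 'simulate'")
        q_min = int(config.prep.get("q_min", 20))
        trimdir = out / "reads_trimmed"
        trimdir.mkdir(exist_ok=True)
        trimmed = {}
        for sid, reads in state["libraries"].items():
            tr = readprep.trim_library(reads, q_min)
            write_fastq(tr, trimdir / f"{sid}.fastq")
            record(trimdir / f"{sid}.fastq")
            trimmed[sid] = tr
        state["trimmed"] = trimmed

    elif stage == "map":
        if "trimmed" not in state:
            raise DependencyError("stage 'map' is missing output of stage 'prep'")
        contigs = reference_contigs(state["build"])
        index = mapping.build_index(contigs, int(config.mapping.get("k", 13)))
        alndir = out / "aln"
        alndir.mkdir(exist_ok=True)
        alignments, piles = {}, {}
        rate = float(config.mapping.get("max_mismatch_rate", 0.08))
        for i, (sid, reads) in enumerate(state["trimmed"].items()):
            alns = mapping.map_reads(reads, index, rate, seed=config.seed + 2000 + i)
            mapping.export_sam(alns, contigs, alndir / f"{sid}.sam")
            record(alndir / f"{sid}.sam")
            alignments[sid] = alns
            piles[sid] = mapping.pileup(alns, contigs)
        state["contigs"] = contigs
        state["alignments"] = alignments
        state["piles"] = piles

    elif stage == "abundance":
        if "piles" not in state:
            raise DependencyError("stage 'abundance' is missing output of stage 'map'")
        tabdir = out / "tables"
        tabdir.mkdir(exist_ok=True)
        tables = {}
        sf_rows = {}
        for sid, pile in state["piles"].items():
            tab = abundance.copy_number_table(pile, sid)
            _write_tsv(tab, tabdir / f"{sid}.family_cn.tsv",
                       meta | {"ucos_baseline": tab.attrs["ucos_baseline"]})
            record(tabdir / f"{sid}.family_cn.tsv")
            tables[sid] = tab
            sf_rows[sid] = abundance.superfamily_abundance(tab)["relative_copy_number"]
        sf = pd.DataFrame(sf_rows).T.sort_index()
        sf.index.name = "sample"
        _write_tsv(sf, tabdir / "superfamily_abundance.tsv", meta)
        record(tabdir / "superfamily_abundance.tsv")
        gsize = float(config.abundance.get("genome_size", state["build"].truth.genome_size))
        gf = pd.DataFrame(
            {sid: abundance.genome_fraction(tab, gsize) for sid, tab in tables.items()}
        ).T.sort_index()
        gf.index.name = "sample"
        _write_tsv(gf, tabdir / "genome_fraction.tsv", meta | {"genome_size": gsize})
        record(tabdir / "genome_fraction.tsv")
        state["tables"] = tables
        state["superfamily"] = sf

    elif stage == "diversity":
        if "piles" not in state:
            raise DependencyError("stage 'diversity' is missing output of stage 'map'")
        tabdir = out / "tables"
        tabdir.mkdir(exist_ok=True)
        cfg = config.diversity
        te_ids = [c.contig_id for c in state["contigs"] if c.category == "TE"]
        lengths = {c.contig_id: len(c) for c in state["contigs"] if c.category == "TE"}
        for sid, pile in state["piles"].items():
            variants = diversity.call_variant_sites(
                pile,
                min_depth=int(cfg.get("min_depth", 7)),
                min_base_quality=int(cfg.get("min_base_quality", 20)),
                min_alt_support=int(cfg.get("min_alt_support", 2)),
                min_alt_fraction=float(cfg.get("min_alt_fraction", 0.2)),
                contig_ids=te_ids,
            )
            vdf = pd.DataFrame(
                [
                    {"contig": v.contig_id, "pos": v.pos, "ref": v.ref_base,
                     "alts": ",".join(f"{b}:{n}" for b, n in v.alt_counts), "depth": v.depth}
                    for v in variants
                ]
            )
            _write_tsv(vdf.set_index("contig") if len(vdf) else vdf, tabdir / f"{sid}.variants.tsv", meta)
            record(tabdir / f"{sid}.variants.tsv")
            dtab = diversity.diversity_table(pile, variants)
            _write_tsv(dtab, tabdir / f"{sid}.diversity.tsv", meta)
            record(tabdir / f"{sid}.diversity.tsv")
            anns = state["build"].annotations
            if anns:
                annotated = {a.contig_id for a in anns}
                part = diversity.partition_variants(
                    variants, anns, {c: lengths[c] for c in lengths if c in annotated}
                )
                _write_tsv(part, tabdir / f"{sid}.partition.tsv", meta)
                record(tabdir / f"{sid}.partition.tsv")

    elif stage == "fingerprint":
        if "superfamily" not in state:
            raise DependencyError("stage 'fingerprint' is missing output of stage 'abundance'")
        tabdir = out / "tables"
        matrix = fingerprint.assemble_matrix(
            {sid: state["superfamily"].loc[sid] for sid in state["superfamily"].index}
        )
        _write_tsv(matrix, tabdir / "fingerprint_matrix.tsv", meta)
        record(tabdir / "fingerprint_matrix.tsv")
        if matrix.shape[0] >= 2:
            res = fingerprint.run_pca(matrix)
            _write_tsv(res.scores, tabdir / "pca_scores.tsv", meta)
            _write_tsv(res.loadings, tabdir / "pca_loadings.tsv", meta)
            ev = pd.DataFrame(
                {"proportion": res.explained_variance},
                index=[f"PC{i + 1}" for i in range(len(res.explained_variance))],
            )
            ev.index.name = "component"
            _write_tsv(ev, tabdir / "pca_variance.tsv", meta)
            for p in ("pca_scores.tsv", "pca_loadings.tsv", "pca_variance.tsv"):
                record(tabdir / p)

    elif stage == "cluster":
        if "trimmed" not in state:
            raise DependencyError("stage 'cluster' is missing output of stage 'prep'")
        cfg = config.cluster
        sid = cfg.get("sample") or sorted(state["trimmed"])[0]
        reads = clustering.subsample_reads(
            state["trimmed"][sid], int(cfg.get("max_vertices", 15000)), seed=config.seed
        )
        G = clustering.build_read_graph(
            reads,
            k=int(cfg.get("k", 17)),
            min_identity=float(cfg.get("min_identity", 0.90)),
            min_overlap_fraction=float(cfg.get("min_overlap_fraction", 0.55)),
            seed=config.seed,
        )
        parts = clustering.louvain_clusters(G, seed=config.seed)
        library = [c for c in state.get("contigs", reference_contigs(state["build"])) if c.category == "TE"]
        report = clustering.cluster_report(
            parts, len(reads), reads, library, graph=G,
            cutoff=float(cfg.get("cutoff", 0.0001)),
        )
        cdir = out / "cluster"
        cdir.mkdir(exist_ok=True)
        _write_tsv(report, cdir / f"{sid}.clusters.tsv", meta | {"total_reads_used": len(reads)})
        record(cdir / f"{sid}.clusters.tsv")
        with open(cdir / f"{sid}.members.tsv", "w") as fh:
            fh.write("cluster_id\tread_id\n")
            for cid, members in enumerate(parts, start=1):
                for v in sorted(members):
                    fh.write(f"{cid}\t{reads[v].read_id}\n")
        record(cdir / f"{sid}.members.tsv")

    elif stage == "phylo":
        if "piles" not in state:
            raise DependencyError("stage 'phylo' is missing output of stage 'map'")
        cfg = config.phylo
        samples = sorted(state["piles"])
        exclude = set(cfg.get("exclude_samples", []))
        samples = [s for s in samples if s not in exclude]
        if len(samples) < 4:
            raise ValidationError("phylo stage needs at least 4 included samples")
        outgroup = cfg.get("outgroup", samples[0])
        ucos_ids = [c.contig_id for c in state["contigs"] if c.category == "UCOS"]
        loci: dict[str, dict[str, str]] = {u: {} for u in ucos_ids}
        for sid in samples:
            cons = phylogeny.consensus_sequences(
                state["piles"][sid],
                ucos_ids,
                min_depth=int(cfg.get("min_depth", 6)),
                majority_fraction=float(cfg.get("majority_fraction", 0.8)),
            )
            for u, seq in cons.items():
                loci[u][sid] = seq
        kept, concat, partitions = phylogeny.filter_columns_and_loci(
            loci, min_length=int(cfg.get("min_locus_length", 50))
        )
        pdir = out / "phylo"
        pdir.mkdir(exist_ok=True)
        phylogeny.write_nexus(concat, partitions, pdir / "matrix.nex")
        record(pdir / "matrix.nex")
        if len(kept) < 2:
            raise ValidationError("fewer than 2 usable loci for the species tree")
        boot = phylogeny.multilocus_bootstrap(
            kept, outgroup, B=int(cfg.get("bootstrap_replicates", 100)), seed=config.seed
        )
        with open(pdir / "star.nwk", "w") as fh:
            fh.write(boot.point_tree.as_string(schema="newick"))
        with open(pdir / "consensus.nwk", "w") as fh:
            fh.write(boot.consensus_tree.as_string(schema="newick"))
        record(pdir / "star.nwk")
        record(pdir / "consensus.nwk")
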