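"""Variable-site calling and nucleotide variability of repeat families.

"Nucleotide diversity" here is the count of qualifying variable sites
on a reference contig divided by contig length. Because reads from all
copies of a family pile onto one consensus, a variable site may reflect
either heterozygosity in one copy or divergence between copies; the two
are deliberately not separated.

Variability of LTR-element components (LTRs, GAG/AP/RT/RH/IT ORFs) is
reported by partitioning called variants across annotated feature
intervals, with everything unannotated counted as "outside".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import GENE_FEATURES, TERMINAL_FEATURES, FeatureAnnotation
from .mapping import Pileup

__all__ = [
    "VariantSite",
    "call_variant_sites",
    "nucleotide_diversity",
    "diversity_table",
    "partition_variants",
    "log10_diversity",
]


@dataclass(frozen=True)
class VariantSite:
    """A called variable site on a reference contig."""

    contig_id: str
    pos: int
    ref_base: str
    alt_counts: tuple[tuple[str, int], ...]  # alt base -> high-quality support
    depth: int  # high-quality filtered depth


def call_variant_sites(
    pile: Pileup,
    min_depth: int = 7,
    min_base_quality: int = 20,
    min_alt_support: int = 2,
    min_alt_fraction: float = 0.2,
    contig_ids: list[str] | None = None,
) -> list[VariantSite]:
    """Call variable sites from a pileup.

    A site qualifies when its quality-filtered depth (bases with
    quality >= ``min_base_quality``) is at least ``min_depth`` and some
    non-reference base is supported by at least ``min_alt_support``
    high-quality reads making up at least ``min_alt_fraction`` of the
    filtered depth. Bases below ``min_base_quality`` are ignored
    entirely. The default depth cutoff of 7 encodes "read depth higher
    than 6".
    """
    if min_base_quality < pile.hq_threshold:
        raise ValueError(
            "min_base_quality below the pileup's hq_threshold: aggregate "
            "high-quality depth was accumulated at a stricter cutoff"
        )
    out: list[VariantSite] = []
    ids = contig_ids if contig_ids is not None else list(pile.contigs)
    for cid in ids:
        contig = pile.contigs[cid]
        hq = pile.hq_depth[cid]
        for pos, tally in sorted(pile.alts[cid].items()):
            depth = int(hq[pos])
            if depth < min_depth:
                continue
            alt_counts = []
            for base, quals in sorted(tally.items()):
                n = sum(1 for q in quals if q >= min_base_quality)
                if n >= min_alt_support and n / depth >= min_alt_fraction:
                    alt_counts.append((base, n))
            if alt_counts:
                out.append(
                    VariantSite(cid, pos, contig.sequence[pos], tuple(alt_counts), depth)
                )
    return out


def nucleotide_diversity(variants: list[VariantSite], contig_length: int) -> float:
    """Variable sites per base pair of the reference contig."""
    if contig_length <= 0:
        raise ValueError("contig length must be > 0")
    return len(variants) / contig_length


def diversity_table(pile: Pileup, variants: list[VariantSite]) -> pd.DataFrame:
    """Per-family diversity with super-family and class labels.

    One row per TE contig: ``n_variants``, ``length``, ``diversity``
    and a floored ``log10_diversity`` for plotting (zeros floored at
    1/(2*length), recorded in ``df.attrs``).
    """
    counts: dict[str, int] = {}
    for v in variants:
        counts[v.contig_id] = counts.get(v.contig_id, 0) + 1
    rows = []
    for c in pile.contigs.values():
        if c.category != "TE":
            continue
        n = counts.get(c.contig_id, 0)
        div = n / len(c)
        rows.append(
            {
                "family": c.contig_id,
                "superfamily": c.superfamily,
                "te_class": c.te_class,
                "length": len(c),
                "n_variants": n,
                "diversity": div,
                "log10_diversity": math.log10(div if div > 0 else 1 / (2 * len(c))),
            }
        )
    df = pd.DataFrame(rows).set_index("family")
    df.attrs["zero_floor"] = "log10 zeros floored at 1/(2*contig_length)"
    return df


def log10_diversity(diversity: float, contig_length: int) -> float:
    """log10 with the documented zero floor of 1/(2*contig_length)."""
    return math.log10(diversity if diversity > 0 else 1 / (2 * contig_length))


def partition_variants(
    variants: list[VariantSite],
    annotations: list[FeatureAnnotation],
    contig_lengths: dict[str, int],
    strict: bool = False,
) -> pd.DataFrame:
    """Split variant counts across element components.

    Every variant is assigned to exactly one class by position, with
    gene features taking precedence over terminal repeats and anything
    unannotated counted as ``outside``. The report carries, per class,
    the variant count, percent of total variants, summed feature length
    and per-bp rate; percentages sum to 100 when any variant exists.
    Only contigs present in ``contig_lengths`` participate.
    """
    ann_by_contig: dict[str, list[FeatureAnnotation]] = {}
    for a in annotations:
        if a.contig_id in contig_lengths:
            if a.end > contig_lengths[a.contig_id]:
                raise ValueError(f"annotation beyond contig end on {a.contig_id}")
            ann_by_contig.setdefault(a.contig_id, []).append(a)

    classes = sorted(GENE_FEATURES | TERMINAL_FEATURES) + ["outside"]
    lengths = {cls: 0 for cls in classes}
    counts = {cls: 0 for cls in classes}

    # per-contig label maps; gene features painted last so they win overlaps
    label_maps: dict[str, np.ndarray] = {}
    idx = {cls: i for i, cls in enumerate(classes)}
    for cid, length in contig_lengths.items():
        lab = np.full(length, idx["outside"], dtype=np.int16)
        anns = ann_by_contig.get(cid, [])
        for a in anns:
            if a.feature in TERMINAL_FEATURES:
                lab[a.start : a.end] = idx[a.feature]
        for a in anns:
            if a.feature in GENE_FEATURES:
                lab[a.start : a.end] = idx[a.feature]
        label_maps[cid] = lab
        for i, cls in enumerate(classes):
            lengths[cls] += int(np.count_nonzero(lab == i))

    for v in variants:
        if v.contig_id not in label_maps:
            if strict:
                raise ValueError(f"variant on unannotated contig {v.contig_id}")
            continue
        cls = classes[label_maps[v.contig_id][v.pos]]
        counts[cls] += 1

    total = sum(counts.values())
    rows = []
    for cls in classes:
        if lengths[cls] == 0 and counts[cls] == 0:
            continue
        rows.append(
            {
                "feature_class": cls,
                "variant_count": counts[cls],
                "percent_of_total": 100.0 * counts[cls] / total if total else 0.0,
                "total_feature_length": lengths[cls],
                "per_bp_rate": counts[cls] / lengths[cls] if lengths[cls] else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("feature_class")
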