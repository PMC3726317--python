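"""UCOS-normalized relative copy numbers and genome fractions.

The depth baseline of a library is the unweighted mean of the per-contig
mean coverages of the single-copy (UCOS) contigs; each TE family's mean
coverage divided by that baseline estimates its copy number relative to
single-copy genes. Super-family summaries come in two flavours: a
count-like total of relative copy numbers (for fingerprint plots) and a
base-pair genome fraction, where each family is weighted by its
consensus length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapping import Pileup, ReferenceContig

__all__ = [
    "contig_mean_coverage",
    "ucos_baseline",
    "relative_copy_number",
    "copy_number_table",
    "superfamily_abundance",
    "genome_fraction",
]


def contig_mean_coverage(coverage: np.ndarray) -> float:
    """Mean per-position depth over the full contig (zeros included)."""
    coverage = np.asarray(coverage)
    if coverage.size == 0:
        raise ValueError("empty contig")
    return float(coverage.mean())


def ucos_baseline(pile: Pileup, pooled: bool = False) -> float:
    """Library depth baseline from the UCOS contigs.

    Unweighted mean of per-contig mean coverages by default, so every
    UCOS gene contributes equally regardless of length; ``pooled=True``
    gives the base-weighted alternative (total bases / total length).
    """
    ucos = [c for c in pile.contigs.values() if c.category == "UCOS"]
    if not ucos:
        raise ValueError("no UCOS contigs in pileup")
    if pooled:
        total = sum(pile.coverage(c.contig_id).sum() for c in ucos)
        length = sum(len(c) for c in ucos)
        return float(total / length)
    return float(np.mean([contig_mean_coverage(pile.coverage(c.contig_id)) for c in ucos]))


def relative_copy_number(family_mean_coverage: float, baseline: float) -> float:
    """Family coverage over the single-copy baseline."""
    if baseline <= 0:
        raise ValueError("UCOS baseline must be > 0")
    return family_mean_coverage / baseline


def copy_number_table(pile: Pileup, sample_id: str = "sample") -> pd.DataFrame:
    """Per-family coverage and relative copy number for one library.

    Returns a DataFrame indexed by family (TE contig) id with columns
    ``superfamily``, ``te_class``, ``length``, ``mean_coverage``,
    ``relative_copy_number`` and ``sample``; the UCOS baseline is stored
    in ``df.attrs["ucos_baseline"]``.
    """
    baseline = ucos_baseline(pile)
    rows = []
    for c in pile.contigs.values():
        if c.category != "TE":
            continue
        mc = contig_mean_coverage(pile.coverage(c.contig_id))
        rows.append(
            {
                "family": c.contig_id,
                "superfamily": c.superfamily,
                "te_class": c.te_class,
                "length": len(c),
                "mean_coverage": mc,
                "relative_copy_number": relative_copy_number(mc, baseline),
                "sample": sample_id,
            }
        )
    df = pd.DataFrame(rows).set_index("family")
    df.attrs["ucos_baseline"] = baseline
    df.attrs["sample"] = sample_id
    return df


def superfamily_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Super-family totals of relative copy number, plus proportions.

    Totals are unweighted sums over member families (a count-like
    quantity); ``proportional_abundance`` normalises them to 1 across
    super-families. All-zero input yields an explicitly empty frame.
    """
    if table["superfamily"].isna().any() or (table["superfamily"] == "NA").any():
        raise ValueError("every TE family needs a superfamily label")
    totals = table.groupby("superfamily")["relative_copy_number"].sum()
    grand = totals.sum()
    if grand == 0:
        return pd.DataFrame(columns=["relative_copy_number", "proportional_abundance"])
    out = totals.to_frame()
    out["proportional_abundance"] = totals / grand
    return out


def genome_fraction(table: pd.DataFrame, genome_size: float) -> pd.Series:
    """Per-super-family genome fraction (0..1 scale).

    fraction_s = sum over families f in s of rel_cn_f * length_f /
    genome_size — relative copy number converted to occupied base pairs
    via the consensus length.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    if table["length"].isna().any():
        raise ValueError("missing consensus length")
    bases = table["relative_copy_number"] * table["length"]
    return bases.groupby(table["superfamily"]).sum() / genome_size
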