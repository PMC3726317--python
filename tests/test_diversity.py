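"""Variable-site calling thresholds, diversity and feature partitioning."""

import math

import numpy as np
import pytest

from repeatfp import diversity
from repeatfp.annotations import FeatureAnnotation
from repeatfp.diversity import VariantSite, call_variant_sites, nucleotide_diversity, partition_variants
from repeatfp.mapping import AlignmentRecord, Pileup, ReferenceContig
from repeatfp.scenarios import run_mapping
from repeatfp.synthetic import FamilySpec, LibraryProfile, build_reference, simulate_reads


def stacked_pileup(ref: str, reads_at_zero: list[str], qual: int = 30) -> Pileup:
    """Pileup of full-length reads all starting at position 0."""
    contig = ReferenceContig("c", ref, "TE", "I", "LTR/Gypsy")
    p = Pileup([contig], hq_threshold=20)
    for i, seq in enumerate(reads_at_zero):
        mism = tuple(j for j, (a, b) in enumerate(zip(ref, seq)) if a != b)
        p.add(
            AlignmentRecord(
                read_id=f"r{i}", contig_id="c", start=0, strand="+",
                aligned_length=len(seq), mismatch_offsets=mism, score=0, mapq_proxy=60,
                aligned_seq=seq, aligned_quals=np.full(len(seq), qual, dtype=np.uint8),
            )
        )
    return p


class TestCallThresholds:
    REF = "AAAAAAAAAA"

    def test_depth_six_never_variable_at_default(self):
        # "read depth higher than 6" => a depth-6 site is excluded
        reads = ["AACAAAAAAA"] * 3 + [self.REF] * 3
        p = stacked_pileup(self.REF, reads)
        assert call_variant_sites(p) == []

    def test_depth_seven_variable(self):
        reads = ["AACAAAAAAA"] * 3 + [self.REF] * 4
        p = stacked_pileup(self.REF, reads)
        sites = call_variant_sites(p)
        assert [(s.pos, s.ref_base) for s in sites] == [(2, "A")]
        assert sites[0].alt_counts == (("C", 3),)

    def test_reference_only_column_not_variable(self):
        p = stacked_pileup(self.REF, [self.REF] * 10)
        assert call_variant_sites(p) == []

    def test_min_alt_support_boundary(self):
        reads = ["AACAAAAAAA"] * 1 + [self.REF] * 9
        p = stacked_pileup(self.REF, reads)
        assert call_variant_sites(p, min_alt_fraction=0.0) == []  # 1 < min_alt_support

    def test_min_alt_fraction_boundary(self):
        reads = ["AACAAAAAAA"] * 2 + [self.REF] * 8
        p = stacked_pileup(self.REF, reads)
        assert call_variant_sites(p, min_alt_fraction=0.2) != []  # 2/10 == 0.2 inclusive
        assert call_variant_sites(p, min_alt_fraction=0.21) == []

    def test_low_quality_bases_ignored_entirely(self):
        reads = ["AACAAAAAAA"] * 3 + [self.REF] * 4
        p = stacked_pileup(self.REF, reads, qual=10)  # all below Q20
        assert call_variant_sites(p) == []


def test_called_sites_match_truth_mismatch_columns():
    """Pooled diverged copies: calls equal the truth-derived site set.

    With ~25x coverage per copy, no sequencing errors, a permissive
    allele fraction and divergence low enough that no read exceeds the
    mapper's mismatch ceiling, a site should be called iff at least one
    planted copy is mutated there (checked away from contig edges,
    where read ends thin the coverage). At higher divergence the
    equality breaks down because reads over locally dense mutation
    clusters stop mapping — the mapping-loss effect asserted in
    test_acceptance.
    """
    specs = [FamilySpec("FAM", "I", "LTR/Gypsy", 2000, 20, 0.02)]
    build = build_reference(specs, n_ucos=3, ucos_length=1000, background_length=60_000, seed=21)
    reads = simulate_reads(
        build.genome, LibraryProfile(read_length=60, mean_depth=25, base_error_rate=0.0, seed=22)
    )
    _, pile = run_mapping(build, reads, seed=23)
    sites = call_variant_sites(pile, min_alt_fraction=0.01, contig_ids=["FAM"])
    called = {s.pos for s in sites}
    truth_cols = set()
    for p in build.truth.placements:
        truth_cols.update(p.mut_offsets)
    interior = range(60, 2000 - 60)
    assert {p for p in called if p in interior} == {p for p in truth_cols if p in interior}


class TestDiversity:
    def test_sites_per_bp(self):
        variants = [VariantSite("c", i, "A", (("C", 2),), 10) for i in range(10)]
        assert nucleotide_diversity(variants, 1000) == 0.01
        assert nucleotide_diversity([], 1000) == 0.0

    def test_log_floor_for_zero(self):
        assert diversity.log10_diversity(0.0, 500) == math.log10(1 / 1000)
        assert diversity.log10_diversity(0.01, 500) == math.log10(0.01)


class TestPartition:
    ANNS = [
        FeatureAnnotation("c", "LTR", 0, 100),
        FeatureAnnotation("c", "RT", 200, 300),
    ]

    def _v(self, pos):
        return VariantSite("c", pos, "A", (("C", 2),), 10)

    def test_all_variants_in_ltr(self):
        rep = partition_variants([self._v(5), self._v(50)], self.ANNS, {"c": 1000})
        assert rep.loc["LTR", "percent_of_total"] == 100.0
        assert rep.loc["RT", "variant_count"] == 0

    def test_ninety_five_five_split(self):
        variants = (
            [self._v(400 + i) for i in range(90)]  # outside
            + [self._v(i) for i in range(5)]  # LTR
            + [self._v(200 + i) for i in range(5)]  # RT (gene)
        )
        rep = partition_variants(variants, self.ANNS, {"c": 1000})
        assert rep.loc["outside", "percent_of_total"] == pytest.approx(90.0)
        assert rep.loc["LTR", "percent_of_total"] == pytest.approx(5.0)
        assert rep.loc["RT", "percent_of_total"] == pytest.approx(5.0)

    def test_conservation_of_counts_and_lengths(self):
        variants = [self._v(p) for p in (0, 150, 250, 999)]
        rep = partition_variants(variants, self.ANNS, {"c": 1000})
        assert rep["variant_count"].sum() == len(variants)
        assert rep["total_feature_length"].sum() == 1000
        assert rep["percent_of_total"].sum() == pytest.approx(100.0, abs=0.1)

    def test_gene_precedence_over_ltr(self):
        anns = self.ANNS + [FeatureAnnotation("c", "RT", 50, 100)]  # overlaps the LTR
        rep = partition_variants([self._v(60)], anns, {"c": 1000})
        assert rep.loc["RT", "variant_count"] == 1

    def test_strict_mode_rejects_unannotated_contig(self):
        with pytest.raises(ValueError):
            partition_variants([VariantSite("x", 1, "A", (("C", 2),), 10)],
                               self.ANNS, {"c": 1000}, strict=True)

    def test_per_bp_rate_definition(self):
        rep = partition_variants([self._v(5)], self.ANNS, {"c": 1000})
        assert rep.loc["LTR", "per_bp_rate"] == pytest.approx(1 / 100)


def test_gff3_round_trip(tmp_path):
    from repeatfp.annotations import read_gff3, write_gff3

    anns = [
        FeatureAnnotation("elem1", "LTR", 0, 700),
        FeatureAnnotation("elem1", "RT", 1500, 2200),
        FeatureAnnotation("elem1", "LTR", 5300, 6000),
    ]
    p = tmp_path / "f.gff3"
    write_gff3(anns, p)
    assert read_gff3(p) == anns


def test_gff3_ltrdigest_style_mapping(tmp_path):
    p = tmp_path / "ltrdigest.gff3"
    p.write_text(
        "##gff-version 3\n"
        "e1\tLTRdigest\tLTR_retrotransposon\t1\t6000\t.\t+\t.\tID=LTRret1\n"
        "e1\tLTRdigest\tlong_terminal_repeat\t1\t700\t.\t+\t.\tParent=LTRret1\n"
        "e1\tLTRdigest\tRR_tract\t710\t720\t.\t+\t.\tParent=LTRret1\n"
        "e1\tLTRdigest\tprotein_match\t1500\t2200\t.\t+\t.\tName=RVT_1\n"
    )
    from repeatfp.annotations import read_gff3

    anns = read_gff3(p)
    assert [(a.feature, a.start, a.end) for a in anns] == [
        ("LTR", 0, 700),
        ("RT", 1499, 2200),
    ]
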