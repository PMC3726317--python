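"""Seed-and-extend mapper, SAM interop and pileups."""

import numpy as np
import pytest

from repeatfp.mapping import (
    ReferenceContig,
    brute_force_best_mismatches,
    build_index,
    export_sam,
    import_alignments,
    map_read,
    map_reads,
    pileup,
)
from repeatfp.records import revcomp
from repeatfp.synthetic import LibraryProfile, simulate_reads

from conftest import make_read


def random_contig(rng, n, contig_id="c", category="other"):
    seq = "".join(rng.choice(list("ACGT"), n))
    return ReferenceContig(contig_id, seq, category)


class TestIndex:
    def test_repeated_kmer_indexed_at_every_offset(self):
        c = ReferenceContig("c", "ACGTACGTACGT", "other")
        idx = build_index([c], k=8)
        hits = sorted(h for h in idx.lookup("ACGTACGT") if h[1] == "+")
        assert hits == [(0, "+", 0), (0, "+", 4)]

    def test_index_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        c = random_contig(rng, 20)
        from repeatfp.mapping import SeedIndex

        idx = SeedIndex([c], 8)
        expected = {}
        for p in range(len(c) - 8 + 1):
            expected.setdefault(c.sequence[p : p + 8], []).append((0, "+", p))
        rc = revcomp(c.sequence)
        for p in range(len(c) - 8 + 1):
            expected.setdefault(rc[p : p + 8], []).append((0, "-", p))
        assert {k: sorted(v) for k, v in idx.kmers.items()} == {
            k: sorted(v) for k, v in expected.items()
        }

    def test_empty_contig_list_is_queryable(self):
        from repeatfp.mapping import SeedIndex

        idx = SeedIndex([], 13)
        assert idx.lookup("A" * 13) == []

    def test_too_small_k_rejected(self):
        with pytest.raises(ValueError):
            build_index([], k=4)


class TestMapRead:
    def test_exact_substring_maps_with_zero_mismatches(self):
        rng = np.random.default_rng(1)
        c = random_contig(rng, 500)
        idx = build_index([c], 13)
        read = make_read(c.sequence[100:160])
        a = map_read(read, idx, rng=np.random.default_rng(0))
        assert (a.contig_id, a.start, a.strand, a.n_mismatches) == ("c", 100, "+", 0)

    def test_reverse_complement_maps_minus_strand_same_interval(self):
        rng = np.random.default_rng(2)
        c = random_contig(rng, 500)
        idx = build_index([c], 13)
        a = map_read(make_read(revcomp(c.sequence[100:160])), idx, rng=np.random.default_rng(0))
        assert (a.start, a.strand, a.n_mismatches) == (100, "-", 0)
        assert a.aligned_seq == c.sequence[100:160]

    def test_unrelated_read_unmapped(self):
        rng = np.random.default_rng(3)
        c = random_contig(rng, 300)
        idx = build_index([c], 13)
        other = "".join(np.random.default_rng(99).choice(list("ACGT"), 60))
        assert map_read(make_read(other), idx, rng=np.random.default_rng(0)) is None

    def test_two_copy_tie_broken_uniformly(self):
        rng = np.random.default_rng(4)
        repeat = "".join(rng.choice(list("ACGT"), 120))
        left = "".join(rng.choice(list("ACGT"), 150))
        mid = "".join(rng.choice(list("ACGT"), 150))
        right = "".join(rng.choice(list("ACGT"), 150))
        c = ReferenceContig("c", left + repeat + mid + repeat + right, "other")
        idx = build_index([c], 13)
        read = make_read(repeat[30:90])
        loci = {150 + 30, 150 + 120 + 150 + 30}
        tie_rng = np.random.default_rng(5)
        starts = []
        for _ in range(10_000):
            a = map_read(read, idx, rng=tie_rng)
            assert a.start in loci and a.mapq_proxy == 0
            starts.append(a.start)
        frac = starts.count(min(loci)) / len(starts)
        assert 0.48 <= frac <= 0.52

    def test_mismatch_ceiling_enforced(self):
        rng = np.random.default_rng(6)
        c = random_contig(rng, 300)
        idx = build_index([c], 13)
        seq = list(c.sequence[50:110])
        # 6 mismatches > ceil(0.08 * 60) = 5, placed away from one seed block
        for pos in (14, 20, 27, 34, 41, 48):
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        assert map_read(make_read("".join(seq)), idx, rng=np.random.default_rng(0)) is None

    def test_agrees_with_brute_force_on_mapped_reads(self):
        rng = np.random.default_rng(7)
        contigs = [random_contig(rng, 400, f"c{i}") for i in range(2)]
        idx = build_index(contigs, 13)
        genome = contigs[0].sequence + contigs[1].sequence
        reads = simulate_reads(
            genome, LibraryProfile(read_length=60, mean_depth=80, base_error_rate=0.01, seed=8)
        )[:1000]
        mapped = 0
        for r in reads:
            a = map_read(r, idx, rng=rng)
            if a is None:
                continue
            mapped += 1
            assert a.n_mismatches == brute_force_best_mismatches(r, contigs)
        assert mapped > 0.8 * len(reads)  # junction reads may legitimately fail


class TestSamRoundTrip:
    def test_round_trip_preserves_placements(self, tmp_path):
        rng = np.random.default_rng(9)
        contigs = [random_contig(rng, 600, "ref1")]
        idx = build_index(contigs, 13)
        reads = simulate_reads(
            contigs[0].sequence,
            LibraryProfile(read_length=60, mean_depth=5, base_error_rate=0.01, seed=10),
        )
        alns = map_reads(reads, idx, seed=11)
        sam = tmp_path / "x.sam"
        export_sam(alns, contigs, sam)
        back, stats = import_alignments(sam, contigs)
        assert stats.imported == len(alns)
        assert [(a.contig_id, a.start, a.strand, a.mismatch_offsets) for a in back] == [
            (a.contig_id, a.start, a.strand, a.mismatch_offsets) for a in alns
        ]

    def test_import_coordinates_and_skips(self, tmp_path):
        contigs = [ReferenceContig("ref1", "A" * 200, "other")]
        sam = tmp_path / "min.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:ref1\tLN:200\n"
            "r1\t0\tref1\t101\t60\t60M\t*\t0\t0\t" + "A" * 60 + "\t" + "I" * 60 + "\tNM:i:0\n"
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 60 + "\t" + "I" * 60 + "\n"
        )
        alns, stats = import_alignments(sam, contigs)
        assert len(alns) == 1
        assert alns[0].start == 100 and alns[0].n_mismatches == 0
        assert stats.skipped_unmapped == 1

    def test_unknown_reference_rejected(self, tmp_path):
        contigs = [ReferenceContig("ref1", "A" * 100, "other")]
        sam = tmp_path / "bad.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:refX\tLN:100\n"
            "r1\t0\trefX\t1\t60\t10M\t*\t0\t0\tAAAAAAAAAA\tIIIIIIIIII\n"
        )
        with pytest.raises(ValueError, match="unknown reference"):
            import_alignments(sam, contigs)


class TestPileup:
    def test_total_coverage_equals_total_aligned_length(self):
        rng = np.random.default_rng(12)
        contigs = [random_contig(rng, 800, "c0")]
        idx = build_index(contigs, 13)
        reads = simulate_reads(
            contigs[0].sequence, LibraryProfile(read_length=60, mean_depth=8, seed=13)
        )
        alns = map_reads(reads, idx, seed=14)
        assert len(alns) >= 100
        p = pileup(alns, contigs)
        assert int(p.coverage("c0").sum()) == sum(a.aligned_length for a in alns)

    def test_no_alignments_gives_zero_coverage(self):
        c = ReferenceContig("c", "ACGT" * 30, "other")
        p = pileup([], [c])
        assert p.coverage("c").sum() == 0 and len(p.coverage("c")) == 120

    def test_zero_divergence_simulation_coverage_recovers_depth(self, small_build):
        # error-free reads from the unmutated single-copy UCOS space
        from repeatfp.scenarios import reference_contigs

        reads = simulate_reads(
            small_build.genome,
            LibraryProfile(read_length=60, mean_depth=10.0, base_error_rate=0.0, seed=15),
        )
        contigs = [c for c in reference_contigs(small_build) if c.category == "UCOS"]
        idx = build_index(contigs, 13)
        alns = map_reads(reads, idx, seed=16)
        p = pileup(alns, contigs)
        for c in contigs:
            mean_cov = p.coverage(c.contig_id).mean()
            assert 8.0 <= mean_cov <= 12.0  # ~10x with edge loss and sampling noise

    def test_column_accessor(self):
        c = ReferenceContig("c", "ACGTACGTACGTACGT", "other")
        idx = build_index([c], 8)
        r = make_read(c.sequence[2:12].replace("G", "T", 1))
        a = map_read(r, idx, max_mismatch_rate=0.2, rng=np.random.default_rng(0))
        p = pileup([a], [c])
        col = p.column("c", a.start + a.mismatch_offsets[0])
        assert col.depth == 1 and col.alt_tally
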