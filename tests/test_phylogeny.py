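"""Consensus matrix rules, NJ, STAR and the multilocus bootstrap."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from repeatfp import phylogeny as ph
from repeatfp.mapping import AlignmentRecord, Pileup, ReferenceContig
from repeatfp.phylogeny import (
    LocusAlignment,
    consensus_sequences,
    filter_columns_and_loci,
    jc69_distance_matrix,
    multilocus_bootstrap,
    neighbor_joining,
    nj_gene_tree,
    star_species_tree,
    tree_from_newick,
)


def pile_with_column(ref: str, reads: list[str], qual: int = 30) -> Pileup:
    contig = ReferenceContig("u", ref, "UCOS")
    p = Pileup([contig], hq_threshold=20)
    for i, seq in enumerate(reads):
        mism = tuple(j for j, (a, b) in enumerate(zip(ref, seq)) if a != b)
        p.add(
            AlignmentRecord(f"r{i}", "u", 0, "+", len(seq), mism, 0, 60,
                            aligned_seq=seq, aligned_quals=np.full(len(seq), qual, dtype=np.uint8))
        )
    return p


class TestConsensus:
    def test_depth_five_is_n_depth_six_is_base(self):
        # "6 or more high quality reads"
        assert consensus_sequences(pile_with_column("A", ["A"] * 5), ["u"]) == {"u": "N"}
        assert consensus_sequences(pile_with_column("A", ["A"] * 6), ["u"]) == {"u": "A"}

    def test_unanimous_alt_is_emitted(self):
        p = pile_with_column("A", ["C"] * 10)
        assert consensus_sequences(p, ["u"]) == {"u": "C"}

    def test_seventy_percent_majority_is_ambiguous(self):
        p = pile_with_column("A", ["A"] * 7 + ["C"] * 3)
        assert consensus_sequences(p, ["u"]) == {"u": "N"}  # 0.7 < 0.8

    def test_eighty_percent_majority_is_called(self):
        p = pile_with_column("A", ["A"] * 8 + ["C"] * 2)
        assert consensus_sequences(p, ["u"]) == {"u": "A"}

    def test_low_quality_reads_do_not_count(self):
        p = pile_with_column("A", ["A"] * 10, qual=10)
        assert consensus_sequences(p, ["u"]) == {"u": "N"}


class TestColumnFilter:
    def _loci(self, lengths_with_n):
        # build one locus of length L with n_cols_with_N columns made ambiguous
        loci = {}
        for name, (L, bad) in lengths_with_n.items():
            s1 = ["A"] * L
            s2 = ["A"] * L
            for i in range(bad):
                s2[i] = "N"
            loci[name] = {"x": "".join(s1), "y": "".join(s2), "z": "".join(s1)}
        return loci

    def test_column_with_single_n_removed(self):
        kept, concat, parts = filter_columns_and_loci(self._loci({"l1": (60, 1)}))
        assert kept[0].retained_length == 59

    def test_locus_length_boundary_49_dropped_50_kept(self):
        loci = self._loci({"short": (60, 11), "long": (60, 10)})
        kept, _, parts = filter_columns_and_loci(loci)
        assert [la.locus_id for la in kept] == ["long"]
        assert kept[0].retained_length == 50

    def test_no_ns_concatenation_is_total_length(self):
        loci = self._loci({"l1": (60, 0), "l2": (80, 0)})
        kept, concat, parts = filter_columns_and_loci(loci)
        assert len(concat["x"]) == 140
        assert parts.to_dict("records") == [
            {"locus": "l1", "start": 1, "end": 60},
            {"locus": "l2", "start": 61, "end": 140},
        ]

    def test_nexus_output(self, tmp_path):
        loci = self._loci({"l1": (60, 0)})
        kept, concat, parts = filter_columns_and_loci(loci)
        p = tmp_path / "m.nex"
        ph.write_nexus(concat, parts, p)
        text = p.read_text()
        assert text.startswith("#NEXUS")
        assert "NCHAR=60" in text and "CHARSET l1 = 1-60;" in text


class TestNeighborJoining:
    def test_additive_matrix_recovered_exactly(self):
        # distances generated on a known 5-taxon tree with branch lengths
        true = tree_from_newick("((A:2,B:3):1,(C:1,D:4):2,E:5);")
        pdm = true.phylogenetic_distance_matrix()
        taxa = sorted(true.taxon_namespace, key=lambda t: t.label)
        D = pd.DataFrame(
            [[pdm.distance(a, b) for b in taxa] for a in taxa],
            index=[t.label for t in taxa],
            columns=[t.label for t in taxa],
        )
        rec = tree_from_newick(neighbor_joining(D), true.taxon_namespace)
        assert ph.bipartitions(rec) == ph.bipartitions(true)
        rec_pdm = rec.phylogenetic_distance_matrix()
        for a, b in itertools.combinations(taxa, 2):
            ra = rec.taxon_namespace.get_taxon(a.label)
            rb = rec.taxon_namespace.get_taxon(b.label)
            assert rec_pdm.distance(ra, rb) == pytest.approx(pdm.distance(a, b), abs=1e-9)

    def test_identical_sequences_give_star_tree_with_zero_lengths(self):
        la = LocusAlignment("l", {"a": "ACGT" * 20, "b": "ACGT" * 20, "c": "ACGT" * 20}, 80)
        t = nj_gene_tree(la)
        assert all(e.length in (0.0, None) for e in t.edges())

    def test_saturated_distance_rejected(self):
        la = LocusAlignment("l", {"a": "A" * 80, "b": "C" * 80, "c": "G" * 80}, 80)
        with pytest.raises(ValueError, match="saturated"):
            jc69_distance_matrix(la)

    def test_fewer_than_three_taxa_rejected(self):
        la = LocusAlignment("l", {"a": "ACGT", "b": "ACGT"}, 4)
        with pytest.raises(ValueError):
            jc69_distance_matrix(la)

    def test_newick_round_trip(self):
        nwk = "((A:1,B:2):0.5,(C:1,D:1):0.5,E:3);"
        t = tree_from_newick(nwk)
        back = tree_from_newick(t.as_string(schema="newick"), t.taxon_namespace)
        assert ph.bipartitions(back) == ph.bipartitions(t)


class TestStar:
    def test_rank_distance_convention(self):
        # concordant gene trees ((A,B),C) rooted on C: d(A,B)=4, d(*,C)=6
        d = ph._rank_distances(tree_from_newick("((A,B),C);"), "C")
        assert d == {frozenset("AB"): 4, frozenset("AC"): 6, frozenset("BC"): 6}

    def test_concordant_trees_return_common_topology(self):
        trees = [tree_from_newick("((A,B),C);") for _ in range(2)]
        sp = star_species_tree(trees, "C")
        leaves = {nd.taxon.label for nd in sp.leaf_node_iter()}
        assert leaves == {"A", "B", "C"}

    def test_single_gene_tree_topology_preserved(self):
        gt = tree_from_newick("(((A,B),(C,D)),E);")
        sp = star_species_tree([gt], "E")
        assert ph.bipartitions(sp) == ph.bipartitions(gt)

    def test_exhaustive_five_taxon_concordance(self):
        """STAR returns the common topology for every unrooted 5-taxon shape."""
        for topo in _all_unrooted_topologies(["A", "B", "C", "D"], "O"):
            gt = tree_from_newick(topo)
            sp = star_species_tree([gt, gt, gt], "O")
            assert ph.bipartitions(sp) == ph.bipartitions(gt), topo

    def test_missing_outgroup_tree_skipped_with_warning(self):
        good = tree_from_newick("((A,B),C);")
        bad = tree_from_newick("(A,B);")
        with pytest.warns(UserWarning, match="outgroup"):
            sp = star_species_tree([good, bad], "C")
        assert {nd.taxon.label for nd in sp.leaf_node_iter()} == {"A", "B", "C"}

    def test_no_usable_trees_rejected(self):
        with pytest.raises(ValueError):
            star_species_tree([tree_from_newick("(A,B);")], "C")


def _all_unrooted_topologies(ingroup, outgroup):
    """All 15 unrooted binary topologies on 4 ingroup taxa + outgroup."""
    # unrooted 5-taxon topologies == rooted 4-taxon topologies with the
    # outgroup attached at the root
    def rooted(taxa):
        if len(taxa) == 1:
            yield taxa[0]
            return
        first = taxa[0]
        for k in range(1, len(taxa)):
            for left_rest in itertools.combinations(taxa[1:], k - 1):
                left = (first,) + left_rest
                right = tuple(t for t in taxa if t not in left)
                for lt in rooted(list(left)):
                    for rt in rooted(list(right)):
                        yield f"({lt},{rt})"

    seen = set()
    for shape in rooted(ingroup):
        if shape not in seen:
            seen.add(shape)
            yield f"({shape},{outgroup});"


class TestBootstrap:
    def _concordant_loci(self, n=6):
        rng = np.random.default_rng(0)
        # sequences consistent with ((A,B),(C,D)),OUT: shared derived sites
        base = rng.choice(list("ACGT"), 200)
        seqs = {}
        for s in ("A", "B", "C", "D", "OUT"):
            seqs[s] = base.copy()
        for i in range(0, 40):  # A,B share changes
            seqs["A"][i] = seqs["B"][i] = "A" if base[i] != "A" else "C"
        for i in range(40, 80):  # C,D share changes
            seqs["C"][i] = seqs["D"][i] = "G" if base[i] != "G" else "T"
        for i in range(80, 140):  # OUT diverges
            seqs["OUT"][i] = "T" if base[i] != "T" else "A"
        return [
            LocusAlignment(f"l{j}", {k: "".join(v) for k, v in seqs.items()}, 200)
            for j in range(n)
        ]

    def test_identical_signal_gives_full_support(self):
        res = multilocus_bootstrap(self._concordant_loci(), "OUT", B=50, seed=1)
        assert res.support and all(v == 100.0 for v in res.support.values())
        assert ph.clade_support(res, {"A", "B"}) == 100.0

    def test_support_labels_on_point_tree(self):
        res = multilocus_bootstrap(self._concordant_loci(), "OUT", B=20, seed=2)
        labels = [nd.label for nd in res.point_tree.postorder_internal_node_iter() if nd.label]
        assert "100" in labels

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            multilocus_bootstrap(self._concordant_loci(), "OUT", B=0, seed=1)

    def test_consensus_tree_matches_point_tree_under_full_concordance(self):
        res = multilocus_bootstrap(self._concordant_loci(), "OUT", B=20, seed=3)
        assert ph.bipartitions(res.consensus_tree) == ph.bipartitions(res.point_tree)
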