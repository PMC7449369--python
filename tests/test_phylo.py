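"""Alignment, trimming, concatenation, distances, NJ, bootstrap, congruence."""

import io
import math

import numpy as np
import pytest
from Bio import Align
from skbio import DistanceMatrix, TreeNode

from mgcminer import phylo, synthetic
from mgcminer.phylo import (Msa, concatenate, congruence_report,
                            is_monophyletic, kimura_protein_distance,
                            neighbor_joining, nontrivial_splits,
                            progressive_align, protein_distance, read_tree,
                            robinson_foulds, trim_blocks)


def tree_of(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick))


class TestProgressiveAlign:
    def test_identical_sequences_gap_free(self):
        msa = progressive_align([("a", "MKWVLT"), ("b", "MKWVLT"), ("c", "MKWVLT")])
        assert msa.rows == ["MKWVLT"] * 3

    def test_two_sequences_reach_optimal_global_score(self):
        a, b = "MKWVLLIAGNETKW", "MKWVIAGNWETKW"
        msa = progressive_align([("a", a), ("b", b)])
        matrix = phylo.load_matrix("BLOSUM62")
        got = 0.0
        for x, y in zip(*msa.rows):
            got += phylo.DEFAULT_LINEAR_GAP if "-" in (x, y) else matrix[x, y]
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = matrix
        aligner.open_gap_score = phylo.DEFAULT_LINEAR_GAP
        aligner.extend_gap_score = phylo.DEFAULT_LINEAR_GAP
        assert got == pytest.approx(aligner.align(a, b).score)

    def test_every_ungapped_row_equals_its_input(self):
        rng = np.random.default_rng(0)
        seqs = [(f"s{i}", synthetic.random_protein(rng, int(rng.integers(30, 60))))
                for i in range(5)]
        msa = progressive_align(seqs)
        for sid, seq in seqs:
            assert msa.ungapped(sid) == seq

    def test_single_sequence_returned_unchanged(self):
        msa = progressive_align([("only", "MKWVLT")])
        assert msa.ids == ["only"] and msa.rows == ["MKWVLT"]


class TestTrimBlocks:
    def test_fully_conserved_unchanged(self):
        msa = Msa(["a", "b"], ["MKWVLTMKWVLT"] * 2)
        out = trim_blocks(msa)
        assert out.rows == msa.rows

    def test_unrelated_random_rows_mostly_removed(self):
        rng = np.random.default_rng(1)
        rows = [synthetic.random_protein(rng, 80) for _ in range(6)]
        out = trim_blocks(Msa([f"s{i}" for i in range(6)], rows),
                          min_conservation=0.5, min_block=5)
        assert out.width <= 10

    def test_block_below_minimum_length_removed(self):
        # 4 conserved columns flanked by junk in 2/3 rows
        msa = Msa(["a", "b", "c"],
                  ["WWWW" + "ACDE", "WWWW" + "FGHI", "WWWW" + "KLMN"])
        out = trim_blocks(msa, min_conservation=0.9, min_block=5)
        assert out.width == 0

    def test_gap_columns_removed_when_disallowed(self):
        msa = Msa(["a", "b"], ["MKWVL-MKWVL", "MKWVLTMKWVL"])
        out = trim_blocks(msa, allow_gaps=False, min_block=5)
        assert "-" not in "".join(out.rows)


class TestConcatenate:
    def test_widths_add_and_partitions_tile(self):
        g1 = Msa(["a", "b"], ["M" * 10] * 2)
        g2 = Msa(["a", "b"], ["K" * 20] * 2)
        out = concatenate([g1, g2])
        assert out.width == 30
        assert out.partitions == [("gene1", 0, 10), ("gene2", 10, 30)]

    def test_missing_taxon_gets_gap_segment(self):
        g1 = Msa(["a", "b"], ["M" * 10] * 2)
        g2 = Msa(["a"], ["K" * 20])
        out = concatenate([g1, g2])
        assert out.row("b") == "M" * 10 + "-" * 20

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            concatenate([])

    def test_trimming_preserves_partition_provenance(self):
        g1 = Msa(["a", "b"], ["MKWVLTMK", "MKWVLTMK"])
        g2 = Msa(["a", "b"], ["AAAA", "CCCC"])
        cat = concatenate([g1, g2])
        out = trim_blocks(cat, min_conservation=0.9, min_block=3)
        assert all(name == "gene1" for name, _, _ in out.partitions)
        assert out.width == 8


class TestProteinDistance:
    def test_identical_rows_distance_zero(self):
        dm = protein_distance(Msa(["a", "b"], ["MKWVLT"] * 2))
        assert dm["a", "b"] == 0.0

    def test_closed_form_at_p_0_1(self):
        d = kimura_protein_distance(0.1)
        assert d == pytest.approx(-math.log(1 - 0.1 - 0.002), abs=1e-12)

    def test_matrix_invariants_on_random_msa(self):
        rng = np.random.default_rng(2)
        rows = [synthetic.random_protein(rng, 50) for _ in range(5)]
        dm = protein_distance(Msa([f"s{i}" for i in range(5)], rows))
        assert np.allclose(dm.data, dm.data.T)
        assert np.all(np.diag(dm.data) == 0)
        assert np.all(np.isfinite(dm.data))

    def test_saturated_pair_hits_ceiling(self):
        rng = np.random.default_rng(3)
        rows = [synthetic.random_protein(rng, 200) for _ in range(2)]
        dm = protein_distance(Msa(["a", "b"], rows))
        assert dm["a", "b"] == phylo.SATURATION_CEILING

    def test_no_shared_columns_names_the_pair(self):
        msa = Msa(["a", "b"], ["MK--", "--VL"])
        with pytest.raises(ValueError, match="'a' and 'b'"):
            protein_distance(msa)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float),
                            ids=list("ABC"))
        t = neighbor_joining(dm)
        d = {n.name: n.length for n in t.children}
        assert d["A"] == pytest.approx(1.0)
        assert d["B"] == pytest.approx(2.0)
        assert d["C"] == pytest.approx(4.0)

    def test_additive_four_taxon_topology_recovered(self):
        dm = DistanceMatrix(np.array(
            [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]],
            float), ids=list("ABCD"))
        t = neighbor_joining(dm)
        assert nontrivial_splits(t) == {frozenset("CD")}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_additive_matrices_reproduced_exactly(self, seed):
        """On additive input, the NJ tree's path distances equal the input
        (tree-metric oracle, n = 5..6)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 7))
        true = synthetic.simulate_tree(n, rng)
        for node in true.traverse(include_self=False):
            node.length = float(rng.uniform(0.1, 1.0))
        dm_true = true.tip_tip_distances()
        t = neighbor_joining(dm_true)
        dm_back = t.tip_tip_distances()
        order = list(dm_true.ids)
        assert np.allclose(dm_back.filter(order).data, dm_true.data, atol=1e-9)

    def test_ultrametric_simulated_tree_topology_recovered(self):
        true = synthetic.simulate_tree(6, seed=5)
        dm = true.tip_tip_distances()
        t = neighbor_joining(dm)
        assert nontrivial_splits(t) == nontrivial_splits(true)

    def test_agrees_with_reference_nj_implementation(self):
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(7)
        true = synthetic.simulate_tree(7, rng)
        for node in true.traverse(include_self=False):
            node.length = float(rng.uniform(0.1, 1.0))
        dm = true.tip_tip_distances()
        ours = neighbor_joining(dm)
        theirs = skbio_nj(dm)
        assert nontrivial_splits(ours) == nontrivial_splits(theirs)

    def test_non_symmetric_matrix_rejected(self):
        with pytest.raises(Exception):
            neighbor_joining((list("ABC"),
                              np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.]])))

    def test_fewer_than_three_labels_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(np.array([[0, 1], [1, 0.]]),
                                            ids=["A", "B"]))


class TestMonophyly:
    def test_clean_split_is_monophyletic(self):
        t = tree_of("((A1,A2),(H1,H2));")
        assert is_monophyletic(t, {"A1", "A2"}, {"H1", "H2"})

    def test_mixed_group_is_not(self):
        t = tree_of("((A1,A2),(H1,H2));")
        assert not is_monophyletic(t, {"A1", "H1"}, {"H2"})

    def test_caterpillar_split_group_is_not(self):
        t = tree_of("(A1,(H1,(A2,H2)));")
        assert not is_monophyletic(t, {"A1", "A2"}, {"H1", "H2"})

    def test_unknown_label_rejected(self):
        t = tree_of("((A1,A2),(H1,H2));")
        with pytest.raises(ValueError, match="Z9"):
            is_monophyletic(t, {"A1", "Z9"}, {"H1"})


class TestRobinsonFoulds:
    def test_identical_trees_distance_zero(self):
        t1 = tree_of("((A,B),(C,D));")
        assert robinson_foulds(t1, tree_of("((A,B),(C,D));")) == 0

    def test_conflicting_quartets_distance_two(self):
        assert robinson_foulds(tree_of("((A,B),(C,D));"),
                               tree_of("((A,C),(B,D));")) == 2

    @pytest.mark.parametrize("s1,s2", [(0, 1), (2, 3), (4, 5)])
    def test_symmetric_and_matches_dendropy(self, s1, s2):
        import dendropy
        from dendropy.calculate import treecompare
        t1 = synthetic.simulate_tree(8, seed=s1)
        t2 = synthetic.simulate_tree(8, seed=s2)
        ours = robinson_foulds(t1, t2)
        assert ours == robinson_foulds(t2, t1)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=str(t1), schema="newick",
                               taxon_namespace=tns, rooting="force-unrooted")
        d2 = dendropy.Tree.get(data=str(t2), schema="newick",
                               taxon_namespace=tns, rooting="force-unrooted")
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        assert ours == treecompare.symmetric_difference(d1, d2)

    def test_leaf_set_mismatch_lists_difference(self):
        with pytest.raises(ValueError, match="E"):
            robinson_foulds(tree_of("((A,B),(C,D));"),
                            tree_of("((A,B),(C,E));"))


@pytest.fixture(scope="module")
def clean_msa():
    # well-resolved shape: every internal edge long enough to leave an
    # unambiguous signal in a 400-column alignment
    tree = tree_of("((A:0.2,B:0.2):0.25,(C:0.2,D:0.2):0.25,E:0.45);")
    seqs = synthetic.evolve_family(
        synthetic.random_protein(np.random.default_rng(11), 400),
        tree, 0.5, seed=11)
    ids = sorted(seqs)
    return Msa(ids, [seqs[i] for i in ids])


class TestBootstrap:
    def test_clean_signal_gets_high_support(self, clean_msa):
        t = phylo.bootstrap_support(clean_msa, n_replicates=100, seed=0)
        sups = [n.support for n in t.non_tips(include_self=False)
                if getattr(n, "support", None) is not None]
        assert sups and min(sups) >= 0.95

    def test_same_seed_reproducible(self, clean_msa):
        t1 = phylo.bootstrap_support(clean_msa, n_replicates=30, seed=5)
        t2 = phylo.bootstrap_support(clean_msa, n_replicates=30, seed=5)
        s = lambda t: sorted(n.support for n in t.non_tips(include_self=False)
                             if getattr(n, "support", None) is not None)
        assert s(t1) == s(t2)

    def test_single_replicate_supports_are_binary(self, clean_msa):
        t = phylo.bootstrap_support(clean_msa, n_replicates=1, seed=0)
        for n in t.non_tips(include_self=False):
            if getattr(n, "support", None) is not None:
                assert n.support in (0.0, 1.0)

    def test_zero_replicates_rejected(self, clean_msa):
        with pytest.raises(ValueError):
            phylo.bootstrap_support(clean_msa, n_replicates=0)


class TestCongruence:
    def test_identical_trees_no_candidates(self):
        t = synthetic.simulate_tree(6, seed=0)
        rep = congruence_report(t, t.copy())
        assert rep.initial_rf == 0 and rep.candidates == []

    def test_single_regrafted_leaf_is_the_candidate(self):
        core, mam, moved = synthetic.simulate_congruence_pair(n_leaves=8, seed=3)
        rep = congruence_report(core, mam)
        assert rep.candidates == [moved]
        assert rep.final_rf == 0

    def test_pruning_distances_non_increasing(self):
        core, mam, _ = synthetic.simulate_congruence_pair(n_leaves=10, seed=9)
        rep = congruence_report(core, mam)
        befores = [b for _, b, _ in rep.removals]
        afters = [a for _, _, a in rep.removals]
        assert all(a <= b for b, a in zip(befores, afters))


class TestNewickIo:
    def test_string_and_file_round_trip(self, tmp_path):
        t = synthetic.simulate_tree(5, seed=1)
        p = tmp_path / "t.nwk"
        phylo.write_tree(t, p)
        again = read_tree(p)
        assert nontrivial_splits(again) == nontrivial_splits(t)
        again2 = read_tree(str(t))
        assert {x.name for x in again2.tips()} == {x.name for x in t.tips()}
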