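"""The generator: trees, evolution, decoys, datasets, determinism."""

import filecmp
import math

import numpy as np
import pytest

from mgcminer import align, synthetic
from mgcminer.synthetic import (SimulationConfig, TruthTable, evolve_family,
                                expected_identity, generate_dataset,
                                make_decoy, mutate_protein, random_protein,
                                simulate_tree)


class TestSimulateTree:
    def test_two_leaves(self):
        t = simulate_tree(2, seed=0)
        assert sorted(x.name for x in t.tips()) == ["T01", "T02"]

    def test_same_seed_identical_newick(self):
        assert str(simulate_tree(9, seed=4)) == str(simulate_tree(9, seed=4))

    def test_fifty_leaves_have_49_internal_nodes(self):
        t = simulate_tree(50, seed=1)
        tips = list(t.tips())
        internals = list(t.non_tips(include_self=True))
        assert len(tips) == 50
        assert len({x.name for x in tips}) == 50
        assert len(internals) == 49

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(1, seed=0)


class TestEvolveFamily:
    def test_near_zero_rate_keeps_root_sequence(self):
        tree = simulate_tree(4, seed=0)
        root = random_protein(np.random.default_rng(0), 100)
        leaves = evolve_family(root, tree, 1e-9, seed=1)
        assert all(s == root for s in leaves.values())

    def test_pairwise_identity_tracks_closed_form(self):
        # two leaves at a known path length; binomial band around the
        # model's expected identity
        from skbio import TreeNode
        import io
        tree = TreeNode.read(io.StringIO("(A:1.0,B:1.0);"))
        L, rate = 2000, 1.0
        root = random_protein(np.random.default_rng(2), L)
        leaves = evolve_family(root, tree, rate, seed=3)
        obs = sum(a == b for a, b in zip(leaves["A"], leaves["B"])) / L
        exp = expected_identity(2.0, rate)
        sigma = math.sqrt(exp * (1 - exp) / L)
        assert abs(obs - exp) < 4 * sigma

    def test_same_seed_identical_output(self):
        tree = simulate_tree(5, seed=7)
        root = random_protein(np.random.default_rng(0), 80)
        assert evolve_family(root, tree, 0.5, seed=9) == \
            evolve_family(root, tree, 0.5, seed=9)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            evolve_family("MKWVLT", simulate_tree(2, seed=0), 0.0, seed=0)


class TestDecoys:
    def test_mutation_fraction_is_exact(self):
        rng = np.random.default_rng(5)
        seq = random_protein(rng, 200)
        mut = mutate_protein(rng, seq, 0.25)
        diff = sum(a != b for a, b in zip(seq, mut))
        assert diff == 50

    def test_screen_safe_decoy_never_passes_thresholds(self):
        rng = np.random.default_rng(6)
        refs = [random_protein(rng, 300)]
        decoy = make_decoy(rng, refs, 0.15, screen_safe=True)
        hit = align.align_and_score("d", decoy, "r", refs[0])
        assert not (hit.identity > 0.30 and hit.evalue <= 1e-5)

    def test_high_divergence_decoys_measured_below_threshold(self, small_dataset,
                                                             small_db):
        """Planted decoy genes are rejected by the screen by construction
        (measured against the align module post hoc)."""
        paths, truth = small_dataset
        from mgcminer.screen import load_proteome
        proteome = load_proteome(paths["proteins"])
        decoys = [(pid, o["family"]) for pid, o in truth.protein_origin.items()
                  if o["kind"] == "decoy"]
        assert decoys
        for pid, fam in decoys:
            for ref in small_db.markers(fam):
                hit = align.align_and_score(pid, proteome[pid],
                                            ref.id, ref.sequence)
                assert not (hit.identity > 0.30 and hit.evalue <= 1e-5)


class TestGenerateDataset:
    def test_truth_lists_exactly_the_planted_loci(self, small_config,
                                                  small_dataset):
        _, truth = small_dataset
        assert len(truth.loci) == small_config.n_planted_loci
        for locus in truth.loci:
            assert locus["families"] == list(small_config.locus_families)

    def test_quality_pass_count_matches_config(self, small_config,
                                               small_dataset):
        _, truth = small_dataset
        assert sum(truth.quality_pass.values()) == small_config.quality_n_pass

    def test_same_seed_regenerates_byte_identical_files(self, small_config,
                                                        tmp_path):
        p1, _ = generate_dataset(small_config, tmp_path / "a")
        p2, _ = generate_dataset(small_config, tmp_path / "b")
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_truth_round_trips_through_json(self, small_dataset):
        paths, truth = small_dataset
        again = TruthTable.from_json(paths["truth"])
        assert again.loci == truth.loci
        assert again.quality_pass == truth.quality_pass

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError, match="loci"):
            SimulationConfig(seed=1, n_scaffolds=2, n_planted_loci=5)

    def test_missing_seed_rejected(self):
        with pytest.raises((ValueError, TypeError)):
            SimulationConfig(seed=None)


class TestCompositionScenario:
    def test_between_group_distances_exceed_three_times_within(self):
        from mgcminer import phylo
        msa, labels, truth = synthetic.simulate_composition_dataset(seed=7)
        dm = phylo.protein_distance(msa)
        groups = {g: [i for i in dm.ids if truth[i] != truth[g] or
                      i.split("_")[0] == g.split("_")[0]] for g in dm.ids}
        within, between = [], []
        for i in dm.ids:
            for j in dm.ids:
                if i < j:
                    (within if i.split("_")[0] == j.split("_")[0]
                     else between).append(dm[i, j])
        assert min(between) > 3 * (sum(within) / len(within))
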