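"""Locus annotation, quality filtering, assembly statistics, fragment ANI."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mgcminer import annotate_qc, synthetic
from mgcminer.annotate_qc import (AssemblyStats, GenomeQuality, assembly_stats,
                                  assign_gene_families, fragment_ani,
                                  load_quality_table, n50, quality_filter)
from mgcminer.refdb import GeneFamily, ReferenceDatabase, ReferenceProtein
from mgcminer.screen import GeneCall, LocusGene, MgcLocus

from .oracles import brute_force_n50


@pytest.fixture(scope="module")
def locus_setup():
    rng = np.random.default_rng(21)
    mam_seq = synthetic.random_protein(rng, 250)
    mad_seq = synthetic.random_protein(rng, 180)
    man_seq = synthetic.random_protein(rng, 160)
    refs = ReferenceDatabase(proteins=[
        ReferenceProtein("rK", GeneFamily("mamK"), "G1", "M1",
                         "magnetite", mam_seq),
        ReferenceProtein("rMad", GeneFamily("mad23"), "G1", "M1",
                         "magnetite", mad_seq),
        ReferenceProtein("rMan", GeneFamily("man3"), "G1", "M1",
                         "magnetite", man_seq),
    ])
    proteome = {
        "g0": synthetic.mutate_protein(rng, mam_seq, 0.2),
        "g1": synthetic.mutate_protein(rng, mad_seq, 0.2),
        "g2": synthetic.mutate_protein(rng, man_seq, 0.2),
        "g3": synthetic.random_protein(rng, 150),
    }
    calls = [GeneCall(f"g{i}", "scf1", 300 * i, 300 * i + 200, "+", i)
             for i in range(4)]
    # screen-stage locus saw only the mamK gene at ordinal 0 and the
    # man gene at ordinal 2; annotation re-examines the whole span
    locus = MgcLocus("scf1", [
        LocusGene(calls[0], GeneFamily("mamK"), 0.8, "rK"),
        LocusGene(calls[2], GeneFamily("man3"), 0.8, "rMan"),
    ])
    return locus, calls, proteome, refs


class TestAssignGeneFamilies:
    def test_planted_mad_derived_gene_labeled_mad(self, locus_setup):
        locus, calls, proteome, refs = locus_setup
        out = assign_gene_families(locus, calls, proteome, refs)
        assert out.families[1] == "mad23"
        assert out.genes[1].family.category == "mad"

    def test_categories_reflect_member_genes(self, locus_setup):
        locus, calls, proteome, refs = locus_setup
        out = assign_gene_families(locus, calls, proteome, refs)
        assert out.categories == {"mam", "mad", "man"}

    def test_random_protein_unassigned(self, locus_setup):
        locus, calls, proteome, refs = locus_setup
        wide = MgcLocus("scf1", [
            LocusGene(calls[0], GeneFamily("mamK"), 0.8, "rK"),
            LocusGene(calls[3], GeneFamily("mamK"), 0.8, "rK"),
        ])
        out = assign_gene_families(wide, calls, proteome, refs)
        assert out.families[-1] == "unassigned"


class TestQualityFilter:
    def test_good_genome_kept(self):
        kept = quality_filter([GenomeQuality("bin25", 92.31, 4.27)])
        assert [r.genome_id for r in kept] == ["bin25"]

    def test_boundaries_are_strict(self):
        records = [GenomeQuality("at_completeness_floor", 45.0, 5.0),
                   GenomeQuality("at_contamination_ceiling", 80.0, 10.0)]
        assert quality_filter(records) == []

    def test_override_keeps_low_completeness_genome(self, caplog):
        rec = GenomeQuality("low_sag", 39.0, 0.0)
        assert quality_filter([rec]) == []
        with caplog.at_level("INFO"):
            kept = quality_filter([rec], overrides={"low_sag"})
        assert kept == [rec]
        assert "override" in caplog.text

    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 50)),
                    max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_order_preserving(self, pairs):
        records = [GenomeQuality(f"g{i}", c, x)
                   for i, (c, x) in enumerate(pairs)]
        kept = quality_filter(records)
        assert quality_filter(kept) == kept
        ids = [r.genome_id for r in records]
        assert [r.genome_id for r in kept] == \
            [i for i in ids if i in {r.genome_id for r in kept}]

    def test_table_loader(self, small_dataset):
        paths, truth = small_dataset
        records = load_quality_table(paths["quality"])
        kept = quality_filter(records)
        assert {r.genome_id for r in kept} == \
            {g for g, ok in truth.quality_pass.items() if ok}


class TestAssemblyStats:
    def test_single_uniform_scaffold(self):
        s = assembly_stats({"scf": "ATGC" * 25})
        assert (s.size_bp, s.n_scaffolds, s.n50_bp) == (100, 1, 100)
        assert s.gc_percent == pytest.approx(50.0)

    def test_n50_hand_example(self):
        assert n50([5, 4, 3, 2, 1]) == 4

    def test_all_ambiguous_assembly_rejected(self):
        with pytest.raises(ValueError, match="GC undefined"):
            assembly_stats({"scf": "NNNNN"})

    def test_empty_assembly_rejected(self):
        with pytest.raises(ValueError):
            assembly_stats({})

    @given(st.lists(st.integers(1, 10_000), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_n50_matches_brute_force(self, lengths):
        assert n50(lengths) == brute_force_n50(lengths)


class TestFragmentAni:
    def test_genome_vs_itself_is_100(self):
        rng = np.random.default_rng(4)
        g = {"scf": synthetic._random_dna(rng, 4000)}
        assert fragment_ani(g, g) == pytest.approx(100.0)

    def test_two_percent_mutated_copy_near_98(self):
        cfg = synthetic.SimulationConfig(seed=1, ani_genome_length=8000)
        a, b = synthetic.generate_ani_pair(cfg, 5)
        ani = fragment_ani(a, b)
        assert ani == pytest.approx(98.0, abs=0.5)

    def test_unrelated_random_sequences_undefined(self):
        rng = np.random.default_rng(0)
        a = {"x": synthetic._random_dna(rng, 4000)}
        b = {"y": synthetic._random_dna(rng, 4000)}
        assert fragment_ani(a, b) is None

    def test_roughly_symmetric_on_mutated_pair(self):
        cfg = synthetic.SimulationConfig(seed=2, ani_genome_length=6000)
        a, b = synthetic.generate_ani_pair(cfg, 9)
        ab, ba = fragment_ani(a, b), fragment_ani(b, a)
        assert abs(ab - ba) < 1.0

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            fragment_ani({}, {"x": "ACGT"})
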