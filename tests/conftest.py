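"""Shared fixtures: synthetic datasets generated once per session."""

import pytest

from mgcminer import refdb, screen
from mgcminer.synthetic import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A reduced three-family study for fast unit-level checks."""
    return SimulationConfig(
        seed=7,
        family_rates={"mamA": 0.40, "mamB": 0.45, "mamK": 0.25},
        homolog_specs={"mamK": (2, 0.15), "mamA": (2, 0.25), "mamB": (2, 0.32)},
        locus_families=("mamA", "mamB", "mamK"),
        n_scaffolds=5,
        n_planted_loci=2,
        n_decoy_genes=2,
        background_genes_per_scaffold=3,
        quality_n_genomes=6,
        quality_n_pass=4,
        ani_genome_length=6000,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_ds")
    paths, truth = generate_dataset(small_config, outdir)
    return paths, truth


@pytest.fixture(scope="session")
def small_db(small_dataset):
    paths, _ = small_dataset
    return refdb.load_reference_db(paths["reference_fasta"],
                                   paths["reference_metadata"])


@pytest.fixture(scope="session")
def small_screen(small_dataset, small_db):
    paths, truth = small_dataset
    proteome = screen.load_proteome(paths["proteins"])
    calls = screen.load_gene_calls(paths["gff"])
    hits = screen.search_scaffolds(proteome, calls, small_db)
    return proteome, calls, hits
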