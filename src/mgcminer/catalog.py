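"""The packaged catalog of MGC-bearing genomes recovered from open databases.

The catalog transcribes the published characteristics of the 38 new
MTB genomes the open-database search produced: 4 genomes found directly in
genomic databases, plus 32 metagenome-assembled genomes (MAGs) and 2
single-cell amplified genomes (SAGs) recovered from metagenomic data. Each
row carries the assembly statistics (size, scaffold count, GC%, N50) and the
single-copy-marker quality estimates (completeness, contamination) used by
the quality filter.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .annotate_qc import GenomeQuality

NUMERIC_COLUMNS = ("size_bp", "n_scaffolds", "gc_percent", "n50_bp",
                   "completeness", "contamination")


def load_catalog() -> pd.DataFrame:
    """The genome catalog as a typed DataFrame (38 rows; ``genome_type`` is
    one of genome/MAG/SAG)."""
    with resources.files("mgcminer.data").joinpath("catalog.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    for c in NUMERIC_COLUMNS:
        df[c] = pd.to_numeric(df[c])
    return df


def catalog_quality_records(df: pd.DataFrame | None = None) -> list[GenomeQuality]:
    """Catalog rows as quality records keyed by organism name."""
    if df is None:
        df = load_catalog()
    return [GenomeQuality(r.organism, r.completeness, r.contamination)
            for r in df.itertuples(index=False)]
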