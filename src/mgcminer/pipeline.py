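"""End-to-end orchestration: marker choice → screen → annotate → QC →
trees → composition, from one declarative config.

Every stage writes its artifacts into the output directory and contributes
its counts to a machine-readable summary whose funnel mirrors a mining
campaign (proteins scanned → marker hits → scaffolds with co-occurring Mam
families → called loci → quality-passing genomes). Each threshold applied
is logged at INFO; per-hit decisions at DEBUG.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotate_qc, composition, marker_eval, phylo, refdb, screen

logger = logging.getLogger(__name__)

STAGES = ("eval_markers", "screen", "annotate", "qc", "congruence", "composition")


@dataclass
class PipelineConfig:
    """Inputs, thresholds, and stage toggles for one pipeline run."""

    reference_fasta: str
    reference_metadata: str
    outdir: str
    proteins: str | None = None
    gff: str | None = None
    quality_table: str | None = None
    core_tree: str | None = None
    mam_tree: str | None = None
    composition_msa: str | None = None
    composition_labels: str | None = None

    min_identity: float = screen.DEFAULT_MIN_IDENTITY
    max_evalue: float = screen.DEFAULT_MAX_EVALUE
    primary_family: str = screen.DEFAULT_PRIMARY_FAMILY
    min_other_families: int = 1
    max_gene_gap: int = screen.DEFAULT_MAX_GENE_GAP
    min_completeness: float = annotate_qc.DEFAULT_MIN_COMPLETENESS
    max_contamination: float = annotate_qc.DEFAULT_MAX_CONTAMINATION
    quality_overrides: list[str] = field(default_factory=list)
    k_groups: int = composition.DEFAULT_K_GROUPS
    bootstrap_replicates: int = 1000
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))

    def __post_init__(self) -> None:
        if not 0 <= self.min_identity <= 1:
            raise ValueError("min_identity must be in [0, 1]")
        if self.max_evalue < 0 or self.max_gene_gap < 0 or self.min_other_families < 0:
            raise ValueError("thresholds must be non-negative")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not self.stages:
            raise ValueError("no stages enabled: nothing to run")
        for attr in ("reference_fasta", "reference_metadata"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise ValueError(f"{attr} path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run summary.

    Any stage failure aborts with the stage name in the exception message;
    artifacts from completed stages are retained on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": [], "funnel": {}, "thresholds": {
        "min_identity": config.min_identity,
        "max_evalue": config.max_evalue,
        "primary_family": config.primary_family,
        "min_other_families": config.min_other_families,
        "max_gene_gap": config.max_gene_gap,
        "min_completeness": config.min_completeness,
        "max_contamination": config.max_contamination,
    }}
    db = refdb.load_reference_db(config.reference_fasta, config.reference_metadata)
    summary["funnel"]["n_reference_proteins"] = len(db.proteins)
    current = "setup"
    try:
        hits: list[screen.ScreenHit] = []
        if "eval_markers" in config.stages:
            current = "eval_markers"
            stats = marker_eval.evaluate_markers(db)
            marker_eval.write_marker_report(stats, out / "marker_report.tsv")
            summary["best_marker"] = stats[0].family.name if stats else None
            summary["stages"].append(current)
        if "screen" in config.stages and config.proteins and config.gff:
            current = "screen"
            proteome = screen.load_proteome(config.proteins)
            calls = screen.load_gene_calls(config.gff)
            logger.info("screen: identity > %.2f, E <= %g",
                        config.min_identity, config.max_evalue)
            marker_db = db.subset([f for f in db.families()
                                   if f.category == "mam"])
            hits = screen.search_scaffolds(
                proteome, calls, marker_db,
                min_identity=config.min_identity, max_evalue=config.max_evalue)
            screen.write_hits_tsv(hits, out / "hits.tsv")
            kept = screen.cooccurrence_filter(
                hits, primary_family=config.primary_family,
                min_other_families=config.min_other_families)
            summary["funnel"]["n_proteins_scanned"] = sum(
                len(v) for v in calls.values())
            summary["funnel"]["n_marker_hits"] = len(hits)
            summary["funnel"]["n_scaffolds_with_cooccurrence"] = len(kept)
            hits = [h for h in hits if h.gene.scaffold_id in set(kept)]
            summary["stages"].append(current)
        if "annotate" in config.stages and hits:
            current = "annotate"
            loci = screen.call_mgc_loci(hits, max_gene_gap=config.max_gene_gap)
            proteome = screen.load_proteome(config.proteins)
            calls = screen.load_gene_calls(config.gff)
            annotated = [
                annotate_qc.assign_gene_families(
                    loc, calls[loc.scaffold_id], proteome, db,
                    min_identity=config.min_identity,
                    max_evalue=config.max_evalue)
                for loc in loci
            ]
            screen.write_loci_tsv(annotated, out / "loci.tsv")
            screen.write_loci_bed(annotated, out / "loci.bed")
            annotate_qc.write_locus_gff3(annotated, out / "loci.gff3")
            summary["funnel"]["n_loci"] = len(annotated)
            summary["stages"].append(current)
        if "qc" in config.stages and config.quality_table:
            current = "qc"
            records = annotate_qc.load_quality_table(config.quality_table)
            kept_q = annotate_qc.quality_filter(
                records, min_completeness=config.min_completeness,
                max_contamination=config.max_contamination,
                overrides=config.quality_overrides)
            summary["funnel"]["n_genomes"] = len(records)
            summary["funnel"]["n_genomes_pass_qc"] = len(kept_q)
            summary["stages"].append(current)
        if "congruence" in config.stages and config.core_tree and config.mam_tree:
            current = "congruence"
            core = phylo.read_tree(config.core_tree)
            mam = phylo.read_tree(config.mam_tree)
            rep = phylo.congruence_report(core, mam)
            summary["congruence"] = {
                "initial_rf": rep.initial_rf,
                "final_rf": rep.final_rf,
                "transfer_candidates": rep.candidates,
            }
            summary["stages"].append(current)
        if "composition" in config.stages and config.composition_msa \
                and config.composition_labels:
            current = "composition"
            msa = phylo.read_msa_fasta(config.composition_msa)
            import pandas as pd
            lab = pd.read_csv(config.composition_labels, sep="\t")
            labels = dict(zip(lab["genome_id"].astype(str), lab["label"]))
            dm = phylo.protein_distance(msa)
            preds = composition.assign_composition(
                dm, labels, k_groups=config.k_groups, seed=config.seed)
            composition.write_predictions_tsv(preds, out / "composition.tsv")
            summary["composition_labels"] = {
                p.genome_id: p.predicted_label for p in preds}
            summary["stages"].append(current)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
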