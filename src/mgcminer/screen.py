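"""Scaffold screening: marker hits, co-occurrence filtering, locus calling.

The screening funnel mirrors a database-mining campaign at desk scale:
every predicted protein on every scaffold is compared against the reference
marker set; hits must exceed 30% identity (strict) and reach an E-value of
at most 1e-5; scaffolds are then kept only when, besides the primary marker
(MamK by default), at least one *additional* distinct Mam family hits the
same scaffold — single isolated marker-like genes are discarded as homolog
noise. Surviving hits are chained into MGC locus calls by gene-index
proximity.

Note on the E-value direction: the screening is stringent — significant
hits have *small* E-values, so the retained side of the threshold is
``E <= 1e-5``.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO

from .align import AlignmentHit, align_and_score, load_matrix, DEFAULT_MATRIX
from .refdb import GeneFamily, ReferenceDatabase

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 0.30
DEFAULT_MAX_EVALUE = 1e-5
DEFAULT_PRIMARY_FAMILY = "mamK"
DEFAULT_MAX_GENE_GAP = 5


@dataclass(frozen=True)
class GeneCall:
    """One predicted gene: 0-based half-open nucleotide coordinates on its
    scaffold plus its ordinal (gene index along the scaffold)."""

    protein_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    ordinal: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad coordinates for {self.protein_id}: "
                             f"[{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class ScreenHit:
    """A proteome protein retained by the threshold screen, with the family
    of its best reference."""

    gene: GeneCall
    best_reference: str
    family: GeneFamily
    hit: AlignmentHit


@dataclass
class LocusGene:
    """One gene of a called locus with its (possibly absent) family label."""

    gene: GeneCall
    family: GeneFamily | None
    identity: float | None
    reference_id: str | None


@dataclass
class MgcLocus:
    """A called magnetosome-gene-cluster locus on one scaffold."""

    scaffold_id: str
    genes: list[LocusGene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes.sort(key=lambda g: g.gene.ordinal)

    @property
    def span(self) -> tuple[int, int]:
        return (min(g.gene.start for g in self.genes),
                max(g.gene.end for g in self.genes))

    @property
    def families(self) -> list[str]:
        return [g.family.name if g.family else "unassigned" for g in self.genes]

    @property
    def strand_pattern(self) -> str:
        return "".join(g.gene.strand for g in self.genes)

    @property
    def categories(self) -> set[str]:
        return {g.family.category for g in self.genes if g.family is not None}


# ---------------------------------------------------------------------------
# Input readers

def load_gene_calls(gff_path: str | Path, feature_type: str = "CDS"
                    ) -> dict[str, list[GeneCall]]:
    """Gene calls per scaffold from GFF3. Coordinates are converted from
    GFF's 1-based closed to 0-based half-open; ordinals follow start order
    within each scaffold. The feature ``ID`` attribute is the protein id."""
    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            merge_strategy="create_unique")
    per_scaffold: dict[str, list] = defaultdict(list)
    for feat in db.features_of_type(feature_type):
        per_scaffold[feat.seqid].append(feat)
    out: dict[str, list[GeneCall]] = {}
    for scf in sorted(per_scaffold):
        feats = sorted(per_scaffold[scf], key=lambda f: (f.start, f.end))
        out[scf] = [
            GeneCall(protein_id=f.id, scaffold_id=scf, start=f.start - 1,
                     end=f.end, strand=f.strand, ordinal=k)
            for k, f in enumerate(feats)
        ]
    return out


def load_proteome(fasta_path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")}


# ---------------------------------------------------------------------------
# Screening

def search_scaffolds(
    proteome: dict[str, str],
    gene_calls: dict[str, list[GeneCall]],
    refs: ReferenceDatabase,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    matrix=None,
) -> list[ScreenHit]:
    """Screen every gene-called protein against the reference marker set.

    For each protein the best-scoring reference per family is found; the
    protein is retained iff identity > ``min_identity`` (strict, so exactly
    30% is rejected) and E-value <= ``max_evalue``; its family is that of
    the overall best passing reference. Homolog-flagged references are not
    search targets. One hit per protein at most.
    """
    if not refs.proteins:
        raise ValueError("empty reference set")
    if matrix is None:
        matrix = load_matrix(DEFAULT_MATRIX)
    by_family: dict[str, list] = defaultdict(list)
    for p in refs.proteins:
        by_family[p.family.name].append(p)
    hits: list[ScreenHit] = []
    for scf in sorted(gene_calls):
        for gene in gene_calls[scf]:
            seq = proteome.get(gene.protein_id)
            if seq is None:
                logger.warning("gene %s has no protein sequence; skipped",
                               gene.protein_id)
                continue
            passing: list[tuple[float, str, str, AlignmentHit]] = []
            for fam in sorted(by_family):
                best: AlignmentHit | None = None
                best_ref = None
                for ref in sorted(by_family[fam], key=lambda r: r.id):
                    h = align_and_score(gene.protein_id, seq, ref.id,
                                        ref.sequence, matrix=matrix)
                    if best is None or h.score > best.score:
                        best, best_ref = h, ref.id
                if best.identity > min_identity and best.evalue <= max_evalue:
                    passing.append((-best.score, fam, best_ref, best))
            if passing:
                passing.sort()
                _, fam, ref_id, h = passing[0]
                hits.append(ScreenHit(gene=gene, best_reference=ref_id,
                                      family=GeneFamily(fam), hit=h))
    return hits


def cooccurrence_filter(
    hits: list[ScreenHit],
    primary_family: str = DEFAULT_PRIMARY_FAMILY,
    min_other_families: int = 1,
    other_categories: tuple[str, ...] = ("mam",),
) -> list[str]:
    """Scaffolds that carry a primary-marker hit plus at least
    ``min_other_families`` additional distinct Mam families.

    Distinctness is by family name, not hit count — two MamK hits alone do
    not qualify. Only families whose category is in ``other_categories``
    count toward the requirement (default: ``mam`` genes only). Returns
    sorted scaffold ids; idempotent and a subset of the input scaffolds.
    """
    fams_by_scaffold: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        fams_by_scaffold[h.gene.scaffold_id].add(h.family.name)
    kept = []
    for scf, fams in fams_by_scaffold.items():
        if primary_family not in fams:
            continue
        others = {f for f in fams - {primary_family}
                  if GeneFamily(f).category in other_categories}
        if len(others) >= min_other_families:
            kept.append(scf)
    return sorted(kept)


def call_mgc_loci(hits: list[ScreenHit],
                  max_gene_gap: int = DEFAULT_MAX_GENE_GAP) -> list[MgcLocus]:
    """Chain screen hits into loci: within a scaffold, consecutive hits
    whose gene ordinals differ by at most ``max_gene_gap`` belong to the
    same locus. Empty input yields no loci."""
    by_scaffold: dict[str, list[ScreenHit]] = defaultdict(list)
    for h in hits:
        by_scaffold[h.gene.scaffold_id].append(h)
    loci: list[MgcLocus] = []
    for scf in sorted(by_scaffold):
        ordered = sorted(by_scaffold[scf], key=lambda h: h.gene.ordinal)
        chain: list[ScreenHit] = []
        for h in ordered:
            if chain and h.gene.ordinal - chain[-1].gene.ordinal > max_gene_gap:
                loci.append(_locus_from_hits(scf, chain))
                chain = []
            chain.append(h)
        if chain:
            loci.append(_locus_from_hits(scf, chain))
    return loci


def _locus_from_hits(scaffold_id: str, chain: list[ScreenHit]) -> MgcLocus:
    return MgcLocus(
        scaffold_id=scaffold_id,
        genes=[LocusGene(gene=h.gene, family=h.family,
                         identity=h.hit.identity, reference_id=h.best_reference)
               for h in chain],
    )


# ---------------------------------------------------------------------------
# Report writers

def write_hits_tsv(hits: list[ScreenHit], path: str | Path) -> None:
    cols = ("protein_id", "scaffold_id", "ordinal", "family", "best_reference",
            "identity", "evalue", "neg_ln_evalue", "score")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for h in hits:
            fh.write("\t".join(str(x) for x in (
                h.gene.protein_id, h.gene.scaffold_id, h.gene.ordinal,
                h.family.name, h.best_reference, f"{h.hit.identity:.4f}",
                f"{h.hit.evalue:.3e}", f"{h.hit.neg_ln_evalue:.2f}", h.hit.score,
            )) + "\n")


def write_loci_tsv(loci: list[MgcLocus], path: str | Path) -> None:
    cols = ("scaffold_id", "start", "end", "n_genes", "families",
            "strand_pattern", "categories")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for loc in loci:
            s, e = loc.span
            fh.write("\t".join(str(x) for x in (
                loc.scaffold_id, s, e, len(loc.genes), ",".join(loc.families),
                loc.strand_pattern, ",".join(sorted(loc.categories)),
            )) + "\n")


def write_loci_bed(loci: list[MgcLocus], path: str | Path) -> None:
    """Locus spans as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for k, loc in enumerate(loci):
            s, e = loc.span
            fh.write(f"{loc.scaffold_id}\t{s}\t{e}\tMGC_locus_{k + 1}\n")
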