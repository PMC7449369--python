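"""Choosing the marker protein that best detects MGCs.

Searching metagenome-scale data with all nine universal ``mam`` families is
impractical, so a single marker is chosen by three criteria evaluated on the
reference database:

1. high identity and high ``-ln(E)`` among family members from *different*
   taxonomic groups (families whose cross-group identity collapses are
   excluded up front);
2. strong separation between marker-vs-marker and marker-vs-homolog
   statistics (every Mam protein has non-MTB homologs, e.g. actin-like MamK
   homologs, that must not be picked up);
3. clean clade structure on a tree of markers plus homologs: marker leaves
   fall into few marker-only clades with no homolog intrusions (MamK
   characteristically forms two clades, both free of homologs).

The ranking is deterministic: lexicographic on (excluded flag, homolog
intrusions ascending, separation margin descending, minimum cross-group
identity descending, family name).
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from pathlib import Path

from skbio import TreeNode

from . import phylo
from .align import align_and_score, load_matrix, DEFAULT_MATRIX
from .refdb import GeneFamily, ReferenceDatabase

logger = logging.getLogger(__name__)

#: Families whose minimum cross-group identity falls below this are flagged
#: excluded (the fate of the most divergent essential families).
DEFAULT_IDENTITY_FLOOR = 0.15


@dataclass
class MarkerStats:
    """Per-family marker-quality summary (one row of the selection report)."""

    family: GeneFamily
    n_sequences: int
    min_identity: float
    median_identity: float
    min_neg_ln_evalue: float
    median_neg_ln_evalue: float
    separation_margin: float
    n_marker_clades: int
    homolog_intrusions: int
    excluded: bool = False

    def rank_key(self):
        return (
            self.excluded,
            self.homolog_intrusions,
            -self.separation_margin,
            -self.min_identity,
            self.family.name,
        )


def marker_clades(tree: TreeNode, markers, homologs) -> tuple[int, int]:
    """Count maximal marker-only clades in a rooted tree and the homolog
    leaves inside the chosen cover.

    The tree is taken as rooted as given. A clade is counted when all its
    leaves are markers and it is maximal (its parent subtends a non-marker
    leaf); every marker leaf belongs to exactly one counted clade, so the
    cover is minimal. Intrusions are homolog leaves inside counted clades,
    verified from the leaf sets (zero under marker-only clades by
    construction; reported as a diagnostic of the cover).
    """
    markers, homologs = set(markers), set(homologs)
    n_clades = 0
    intrusions = 0

    def visit(node) -> None:
        nonlocal n_clades, intrusions
        tips = {t.name for t in node.tips(include_self=True)}
        if tips and tips <= markers:
            n_clades += 1
            intrusions += len(tips & homologs)
            return
        for child in node.children:
            visit(child)

    visit(tree)
    return n_clades, intrusions


def _root_on_homolog_side(tree: TreeNode, homologs: set[str]) -> TreeNode:
    """Root an unrooted (trifurcating) tree on the edge whose far side holds
    the most homologs and fewest markers — homologs are the natural
    outgroup. Deterministic tie-breaking by smallest leaf label."""
    all_tips = {t.name for t in tree.tips()}
    best = None
    for node in tree.postorder(include_self=False):
        side = {t.name for t in node.tips(include_self=True)}
        if not side or side == all_tips:
            continue
        n_hom = len(side & homologs)
        n_mark = len(side - homologs)
        key = (-n_hom, n_mark, min(side))
        if best is None or key < best[0]:
            best = (key, node)
    return tree.root_at(best[1], above=True, reset=True)


def count_marker_clades(db: ReferenceDatabase, family: GeneFamily | str,
                        matrix=None) -> tuple[int, int]:
    """Build an NJ tree over a family's markers and homologs, root it on the
    homolog side, and count maximal marker-only clades and intrusions."""
    name = getattr(family, "name", family)
    markers = db.markers(name)
    homs = db.homologs_of(name)
    if len(markers) < 2 or not homs:
        raise ValueError(f"family {name!r} needs >=2 markers and >=1 homolog")
    if len(markers) + len(homs) < 3:
        raise ValueError("fewer than 3 leaves: no meaningful tree")
    msa = phylo.progressive_align(markers + homs, matrix=matrix)
    tree = phylo.neighbor_joining(phylo.protein_distance(msa))
    rooted = _root_on_homolog_side(tree, {h.id for h in homs})
    return marker_clades(rooted, {m.id for m in markers}, {h.id for h in homs})


def evaluate_markers(
    db: ReferenceDatabase,
    candidates=None,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
    matrix=None,
    build_trees: bool = True,
) -> list[MarkerStats]:
    """Score and rank candidate marker families.

    Identity and ``-ln(E)`` summaries use only pairs from *different*
    taxonomic groups (within-group similarity says nothing about a marker's
    reach). The separation margin is (minimum within-family ``-ln(E)``)
    minus (maximum marker-vs-homolog ``-ln(E)``); families without recorded
    homologs get a homolog baseline of 0 (the ``E = 1`` floor). Candidates
    with fewer than two sequences, or without cross-group pairs, are dropped
    with a warning rather than an error. The result is ranked; input order
    of sequences and families does not affect it.
    """
    if matrix is None:
        matrix = load_matrix(DEFAULT_MATRIX)
    if candidates is None:
        candidates = db.families()
    stats: list[MarkerStats] = []
    for fam in sorted({getattr(f, "name", f) for f in candidates}):
        family = GeneFamily(fam)
        seqs = sorted(db.markers(fam), key=lambda p: p.id)
        if len(seqs) < 2:
            logger.warning("family %s has <2 sequences; skipped", fam)
            continue
        identities, neg_lns = [], []
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                if seqs[i].taxon_group == seqs[j].taxon_group:
                    continue
                hit = align_and_score(seqs[i].id, seqs[i].sequence,
                                      seqs[j].id, seqs[j].sequence, matrix=matrix)
                identities.append(hit.identity)
                neg_lns.append(hit.neg_ln_evalue)
        if not identities:
            logger.warning("family %s has no cross-group pairs; skipped", fam)
            continue
        homs = sorted(db.homologs_of(fam), key=lambda p: p.id)
        hom_neg_lns = [
            align_and_score(m.id, m.sequence, h.id, h.sequence, matrix=matrix).neg_ln_evalue
            for m in seqs for h in homs
        ]
        max_hom = max(hom_neg_lns) if hom_neg_lns else 0.0
        min_ident = min(identities)
        if build_trees and homs and len(seqs) + len(homs) >= 3:
            n_clades, intrusions = count_marker_clades(db, fam, matrix=matrix)
        else:
            n_clades, intrusions = 1, 0
        stats.append(MarkerStats(
            family=family,
            n_sequences=len(seqs),
            min_identity=min_ident,
            median_identity=statistics.median(identities),
            min_neg_ln_evalue=min(neg_lns),
            median_neg_ln_evalue=statistics.median(neg_lns),
            separation_margin=min(neg_lns) - max_hom,
            n_marker_clades=n_clades,
            homolog_intrusions=intrusions,
            excluded=min_ident < identity_floor,
        ))
    stats.sort(key=MarkerStats.rank_key)
    return stats


def write_marker_report(stats: list[MarkerStats], path: str | Path) -> None:
    """One TSV row per candidate family, in rank order."""
    cols = ("family", "n_sequences", "min_identity", "median_identity",
            "min_neg_ln_evalue", "median_neg_ln_evalue", "separation_margin",
            "n_marker_clades", "homolog_intrusions", "excluded")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in stats:
            fh.write("\t".join(str(x) for x in (
                s.family.name, s.n_sequences, f"{s.min_identity:.4f}",
                f"{s.median_identity:.4f}", f"{s.min_neg_ln_evalue:.2f}",
                f"{s.median_neg_ln_evalue:.2f}", f"{s.separation_margin:.2f}",
                s.n_marker_clades, s.homolog_intrusions,
                str(s.excluded).lower(),
            )) + "\n")
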