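"""Multiple alignment, corrected distances, NJ trees, bootstrap, congruence.

This module provides the phylogenetic machinery used throughout the MGC
pipeline: progressive protein alignment with a single-linkage guide tree,
conserved-block trimming, per-gene concatenation with partition bookkeeping,
Kimura-corrected protein distances, neighbor-joining tree inference with
nonparametric column bootstrap, monophyly tests, Robinson–Foulds distances,
and a greedy leaf-pruning congruence report for comparing a "core genome"
tree against a "Mam tree".

Tree inference here is corrected-distance neighbor joining with column
bootstrap — a deliberately light-weight approach that preserves the
monophyly/congruence logic at desk scale. Externally built
maximum-likelihood trees can be injected as newick via :func:`read_tree`.

Trees are :class:`skbio.TreeNode` objects (newick I/O through scikit-bio);
distance matrices are :class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align, SeqIO
from scipy.cluster.hierarchy import linkage
from skbio import DistanceMatrix, TreeNode

from .align import DEFAULT_MATRIX, load_matrix

logger = logging.getLogger(__name__)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: Linear gap score per gapped column in progressive/global alignment.
DEFAULT_LINEAR_GAP = -4.0
#: p-distances at or above this are treated as saturated.
SATURATION_P = 0.85
#: Corrected distance assigned to saturated pairs.
SATURATION_CEILING = 5.0


# ---------------------------------------------------------------------------
# Msa container

@dataclass
class Msa:
    """A multiple sequence alignment with per-column gene partitions.

    ``partitions`` is a list of ``(gene_name, start, end)`` half-open column
    intervals that tile ``[0, width)`` exactly.
    """

    ids: list[str]
    rows: list[str]
    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in alignment")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("rows differ in length")
        if not self.partitions:
            self.partitions = [("seq", 0, self.width)]
        pos = 0
        for name, start, end in self.partitions:
            if start != pos or end < start:
                raise ValueError("partitions must tile the alignment exactly")
            pos = end
        if pos != self.width:
            raise ValueError("partitions must tile the alignment exactly")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.ids)

    def row(self, id_: str) -> str:
        return self.rows[self.ids.index(id_)]

    def ungapped(self, id_: str) -> str:
        return self.row(id_).replace("-", "")

    def to_array(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows])

    def select_columns(self, cols) -> "Msa":
        """New Msa from the given column indices (order preserved as given);
        partition bookkeeping maps every kept column to its source gene."""
        arr = self.to_array()[:, cols]
        rows = ["".join(r) for r in arr]
        gene_of = np.empty(self.width, dtype=object)
        for name, start, end in self.partitions:
            gene_of[start:end] = name
        parts: list[tuple[str, int, int]] = []
        for k, c in enumerate(np.atleast_1d(cols)):
            g = gene_of[c]
            if parts and parts[-1][0] == g:
                parts[-1] = (g, parts[-1][1], k + 1)
            else:
                parts.append((g, k, k + 1))
        return Msa(list(self.ids), rows, parts)


def read_msa_fasta(path: str | Path) -> Msa:
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return Msa(ids, rows)


def write_msa_fasta(msa: Msa, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in zip(msa.ids, msa.rows):
            fh.write(f">{i}\n{r}\n")


def write_msa_phylip(msa: Msa, path: str | Path) -> None:
    """Relaxed PHYLIP (names of any length, single space separator)."""
    with open(path, "w") as fh:
        fh.write(f" {len(msa)} {msa.width}\n")
        for i, r in zip(msa.ids, msa.rows):
            fh.write(f"{i} {r}\n")


# ---------------------------------------------------------------------------
# Progressive alignment

def _profile(rows: list[str]) -> np.ndarray:
    """Column frequency matrix (L, 20); gaps and non-standard letters carry
    zero mass, so gap-rich columns score weakly."""
    L = len(rows[0])
    F = np.zeros((L, 20))
    for r in rows:
        for j, c in enumerate(r):
            k = _AA_INDEX.get(c)
            if k is not None:
                F[j, k] += 1.0
    return F / len(rows)


def _matrix20(matrix) -> np.ndarray:
    S = np.zeros((20, 20))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            S[i, j] = matrix[a, b]
    return S


def _nw_profile(M: np.ndarray, gap: float) -> list[tuple[int | None, int | None]]:
    """Global DP over a precomputed column-score matrix with linear gap
    penalty; returns aligned column index pairs (None = gap). Traceback
    prefers diagonal, then up (gap in second profile), then left."""
    L1, L2 = M.shape
    H = np.empty((L1 + 1, L2 + 1))
    H[0, :] = gap * np.arange(L2 + 1)
    H[:, 0] = gap * np.arange(L1 + 1)
    jj = np.arange(L2 + 1, dtype=float)
    for i in range(1, L1 + 1):
        A = np.empty(L2 + 1)
        A[0] = H[i, 0]
        A[1:] = np.maximum(H[i - 1, :-1] + M[i - 1, :], H[i - 1, 1:] + gap)
        # H[i, j] = max_{k<=j} A[k] + gap*(j-k): running-max in shifted space
        H[i, :] = np.maximum.accumulate(A - gap * jj) + gap * jj
    path: list[tuple[int | None, int | None]] = []
    i, j = L1, L2
    tol = 1e-9
    while i > 0 or j > 0:
        if i > 0 and j > 0 and abs(H[i, j] - (H[i - 1, j - 1] + M[i - 1, j - 1])) < tol:
            path.append((i - 1, j - 1)); i -= 1; j -= 1
        elif i > 0 and abs(H[i, j] - (H[i - 1, j] + gap)) < tol:
            path.append((i - 1, None)); i -= 1
        else:
            path.append((None, j - 1)); j -= 1
    path.reverse()
    return path


def _merge(rows1: list[str], rows2: list[str], S20: np.ndarray, gap: float
           ) -> tuple[list[str], list[str]]:
    F1, F2 = _profile(rows1), _profile(rows2)
    M = F1 @ S20 @ F2.T
    path = _nw_profile(M, gap)
    out1 = ["" for _ in rows1]
    out2 = ["" for _ in rows2]
    for i, j in path:
        c1 = [r[i] for r in rows1] if i is not None else ["-"] * len(rows1)
        c2 = [r[j] for r in rows2] if j is not None else ["-"] * len(rows2)
        for k, ch in enumerate(c1):
            out1[k] += ch
        for k, ch in enumerate(c2):
            out2[k] += ch
    return out1, out2


def pairwise_distance(a: str, b: str, matrix=None, gap: float = DEFAULT_LINEAR_GAP) -> float:
    """1 - identity of the optimal global alignment (linear gap penalty);
    the guide distance for progressive alignment."""
    if matrix is None:
        matrix = load_matrix(DEFAULT_MATRIX)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(a.upper(), b.upper())[0]
    s1, s2 = str(aln[0]), str(aln[1])
    ident = sum(x == y for x, y in zip(s1, s2)) / len(s1)
    return 1.0 - ident


def progressive_align(seqs, matrix=None, gap: float = DEFAULT_LINEAR_GAP) -> Msa:
    """Progressive multiple alignment: single-linkage guide tree on pairwise
    global-alignment distances, profiles merged leaf-to-root with linear gap
    penalties. Deterministic; every ungapped row equals its input sequence.

    ``seqs`` is a mapping id -> sequence or an iterable of (id, sequence).
    """
    items = list(seqs.items()) if hasattr(seqs, "items") else \
        [(s.id, s.sequence) if hasattr(s, "id") else tuple(s) for s in seqs]
    if not items:
        raise ValueError("no sequences to align")
    ids = [i for i, _ in items]
    raw = [s.upper() for _, s in items]
    if len(items) == 1:
        return Msa(ids, raw)
    if matrix is None:
        matrix = load_matrix(DEFAULT_MATRIX)
    if len(items) == 2:
        S20 = _matrix20(matrix)
        r1, r2 = _merge([raw[0]], [raw[1]], S20, gap)
        return Msa(ids, [r1[0], r2[0]])
    n = len(items)
    cond = []
    for i in range(n):
        for j in range(i + 1, n):
            cond.append(pairwise_distance(raw[i], raw[j], matrix=matrix, gap=gap))
    Z = linkage(np.asarray(cond), method="single")
    S20 = _matrix20(matrix)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [raw[i]]) for i in range(n)
    }
    for k, (a, b, _, _) in enumerate(Z):
        ia, ib = int(a), int(b)
        idx1, rows1 = clusters.pop(ia)
        idx2, rows2 = clusters.pop(ib)
        m1, m2 = _merge(rows1, rows2, S20, gap)
        clusters[n + k] = (idx1 + idx2, m1 + m2)
    order, rows = clusters.popitem()[1]
    # restore input id order
    paired = sorted(zip(order, rows))
    return Msa([ids[i] for i, _ in paired], [r for _, r in paired])


# ---------------------------------------------------------------------------
# Trimming and concatenation

def trim_blocks(msa: Msa, min_conservation: float = 0.5, min_block: int = 5,
                allow_gaps: bool = True) -> Msa:
    """Keep maximal runs of >= ``min_block`` consecutive columns whose modal
    residue frequency (most common non-gap residue over all rows) is at
    least ``min_conservation``. With ``allow_gaps=False``, columns containing
    any gap are removed before run detection. May return a zero-width Msa.
    """
    arr = msa.to_array()
    n = len(msa)
    keep = np.zeros(msa.width, dtype=bool)
    for j in range(msa.width):
        col = arr[:, j]
        if not allow_gaps and (col == "-").any():
            continue
        vals, counts = np.unique(col[col != "-"], return_counts=True)
        modal = counts.max() if counts.size else 0
        keep[j] = modal / n >= min_conservation
    cols: list[int] = []
    run: list[int] = []
    for j in range(msa.width):
        if keep[j]:
            run.append(j)
        else:
            if len(run) >= min_block:
                cols.extend(run)
            run = []
    if len(run) >= min_block:
        cols.extend(run)
    if not cols:
        return Msa(list(msa.ids), ["" for _ in msa.ids], [])
    return msa.select_columns(cols)


def concatenate(msas: list[Msa], taxa=None, names: list[str] | None = None) -> Msa:
    """Concatenate per-gene alignments into one partitioned supermatrix.

    Taxa missing from a gene receive an all-gap segment of that gene's
    width. ``taxa`` defaults to the union of ids in first-seen order;
    partition names default to ``gene1..geneN``.
    """
    if not msas:
        raise ValueError("no alignments to concatenate")
    if names is None:
        names = [f"gene{i + 1}" for i in range(len(msas))]
    if taxa is None:
        taxa = []
        for m in msas:
            for i in m.ids:
                if i not in taxa:
                    taxa.append(i)
    taxa = list(taxa)
    rows = {t: "" for t in taxa}
    parts = []
    pos = 0
    for name, m in zip(names, msas):
        if len(set(m.ids)) != len(m.ids):  # pragma: no cover - Msa validates
            raise ValueError(f"duplicate taxon within gene {name}")
        unknown = set(m.ids) - set(taxa)
        if unknown:
            raise ValueError(f"gene {name} has taxa outside the taxon set: {sorted(unknown)}")
        w = m.width
        for t in taxa:
            rows[t] += m.row(t) if t in m.ids else "-" * w
        parts.append((name, pos, pos + w))
        pos += w
    return Msa(taxa, [rows[t] for t in taxa], parts)


# ---------------------------------------------------------------------------
# Distances

def kimura_protein_distance(p: float, saturation: float = SATURATION_P,
                            ceiling: float = SATURATION_CEILING) -> float:
    """Kimura's correction of a protein p-distance,
    ``d = -ln(1 - p - 0.2 p^2)``; pairs at ``p >= saturation`` get the
    documented ceiling."""
    if p >= saturation:
        return ceiling
    return -math.log(1.0 - p - 0.2 * p * p)


def protein_distance(msa: Msa, saturation: float = SATURATION_P,
                     ceiling: float = SATURATION_CEILING) -> DistanceMatrix:
    """Pairwise corrected distances over columns ungapped in both rows.

    Raises ``ValueError`` naming the pair if two rows share no ungapped
    column.
    """
    if len(msa) < 2:
        raise ValueError("need at least two rows")
    arr = msa.to_array()
    ok = arr != "-"
    n = len(msa)
    D = np.zeros((n, n))
    saturated = 0
    for i in range(n):
        for j in range(i + 1, n):
            shared = ok[i] & ok[j]
            m = int(shared.sum())
            if m == 0:
                raise ValueError(
                    f"no shared ungapped columns between {msa.ids[i]!r} and {msa.ids[j]!r}"
                )
            p = float((arr[i, shared] != arr[j, shared]).sum()) / m
            d = kimura_protein_distance(p, saturation, ceiling)
            if p >= saturation:
                saturated += 1
            D[i, j] = D[j, i] = d
    if saturated:
        logger.info("protein_distance: %d saturated pairs set to ceiling %.1f",
                    saturated, ceiling)
    return DistanceMatrix(D, ids=list(msa.ids))


# ---------------------------------------------------------------------------
# Neighbor joining

def _as_distance_matrix(dm) -> DistanceMatrix:
    if isinstance(dm, DistanceMatrix):
        return dm
    labels, M = dm
    M = np.asarray(M, dtype=float)
    if not np.allclose(M, M.T):
        raise ValueError("distance matrix is not symmetric")
    return DistanceMatrix(M, ids=list(labels))


def neighbor_joining(dm) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken toward the pair whose (sorted)
    lexicographically smallest member labels come first; each cluster is
    keyed by its smallest leaf label. Negative branch lengths are clamped
    to zero (logged). Requires >= 3 labels; the returned tree is rooted at
    a trifurcation (the conventional unrooted-NJ representation).
    """
    dm = _as_distance_matrix(dm)
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    D = dm.data.copy()
    nodes = [TreeNode(name=l) for l in labels]
    keys = list(labels)  # smallest leaf label per active cluster

    def clamp(x: float) -> float:
        if x < 0:
            logger.debug("clamping negative branch length %.4g to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cands = [
            (tuple(sorted((keys[i], keys[j]))), i, j)
            for i, j in zip(*np.nonzero(Q <= qmin + 1e-10))
            if i < j
        ]
        _, i, j = min(cands)
        li = clamp(0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2)))
        lj = clamp(D[i, j] - (0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))))
        nodes[i].length, nodes[j].length = li, lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # solve the final three branch lengths exactly
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = clamp(0.5 * (dab + dac - dbc))
    b.length = clamp(0.5 * (dab + dbc - dac))
    c.length = clamp(0.5 * (dac + dbc - dab))
    return TreeNode(children=[a, b, c])


# ---------------------------------------------------------------------------
# Splits, monophyly, Robinson-Foulds

def nontrivial_splits(tree: TreeNode) -> set[frozenset]:
    """Unrooted non-trivial bipartitions, each represented by the side not
    containing the lexicographically smallest leaf."""
    tips = sorted(t.name for t in tree.tips())
    full = frozenset(tips)
    ref = tips[0]
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = full - side
        if 2 <= len(side) <= len(full) - 2:
            out.add(side)
    return out


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Symmetric-difference count of non-trivial bipartitions."""
    l1 = {t.name for t in t1.tips()}
    l2 = {t.name for t in t2.tips()}
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only in first {sorted(l1 - l2)}, "
            f"only in second {sorted(l2 - l1)}"
        )
    return len(nontrivial_splits(t1) ^ nontrivial_splits(t2))


def is_monophyletic(tree: TreeNode, group, outgroup) -> bool:
    """True iff some edge separates exactly ``group`` from all other leaves
    (equivalently: ``group`` is a clade once the tree is rooted on the
    outgroup side)."""
    group, outgroup = frozenset(group), frozenset(outgroup)
    tips = frozenset(t.name for t in tree.tips())
    unknown = (group | outgroup) - tips
    if unknown:
        raise ValueError(f"unknown leaf labels: {sorted(unknown)}")
    if not outgroup:
        raise ValueError("outgroup must be non-empty")
    if group & outgroup:
        raise ValueError("group and outgroup must be disjoint")
    if len(group) == 1:
        return True  # a pendant edge always separates a single leaf
    for node in tree.postorder(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if side == group or tips - side == group:
            return True
    return False


# ---------------------------------------------------------------------------
# Bootstrap

def bootstrap_support(msa: Msa, n_replicates: int = 1000, seed=None,
                      tree: TreeNode | None = None) -> TreeNode:
    """Nonparametric bootstrap over alignment columns.

    Columns are resampled with replacement; an NJ tree is rebuilt per
    replicate; each internal edge of the original tree gets
    ``support`` = fraction of replicates containing its bipartition.
    Replicates in which some pair loses all shared columns are skipped (and
    excluded from the denominator). Seeded and reproducible.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if len(msa) < 4:
        raise ValueError("bootstrap needs at least 4 rows")
    rng = np.random.default_rng(seed)
    if tree is None:
        tree = neighbor_joining(protein_distance(msa))
    counts: dict[frozenset, int] = {s: 0 for s in nontrivial_splits(tree)}
    ok = 0
    L = msa.width
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep = msa.select_columns(cols)
        try:
            rep_tree = neighbor_joining(protein_distance(rep))
        except ValueError:
            continue
        ok += 1
        rep_splits = nontrivial_splits(rep_tree)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    tips = sorted(t.name for t in tree.tips())
    full, ref = frozenset(tips), tips[0]
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = full - side
        if side in counts:
            node.support = counts[side] / ok if ok else float("nan")
    return tree


# ---------------------------------------------------------------------------
# Congruence

@dataclass
class CongruenceReport:
    """Greedy leaf-pruning comparison of two trees on their shared leaves.

    ``removals`` lists ``(leaf, rf_before, rf_after)`` in pruning order;
    the removed leaves are the putative horizontal-transfer candidates.
    """

    shared_leaves: list[str]
    initial_rf: int
    removals: list[tuple[str, int, int]]
    final_rf: int

    @property
    def candidates(self) -> list[str]:
        return [leaf for leaf, _, _ in self.removals]


def congruence_report(core_tree: TreeNode, mam_tree: TreeNode) -> CongruenceReport:
    """Repeatedly remove the shared leaf whose removal maximally reduces the
    Robinson–Foulds distance until the trees agree (or too few leaves
    remain). Ties are broken toward the lexicographically smallest leaf."""
    shared = sorted({t.name for t in core_tree.tips()} &
                    {t.name for t in mam_tree.tips()})
    if len(shared) < 4:
        raise ValueError("need at least 4 shared leaves")
    c = core_tree.shear(shared)
    m = mam_tree.shear(shared)
    current = list(shared)
    rf = robinson_foulds(c, m)
    initial = rf
    removals: list[tuple[str, int, int]] = []
    while rf > 0 and len(current) > 4:
        best: tuple[int, str] | None = None
        for leaf in current:
            rest = [x for x in current if x != leaf]
            r = robinson_foulds(c.shear(rest), m.shear(rest))
            if best is None or (r, leaf) < best:
                best = (r, leaf)
        r, leaf = best
        removals.append((leaf, rf, r))
        current = [x for x in current if x != leaf]
        c, m = c.shear(current), m.shear(current)
        rf = r
    return CongruenceReport(shared, initial, removals, rf)


# ---------------------------------------------------------------------------
# Newick I/O

def read_tree(source: str | Path) -> TreeNode:
    """Read a newick tree from a path or a newick string."""
    s = str(source)
    if Path(s).exists():
        return TreeNode.read(s, format="newick")
    return TreeNode.read(io.StringIO(s), format="newick")


def write_tree(tree: TreeNode, path: str | Path, support_labels: bool = True) -> None:
    """Write newick; bootstrap supports (if present) become internal-node
    labels."""
    if support_labels:
        for node in tree.non_tips(include_self=False):
            sup = getattr(node, "support", None)
            if sup is not None and node.name is None:
                node.name = f"{sup:.2f}"
    tree.write(str(path), format="newick")
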