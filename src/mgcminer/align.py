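"""Pairwise local alignment, percent identity, and E-value statistics.

Marker screening rests on three per-pair quantities: the optimal local
alignment score under a substitution matrix with affine gap penalties, the
fraction of identical alignment columns, and the Karlin–Altschul expectation
value ``E = K * m * n * exp(-lambda * S)`` for a score ``S`` between a query
of length ``m`` and a target of length ``n``. Screening thresholds are
expressed on identity and E-value; marker choice additionally uses
``-ln(E)`` so that very significant hits remain on a finite, plottable
scale.

Conventions
-----------
- Gap penalties are scores (non-positive): a gap of length ``k`` contributes
  ``gap_open + k * gap_extend`` to the alignment score, so the defaults
  ``gap_open=-11, gap_extend=-1`` reproduce the classic BLOSUM62/11/1
  protein-search setting.
- Percent identity divides identical columns by *all* alignment columns,
  including gapped ones.
- E-values use raw sequence lengths ``m`` and ``n`` with no edge-effect
  correction; ``-ln(E)`` is clamped to ``[0, 745]`` (745 is just below
  ``-ln`` of the smallest positive double).

The alignment engine is :class:`Bio.Align.PairwiseAligner` in local mode,
which implements Smith–Waterman–Gotoh exactly (the empty alignment is
allowed, so scores are never negative).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

#: Gapped Karlin-Altschul parameters for BLOSUM62 with 11/1 gap costs.
GAPPED_LAMBDA = 0.267
GAPPED_K = 0.041
#: Clamp for -ln(E); exp(-745) is near the smallest positive double.
NEG_LN_EVALUE_CAP = 745.0

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = -11
DEFAULT_GAP_EXTEND = -1


def load_matrix(name_or_path: str | Path):
    """Load a substitution matrix by name (e.g. ``"BLOSUM62"``) or from a
    file in standard NCBI matrix text format."""
    p = Path(str(name_or_path))
    if p.exists():
        with open(p) as fh:
            return substitution_matrices.read(fh)
    return substitution_matrices.load(str(name_or_path))


@dataclass
class LocalAlignment:
    """One optimal local alignment of a sequence pair.

    ``aligned_query``/``aligned_target`` are gapped strings of equal length
    covering only the locally aligned region; spans are 0-based half-open
    intervals on the ungapped inputs. The empty alignment (score 0, empty
    strings) is returned when no residue pair scores positively.
    """

    query_id: str
    target_id: str
    score: int
    aligned_query: str
    aligned_target: str
    query_span: tuple[int, int]
    target_span: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_target):
            raise ValueError("gapped rows differ in length")
        for k, (x, y) in enumerate(zip(self.aligned_query, self.aligned_target)):
            if x == "-" and y == "-":
                raise ValueError(f"column {k} is gap/gap")

    def __len__(self) -> int:
        return len(self.aligned_query)


@dataclass
class AlignmentHit:
    """Summary statistics of one pairwise comparison (one point of a
    marker-selection scatter: identity against ``-ln(E)``)."""

    query_id: str
    target_id: str
    identity: float
    evalue: float
    neg_ln_evalue: float
    score: int


def _aligner(matrix, gap_open: int, gap_extend: int, mode: str = "local") -> Align.PairwiseAligner:
    if not gap_open <= gap_extend <= 0:
        raise ValueError(
            f"gap penalties must satisfy gap_open <= gap_extend <= 0, got "
            f"({gap_open}, {gap_extend})"
        )
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = matrix
    # Biopython charges open_gap_score for a gap's first position; our
    # convention charges gap_open + k*gap_extend for a length-k gap.
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def smith_waterman(
    a: str,
    b: str,
    matrix=None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    query_id: str = "query",
    target_id: str = "target",
) -> LocalAlignment:
    """Optimal local alignment of protein sequences ``a`` (query) and ``b``
    (target) under affine gap penalties.

    Ties between co-optimal alignments are broken deterministically (the
    engine's first enumerated traceback). Raises ``ValueError`` on empty
    input.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    a, b = a.upper(), b.upper()
    if matrix is None:
        matrix = load_matrix(DEFAULT_MATRIX)
    aligner = _aligner(matrix, gap_open, gap_extend)
    alignments = aligner.align(a, b)
    score = int(round(alignments.score))
    if score <= 0 or len(alignments) == 0:
        # No positively scoring residue pair: the optimum is the empty
        # local alignment.
        return LocalAlignment(query_id, target_id, max(score, 0), "", "", (0, 0), (0, 0))
    best = alignments[0]
    blocks = best.aligned  # [[target blocks],[query blocks]] per Biopython (target=a)
    a_blocks, b_blocks = blocks[0], blocks[1]
    a_span = (int(a_blocks[0][0]), int(a_blocks[-1][1]))
    b_span = (int(b_blocks[0][0]), int(b_blocks[-1][1]))
    return LocalAlignment(
        query_id=query_id,
        target_id=target_id,
        score=score,
        aligned_query=str(best[0]),
        aligned_target=str(best[1]),
        query_span=a_span,
        target_span=b_span,
    )


def rescore(aln: LocalAlignment, matrix=None, gap_open: int = DEFAULT_GAP_OPEN,
            gap_extend: int = DEFAULT_GAP_EXTEND) -> int:
    """Re-derive the score of a gapped pair column by column (invariant
    check: must equal ``aln.score``)."""
    if matrix is None:
        matrix = load_matrix(DEFAULT_MATRIX)
    score = 0.0
    in_gap = False
    for x, y in zip(aln.aligned_query, aln.aligned_target):
        if x == "-" or y == "-":
            score += gap_extend + (gap_open if not in_gap else 0)
            in_gap = True
        else:
            score += matrix[x, y]
            in_gap = False
    return int(round(score))


def percent_identity(aln: LocalAlignment) -> float:
    """Identical columns / total alignment columns (gaps count in the
    denominator). Raises on the empty alignment."""
    if len(aln) == 0:
        raise ValueError("identity undefined for an empty alignment")
    same = sum(x == y for x, y in zip(aln.aligned_query, aln.aligned_target))
    return same / len(aln)


def score_to_evalue(
    score: int,
    m: int,
    n: int,
    lambda_: float = GAPPED_LAMBDA,
    K: float = GAPPED_K,
    cap: float = NEG_LN_EVALUE_CAP,
) -> tuple[float, float]:
    """Karlin–Altschul expectation ``E = K*m*n*exp(-lambda*score)`` and the
    clamped ``-ln(E)``.

    ``-ln(E)`` is computed in log space (it stays finite even when ``E``
    underflows) and clamped to ``[0, cap]``; hits with ``E > 1`` are
    uninformative and map to 0.
    """
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    if lambda_ <= 0 or K <= 0:
        raise ValueError("lambda and K must be positive")
    log_e = math.log(K) + math.log(m) + math.log(n) - lambda_ * score
    evalue = math.exp(log_e) if log_e < 700 else math.inf
    neg_ln = min(max(-log_e, 0.0), cap)
    return evalue, neg_ln


def align_and_score(
    query_id: str,
    query_seq: str,
    target_id: str,
    target_seq: str,
    matrix=None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    lambda_: float = GAPPED_LAMBDA,
    K: float = GAPPED_K,
) -> AlignmentHit:
    """Align one pair and package score, identity, and E-value statistics.

    The empty alignment yields identity 0 and E computed at score 0.
    """
    aln = smith_waterman(
        query_seq, target_seq, matrix=matrix, gap_open=gap_open,
        gap_extend=gap_extend, query_id=query_id, target_id=target_id,
    )
    ident = percent_identity(aln) if len(aln) else 0.0
    evalue, neg_ln = score_to_evalue(
        aln.score, len(query_seq), len(target_seq), lambda_=lambda_, K=K
    )
    return AlignmentHit(query_id, target_id, ident, evalue, neg_ln, aln.score)


def all_vs_all(
    seqs: Sequence,
    matrix=None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> list[AlignmentHit]:
    """All unordered pairwise hits among ``seqs`` (items expose ``.id`` and
    ``.sequence``, or are ``(id, sequence)`` tuples); the earlier item of a
    pair is the query (the ``m`` of the E-value formula)."""
    items = [(s.id, s.sequence) if hasattr(s, "id") else tuple(s) for s in seqs]
    if len(items) < 2:
        raise ValueError("all_vs_all needs at least two sequences")
    if matrix is None:
        matrix = load_matrix(DEFAULT_MATRIX)
    hits = []
    for (qi, qs), (ti, ts) in itertools.combinations(items, 2):
        hits.append(align_and_score(qi, qs, ti, ts, matrix=matrix,
                                    gap_open=gap_open, gap_extend=gap_extend))
    return hits


def iter_pairs(seqs: Iterable) -> Iterable[tuple]:
    """Unordered pairs helper (mirrors the pairing used by all_vs_all)."""
    return itertools.combinations(seqs, 2)
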