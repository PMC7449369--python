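"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: local alignment by
exhaustive enumeration of all gapped pairings, N50 by scanning every
candidate length, tree distances by explicit path summation.
"""

from __future__ import annotations

import itertools


def enumerate_alignment_scores(x: str, y: str, score, gap_open: int,
                               gap_extend: int) -> list[float]:
    """Scores of every global alignment of x and y (affine gap charging:
    a run of k gaps costs ``gap_open + k * gap_extend``)."""

    def rec(i, j, cols):
        if i == len(x) and j == len(y):
            yield list(cols)
            return
        if i < len(x) and j < len(y):
            yield from rec(i + 1, j + 1, cols + [(x[i], y[j])])
        if i < len(x):
            yield from rec(i + 1, j, cols + [(x[i], "-")])
        if j < len(y):
            yield from rec(i, j + 1, cols + [("-", y[j])])

    out = []
    for cols in rec(0, 0, []):
        s = 0.0
        prev_gap_side = None  # a gap run continues only on the same side
        for a, b in cols:
            if a == "-":
                s += gap_extend + (gap_open if prev_gap_side != "a" else 0)
                prev_gap_side = "a"
            elif b == "-":
                s += gap_extend + (gap_open if prev_gap_side != "b" else 0)
                prev_gap_side = "b"
            else:
                s += score(a, b)
                prev_gap_side = None
        out.append(s)
    return out


def brute_force_local_score(a: str, b: str, score, gap_open: int,
                            gap_extend: int) -> float:
    """Optimal non-empty local alignment score by enumerating every
    substring pair and every alignment of each pair; 0 when nothing
    positive exists (the empty alignment)."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    for s in enumerate_alignment_scores(a[i1:i2], b[j1:j2],
                                                        score, gap_open,
                                                        gap_extend):
                        best = max(best, s)
    return best


def brute_force_n50(lengths) -> int:
    """N50 by checking, for every distinct length L, whether scaffolds of
    length >= L cover at least half the assembly; answer is the largest
    such L."""
    total = sum(lengths)
    best = 0
    for L in sorted(set(lengths)):
        if 2 * sum(x for x in lengths if x >= L) >= total:
            best = max(best, L)
    return best


def all_words(alphabet: str, max_len: int):
    for n in range(1, max_len + 1):
        for w in itertools.product(alphabet, repeat=n):
            yield "".join(w)
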