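"""Global pairwise alignment with free end gaps, and percent identity.

Scoring: match +1, mismatch 0, affine gaps (open -10, extend -0.5 for each
further gapped position), end gaps free.  Identity is 100 x matches /
aligned columns, where the aligned columns are those on the traceback path
(end-gap overhangs are excluded; internal gap columns count as non-matches).

Ties in the traceback are broken by preferring diagonal, then up (gap in
the second sequence), then left.  All scores are multiples of 0.5, so
float comparisons are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NEG = -1e18

GAP_OPEN = -10.0
GAP_EXTEND = -0.5
MATCH = 1.0
MISMATCH = 0.0


@dataclass(frozen=True)
class AlignmentSummary:
    score: float
    n_matches: int
    n_columns: int

    @property
    def identity(self) -> float:
        return 100.0 * self.n_matches / self.n_columns


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def overlap_align(a: str, b: str) -> AlignmentSummary:
    """Align ``a`` against ``b`` and summarise the optimal path.

    Uses the three-state Gotoh recursion with free end gaps: row 0 and
    column 0 of the match matrix are zero (alignments may start on any
    boundary cell) and the optimum is taken over the last row and column.
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    av = _encode(a)
    bv = _encode(b)
    n, m = len(av), len(bv)

    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b ("up" moves)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a ("left" moves)
    M[0, :] = 0.0
    M[:, 0] = 0.0

    js = np.arange(m) * GAP_EXTEND  # (j-1)*extend for j = 1..m
    for i in range(1, n + 1):
        s_row = np.where(bv == av[i - 1], MATCH, MISMATCH)
        diag = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        M[i, 1:] = s_row + diag
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:] + GAP_OPEN, Y[i - 1, 1:] + GAP_OPEN),
            X[i - 1, 1:] + GAP_EXTEND,
        )
        # Y[i,j] = open + (j-1)*ext + max_{k<=j-1} (max(M[i,k],X[i,k]) - k*ext)
        g = np.maximum(M[i, :-1], X[i, :-1]) - np.arange(m) * GAP_EXTEND
        Y[i, 1:] = GAP_OPEN + js + np.maximum.accumulate(g)

    # pick the end cell: scan the last row left-to-right, then the last
    # column top-to-bottom; keep the first strictly-best cell.
    best_score = NEG
    end = (n, m)
    for j in range(1, m + 1):
        sc = max(M[n, j], X[n, j], Y[n, j])
        if sc > best_score:
            best_score, end = sc, (n, j)
    for i in range(1, n):
        sc = max(M[i, m], X[i, m], Y[i, m])
        if sc > best_score:
            best_score, end = sc, (i, m)

    n_matches, n_columns = _traceback(av, bv, M, X, Y, end)
    return AlignmentSummary(best_score, n_matches, n_columns)


def _state_at(M, X, Y, i, j) -> str:
    # preference: diagonal (M), up (X), left (Y)
    best = max(M[i, j], X[i, j], Y[i, j])
    if M[i, j] == best:
        return "M"
    if X[i, j] == best:
        return "X"
    return "Y"


def _traceback(av, bv, M, X, Y, end) -> tuple[int, int]:
    i, j = end
    state = _state_at(M, X, Y, i, j)
    n_matches = 0
    n_columns = 0
    while i > 0 and j > 0:
        if state == "M":
            n_columns += 1
            if av[i - 1] == bv[j - 1]:
                n_matches += 1
            need = M[i, j] - (MATCH if av[i - 1] == bv[j - 1] else MISMATCH)
            i, j = i - 1, j - 1
            if i == 0 or j == 0:
                break
            for cand, mat in (("M", M), ("X", X), ("Y", Y)):
                if mat[i, j] == need:
                    state = cand
                    break
        elif state == "X":
            n_columns += 1
            if M[i - 1, j] + GAP_OPEN == X[i, j]:
                state = "M"
            elif X[i - 1, j] + GAP_EXTEND == X[i, j]:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:  # Y
            n_columns += 1
            if M[i, j - 1] + GAP_OPEN == Y[i, j]:
                state = "M"
            elif X[i, j - 1] + GAP_OPEN == Y[i, j]:
                state = "X"
            else:
                state = "Y"
            j -= 1
    return n_matches, n_columns


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity between two sequences under the fixed scoring scheme.

    Returns 100.0 for identical sequences and 0.0 when no aligned column
    matches.
    """
    if a == b:
        return 100.0
    if a > b:  # canonical order: the scoring is symmetric, so this makes
        a, b = b, a  # the reported identity symmetric under tie-breaking too
    return overlap_align(a, b).identity
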