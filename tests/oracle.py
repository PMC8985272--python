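"""Independent brute-force alignment oracle for the clustering tests.

A pure-Python Gotoh (affine-gap) global aligner over BLOSUM62 scoring,
maximising (score, identities) lexicographically — additive in both
components, so the lexicographic DP is exact. Quadratic and slow; used
only on short sequences and small inputs.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")
GAP_OPEN = -10.0
GAP_EXTEND = -1.0
NEG = (float("-inf"), 0)


def _sub(a: str, b: str):
    return float(_BLOSUM[a, b])


def gotoh_identity(a: str, b: str) -> float:
    """Identity (identical aligned residues / shorter length) of the
    global affine-gap alignment with the most identities among the
    optimal-score alignments."""
    n, m = len(a), len(b)
    # states: M (match/mismatch), X (gap in b), Y (gap in a)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = (0.0, 0)
    for i in range(1, n + 1):
        X[i][0] = (GAP_OPEN + GAP_EXTEND * (i - 1), 0)
    for j in range(1, m + 1):
        Y[0][j] = (GAP_OPEN + GAP_EXTEND * (j - 1), 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _sub(a[i - 1], b[j - 1])
            ident = 1 if a[i - 1] == b[j - 1] else 0
            best = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = (best[0] + s, best[1] + ident)
            X[i][j] = max(
                (M[i - 1][j][0] + GAP_OPEN, M[i - 1][j][1]),
                (X[i - 1][j][0] + GAP_EXTEND, X[i - 1][j][1]),
                (Y[i - 1][j][0] + GAP_OPEN, Y[i - 1][j][1]),
            )
            Y[i][j] = max(
                (M[i][j - 1][0] + GAP_OPEN, M[i][j - 1][1]),
                (X[i][j - 1][0] + GAP_OPEN, X[i][j - 1][1]),
                (Y[i][j - 1][0] + GAP_EXTEND, Y[i][j - 1][1]),
            )
    score, identities = max(M[n][m], X[n][m], Y[n][m])
    return identities / min(n, m)
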