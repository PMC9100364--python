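"""Independent brute-force global aligner used as the test oracle.

A plain-Python Needleman-Wunsch/Gotoh dynamic program, written separately
from the package implementation (lists and floats, no numpy/numba), under
the same stated definition: BLOSUM62, gap open 10 / extend 1 with a gap of
length L costing open + (L-1)*extend, identity = identical columns over
all alignment columns, traceback tie preference match > gap-in-b > gap-in-a.
"""

from Bio.Align import substitution_matrices

_SM = substitution_matrices.load("BLOSUM62")
NEG = float("-inf")


def nw_align(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 1.0):
    """Return (score, matches, columns) of the optimal global alignment."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    pM = [[0] * (m + 1) for _ in range(n + 1)]
    pX = [[0] * (m + 1) for _ in range(n + 1)]
    pY = [[0] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + (i - 1) * gap_extend)
        pX[i][0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + (j - 1) * gap_extend)
        pY[0][j] = 0 if j == 1 else 2

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _SM[a[i - 1], b[j - 1]]
            best, p = M[i - 1][j - 1], 0
            if X[i - 1][j - 1] > best:
                best, p = X[i - 1][j - 1], 1
            if Y[i - 1][j - 1] > best:
                best, p = Y[i - 1][j - 1], 2
            M[i][j] = best + s
            pM[i][j] = p

            best, p = M[i - 1][j] - gap_open, 0
            if X[i - 1][j] - gap_extend > best:
                best, p = X[i - 1][j] - gap_extend, 1
            if Y[i - 1][j] - gap_open > best:
                best, p = Y[i - 1][j] - gap_open, 2
            X[i][j] = best
            pX[i][j] = p

            best, p = M[i][j - 1] - gap_open, 0
            if X[i][j - 1] - gap_open > best:
                best, p = X[i][j - 1] - gap_open, 1
            if Y[i][j - 1] - gap_extend > best:
                best, p = Y[i][j - 1] - gap_extend, 2
            Y[i][j] = best
            pY[i][j] = p

    state, score = 0, M[n][m]
    if X[n][m] > score:
        state, score = 1, X[n][m]
    if Y[n][m] > score:
        state, score = 2, Y[n][m]

    matches = cols = 0
    i, j = n, m
    while i > 0 or j > 0:
        cols += 1
        if state == 0:
            if a[i - 1] == b[j - 1]:
                matches += 1
            state = pM[i][j]
            i, j = i - 1, j - 1
        elif state == 1:
            state = pX[i][j]
            i -= 1
        else:
            state = pY[i][j]
            j -= 1
    return score, matches, cols


def nw_identity(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 1.0) -> float:
    score, matches, cols = nw_align(a, b, gap_open, gap_extend)
    return 100.0 * matches / cols
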