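"""Global protein alignment and percent identity.

Percent identity drives the nomenclature thresholds, so its definition is
fixed and documented here: a global (Needleman-Wunsch) alignment with
affine gaps (Gotoh recurrences), BLOSUM62 scores, gap open 10 and gap
extend 1 (a gap of length L costs ``open + (L-1)*extend``), and

    identity = 100 * identical columns / alignment columns (gaps included).

Where several alignments share the optimal score, the traceback prefers,
in order: match/mismatch, gap in the second sequence, gap in the first.
This tie-break is part of the definition and is mirrored by the
independent brute-force oracle in the test suite.
"""

from __future__ import annotations

from functools import lru_cache
from typing import NamedTuple

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .errors import ValidationError

_LETTERS = "ACDEFGHIKLMNPQRSTVWYX"
_CODE = np.full(128, -1, dtype=np.int16)
for _i, _x in enumerate(_LETTERS):
    _CODE[ord(_x)] = _i

_NEG = -1.0e30


@lru_cache(maxsize=4)
def load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Substitution scores as a dense 21x21 array over the residue alphabet."""
    sm = substitution_matrices.load(name)
    mat = np.zeros((len(_LETTERS), len(_LETTERS)), dtype=np.float64)
    for i, a in enumerate(_LETTERS):
        for j, b in enumerate(_LETTERS):
            mat[i, j] = sm[a, b]
    return mat


def encode(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted({c for c in seq if c not in _LETTERS})
        raise ValidationError(f"sequence contains invalid residue(s) {bad}")
    return codes.astype(np.uint8)


@njit(cache=False)
def _gotoh(a, b, sub, go, ge):  # pragma: no cover - exercised via wrapper
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in b (consumes a)
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in a (consumes b)
    pM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pX = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pY = np.zeros((n + 1, m + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(go + (i - 1) * ge)
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Iy[0, j] = -(go + (j - 1) * ge)
        pY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            best = M[i - 1, j - 1]
            p = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                p = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
            pM[i, j] = p

            best = M[i - 1, j] - go
            p = 0
            if Ix[i - 1, j] - ge > best:
                best = Ix[i - 1, j] - ge
                p = 1
            if Iy[i - 1, j] - go > best:
                best = Iy[i - 1, j] - go
                p = 2
            Ix[i, j] = best
            pX[i, j] = p

            best = M[i, j - 1] - go
            p = 0
            if Ix[i, j - 1] - go > best:
                best = Ix[i, j - 1] - go
                p = 1
            if Iy[i, j - 1] - ge > best:
                best = Iy[i, j - 1] - ge
                p = 2
            Iy[i, j] = best
            pY[i, j] = p

    state = 0
    score = M[n, m]
    if Ix[n, m] > score:
        score = Ix[n, m]
        state = 1
    if Iy[n, m] > score:
        score = Iy[n, m]
        state = 2

    matches = 0
    cols = 0
    i = n
    j = m
    while i > 0 or j > 0:
        if state == 0:
            if a[i - 1] == b[j - 1]:
                matches += 1
            cols += 1
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            cols += 1
            state = pX[i, j]
            i -= 1
        else:
            cols += 1
            state = pY[i, j]
            j -= 1
    return score, matches, cols


class AlignmentStats(NamedTuple):
    score: float
    matches: int
    columns: int


def global_align(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> AlignmentStats:
    """Globally align two sequences; return score, matches and columns."""
    if not a or not b:
        raise ValidationError("cannot align an empty sequence")
    score, matches, cols = _gotoh(
        encode(a), encode(b), load_matrix(matrix_name), float(gap_open), float(gap_extend)
    )
    return AlignmentStats(float(score), int(matches), int(cols))


def global_identity(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> float:
    """Percent identity of the global alignment (0..100)."""
    stats = global_align(a, b, matrix_name, gap_open, gap_extend)
    return 100.0 * stats.matches / stats.columns
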