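"""Independent brute-force alignment oracles used only by the tests.

These re-derive alignment scores and identities from first principles
(explicit dynamic-programming recurrences over every cell) so the package's
aligner can be checked against a second, independent route. The affine-gap
convention matches the package contract: a gap of length L costs
open + L * extend, and opening is allowed from any state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_IDX = {aa: i for i, aa in enumerate(PROTEIN_ALPHABET)}
_NT_IDX = {nt: i for i, nt in enumerate("ACGT")}


def encode(seq: str, table: dict[str, int]) -> np.ndarray:
    return np.array([table[c] for c in seq], dtype=np.int64)


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 over the 20-letter alphabet as a dense array."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20))
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            out[i, j] = m[a, b]
    return out


def nt_matrix(match: float = 2.0, mismatch: float = -3.0) -> np.ndarray:
    out = np.full((4, 4), mismatch)
    np.fill_diagonal(out, match)
    return out


@njit(cache=False)
def affine_local_score(a, b, submat, gap_open, gap_extend):
    """Exhaustive Smith–Waterman with affine gaps; every cell recurrence.

    Returns the maximal local alignment score (>= 0).
    """
    n, m = len(a), len(b)
    neg = -1e18
    M = np.full((n + 1, m + 1), neg)
    E = np.full((n + 1, m + 1), neg)  # gap in query (moves along b)
    F = np.full((n + 1, m + 1), neg)  # gap in subject (moves along a)
    best = 0.0
    go = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = M[i - 1, j - 1]
            if E[i - 1, j - 1] > prev:
                prev = E[i - 1, j - 1]
            if F[i - 1, j - 1] > prev:
                prev = F[i - 1, j - 1]
            if prev < 0.0:
                prev = 0.0
            M[i, j] = prev + submat[a[i - 1], b[j - 1]]

            e_open = M[i, j - 1]
            if F[i, j - 1] > e_open:
                e_open = F[i, j - 1]
            e1 = e_open - go
            e2 = E[i, j - 1] - gap_extend
            E[i, j] = e1 if e1 > e2 else e2

            f_open = M[i - 1, j]
            if E[i - 1, j] > f_open:
                f_open = E[i - 1, j]
            f1 = f_open - go
            f2 = F[i - 1, j] - gap_extend
            F[i, j] = f1 if f1 > f2 else f2

            cell = M[i, j]
            if E[i, j] > cell:
                cell = E[i, j]
            if F[i, j] > cell:
                cell = F[i, j]
            if cell > best:
                best = cell
    return best


def local_score_protein(a: str, b: str, gap_open: float = 11, gap_extend: float = 1) -> float:
    return float(
        affine_local_score(
            encode(a, _AA_IDX), encode(b, _AA_IDX), blosum62_matrix(), gap_open, gap_extend
        )
    )


def local_score_nt(
    a: str, b: str, match: float = 2, mismatch: float = -3,
    gap_open: float = 5, gap_extend: float = 2,
) -> float:
    return float(
        affine_local_score(
            encode(a, _NT_IDX), encode(b, _NT_IDX), nt_matrix(match, mismatch),
            gap_open, gap_extend,
        )
    )


def global_identity_oracle(
    a: str, b: str, gap_open: float = 11, gap_extend: float = 1
) -> float:
    """Needleman–Wunsch (affine, BLOSUM62) identity over all columns.

    Pure-python Gotoh with traceback, independent of the package's aligner.
    """
    submat = blosum62_matrix()
    ai = encode(a, _AA_IDX)
    bi = encode(b, _AA_IDX)
    n, m = len(a), len(b)
    neg = float("-inf")
    go = gap_open + gap_extend
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]
    F = [[neg] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        F[i][0] = -(gap_open + gap_extend * i)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i][j] = max(M[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1]) + submat[
                ai[i - 1], bi[j - 1]
            ]
            E[i][j] = max(M[i][j - 1] - go, E[i][j - 1] - gap_extend, F[i][j - 1] - go)
            F[i][j] = max(M[i - 1][j] - go, F[i - 1][j] - gap_extend, E[i - 1][j] - go)
    # traceback from the best final state
    i, j = n, m
    state = max(("M", "E", "F"), key=lambda s: {"M": M, "E": E, "F": F}[s][i][j])
    identities = columns = 0
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            identities += int(ai[i - 1] == bi[j - 1])
            columns += 1
            prev = M[i - 1][j - 1] + submat[ai[i - 1], bi[j - 1]]
            for s, mat in (("M", M), ("E", E), ("F", F)):
                if abs(mat[i - 1][j - 1] + submat[ai[i - 1], bi[j - 1]] - M[i][j]) < 1e-9:
                    state = s
                    break
            i, j = i - 1, j - 1
        elif state == "E" and j > 0:
            columns += 1
            if abs(E[i][j - 1] - gap_extend - E[i][j]) < 1e-9:
                state = "E"
            elif abs(M[i][j - 1] - go - E[i][j]) < 1e-9:
                state = "M"
            else:
                state = "F"
            j -= 1
        elif state == "F" and i > 0:
            columns += 1
            if abs(F[i - 1][j] - gap_extend - F[i][j]) < 1e-9:
                state = "F"
            elif abs(M[i - 1][j] - go - F[i][j]) < 1e-9:
                state = "M"
            else:
                state = "E"
            i -= 1
        else:  # boundary: forced gaps
            if i > 0:
                i -= 1
            else:
                j -= 1
            columns += 1
    return 100.0 * identities / columns if columns else 0.0
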