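"""Independent reference implementations used only by the test suite.

Deliberately naive: plain-python dynamic programming and exhaustive
path enumeration, written from the documented contracts rather than
from the package internals, so they can arbitrate what the optimized
kernels should return.
"""

from __future__ import annotations

import math

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def overlap_dp(a: str, b: str) -> tuple[int, int, int]:
    """Free-end-gap alignment scored +1 match / -1 mismatch / -2 gap.

    Returns (score, matches, aligned_columns) of the optimal alignment,
    terminal gaps excluded from the column count. N matches nothing.
    End cell: the maximum over the last row and column, smaller i then
    smaller j on ties; within the traceback diagonal is preferred over
    vertical over horizontal.
    """
    la, lb = len(a), len(b)
    S = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            m = 1 if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else -1
            S[i][j] = max(S[i - 1][j - 1] + m, S[i - 1][j] - 2, S[i][j - 1] - 2)
    best = (S[la][lb], la, lb)
    for i in range(la + 1):
        if S[i][lb] > best[0]:
            best = (S[i][lb], i, lb)
    for j in range(lb + 1):
        if S[la][j] > best[0]:
            best = (S[la][j], la, j)
    score, i, j = best
    matches = cols = 0
    while i > 0 and j > 0:
        m = 1 if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else -1
        if S[i][j] == S[i - 1][j - 1] + m:
            cols += 1
            matches += m == 1
            i, j = i - 1, j - 1
        elif S[i][j] == S[i - 1][j] - 2:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return score, matches, cols


def overlap_identity_oracle(a: str, b: str) -> tuple[float, int]:
    sf, mf, cf = overlap_dp(a, b)
    sr, mr, cr = overlap_dp(a, rc(b))
    matches, cols = (mr, cr) if sr > sf else (mf, cf)
    if cols == 0:
        return 0.0, 0
    return matches / cols, cols


def reads_overlap(a: str, b: str, min_identity: float, min_overlap: int) -> bool:
    ident, cols = overlap_identity_oracle(a, b)
    return cols >= min_overlap and ident >= min_identity


# --- fast variant of the same DP for the all-pairs BFS oracle ---------
# The score matrix is filled by a jitted helper (the quadratic all-pairs
# loop is otherwise too slow to run many randomized trials), but the
# recurrence is restated here from the contract and the traceback stays
# in plain python.

import numpy as np
from numba import njit

_CODE = {b: i for i, b in enumerate("ACGT")}


def _enc(seq: str) -> np.ndarray:
    return np.array([_CODE.get(b, 4) for b in seq], dtype=np.int8)


@njit(cache=False)
def _score_matrix(a, b):  # pragma: no cover - jitted
    la, lb = a.shape[0], b.shape[0]
    S = np.zeros((la + 1, lb + 1), dtype=np.int64)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            m = 1 if (a[i - 1] == b[j - 1] and a[i - 1] != 4) else -1
            best = S[i - 1][j - 1] + m
            if S[i - 1][j] - 2 > best:
                best = S[i - 1][j] - 2
            if S[i][j - 1] - 2 > best:
                best = S[i][j - 1] - 2
            S[i][j] = best
    return S


def _fast_overlap(a: str, b: str) -> tuple[int, int, int]:
    ea, eb = _enc(a), _enc(b)
    S = _score_matrix(ea, eb)
    la, lb = len(a), len(b)
    best = (S[la][lb], la, lb)
    for i in range(la + 1):
        if S[i][lb] > best[0]:
            best = (S[i][lb], i, lb)
    for j in range(lb + 1):
        if S[la][j] > best[0]:
            best = (S[la][j], la, j)
    score, i, j = best
    matches = cols = 0
    while i > 0 and j > 0:
        m = 1 if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else -1
        if S[i][j] == S[i - 1][j - 1] + m:
            cols += 1
            matches += m == 1
            i, j = i - 1, j - 1
        elif S[i][j] == S[i - 1][j] - 2:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return int(score), matches, cols


def _fast_edge(a: str, b: str, min_identity: float, min_overlap: int) -> bool:
    sf, mf, cf = _fast_overlap(a, b)
    sr, mr, cr = _fast_overlap(a, rc(b))
    matches, cols = (mr, cr) if sr > sf else (mf, cf)
    return cols >= min_overlap and cols > 0 and matches / cols >= min_identity


def bfs_recruit(
    seqs: dict[str, str], seeds: set[str], cycles: int,
    min_identity: float, min_overlap: int,
) -> set[str]:
    """Breadth-first recruitment of radius `cycles` over the all-pairs
    overlap graph (quadratic, no prefiltering)."""
    ids = sorted(seqs)
    adj: dict[str, set[str]] = {i: set() for i in ids}
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            if _fast_edge(seqs[ids[x]], seqs[ids[y]], min_identity, min_overlap):
                adj[ids[x]].add(ids[y])
                adj[ids[y]].add(ids[x])
    visited = set(seeds)
    frontier = set(seeds)
    for _ in range(cycles):
        nxt = {n for f in frontier for n in adj[f]} - visited
        visited |= nxt
        frontier = nxt
    return visited


def viterbi_enumerate(pep: list[int], hmm) -> float:
    """Exhaustive maximum over every local state path through the profile.

    Mirrors the model definition only: entry into any match state at
    hmm.entry_bits, exit after any match for free, transitions indexed
    [M->M, M->I, M->D, I->M, I->I, D->M, D->D].
    """
    me, ie, tr = hmm.match_emit, hmm.insert_emit, hmm.transitions
    M, L = hmm.M, len(pep)
    best = -math.inf

    def walk(i: int, k: int, state: str, score: float) -> None:
        # i = residues consumed, k = current node (0-based), score so far
        nonlocal best
        if state == "M":
            best = max(best, score)  # free exit after any match
        if state in ("M", "D") and k + 1 < M:
            col = {"M": 2, "D": 6}[state]
            walk(i, k + 1, "D", score + tr[k][col])
        if i < L:
            aa = pep[i]
            if state in ("M", "I"):
                col = {"M": 1, "I": 4}[state]
                walk(i + 1, k, "I", score + tr[k][col] + ie[k][aa])
            if k + 1 < M:
                col = {"M": 0, "I": 3, "D": 5}[state]
                walk(i + 1, k + 1, "M", score + tr[k][col] + me[k + 1][aa])

    for i0 in range(L):
        for k0 in range(M):
            walk(i0 + 1, k0, "M", hmm.entry_bits + me[k0][pep[i0]])
    return best
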