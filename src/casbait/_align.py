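"""Numeric alignment kernels (numba-compiled).

One kernel: semi-global (overlap) alignment with terminal gaps free on
both sequences, scored +1 match / -1 mismatch / -2 gap. The traceback
of the best-scoring alignment yields the aligned-column count and the
match count, from which the caller derives percent identity over the
overlap (terminal gaps are excluded by construction: the traceback
stops at the first row/column).

N (code 4) never counts as a match, against anything including N.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i  # lowercase


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_rc(seq: str) -> np.ndarray:
    """Encoded reverse complement (N stays N)."""
    enc = encode(seq)[::-1].copy()
    rc = enc.copy()
    mask = enc < 4
    rc[mask] = 3 - enc[mask]
    return rc


MATCH = 1
MISMATCH = -1
GAP = -2


@njit(cache=False)
def overlap_align(a: np.ndarray, b: np.ndarray):  # pragma: no cover - jitted
    """Best free-end-gap alignment of a vs b.

    Returns (score, matches, columns) for the optimal alignment, where
    columns counts aligned columns excluding terminal gaps. Tie-breaks
    are deterministic: among equal-scoring end cells the one with the
    smaller i, then smaller j wins; within the traceback diagonal moves
    are preferred over vertical over horizontal.
    """
    la = a.shape[0]
    lb = b.shape[0]
    S = np.zeros((la + 1, lb + 1), dtype=np.int32)
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            sub = MATCH if (ai == b[j - 1] and ai < 4) else MISMATCH
            best = S[i - 1, j - 1] + sub
            v = S[i - 1, j] + GAP
            if v > best:
                best = v
            h = S[i, j - 1] + GAP
            if h > best:
                best = h
            S[i, j] = best
    # free trailing gaps: best over last row and last column
    bi, bj = la, lb
    bscore = S[la, lb]
    for i in range(la + 1):
        if S[i, lb] > bscore:
            bscore = S[i, lb]
            bi, bj = i, lb
    for j in range(lb + 1):
        if S[la, j] > bscore:
            bscore = S[la, j]
            bi, bj = la, j
    # traceback
    i, j = bi, bj
    matches = 0
    cols = 0
    while i > 0 and j > 0:
        sub = MATCH if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else MISMATCH
        if S[i, j] == S[i - 1, j - 1] + sub:
            cols += 1
            if sub == MATCH:
                matches += 1
            i -= 1
            j -= 1
        elif S[i, j] == S[i - 1, j] + GAP:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return bscore, matches, cols


@njit(cache=False)
def viterbi_local(pep: np.ndarray, me: np.ndarray, ie: np.ndarray, tr: np.ndarray, entry: float):  # pragma: no cover - jitted
    """Uni-local Viterbi bit score of a peptide against a profile.

    pep: residue indices (0..19 canonical, 20 = anything else, which
    emits at background, i.e. log-odds 0 -- me/ie carry a zero 21st
    column for that).
    me, ie: (M, 21) match / insert emission log-odds in bits.
    tr: (M, 7) transition scores in bits, order
        [M->M, M->I, M->D, I->M, I->I, D->M, D->D], row k holding the
        transitions out of state k+1 (into k+2 for the advancing ones).
    entry: the local-entry score in bits paid once to begin an
    alignment at any match state (Plan7 uniform local entry,
    log2(2 / (M * (M + 1)))); exit from any match state is free. The
    score is the max over all local alignments.
    """
    L = pep.shape[0]
    M = me.shape[0]
    NEG = -1e30
    vm_prev = np.full(M, NEG)
    vi_prev = np.full(M, NEG)
    vd_prev = np.full(M, NEG)
    best = NEG
    vm = np.empty(M)
    vi = np.empty(M)
    vd = np.empty(M)
    for i in range(L):
        aa = pep[i]
        for k in range(M):
            # match state k (0-based): local entry costs `entry` bits
            cand = entry
            if k > 0:
                x = vm_prev[k - 1] + tr[k - 1, 0]
                if x > cand:
                    cand = x
                x = vi_prev[k - 1] + tr[k - 1, 3]
                if x > cand:
                    cand = x
                x = vd_prev[k - 1] + tr[k - 1, 5]
                if x > cand:
                    cand = x
            vm[k] = cand + me[k, aa]
            # insert state k
            x = vm_prev[k] + tr[k, 1]
            y = vi_prev[k] + tr[k, 4]
            vi[k] = (x if x > y else y) + ie[k, aa]
        # delete states sweep left-to-right within column i
        for k in range(M):
            if k == 0:
                vd[k] = NEG
            else:
                x = vm[k - 1] + tr[k - 1, 2]
                y = vd[k - 1] + tr[k - 1, 6]
                vd[k] = x if x > y else y
        for k in range(M):
            if vm[k] > best:
                best = vm[k]
        vm_prev, vm = vm, vm_prev
        vi_prev, vi = vi, vi_prev
        vd_prev, vd = vd, vd_prev
    return best
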