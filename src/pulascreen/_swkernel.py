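"""Numba kernel: affine-gap local (Smith-Waterman) alignment with traceback.

Scoring convention: a gap of length L costs ``gap_open + L * gap_extend``
(the opening transition already includes one extension).  The kernel is run
on a reference window selected by the seeding stage, so the matrix is small;
within the window it is exact, not heuristic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = np.int32(-(2**30))

# traceback op codes
OP_M, OP_I, OP_D = 0, 1, 2


@njit(cache=True)
def sw_align(q, t, match, mismatch, gap_open, gap_extend):
    """Exact local alignment of query ``q`` against target ``t`` (uint8 codes).

    Returns (score, q_start, q_end, t_start, t_end, ops) with 0-based
    half-open query/target intervals and ``ops`` the alignment operations
    (OP_M/OP_I/OP_D) from alignment start to end.  Codes >= 4 never match.
    Ties are broken toward the smallest end cell (row-major), and in the
    traceback toward diagonal, then deletion, then insertion.
    """
    m = q.shape[0]
    n = t.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)  # gap in query (D)
    F = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)  # gap in target (I)

    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = H[i, j - 1] + gap_open + gap_extend
            if E[i, j - 1] + gap_extend > e:
                e = E[i, j - 1] + gap_extend
            E[i, j] = e
            f = H[i - 1, j] + gap_open + gap_extend
            if F[i - 1, j] + gap_extend > f:
                f = F[i - 1, j] + gap_extend
            F[i, j] = f
            s = match if (qi == t[j - 1] and qi < 4) else mismatch
            h = H[i - 1, j - 1] + s
            if h < 0:
                h = 0
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j

    ops = np.empty(m + n, dtype=np.uint8)
    k = m + n
    i = bi
    j = bj
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            s = match if (q[i - 1] == t[j - 1] and q[i - 1] < 4) else mismatch
            if h == H[i - 1, j - 1] + s:
                k -= 1
                ops[k] = OP_M
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            k -= 1
            ops[k] = OP_D
            if E[i, j] == E[i, j - 1] + gap_extend:
                j -= 1
            else:
                j -= 1
                state = 0
        else:
            k -= 1
            ops[k] = OP_I
            if F[i, j] == F[i - 1, j] + gap_extend:
                i -= 1
            else:
                i -= 1
                state = 0
    return best, i, bi, j, bj, ops[k:]
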