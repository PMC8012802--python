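"""Numba dynamic-programming kernel for sequential structure alignment.

Gotoh-style affine DP with a gap-opening penalty and free gap extension
(matching the TM-align convention), free end gaps on both sequences, and
deterministic tie-breaking: diagonal (match) preferred over up (gap in the
second trace) preferred over left.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NEG = -1e18


@njit(cache=True)
def _fill(S, gap_open):  # pragma: no cover - exercised via align()
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)
    Iy = np.full((n + 1, m + 1), _NEG)
    PM = np.zeros((n + 1, m + 1), dtype=np.int8)   # 0:M 1:Ix 2:Iy 3:start
    PIx = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0:open from M, 1:extend
    PIy = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = M[i - 1, j - 1]
            ptr = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                ptr = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                ptr = 2
            if 0.0 > best:
                best = 0.0
                ptr = 3
            M[i, j] = S[i - 1, j - 1] + best
            PM[i, j] = ptr

            a_open = M[i - 1, j] + gap_open
            a_ext = Ix[i - 1, j]
            if a_open >= a_ext:
                Ix[i, j] = a_open
                PIx[i, j] = 0
            else:
                Ix[i, j] = a_ext
                PIx[i, j] = 1

            b_open = M[i, j - 1] + gap_open
            b_ext = Iy[i, j - 1]
            if b_open >= b_ext:
                Iy[i, j] = b_open
                PIy[i, j] = 0
            else:
                Iy[i, j] = b_ext
                PIy[i, j] = 2
    return M, PM, PIx, PIy


@njit(cache=True)
def _traceback(M, PM, PIx, PIy):  # pragma: no cover
    n = M.shape[0] - 1
    m = M.shape[1] - 1
    bi, bj, bv = 1, 1, _NEG
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if M[i, j] > bv:
                bv = M[i, j]
                bi, bj = i, j
    kmax = n if n < m else m
    pairs = np.empty((kmax, 2), dtype=np.int64)
    k = 0
    i, j = bi, bj
    state = 0
    while i > 0 and j > 0:
        if state == 0:
            k += 1
            pairs[kmax - k, 0] = i - 1
            pairs[kmax - k, 1] = j - 1
            p = PM[i, j]
            i -= 1
            j -= 1
            if p == 3:
                break
            state = p
        elif state == 1:
            p = PIx[i, j]
            i -= 1
            state = 0 if p == 0 else 1
        else:
            p = PIy[i, j]
            j -= 1
            state = 0 if p == 0 else 2
    return pairs[kmax - k :], bv


def align(score_matrix: np.ndarray, gap_open: float) -> tuple[np.ndarray, float]:
    """Best monotone matching under the score matrix with gap-open penalty.

    Returns a (k, 2) array of matched index pairs, strictly increasing in
    both columns, and the DP score.
    """
    S = np.ascontiguousarray(score_matrix, dtype=np.float64)
    M, PM, PIx, PIy = _fill(S, float(gap_open))
    return _traceback(M, PM, PIx, PIy)
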