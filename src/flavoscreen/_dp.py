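"""Compiled dynamic-programming kernels (Smith-Waterman, LCS).

The kernels are exact: full dynamic programming with affine gaps, no seeding
or banding.  A gap of length L costs ``gap_open + L * gap_extend``, so the
open transition from the match state is ``H - (gap_open + gap_extend)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(10**8))


@njit(cache=True)
def sw_score(q: np.ndarray, s: np.ndarray, sub: np.ndarray, gap_open: int, gap_extend: int) -> int:
    """Best local-alignment score, linear memory."""
    n = s.shape[0]
    h_prev = np.zeros(n + 1, dtype=np.int32)
    f = np.full(n + 1, NEG, dtype=np.int32)
    best = 0
    go = gap_open + gap_extend
    for i in range(1, q.shape[0] + 1):
        h_cur = np.zeros(n + 1, dtype=np.int32)
        e = NEG
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = max(h_cur[j - 1] - go, e - gap_extend)
            f[j] = max(h_prev[j] - go, f[j] - gap_extend)
            h = h_prev[j - 1] + sub[qi, s[j - 1]]
            if e > h:
                h = e
            if f[j] > h:
                h = f[j]
            if h < 0:
                h = 0
            h_cur[j] = h
            if h > best:
                best = h
        h_prev = h_cur
    return best


@njit(cache=True)
def sw_matrices(q: np.ndarray, s: np.ndarray, sub: np.ndarray, gap_open: int, gap_extend: int):
    """Full H/E/F matrices plus the best cell, for traceback."""
    m, n = q.shape[0], s.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    best = np.int32(0)
    bi = np.int32(0)
    bj = np.int32(0)
    go = gap_open + gap_extend
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - go, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - go, F[i - 1, j] - gap_extend)
            h = H[i - 1, j - 1] + sub[qi, s[j - 1]]
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=True)
def lcs_length(a: np.ndarray, b: np.ndarray) -> int:
    """Length of the longest common subsequence (max identically paired
    residues over all global alignments)."""
    n = b.shape[0]
    prev = np.zeros(n + 1, dtype=np.int32)
    for i in range(a.shape[0]):
        cur = np.zeros(n + 1, dtype=np.int32)
        ai = a[i]
        for j in range(1, n + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return int(prev[n])
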