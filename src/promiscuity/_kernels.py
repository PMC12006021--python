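"""Score-only affine-gap DP kernels used by the bulk screening stage.

These compute optimal alignment scores without traceback, in O(min(m,n))
memory, and are JIT-compiled with numba.  The full-traceback aligners in
:mod:`promiscuity.align` are the reference implementation; tests assert
the kernels agree with them.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - numba is a hard dependency but guard anyway
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

NEG = -(10 ** 9)


@njit(cache=True)
def local_score(qi: np.ndarray, si: np.ndarray, mat: np.ndarray,
                gap_open: int, gap_extend: int) -> int:
    """Optimal Smith-Waterman score, gaps costing open + extend*(len-1)."""
    m = qi.shape[0]
    n = si.shape[0]
    M_prev = np.full(n + 1, 0, dtype=np.int64)
    Iy_prev = np.full(n + 1, NEG, dtype=np.int64)
    Ix_prev = np.full(n + 1, NEG, dtype=np.int64)
    M_cur = np.zeros(n + 1, dtype=np.int64)
    Iy_cur = np.zeros(n + 1, dtype=np.int64)
    Ix_cur = np.zeros(n + 1, dtype=np.int64)
    best = 0
    for i in range(1, m + 1):
        M_cur[0] = 0
        Iy_cur[0] = NEG
        Ix_cur[0] = NEG
        for j in range(1, n + 1):
            s = mat[qi[i - 1], si[j - 1]]
            diag = M_prev[j - 1]
            if Iy_prev[j - 1] > diag:
                diag = Iy_prev[j - 1]
            if Ix_prev[j - 1] > diag:
                diag = Ix_prev[j - 1]
            h = s + diag
            if h < 0:
                h = 0
            M_cur[j] = h
            if h > best:
                best = h
            a = M_prev[j] - gap_open
            b = Iy_prev[j] - gap_extend
            c = Ix_prev[j] - gap_open
            v = a
            if b > v:
                v = b
            if c > v:
                v = c
            Iy_cur[j] = v
            a = M_cur[j - 1] - gap_open
            b = Ix_cur[j - 1] - gap_extend
            c = Iy_cur[j - 1] - gap_open
            v = a
            if b > v:
                v = b
            if c > v:
                v = c
            Ix_cur[j] = v
        M_prev, M_cur = M_cur, M_prev
        Iy_prev, Iy_cur = Iy_cur, Iy_prev
        Ix_prev, Ix_cur = Ix_cur, Ix_prev
    return best


@njit(cache=True)
def global_score(qi: np.ndarray, si: np.ndarray, mat: np.ndarray,
                 gap_open: int, gap_extend: int) -> int:
    """Optimal Needleman-Wunsch score with terminal gaps penalized."""
    m = qi.shape[0]
    n = si.shape[0]
    M_prev = np.full(n + 1, NEG, dtype=np.int64)
    Iy_prev = np.full(n + 1, NEG, dtype=np.int64)
    Ix_prev = np.full(n + 1, NEG, dtype=np.int64)
    M_prev[0] = 0
    for j in range(1, n + 1):
        Ix_prev[j] = -(gap_open + gap_extend * (j - 1))
    M_cur = np.zeros(n + 1, dtype=np.int64)
    Iy_cur = np.zeros(n + 1, dtype=np.int64)
    Ix_cur = np.zeros(n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        M_cur[0] = NEG
        Ix_cur[0] = NEG
        Iy_cur[0] = -(gap_open + gap_extend * (i - 1))
        for j in range(1, n + 1):
            s = mat[qi[i - 1], si[j - 1]]
            diag = M_prev[j - 1]
            if Iy_prev[j - 1] > diag:
                diag = Iy_prev[j - 1]
            if Ix_prev[j - 1] > diag:
                diag = Ix_prev[j - 1]
            M_cur[j] = s + diag
            a = M_prev[j] - gap_open
            b = Iy_prev[j] - gap_extend
            c = Ix_prev[j] - gap_open
            v = a
            if b > v:
                v = b
            if c > v:
                v = c
            Iy_cur[j] = v
            a = M_cur[j - 1] - gap_open
            b = Ix_cur[j - 1] - gap_extend
            c = Iy_cur[j - 1] - gap_open
            v = a
            if b > v:
                v = b
            if c > v:
                v = c
            Ix_cur[j] = v
        M_prev, M_cur = M_cur, M_prev
        Iy_prev, Iy_cur = Iy_cur, Iy_prev
        Ix_prev, Ix_cur = Ix_cur, Ix_prev
    best = M_prev[n]
    if Iy_prev[n] > best:
        best = Iy_prev[n]
    if Ix_prev[n] > best:
        best = Ix_prev[n]
    return best
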