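"""Pairwise protein alignment with affine gaps and Karlin-Altschul E-values.

Both a global (Needleman-Wunsch) and a local (Smith-Waterman) aligner
are provided under a common scoring scheme (substitution matrix plus
affine gap penalties, a gap of length L costing open + extend*(L-1)).
Tracebacks are deterministic with the fixed tie order
diagonal > up > left, so identical inputs always yield the identical
alignment string pair.

Percent identity is reported over all alignment columns (gaps included)
in global mode, and over the local alignment length in local mode (the
BLAST ``pident`` convention).  X never counts as identical and scores 0
against every residue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

__all__ = ["ScoringScheme", "AlignmentResult", "global_align", "local_align", "evalue"]

ALPHABET = "ARNDCQEGHILKMFPSTWYVX"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}
GAP = "-"

# Karlin-Altschul parameters for gapped BLOSUM62 with open 11 / extend 1,
# the standard BLASTP defaults for this regime.
BLOSUM62_GAPPED_LAMBDA = 0.267
BLOSUM62_GAPPED_K = 0.041

_NEG = -(10 ** 9)


def _blosum62_matrix() -> np.ndarray:
    bl = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            if a == "X" or b == "X":
                mat[i, j] = 0  # X is uninformative: scores 0 vs everything
            else:
                mat[i, j] = int(bl[a][b])
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and E-value parameters."""

    matrix: np.ndarray = field(default_factory=_blosum62_matrix)
    gap_open: int = 11
    gap_extend: int = 1
    ka_lambda: float = BLOSUM62_GAPPED_LAMBDA
    ka_K: float = BLOSUM62_GAPPED_K
    alphabet: str = ALPHABET

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=np.int64)
        if mat.shape != (len(self.alphabet), len(self.alphabet)):
            raise ValueError("matrix shape does not match alphabet")
        if not np.array_equal(mat, mat.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.ka_lambda <= 0 or self.ka_K <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        object.__setattr__(self, "matrix", mat)

    def encode(self, seq: str) -> np.ndarray:
        try:
            return np.array([_INDEX[c] for c in seq], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"residue {exc.args[0]!r} outside alphabet") from None

    def score_pair(self, a: str, b: str) -> int:
        return int(self.matrix[_INDEX[a], _INDEX[b]])

    @classmethod
    def from_matrix_file(
        cls, path: str | Path, gap_open: int = 11, gap_extend: int = 1,
        ka_lambda: float = BLOSUM62_GAPPED_LAMBDA, ka_K: float = BLOSUM62_GAPPED_K,
    ) -> "ScoringScheme":
        """Load a substitution matrix in NCBI matrix text format."""
        loaded = substitution_matrices.read(str(path))
        mat = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int64)
        for i, a in enumerate(ALPHABET):
            for j, b in enumerate(ALPHABET):
                if a == "X" or b == "X":
                    mat[i, j] = 0
                else:
                    mat[i, j] = int(loaded[a][b])
        return cls(matrix=mat, gap_open=gap_open, gap_extend=gap_extend,
                   ka_lambda=ka_lambda, ka_K=ka_K)


@dataclass(frozen=True)
class AlignmentResult:
    """A scored pairwise alignment with identity and (local) E-value."""

    mode: str  # "global" | "local"
    score: int
    aligned_query: str
    aligned_subject: str
    n_identical: int
    n_columns: int
    percent_identity: float
    query_coverage: float
    e_value: float | None = None

    def rescore(self, scheme: ScoringScheme) -> int:
        """Re-derive the score from the aligned strings (invariant check)."""
        return _score_aligned(self.aligned_query, self.aligned_subject, scheme)


def _score_aligned(aq: str, asub: str, scheme: ScoringScheme) -> int:
    if len(aq) != len(asub):
        raise ValueError("aligned strings differ in length")
    total = 0
    in_gap_q = in_gap_s = False
    for a, b in zip(aq, asub):
        if a == GAP and b == GAP:
            raise ValueError("double-gap alignment column")
        if a == GAP:
            total -= scheme.gap_extend if in_gap_q else scheme.gap_open
            in_gap_q, in_gap_s = True, False
        elif b == GAP:
            total -= scheme.gap_extend if in_gap_s else scheme.gap_open
            in_gap_q, in_gap_s = False, True
        else:
            total += scheme.score_pair(a, b)
            in_gap_q = in_gap_s = False
    return total


def _identity_stats(aq: str, asub: str) -> tuple[int, int, float]:
    n_cols = len(aq)
    n_id = sum(
        1 for a, b in zip(aq, asub) if a == b and a != GAP and a != "X"
    )
    pid = 100.0 * n_id / n_cols if n_cols else 0.0
    return n_id, n_cols, pid


# traceback state / predecessor codes
_M, _IY, _IX, _START = 0, 1, 2, 3


def _affine_dp(qi: np.ndarray, si: np.ndarray, scheme: ScoringScheme, local: bool):
    """Three-state Gotoh DP with full backpointers.

    States: M (diagonal), Iy ("up": query residue vs gap), Ix ("left":
    gap vs subject residue).  Ties are broken preferring M > Iy > Ix,
    which realizes the diagonal > up > left traceback order.
    """
    m, n = len(qi), len(si)
    go, ge = scheme.gap_open, scheme.gap_extend
    mat = scheme.matrix
    M = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    Iy = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    Ix = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    BM = np.zeros((m + 1, n + 1), dtype=np.int8)
    BY = np.zeros((m + 1, n + 1), dtype=np.int8)
    BX = np.zeros((m + 1, n + 1), dtype=np.int8)
    M[0, 0] = 0
    BM[0, 0] = _START
    if not local:
        for i in range(1, m + 1):
            Iy[i, 0] = -(go + ge * (i - 1))
            BY[i, 0] = _M if i == 1 else _IY
        for j in range(1, n + 1):
            Ix[0, j] = -(go + ge * (j - 1))
            BX[0, j] = _M if j == 1 else _IX
    for i in range(1, m + 1):
        if local:
            M[i, 0] = 0
            BM[i, 0] = _START
        for j in range(1, n + 1):
            if local and i == 1:
                M[0, j] = 0
                BM[0, j] = _START
            s = mat[qi[i - 1], si[j - 1]]
            # M: diagonal move; tie order M > Iy > Ix (> fresh start, local)
            best, ptr = M[i - 1, j - 1], _M
            if Iy[i - 1, j - 1] > best:
                best, ptr = Iy[i - 1, j - 1], _IY
            if Ix[i - 1, j - 1] > best:
                best, ptr = Ix[i - 1, j - 1], _IX
            val = s + best
            if local and val < 0:
                val, ptr = 0, _START
            M[i, j], BM[i, j] = val, ptr
            # Iy: consume query residue against a gap ("up")
            best, ptr = M[i - 1, j] - go, _M
            if Iy[i - 1, j] - ge > best:
                best, ptr = Iy[i - 1, j] - ge, _IY
            if Ix[i - 1, j] - go > best:
                best, ptr = Ix[i - 1, j] - go, _IX
            Iy[i, j], BY[i, j] = best, ptr
            # Ix: consume subject residue against a gap ("left")
            best, ptr = M[i, j - 1] - go, _M
            if Iy[i, j - 1] - go > best:
                best, ptr = Iy[i, j - 1] - go, _IY
            if Ix[i, j - 1] - ge > best:
                best, ptr = Ix[i, j - 1] - ge, _IX
            Ix[i, j], BX[i, j] = best, ptr
    return M, Iy, Ix, BM, BY, BX


def _traceback(qseq: str, sseq: str, end_i: int, end_j: int, end_state: int,
               BM, BY, BX, M=None) -> tuple[str, str, int, int]:
    """Reconstruct the alignment; in local mode (M given) stop at the
    first zero-valued M cell, the Smith-Waterman convention."""
    aq: list[str] = []
    asub: list[str] = []
    i, j, state = end_i, end_j, end_state
    while True:
        if state == _M:
            if M is not None and M[i, j] == 0:
                break
            ptr = BM[i, j]
            if ptr == _START and (i == 0 or j == 0):
                break
            if i == 0 and j == 0:
                break
            aq.append(qseq[i - 1])
            asub.append(sseq[j - 1])
            i, j = i - 1, j - 1
            if ptr == _START:
                break
            state = ptr
        elif state == _IY:
            ptr = BY[i, j]
            aq.append(qseq[i - 1])
            asub.append(GAP)
            i -= 1
            state = ptr
            if i == 0 and j == 0:
                break
        else:  # _IX
            ptr = BX[i, j]
            aq.append(GAP)
            asub.append(sseq[j - 1])
            j -= 1
            state = ptr
            if i == 0 and j == 0:
                break
    return "".join(reversed(aq)), "".join(reversed(asub)), i, j


def global_align(query: str, subject: str, scheme: ScoringScheme | None = None) -> AlignmentResult:
    """Optimal global alignment; terminal gaps are penalized and counted.

    Percent identity uses all alignment columns (internal and terminal
    gaps included) as the denominator.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    scheme = scheme or ScoringScheme()
    qi, si = scheme.encode(query), scheme.encode(subject)
    m, n = len(qi), len(si)
    M, Iy, Ix, BM, BY, BX = _affine_dp(qi, si, scheme, local=False)
    score, state = M[m, n], _M
    if Iy[m, n] > score:
        score, state = Iy[m, n], _IY
    if Ix[m, n] > score:
        score, state = Ix[m, n], _IX
    aq, asub, i0, j0 = _traceback(query, subject, m, n, state, BM, BY, BX)
    assert i0 == 0 and j0 == 0
    n_id, n_cols, pid = _identity_stats(aq, asub)
    return AlignmentResult(
        mode="global", score=int(score), aligned_query=aq, aligned_subject=asub,
        n_identical=n_id, n_columns=n_cols, percent_identity=pid,
        query_coverage=1.0,
    )


def local_align(query: str, subject: str, scheme: ScoringScheme | None = None) -> AlignmentResult:
    """Optimal local alignment with an E-value for the reported score."""
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    scheme = scheme or ScoringScheme()
    qi, si = scheme.encode(query), scheme.encode(subject)
    m, n = len(qi), len(si)
    M, Iy, Ix, BM, BY, BX = _affine_dp(qi, si, scheme, local=True)
    best, bi, bj = 0, 0, 0
    for i in range(m + 1):
        for j in range(n + 1):
            if M[i, j] > best:
                best, bi, bj = M[i, j], i, j
    if best <= 0:
        e = evalue(0, m, n, scheme)
        return AlignmentResult(
            mode="local", score=0, aligned_query="", aligned_subject="",
            n_identical=0, n_columns=0, percent_identity=0.0,
            query_coverage=0.0, e_value=e,
        )
    aq, asub, _, _ = _traceback(query, subject, bi, bj, _M, BM, BY, BX, M=M)
    n_id, n_cols, pid = _identity_stats(aq, asub)
    cov = sum(1 for c in aq if c != GAP) / m
    return AlignmentResult(
        mode="local", score=int(best), aligned_query=aq, aligned_subject=asub,
        n_identical=n_id, n_columns=n_cols, percent_identity=pid,
        query_coverage=cov, e_value=evalue(int(best), m, n, scheme),
    )


def evalue(score: int, m: int, n: int, scheme: ScoringScheme | None = None) -> float:
    """Karlin-Altschul expectation K*m*n*exp(-lambda*score).

    ``m`` and ``n`` are the unaligned sequence lengths.  Strictly
    decreasing in score, linear in each length.
    """
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    if score < 0:
        raise ValueError("score must be non-negative")
    scheme = scheme or ScoringScheme()
    return scheme.ka_K * m * n * math.exp(-scheme.ka_lambda * score)
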