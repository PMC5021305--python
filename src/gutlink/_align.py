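"""Local affine-gap alignment kernel (Gotoh) compiled with numba.

Scoring follows the blastn-like convention used throughout the package:
match +1, mismatch -2, and a gap of length L costs gap_open + L * gap_extend
(default 5 + 2L, so the first gapped base costs 7). Sequences are encoded as
uint8 with A,C,G,T -> 0..3 and N -> 4; N never matches anything, including
another N.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# traceback pointer codes for the H matrix
_STOP, _DIAG, _FROM_E, _FROM_F = 0, 1, 2, 3


@njit(cache=True)
def _sw_gotoh(q, s, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m = q.shape[0]
    n = s.shape[0]
    NEG = -10**9
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    ph = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pe = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 1 = extend, 0 = open
    pf = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    open_cost = gap_open + gap_extend
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            # E: gap in the query (consumes subject base j)
            e_open = H[i, j - 1] - open_cost
            e_ext = E[i, j - 1] - gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                pe[i, j] = 1
            else:
                E[i, j] = e_open
                pe[i, j] = 0
            # F: gap in the subject (consumes query base i)
            f_open = H[i - 1, j] - open_cost
            f_ext = F[i - 1, j] - gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                pf[i, j] = 1
            else:
                F[i, j] = f_open
                pf[i, j] = 0
            sj = s[j - 1]
            if qi == sj and qi < 4:
                sub = match
            else:
                sub = mismatch
            diag = H[i - 1, j - 1] + sub
            h = 0
            p = _STOP
            if diag > h:
                h = diag
                p = _DIAG
            if E[i, j] > h:
                h = E[i, j]
                p = _FROM_E
            if F[i, j] > h:
                h = F[i, j]
                p = _FROM_F
            H[i, j] = h
            ph[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback from (bi, bj)
    i = bi
    j = bj
    matches = 0
    columns = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        if state == 0:
            p = ph[i, j]
            if p == _STOP:
                break
            if p == _DIAG:
                columns += 1
                if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif p == _FROM_E:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns += 1
            ext = pe[i, j]
            j -= 1
            if ext == 0:
                state = 0
        else:
            columns += 1
            ext = pf[i, j]
            i -= 1
            if ext == 0:
                state = 0
    return best, i, bi, j, bj, matches, columns


@njit(cache=True)
def _sw_gotoh_banded(q, s, lo, band_w, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Banded Gotoh: cells restricted to lo <= j - i < lo + band_w.

    H/E/F are stored band-relative: column b of row i is subject position
    j = i + lo + b. Returns the same tuple as the full kernel; the score is
    the optimum over the band.
    """
    m = q.shape[0]
    n = s.shape[0]
    NEG = -(10**9)
    H = np.full((m + 1, band_w), 0, dtype=np.int32)
    E = np.full((m + 1, band_w), NEG, dtype=np.int32)
    F = np.full((m + 1, band_w), NEG, dtype=np.int32)
    ph = np.zeros((m + 1, band_w), dtype=np.uint8)
    pe = np.zeros((m + 1, band_w), dtype=np.uint8)
    pf = np.zeros((m + 1, band_w), dtype=np.uint8)
    best = 0
    bi = 0
    bb = 0
    open_cost = gap_open + gap_extend
    for i in range(1, m + 1):
        qi = q[i - 1]
        for b in range(band_w):
            j = i + lo + b
            if j < 1 or j > n:
                H[i, b] = NEG
                E[i, b] = NEG
                F[i, b] = NEG
                continue
            # E: gap consuming subject base j -> from (i, j-1) = band b-1
            if b >= 1 and H[i, b - 1] > NEG // 2:
                e_open = H[i, b - 1] - open_cost
            else:
                e_open = NEG
            if b >= 1:
                e_ext = E[i, b - 1] - gap_extend
            else:
                e_ext = NEG
            if e_ext > e_open:
                E[i, b] = e_ext
                pe[i, b] = 1
            else:
                E[i, b] = e_open
                pe[i, b] = 0
            # F: gap consuming query base i -> from (i-1, j) = band b+1
            if b + 1 < band_w and H[i - 1, b + 1] > NEG // 2:
                f_open = H[i - 1, b + 1] - open_cost
            else:
                f_open = NEG
            if b + 1 < band_w:
                f_ext = F[i - 1, b + 1] - gap_extend
            else:
                f_ext = NEG
            if f_ext > f_open:
                F[i, b] = f_ext
                pf[i, b] = 1
            else:
                F[i, b] = f_open
                pf[i, b] = 0
            # diagonal from (i-1, j-1) = same band column
            sj = s[j - 1]
            if qi == sj and qi < 4:
                sub = match
            else:
                sub = mismatch
            prev = H[i - 1, b]
            diag = prev + sub if prev > NEG // 2 else NEG
            h = 0
            p = _STOP
            if diag > h:
                h = diag
                p = _DIAG
            if E[i, b] > h:
                h = E[i, b]
                p = _FROM_E
            if F[i, b] > h:
                h = F[i, b]
                p = _FROM_F
            H[i, b] = h
            ph[i, b] = p
            if h > best:
                best = h
                bi = i
                bb = b
    # traceback
    i = bi
    b = bb
    matches = 0
    columns = 0
    state = 0
    while True:
        j = i + lo + b
        if state == 0:
            p = ph[i, b]
            if p == _STOP:
                break
            if p == _DIAG:
                columns += 1
                if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                    matches += 1
                i -= 1
            elif p == _FROM_E:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns += 1
            ext = pe[i, b]
            b -= 1
            if ext == 0:
                state = 0
        else:
            columns += 1
            ext = pf[i, b]
            i -= 1
            b += 1
            if ext == 0:
                state = 0
    return best, i, bi, i + lo + b, bi + lo + bb, matches, columns


def local_align_banded(
    query: np.ndarray,
    subject: np.ndarray,
    diag_lo: int,
    diag_hi: int,
    pad: int = 30,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = 5,
    gap_extend: int = 2,
):
    """Best local alignment restricted to a diagonal band.

    ``diag_lo``/``diag_hi`` bound the subject-minus-query diagonals of the
    seed chain; the band is widened by ``pad`` on each side to allow gaps.
    Coordinates are half-open as in :func:`local_align`.
    """
    lo = diag_lo - pad
    band_w = diag_hi - diag_lo + 2 * pad + 1
    score, q0, q1, s0, s1, matches, columns = _sw_gotoh_banded(
        np.ascontiguousarray(query, dtype=np.uint8),
        np.ascontiguousarray(subject, dtype=np.uint8),
        lo,
        band_w,
        match,
        mismatch,
        gap_open,
        gap_extend,
    )
    return int(score), int(q0), int(q1), int(s0), int(s1), int(matches), int(columns)


def local_align(
    query: np.ndarray,
    subject: np.ndarray,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = 5,
    gap_extend: int = 2,
):
    """Best local alignment of two encoded sequences.

    Returns (score, q_start, q_end, s_start, s_end, matches, columns) with
    half-open, 0-based coordinates. A score of 0 means no positive-scoring
    local alignment exists.
    """
    score, q0, q1, s0, s1, matches, columns = _sw_gotoh(
        np.ascontiguousarray(query, dtype=np.uint8),
        np.ascontiguousarray(subject, dtype=np.uint8),
        match,
        mismatch,
        gap_open,
        gap_extend,
    )
    return int(score), int(q0), int(q1), int(s0), int(s1), int(matches), int(columns)
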