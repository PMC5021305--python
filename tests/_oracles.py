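"""Independent oracles used to cross-check the package's implementations.

These deliberately use different algorithmic organisations from the code
under test: a row-vectorised full-matrix Gotoh recurrence for local
alignment scores, an exhaustive tandem-repeat scanner, and nested-loop
interval overlap checks.
"""

from __future__ import annotations

import numpy as np

_MAP = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _enc(s: str) -> np.ndarray:
    return np.array([_MAP[c] for c in s], dtype=np.int64)


def sw_score_full(
    query: str,
    subject: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = 5,
    gap_extend: int = 2,
) -> int:
    """Optimal local affine-gap alignment score, full dynamic program.

    Row-vectorised Gotoh: within a row, gap-in-query scores are obtained
    from a prefix maximum of H + extend*j (a gap never profitably starts
    from another gap in the same direction), so no sequential scan is
    needed. A gap of length L costs gap_open + L*gap_extend.
    """
    q = _enc(query)
    s = _enc(subject)
    m, n = len(q), len(s)
    NEG = -(10**9)
    ext = gap_extend
    open_cost = gap_open + gap_extend
    H_prev = np.zeros(n + 1, dtype=np.int64)
    F = np.full(n + 1, NEG, dtype=np.int64)
    best = 0
    j_idx = np.arange(n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        sub = np.where((s == q[i - 1]) & (q[i - 1] < 4), match, mismatch)
        D = np.concatenate(([NEG], H_prev[:-1] + sub))
        F = np.maximum(F - ext, H_prev - open_cost)
        Ht = np.maximum.reduce([np.zeros(n + 1, dtype=np.int64), D, F])
        # E via prefix max of Ht + ext*j
        T = Ht + ext * j_idx
        P = np.maximum.accumulate(T)
        E = np.concatenate(([NEG], P[:-1])) - open_cost - ext * j_idx + ext
        H = np.maximum(Ht, E)
        best = max(best, int(H.max()))
        H_prev = H
    return best


def brute_ssr_positions(
    sequence: str,
    motif_len_range: tuple[int, int] = (1, 6),
    min_total_len: int = 12,
) -> set[int]:
    """Positions covered by qualifying perfect tandem repeats (exhaustive).

    For every start position and motif length, extends the period-m match
    as far as possible and records covered positions when the run reaches
    max(min_total_len, 2*m) and contains no N.
    """
    n = len(sequence)
    covered: set[int] = set()
    lo, hi = motif_len_range
    for m in range(lo, hi + 1):
        for i in range(n):
            j = i + m
            while (
                j < n
                and sequence[j] == sequence[j - m]
                and sequence[j] != "N"
                and "N" not in sequence[i : i + m]
            ):
                j += 1
            if j - i >= max(min_total_len, 2 * m) and "N" not in sequence[i:j]:
                covered.update(range(i, j))
    return covered


def brute_overlaps(
    interval: tuple[int, int], masks: list[tuple[int, int]], min_bp: int = 1
) -> bool:
    a0, a1 = interval
    for b0, b1 in masks:
        lo = max(a0, b0)
        hi = min(a1, b1)
        if hi - lo >= min_bp:
            return True
    return False


def mutate_with_rate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Independent per-site substitution at the given rate (test helper)."""
    bases = "ACGT"
    out = []
    for c in seq:
        if rng.random() < rate:
            out.append(bases[(bases.index(c) + 1 + rng.integers(0, 3)) % 4])
        else:
            out.append(c)
    return "".join(out)
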