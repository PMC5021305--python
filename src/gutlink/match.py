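"""Seed-and-extend matching of reads against a reference database.

Produces local-alignment hits honouring the per-database search policy
(E-value ceiling, maximum targets). Identity and overlap thresholds are NOT
applied here — that is the job of the downstream filtering stage, mirroring
how a BLAST search precedes threshold filtering.

The built-in aligner indexes exact k-mers (default k=12) over the forward
strand of every subject, searches the read and its reverse complement,
chains seeds per subject/diagonal, and runs an exact local affine-gap
dynamic program over the seeded subject window. No query masking is
performed ("no dust"). An outfmt-6 import path is provided for
interoperability with standard BLAST tabular output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from ._align import local_align, local_align_banded
from .readqc import Read
from .refdb import MatchPolicy, ReferenceDatabase

# ---------------------------------------------------------------------------
# nucleotide encoding

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 (A,C,G,T -> 0..3, other -> 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp_encoded(enc: np.ndarray) -> np.ndarray:
    return _COMP[enc[::-1]]


def kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-mers of an encoded sequence.

    Returns (codes, valid) where valid marks windows free of non-ACGT
    symbols; invalid windows carry arbitrary codes and must be ignored.
    """
    n = enc.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(enc, k)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    codes = windows.astype(np.int64) @ powers
    valid = ~np.lib.stride_tricks.sliding_window_view(enc == 4, k).any(axis=1)
    return codes, valid


def _rc_code(code: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


def rc_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorised reverse-complement of k-mer integer codes."""
    out = np.zeros_like(codes)
    c = codes.copy()
    for _ in range(k):
        out = (out << 2) | (3 - (c & 3))
        c >>= 2
    return out


# ---------------------------------------------------------------------------
# alignment hits


@dataclass
class AlignmentHit:
    """A local alignment between a read and a reference subject.

    percent_identity = matches / alignment columns x 100; alignment_length
    counts columns including gaps. Intervals are 0-based half-open; the
    subject interval is always on the forward strand, with ``strand`` marking
    the orientation of the read.
    """

    read_id: str
    db_id: str
    seq_id: str
    taxon_id: Optional[str]
    percent_identity: float
    alignment_length: int
    read_start: int
    read_end: int
    subject_start: int
    subject_end: int
    strand: str
    raw_score: float
    evalue: float


# ---------------------------------------------------------------------------
# E-value estimation (Karlin-Altschul)


@lru_cache(maxsize=None)
def _lambda_for(match: int, mismatch: int, freqs: tuple[float, ...]) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for lambda > 0."""
    p = np.asarray(freqs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("base frequencies must sum to 1")
    p_match = float((p**2).sum())
    p_mismatch = 1.0 - p_match
    expected = p_match * match + p_mismatch * mismatch
    if expected >= 0:
        raise ValueError(
            "scoring scheme has non-negative expected score; lambda undefined"
        )

    def f(lam: float) -> float:
        return p_match * math.exp(lam * match) + p_mismatch * math.exp(lam * mismatch) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e3:
            raise ValueError("lambda solve did not converge")
    return float(brentq(f, 1e-9, hi, xtol=1e-12))


def estimate_evalue(
    raw_score: float,
    read_len: int,
    db_len: int,
    match: int = 1,
    mismatch: int = -2,
    K: float = 0.1,
    freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S).

    lambda is solved numerically from the substitution scores and background
    base frequencies; K is a configurable constant (default 0.1).
    """
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    lam = _lambda_for(match, mismatch, tuple(float(x) for x in freqs))
    return float(K * read_len * db_len * math.exp(-lam * raw_score))


# ---------------------------------------------------------------------------
# seed index


class SeedIndex:
    """Exact k-mer index over the forward strand of every subject sequence.

    ``lookup`` answers queries over both strands: a k-mer matching the
    reverse strand at forward position p is reported with strand '-'.
    Postings are stored as sorted numpy arrays for memory- and cache-friendly
    range lookups.
    """

    def __init__(self, db: ReferenceDatabase, k: int = 12, screen_k: int = 16):
        if not (8 <= k <= 16):
            raise ValueError("k must be in [8, 16]")
        self.db = db
        self.k = k
        self.screen_k = screen_k
        self.seq_ids = db.seq_ids
        self.encoded = [encode(seq) for _, seq, _ in db.sequences]

        codes_all, seq_all, pos_all = [], [], []
        screen_all = []
        for idx, enc in enumerate(self.encoded):
            codes, valid = kmer_codes(enc, k)
            pos = np.nonzero(valid)[0]
            codes_all.append(codes[pos])
            seq_all.append(np.full(pos.shape[0], idx, dtype=np.int32))
            pos_all.append(pos.astype(np.int32))
            scodes, svalid = kmer_codes(enc, screen_k)
            sc = scodes[svalid]
            screen_all.append(sc)
            screen_all.append(rc_codes(sc, screen_k))
        codes = np.concatenate(codes_all) if codes_all else np.empty(0, np.int64)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._seq_idx = (
            np.concatenate(seq_all)[order] if seq_all else np.empty(0, np.int32)
        )
        self._pos = np.concatenate(pos_all)[order] if pos_all else np.empty(0, np.int32)
        self.screen_keys = (
            np.unique(np.concatenate(screen_all)).astype(np.uint32)
            if screen_all
            else np.empty(0, np.uint32)
        )
        self.n_forward_seeds = int(self._codes.shape[0])

    def postings(self, code: int) -> tuple[np.ndarray, np.ndarray]:
        """(seq_idx, pos) arrays for one forward-strand k-mer code."""
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return self._seq_idx[lo:hi], self._pos[lo:hi]

    def postings_many(
        self, codes: np.ndarray, qpos: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised postings for many query k-mers.

        Returns (seq_idx, subject_pos, query_pos) with one row per seed
        match.
        """
        lo = np.searchsorted(self._codes, codes, side="left")
        hi = np.searchsorted(self._codes, codes, side="right")
        counts = hi - lo
        nz = np.nonzero(counts)[0]
        if nz.size == 0:
            e = np.empty(0, np.int32)
            return e, e, e
        spans = counts[nz]
        flat = np.concatenate([np.arange(lo[i], hi[i]) for i in nz])
        qp = np.repeat(qpos[nz], spans).astype(np.int32)
        return self._seq_idx[flat], self._pos[flat], qp

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """All (seq_id, forward position, strand) occurrences of a k-mer."""
        enc = encode(kmer)
        if enc.shape[0] != self.k or (enc == 4).any():
            return []
        powers = (4 ** np.arange(self.k - 1, -1, -1)).astype(np.int64)
        code = int(enc.astype(np.int64) @ powers)
        out = []
        si, sp = self.postings(code)
        for i, p in zip(si, sp):
            out.append((self.seq_ids[int(i)], int(p), "+"))
        rc = _rc_code(code, self.k)
        if rc != code:
            si, sp = self.postings(rc)
            for i, p in zip(si, sp):
                out.append((self.seq_ids[int(i)], int(p), "-"))
        return out


def build_seed_index(db: ReferenceDatabase, k: int = 12) -> SeedIndex:
    """Build (and cache on the database object) an exact k-mer seed index."""
    cached = getattr(db, "_seed_index", None)
    if cached is not None and cached.k == k:
        return cached
    index = SeedIndex(db, k=k)
    db._seed_index = index
    return index


# ---------------------------------------------------------------------------
# alignment driver


def _as_id_seq(read) -> tuple[str, str]:
    if isinstance(read, Read):
        return read.read_id, read.sequence
    if isinstance(read, tuple):
        return read[0], read[1]
    # Biopython SeqRecord
    return read.id, str(read.seq)


def _align_one(
    read_id: str,
    seq: str,
    index: SeedIndex,
    policy: MatchPolicy,
    min_seed_chain: int,
    max_diag_gap: int,
    window_pad: int,
    scoring: tuple[int, int, int, int],
    evalue_K: float,
    max_extensions: int = 12,
) -> list[AlignmentHit]:
    db = index.db
    qlen = len(seq)
    enc_fwd = encode(seq)
    match_s, mismatch_s, gap_open, gap_extend = scoring
    best_by_subject: dict[int, tuple] = {}

    # collect seed clusters over both strands, extend the richest first
    clusters: list[tuple[int, str, int, int, int]] = []  # (nseeds, strand, sub, dlo, dhi)
    enc_by_strand = {"+": enc_fwd, "-": revcomp_encoded(enc_fwd)}
    for strand, enc in enc_by_strand.items():
        codes, valid = kmer_codes(enc, index.k)
        qpos = np.nonzero(valid)[0]
        if qpos.size == 0:
            continue
        si, sp, qp = index.postings_many(codes[qpos], qpos)
        if si.size == 0:
            continue
        diag = sp.astype(np.int64) - qp.astype(np.int64)
        order = np.lexsort((diag, si))
        si, diag = si[order], diag[order]
        # split into clusters: new subject, or diagonal jump > max_diag_gap
        brk = np.nonzero((np.diff(si) != 0) | (np.diff(diag) > max_diag_gap))[0]
        starts = np.concatenate(([0], brk + 1))
        ends = np.concatenate((brk + 1, [si.shape[0]]))
        for a, b in zip(starts, ends):
            if b - a < min_seed_chain:
                continue
            clusters.append(
                (int(b - a), strand, int(si[a]), int(diag[a]), int(diag[b - 1]))
            )
    clusters.sort(key=lambda c: -c[0])
    for _nseeds, strand, sub_idx, d_lo, d_hi in clusters[:max_extensions]:
        enc = enc_by_strand[strand]
        senc = index.encoded[sub_idx]
        slen = senc.shape[0]
        w0 = max(0, d_lo - window_pad)
        w1 = min(slen, d_hi + qlen + window_pad)
        if w1 - w0 < index.k:
            continue
        window = senc[w0:w1]
        if d_hi - d_lo <= 120:
            score, q0, q1, s0, s1, matches, columns = local_align_banded(
                enc, window, d_lo - w0, d_hi - w0, pad=window_pad,
                match=match_s, mismatch=mismatch_s,
                gap_open=gap_open, gap_extend=gap_extend,
            )
        else:
            score, q0, q1, s0, s1, matches, columns = local_align(
                enc, window, match_s, mismatch_s, gap_open, gap_extend
            )
        if score <= 0:
            continue
        s0 += w0
        s1 += w0
        if strand == "-":
            q0, q1 = qlen - q1, qlen - q0
        prev = best_by_subject.get(sub_idx)
        ident = matches / columns if columns else 0.0
        if prev is None or (score, ident) > (prev[0], prev[1]):
            best_by_subject[sub_idx] = (
                score, ident, strand, q0, q1, s0, s1, matches, columns,
            )

    hits = []
    for sub_idx, (score, ident, strand, q0, q1, s0, s1, matches, columns) in (
        best_by_subject.items()
    ):
        ev = estimate_evalue(
            score, qlen, db.total_length, match=match_s, mismatch=mismatch_s, K=evalue_K
        )
        if ev > policy.max_evalue:
            continue
        seq_id = index.seq_ids[sub_idx]
        hits.append(
            AlignmentHit(
                read_id=read_id,
                db_id=db.db_id,
                seq_id=seq_id,
                taxon_id=db.taxon_of(seq_id),
                percent_identity=100.0 * ident,
                alignment_length=columns,
                read_start=q0,
                read_end=q1,
                subject_start=s0,
                subject_end=s1,
                strand=strand,
                raw_score=float(score),
                evalue=ev,
            )
        )
    hits.sort(key=lambda h: (-h.raw_score, -h.percent_identity, h.seq_id))
    return hits[: policy.max_targets]


def _batch_matrix(reads: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Pack a batch of reads into a 4-padded uint8 matrix plus lengths."""
    encs = []
    for r in reads:
        _, seq = _as_id_seq(r)
        encs.append(encode(seq))
    lens = np.array([e.shape[0] for e in encs], dtype=np.int64)
    maxlen = int(lens.max()) if len(encs) else 0
    mat = np.full((len(encs), maxlen), 4, dtype=np.uint8)
    for i, e in enumerate(encs):
        mat[i, : e.shape[0]] = e
    return mat, lens


def _batch_codes(mat: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer codes per row (uint32, k <= 16) plus a validity mask.

    One pass over the columns: the code of the window ending at column j is
    accumulated as ((c << 2) | base) mod 2^32, and a run-length counter
    invalidates windows containing non-ACGT symbols (including padding).
    """
    if k > 16:
        raise ValueError("batch codes support k <= 16")
    rows, n = mat.shape
    w = n - k + 1
    if w <= 0:
        return (
            np.empty((rows, 0), dtype=np.uint32),
            np.empty((rows, 0), dtype=bool),
        )
    codes = np.empty((rows, w), dtype=np.uint32)
    valid = np.empty((rows, w), dtype=bool)
    c = np.zeros(rows, dtype=np.uint32)
    run = np.zeros(rows, dtype=np.int32)  # clean bases since last non-ACGT
    for j in range(n):
        col = mat[:, j]
        isn = col >= 4
        c = (c << np.uint32(2)) | (col & 3).astype(np.uint32)
        run = np.where(isn, 0, run + 1)
        if j >= k - 1:
            codes[:, j - k + 1] = c
            valid[:, j - k + 1] = run >= k
    return codes, valid


def _count_key_hits(
    codes: np.ndarray, valid: np.ndarray, keys: np.ndarray
) -> np.ndarray:
    """Per-row count of valid codes present in a sorted uint32 key array."""
    if keys.shape[0] == 0 or codes.size == 0:
        return np.zeros(codes.shape[0], dtype=np.int64)
    pos = np.clip(np.searchsorted(keys, codes), 0, keys.shape[0] - 1)
    hit = (keys[pos] == codes) & valid
    return hit.sum(axis=1)


class ScreenBank:
    """Shared exact-16-mer prescreen over several databases.

    For multi-million-read libraries, each read's 16-mer codes are computed
    once and tested against the union of all database screen keys via a
    bitset over the 32-bit code space; only reads passing the union screen
    are assigned per-database by exact membership counts. A read is a
    candidate for a database when it shares at least ``min_shared`` exact
    screen k-mers with it (reads shorter than the screen k-mer are always
    candidates everywhere).
    """

    def __init__(self, indexes: Sequence[SeedIndex], min_shared: int = 4):
        self.indexes = list(indexes)
        if not self.indexes:
            raise ValueError("ScreenBank requires at least one index")
        sks = {ix.screen_k for ix in self.indexes}
        if len(sks) != 1:
            raise ValueError("all indexes must share screen_k")
        self.screen_k = sks.pop()
        if self.screen_k > 16:
            raise ValueError("screen_k > 16 exceeds the 32-bit bitset space")
        self.min_shared = min_shared
        keys = np.unique(
            np.concatenate([ix.screen_keys for ix in self.indexes])
        ).astype(np.uint64)
        self._words = np.zeros(
            max(1, 1 << max(0, 2 * self.screen_k - 6)), dtype=np.uint64
        )
        np.bitwise_or.at(
            self._words, (keys >> 6).astype(np.int64), np.uint64(1) << (keys & 63)
        )

    def _union_present(self, codes: np.ndarray, valid: np.ndarray) -> np.ndarray:
        c = codes.astype(np.uint64)
        present = (self._words[(c >> 6).astype(np.int64)] >> (c & 63)) & 1
        return (present.astype(bool)) & valid

    def candidates(
        self, reads: Sequence, chunk: int = 100_000
    ) -> dict[str, np.ndarray]:
        """Per-database candidate read indices."""
        out: dict[str, list[int]] = {ix.db.db_id: [] for ix in self.indexes}
        n = len(reads)
        for c0 in range(0, n, chunk):
            batch = reads[c0 : c0 + chunk]
            mat, lens = _batch_matrix(batch)
            short = np.nonzero(lens < self.screen_k)[0]
            codes, valid = _batch_codes(mat, self.screen_k)
            if codes.shape[1]:
                present = self._union_present(codes, valid)
                rows = np.nonzero(present.sum(axis=1) >= self.min_shared)[0]
            else:
                rows = np.empty(0, dtype=np.int64)
            for ix in self.indexes:
                db_id = ix.db.db_id
                if rows.size:
                    counts = _count_key_hits(
                        codes[rows], valid[rows], ix.screen_keys
                    )
                    keep = rows[counts >= self.min_shared]
                else:
                    keep = rows
                merged = np.union1d(keep, short) if short.size else keep
                out[db_id].extend((merged + c0).tolist())
        return {db_id: np.asarray(v, dtype=np.int64) for db_id, v in out.items()}


def prescreen_candidates(
    reads: Sequence, index: SeedIndex, min_shared: int = 2, chunk: int = 100_000
) -> np.ndarray:
    """Indices of reads sharing >= min_shared exact screen k-mers with the db.

    A throughput heuristic for large libraries: membership of read 16-mers
    (forward codes; the key set already contains both subject strands) is
    tested against the database's sorted screen-key array. Reads shorter
    than the screen k-mer are always candidates.
    """
    out = []
    n = len(reads)
    for c0 in range(0, n, chunk):
        batch = reads[c0 : c0 + chunk]
        mat, lens = _batch_matrix(batch)
        codes, valid = _batch_codes(mat, index.screen_k)
        counts = (
            _count_key_hits(codes, valid, index.screen_keys)
            if codes.shape[1]
            else np.zeros(len(batch), dtype=np.int64)
        )
        keep = np.nonzero((counts >= min_shared) | (lens < index.screen_k))[0]
        out.extend((keep + c0).tolist())
    return np.asarray(out, dtype=np.int64)


def align_reads(
    reads: Sequence,
    db: ReferenceDatabase,
    policy: Optional[MatchPolicy] = None,
    k: int = 12,
    min_seed_chain: int = 2,
    max_diag_gap: int = 20,
    window_pad: int = 30,
    scoring: tuple[int, int, int, int] = (1, -2, 5, 2),
    evalue_K: float = 0.1,
    prescreen_threshold: int = 20_000,
    candidate_indices: Optional[np.ndarray] = None,
) -> list[AlignmentHit]:
    """Align reads against a reference database.

    Per read, at most ``policy.max_targets`` distinct subjects are retained
    (best raw score first; ties broken by higher identity, then lexicographic
    seq_id), keeping only the best-scoring local alignment per subject. Hits
    with E-value above the policy ceiling are discarded. Reads without
    chainable seeds yield no hits. ``candidate_indices`` (e.g. from a
    :class:`ScreenBank`) bypasses the internal prescreen.
    """
    policy = policy or db.policy
    index = build_seed_index(db, k=k)
    if candidate_indices is not None:
        candidates = candidate_indices
    elif len(reads) > prescreen_threshold:
        candidates = prescreen_candidates(reads, index)
    else:
        candidates = np.arange(len(reads))
    hits: list[AlignmentHit] = []
    for i in candidates:
        read_id, seq = _as_id_seq(reads[int(i)])
        hits.extend(
            _align_one(
                read_id,
                seq,
                index,
                policy,
                min_seed_chain,
                max_diag_gap,
                window_pad,
                scoring,
                evalue_K,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# BLAST outfmt 6 interoperability

_OUTFMT6_COLS = 12


def import_blast_tabular(
    path: str | Path, db_id: str, db: Optional[ReferenceDatabase] = None
) -> list[AlignmentHit]:
    """Import 12-column BLAST outfmt 6 hits.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore. 1-based inclusive coordinates become 0-based
    half-open; sstart > send encodes a reverse-strand hit whose subject
    interval is normalised to the forward strand. pident and length are
    passed through verbatim.
    """
    hits = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < _OUTFMT6_COLS:
                raise ValueError(
                    f"{path}:{ln}: expected {_OUTFMT6_COLS} columns, got {len(parts)}"
                )
            try:
                (qseqid, sseqid, pident, length, _mism, _gapo, qstart, qend,
                 sstart, send, evalue, bitscore) = parts[:_OUTFMT6_COLS]
                pident_f = float(pident)
                length_i = int(length)
                qs, qe = int(qstart), int(qend)
                ss, se = int(sstart), int(send)
                ev = float(evalue)
                score = float(bitscore)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed row ({exc})") from None
            if ss <= se:
                strand, s0, s1 = "+", ss - 1, se
            else:
                strand, s0, s1 = "-", se - 1, ss
            taxon = db.taxon_of(sseqid) if db is not None else None
            hits.append(
                AlignmentHit(
                    read_id=qseqid,
                    db_id=db_id,
                    seq_id=sseqid,
                    taxon_id=taxon,
                    percent_identity=pident_f,
                    alignment_length=length_i,
                    read_start=qs - 1,
                    read_end=qe,
                    subject_start=s0,
                    subject_end=s1,
                    strand=strand,
                    raw_score=score,
                    evalue=ev,
                )
            )
    return hits


def export_blast_tabular(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits as 12-column outfmt 6 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for h in hits:
            mismatches = round(
                h.alignment_length * (1 - h.percent_identity / 100.0)
            )
            if h.strand == "+":
                ss, se = h.subject_start + 1, h.subject_end
            else:
                ss, se = h.subject_end, h.subject_start + 1
            fh.write(
                f"{h.read_id}\t{h.seq_id}\t{h.percent_identity:.3f}\t"
                f"{h.alignment_length}\t{mismatches}\t0\t"
                f"{h.read_start + 1}\t{h.read_end}\t{ss}\t{se}\t"
                f"{h.evalue:.2e}\t{h.raw_score:.1f}\n"
            )


__all__ = [
    "AlignmentHit",
    "SeedIndex",
    "build_seed_index",
    "align_reads",
    "prescreen_candidates",
    "ScreenBank",
    "estimate_evalue",
    "import_blast_tabular",
    "export_blast_tabular",
    "encode",
    "revcomp_encoded",
    "kmer_codes",
    "rc_codes",
]
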