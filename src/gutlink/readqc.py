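"""Read pre-processing: adapter clipping, mean-quality filtering, FASTA output.

The pipeline contract is deliberately small: clip 3'-anchored library
adapters, drop reads whose mean Phred quality falls below a floor (default
20), and convert survivors to FASTA for matching. No operation ever alters a
base call.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class Read:
    """A sequencing read: id, bases, per-base Phred scores (0..60)."""

    read_id: str
    sequence: str
    qualities: np.ndarray  # uint8 Phred scores

    def __post_init__(self):
        self.qualities = np.asarray(self.qualities, dtype=np.uint8)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if self.qualities.size and self.qualities.max() > 60:
            raise ValueError(f"read {self.read_id!r}: Phred score > 60")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_quality(self) -> float:
        if not len(self.qualities):
            return 0.0
        return float(self.qualities.mean())


# ---------------------------------------------------------------------------
# FASTQ / FASTA IO


def read_fastq(path: str | Path) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = np.array(rec.letter_annotations["phred_quality"], dtype=np.uint8)
        reads.append(Read(rec.description or rec.id, str(rec.seq).upper(), quals))
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def to_fasta(reads: Iterable[Read]) -> list[SeqRecord]:
    """Order- and id-preserving FASTA conversion; qualities are discarded.

    Ids containing whitespace follow the FASTA dialect: the id is the first
    whitespace-delimited token, the full original header is kept as the
    record description.
    """
    records = []
    for r in reads:
        token = r.read_id.split()[0] if r.read_id.split() else r.read_id
        records.append(SeqRecord(Seq(r.sequence), id=token, description=r.read_id))
    return records


def write_fasta(reads: Iterable[Read], path: str | Path) -> None:
    records = to_fasta(reads)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            fh.write(f">{header}\n{str(rec.seq)}\n")


# ---------------------------------------------------------------------------
# adapter clipping


def _find_adapter(seq: str, adapter: str, min_match: int, max_mismatch_rate: float) -> int:
    """Leftmost start of a 3'-anchored adapter occurrence, or -1.

    At position p the adapter prefix of length L = min(len(adapter),
    len(seq) - p) is compared; the occurrence counts if L >= min_match and
    mismatches / L <= max_mismatch_rate. The occurrence may run off the 3'
    end of the read (partial adapter).
    """
    n = len(seq)
    for p in range(0, n - min_match + 1):
        L = min(len(adapter), n - p)
        if L < min_match:
            break
        window = seq[p : p + L]
        mism = sum(1 for a, b in zip(window, adapter) if a != b)
        if mism / L <= max_mismatch_rate:
            return p
    return -1


def trim_adapters(
    reads: Iterable[Read],
    adapter_sequences: Sequence[str],
    min_match: int = 10,
    max_mismatch_rate: float = 0.2,
) -> list[Read]:
    """Clip the leftmost adapter occurrence and everything 3' of it.

    Reads clipped to zero length are dropped. Bases left on the read are
    never altered.
    """
    adapters = [a.upper() for a in adapter_sequences if a]
    if not adapters and list(adapter_sequences) != []:
        raise ValueError("adapter sequences must be non-empty strings")
    out = []
    for r in reads:
        cut = len(r.sequence)
        for adapter in adapters:
            p = _find_adapter(r.sequence, adapter, min_match, max_mismatch_rate)
            if p >= 0:
                cut = min(cut, p)
        if cut == len(r.sequence):
            out.append(r)
        elif cut > 0:
            out.append(Read(r.read_id, r.sequence[:cut], r.qualities[:cut]))
        # cut == 0: adapter at the very start; drop the read
    return out


# ---------------------------------------------------------------------------
# quality filtering


def quality_filter(reads: Iterable[Read], min_mean_phred: float = 20.0) -> list[Read]:
    """Keep reads whose arithmetic mean Phred score is >= the floor.

    Surviving reads are untouched. Idempotent.
    """
    return [r for r in reads if r.mean_quality >= min_mean_phred]


def trim_quality_3prime(reads: Iterable[Read], min_phred: int = 20) -> list[Read]:
    """Alternative per-base mode: trim the 3' tail while quality < min_phred.

    Provided as a configurable alternative to the mean-quality filter; reads
    trimmed to zero length are dropped.
    """
    out = []
    for r in reads:
        q = r.qualities
        end = len(q)
        while end > 0 and q[end - 1] < min_phred:
            end -= 1
        if end == len(q):
            out.append(r)
        elif end > 0:
            out.append(Read(r.read_id, r.sequence[:end], q[:end]))
    return out


__all__ = [
    "Read",
    "read_fastq",
    "write_fastq",
    "to_fasta",
    "write_fasta",
    "trim_adapters",
    "quality_filter",
    "trim_quality_3prime",
]
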