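"""Reference databases: sequences, per-database matching policy, masked regions.

The identification stage matches gut-content reads against several reference
databases of different taxonomic resolution (whole insect mitogenomes, cox1
barcodes, aphid nuclear genomes, parasitoid markers, rRNA genes, bacterial
endosymbiont genomes). Each database carries its own matching policy: the
minimum alignment overlap and percent identity a hit must reach, the E-value
ceiling and maximum number of targets of the underlying search, and an
optional host-exclusion rank for markers that cannot separate the focal
predator from its close relatives.

Coordinates are 0-based half-open throughout (BED convention); 1-based
inclusive coordinates appear only at the BLAST outfmt-6 import/export
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import yaml
from Bio import SeqIO

from .taxonomy import RANK_INDEX, TAG_VOCABULARY, Taxonomy

VALID_BASES = frozenset("ACGTN")

MARKER_CLASSES = (
    "insect_mitogenome",
    "cox1_barcode",
    "nuclear_genome",
    "parasitoid_markers",
    "rrna",
    "bacterial_genome",
)

MASK_REASONS = ("control_region", "ssr", "shared_marker")


@dataclass(frozen=True)
class MatchPolicy:
    """Per-database hit acceptance policy.

    min_identity is a percentage in (0, 100]; min_overlap counts alignment
    columns (gaps included, as in BLAST outfmt 6). max_evalue and max_targets
    control the search stage; identity/overlap are applied downstream by the
    filtering stage.
    """

    min_identity: float
    min_overlap: int
    max_evalue: float = 1e-5
    max_targets: int = 3
    algorithm_hint: str = "blastn_like"
    host_exclusion_rank: Optional[str] = None

    def __post_init__(self):
        if not (0 < self.min_identity <= 100):
            raise ValueError("min_identity must be in (0, 100]")
        if self.min_overlap <= 0:
            raise ValueError("min_overlap must be positive")
        if self.max_targets < 1:
            raise ValueError("max_targets must be >= 1")
        if self.algorithm_hint not in ("blastn_like", "megablast_like"):
            raise ValueError(f"unknown algorithm_hint {self.algorithm_hint!r}")
        if (
            self.host_exclusion_rank is not None
            and self.host_exclusion_rank not in RANK_INDEX
        ):
            raise ValueError(f"unknown rank {self.host_exclusion_rank!r}")


@dataclass(frozen=True)
class MaskedRegion:
    """A subject interval whose matches are non-diagnostic (discarded)."""

    seq_id: str
    start: int
    end: int
    reason: str = "ssr"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")
        if self.reason not in MASK_REASONS:
            raise ValueError(f"unknown mask reason {self.reason!r}")


@dataclass
class ReferenceDatabase:
    """A reference database: sequences with taxon labels plus its policy."""

    db_id: str
    marker_class: str
    sequences: list[tuple[str, str, str]]  # (seq_id, sequence, taxon_id)
    policy: MatchPolicy
    masked: list[MaskedRegion] = field(default_factory=list)

    def __post_init__(self):
        if self.marker_class not in MARKER_CLASSES:
            raise ValueError(f"unknown marker_class {self.marker_class!r}")
        seen = set()
        lengths = {}
        for seq_id, seq, _taxon in self.sequences:
            if seq_id in seen:
                raise ValueError(f"duplicate seq_id {seq_id!r} in {self.db_id}")
            seen.add(seq_id)
            if not seq:
                raise ValueError(f"empty sequence {seq_id!r} in {self.db_id}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"sequence {seq_id!r} contains non-ACGTN symbols {sorted(bad)}"
                )
            lengths[seq_id] = len(seq)
        for region in self.masked:
            if region.seq_id in lengths and region.end > lengths[region.seq_id]:
                raise ValueError(
                    f"mask {region.seq_id}:[{region.start},{region.end}) exceeds "
                    f"sequence length {lengths[region.seq_id]}"
                )
        self._by_id = {sid: (seq, taxon) for sid, seq, taxon in self.sequences}

    # -- access ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def seq_ids(self) -> list[str]:
        return [sid for sid, _, _ in self.sequences]

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq, _ in self.sequences)

    def sequence(self, seq_id: str) -> str:
        return self._by_id[seq_id][0]

    def taxon_of(self, seq_id: str) -> str:
        return self._by_id[seq_id][1]

    def masked_by_seq(self) -> dict[str, list[MaskedRegion]]:
        out: dict[str, list[MaskedRegion]] = {}
        for region in self.masked:
            out.setdefault(region.seq_id, []).append(region)
        return out


# ---------------------------------------------------------------------------
# loading


def load_metadata_table(path: str | Path) -> dict[str, str]:
    """Read a TSV of (seq_id, taxon_id) into a dict."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns")
            table[parts[0]] = parts[1]
    return table


def load_database(
    fasta_path: str | Path,
    metadata_table: dict[str, str] | str | Path,
    policy: MatchPolicy,
    db_id: str = "db",
    marker_class: str = "insect_mitogenome",
    masked: Optional[Iterable[MaskedRegion]] = None,
) -> ReferenceDatabase:
    """Load a FASTA reference database, attaching taxon labels from metadata.

    Every FASTA record id must appear in the metadata table; a missing row is
    a hard error naming the sequence, never a silent drop.
    """
    if not isinstance(metadata_table, dict):
        metadata_table = load_metadata_table(metadata_table)
    sequences = []
    missing = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(record.seq).upper()
        taxon = metadata_table.get(record.id)
        if taxon is None:
            missing.append(record.id)
            continue
        sequences.append((record.id, seq, taxon))
    if missing:
        raise ValueError(
            f"FASTA records without metadata rows in {fasta_path}: "
            + ", ".join(repr(m) for m in missing)
        )
    if not sequences:
        raise ValueError(f"empty FASTA {fasta_path}")
    return ReferenceDatabase(
        db_id=db_id,
        marker_class=marker_class,
        sequences=sequences,
        policy=policy,
        masked=list(masked) if masked else [],
    )


def load_masked_bed(path: str | Path, default_reason: str = "ssr") -> list[MaskedRegion]:
    """Read masked regions from a BED 3+1 file (column 4 = reason)."""
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >=3 BED columns")
            reason = parts[3] if len(parts) > 3 and parts[3] else default_reason
            regions.append(
                MaskedRegion(parts[0], int(parts[1]), int(parts[2]), reason)
            )
    return regions


def write_masked_bed(regions: Iterable[MaskedRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.seq_id}\t{r.start}\t{r.end}\t{r.reason}\n")


def policy_from_config(config: dict | str) -> MatchPolicy:
    """Build a MatchPolicy from a YAML mapping (string or parsed dict)."""
    if isinstance(config, str):
        config = yaml.safe_load(config)
    return MatchPolicy(
        min_identity=float(config["min_identity"]),
        min_overlap=int(config["min_overlap"]),
        max_evalue=float(config.get("max_evalue", 1e-5)),
        max_targets=int(config.get("max_targets", 3)),
        algorithm_hint=config.get("algorithm_hint", "blastn_like"),
        host_exclusion_rank=config.get("host_exclusion_rank"),
    )


# ---------------------------------------------------------------------------
# masked-region utilities


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching half-open intervals. Idempotent."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ivs:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def detect_ssr_regions(
    sequence: str,
    motif_len_range: tuple[int, int] = (1, 6),
    min_total_len: int = 12,
    seq_id: str = "",
) -> list[MaskedRegion]:
    """Find maximal perfect tandem-repeat runs (SSRs) as masked regions.

    A run of motif length m is a maximal interval [i, j) such that
    s[k] == s[k-m] for all k in [i+m, j). Runs shorter than
    max(min_total_len, 2*m) are ignored (at least two full copies), runs
    containing N are ignored, and overlapping runs across motif lengths are
    merged into single intervals.
    """
    lo, hi = motif_len_range
    if lo < 1 or hi > 6 or lo > hi:
        raise ValueError("motif_len_range must be within 1..6")
    n = len(sequence)
    raw: list[tuple[int, int]] = []
    for m in range(lo, hi + 1):
        # positions k with s[k] == s[k-m] extend a period-m run; a maximal
        # stretch of such positions [a, k) is the repeat interval [a-m, k)
        k = m
        while k < n:
            if sequence[k] == sequence[k - m] and sequence[k] != "N":
                a = k
                while k < n and sequence[k] == sequence[k - m] and sequence[k] != "N":
                    k += 1
                if k - (a - m) >= max(min_total_len, 2 * m):
                    raw.append((a - m, k))
            else:
                k += 1
    merged = merge_intervals(raw)
    return [MaskedRegion(seq_id, s, e, "ssr") for s, e in merged]


# ---------------------------------------------------------------------------
# registry validation


def validate_taxonomy(
    databases: Iterable[ReferenceDatabase], taxonomy: Taxonomy
) -> list[str]:
    """Cross-check databases against the taxonomy; report-only.

    Reports unresolvable taxon_ids, rank inconsistencies in the taxonomy
    itself, tags outside the rule vocabulary, and biologically implausible
    tag placements (an aphid-specific symbiont tag on a taxon that is not a
    bacterium/symbiont lineage, e.g. on a Lepidoptera taxon).
    """
    report = list(taxonomy.validate())
    for db in databases:
        for seq_id, _seq, taxon_id in db.sequences:
            if taxon_id not in taxonomy:
                report.append(
                    f"db {db.db_id}: sequence {seq_id!r} has unresolvable "
                    f"taxon_id {taxon_id!r}"
                )
    # tag placement checks
    for rec in taxonomy:
        if "aphid_specific_symbiont" in rec.tags and rec.guild not in (
            "symbiont",
            "other",
        ):
            report.append(
                f"taxon {rec.taxon_id!r}: aphid_specific_symbiont tag on guild "
                f"{rec.guild!r} looks wrong"
            )
        if (
            "aphid_parasitoid" in rec.tags or "coccinellid_parasitoid" in rec.tags
        ) and rec.guild != "parasitoid":
            report.append(
                f"taxon {rec.taxon_id!r}: parasitoid tag on guild {rec.guild!r} "
                f"looks wrong"
            )
    return report


__all__ = [
    "MatchPolicy",
    "MaskedRegion",
    "ReferenceDatabase",
    "load_database",
    "load_metadata_table",
    "load_masked_bed",
    "write_masked_bed",
    "policy_from_config",
    "merge_intervals",
    "detect_ssr_regions",
    "validate_taxonomy",
    "MARKER_CLASSES",
]
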