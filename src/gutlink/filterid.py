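"""Foreign-read identification: threshold filtering, exclusions, LCA, tallies.

This is the heart of the analysis. Alignment hits from one database pass
through, in order:

1. ``filter_hits`` — keep hits with alignment overlap >= the database's
   minimum (default 225 columns) and percent identity >= its threshold
   (95 % bacterial genomes, 98 % insect mitogenomes, 99 % elsewhere); both
   bounds inclusive.
2. ``exclude_masked`` — discard hits whose subject interval overlaps a
   masked region (mitochondrial control region, SSRs, shared markers) by at
   least one base.
3. ``exclude_host_lineage`` — for databases whose marker cannot separate the
   focal predator from its close relatives (rRNA), discard hits to taxa
   sharing an ancestor with the focal predator at or below a configured rank
   (default tribe).
4. ``separate_host`` — partition reads into host (focal predator or its
   descendants) and foreign, resolving mixed reads by best raw score with
   ties going conservatively to host.
5. ``assign_taxon`` — assign each surviving foreign read to the lowest
   common ancestor of its near-best hits: the lowest taxonomic level that
   can be reliably identified.
6. ``tally_detections`` — aggregate per-taxon read counts per database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .match import AlignmentHit
from .refdb import MaskedRegion, MatchPolicy, ReferenceDatabase
from .taxonomy import RANK_INDEX, Taxonomy


@dataclass
class TaxonDetection:
    """A per-predator, per-database detection: taxon, rank, read tally."""

    predator_id: str
    db_id: str
    taxon_id: str
    rank: str
    read_ids: frozenset[str]

    @property
    def read_count(self) -> int:
        return len(self.read_ids)

    def __post_init__(self):
        self.read_ids = frozenset(self.read_ids)
        if not self.read_ids:
            raise ValueError("a detection requires at least one read")


@dataclass
class ExcludedHit:
    hit: AlignmentHit
    reason: str


# ---------------------------------------------------------------------------
# 1. thresholds


def filter_hits(hits: Sequence[AlignmentHit], policy: MatchPolicy) -> list[AlignmentHit]:
    """Keep hits meeting the overlap and identity thresholds (inclusive).

    Overlap is measured as alignment_length (columns including gaps, the
    BLAST outfmt-6 ``length`` field), not read span. Order is preserved.
    """
    return [
        h
        for h in hits
        if h.alignment_length >= policy.min_overlap
        and h.percent_identity >= policy.min_identity
    ]


# ---------------------------------------------------------------------------
# 2. masked regions


def _overlaps(a0: int, a1: int, b0: int, b1: int, min_bp: int) -> bool:
    return min(a1, b1) - max(a0, b0) >= min_bp


def exclude_masked(
    hits: Sequence[AlignmentHit],
    masked_regions: Iterable[MaskedRegion],
    min_overlap_bp: int = 1,
) -> tuple[list[AlignmentHit], list[ExcludedHit]]:
    """Discard hits whose subject interval overlaps any masked interval.

    Any overlap (>= 1 bp by default) triggers the discard; the minimum
    overlap with the mask is configurable. Returns (kept, excluded-with-
    reason).
    """
    by_seq: dict[str, list[MaskedRegion]] = {}
    for region in masked_regions:
        by_seq.setdefault(region.seq_id, []).append(region)
    kept: list[AlignmentHit] = []
    excluded: list[ExcludedHit] = []
    for h in hits:
        reason = None
        for region in by_seq.get(h.seq_id, ()):
            if _overlaps(
                h.subject_start, h.subject_end, region.start, region.end, min_overlap_bp
            ):
                reason = f"masked:{region.reason}"
                break
        if reason is None:
            kept.append(h)
        else:
            excluded.append(ExcludedHit(h, reason))
    return kept, excluded


# ---------------------------------------------------------------------------
# 3. host-lineage exclusion


def exclude_host_lineage(
    hits: Sequence[AlignmentHit],
    taxonomy: Taxonomy,
    focal_predator: str,
    host_exclusion_rank: str,
) -> tuple[list[ExcludedHit], list[AlignmentHit]]:
    """Move hits whose taxon is too close to the focal predator to excluded.

    A hit is non-diagnostic when its subject taxon shares an ancestor with
    the focal predator at or below ``host_exclusion_rank`` — such markers
    (e.g. rRNA within the predator's tribe) cannot distinguish prey from
    predator. Returns (excluded, kept).
    """
    if host_exclusion_rank not in RANK_INDEX:
        raise ValueError(f"unknown rank {host_exclusion_rank!r}")
    excluded: list[ExcludedHit] = []
    kept: list[AlignmentHit] = []
    for h in hits:
        if h.taxon_id is not None and taxonomy.shares_ancestor_at_or_below(
            h.taxon_id, focal_predator, host_exclusion_rank
        ):
            excluded.append(ExcludedHit(h, f"host_lineage:{host_exclusion_rank}"))
        else:
            kept.append(h)
    return excluded, kept


# ---------------------------------------------------------------------------
# 4. host / foreign separation


def separate_host(
    hits: Sequence[AlignmentHit],
    taxonomy: Taxonomy,
    focal_predator: str,
) -> tuple[list[AlignmentHit], list[AlignmentHit]]:
    """Partition hits by read into host and foreign sets.

    A hit is host-like when its subject taxon equals, or descends from, the
    focal predator's taxon. A read carrying both host-like and foreign hits
    is resolved by the best raw score; ties go to host (conservative: never
    claim prey on an ambiguous read). The partition is exhaustive and
    disjoint by read.
    """
    by_read: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_read.setdefault(h.read_id, []).append(h)
    host_hits: list[AlignmentHit] = []
    foreign_hits: list[AlignmentHit] = []
    for read_id, read_hits in by_read.items():
        is_host_hit = [
            h.taxon_id is not None
            and taxonomy.is_descendant(h.taxon_id, focal_predator)
            for h in read_hits
        ]
        if all(is_host_hit):
            host_hits.extend(read_hits)
        elif not any(is_host_hit):
            foreign_hits.extend(read_hits)
        else:
            best_host = max(
                h.raw_score for h, is_h in zip(read_hits, is_host_hit) if is_h
            )
            best_foreign = max(
                h.raw_score for h, is_h in zip(read_hits, is_host_hit) if not is_h
            )
            if best_host >= best_foreign:  # tie -> host
                host_hits.extend(read_hits)
            else:
                foreign_hits.extend(read_hits)
    return host_hits, foreign_hits


# ---------------------------------------------------------------------------
# 5. LCA assignment


def assign_taxon(
    hits: Sequence[AlignmentHit],
    taxonomy: Taxonomy,
    score_tolerance: float = 0.98,
) -> tuple[str, str]:
    """Assign one read to the lowest reliably identifiable taxon.

    All hits within ``score_tolerance`` of the best raw score (raw_score >=
    tolerance * best) are considered equally good matches — reads landing in
    regions identical across closely related species produce several such
    hits — and the read is assigned to their lowest common ancestor.
    Returns (taxon_id, rank).
    """
    if not hits:
        raise ValueError("assign_taxon requires at least one hit")
    best = max(h.raw_score for h in hits)
    near = [h.taxon_id for h in hits if h.raw_score >= score_tolerance * best]
    lca = taxonomy.lca(near)
    return lca, taxonomy.rank(lca)


# ---------------------------------------------------------------------------
# 6. tallies


def tally_detections(
    assignments: Sequence[tuple[str, str, str]],
    predator_id: str,
) -> list[TaxonDetection]:
    """Aggregate (read_id, db_id, taxon_id) assignments into detections.

    Assignments must be deduplicated per (read_id, db_id). Output is sorted
    by db_id then descending read count (ties by taxon_id).
    """
    seen: set[tuple[str, str]] = set()
    groups: dict[tuple[str, str], set[str]] = {}
    ranks: dict[str, str] = {}
    for read_id, db_id, taxon_id in assignments:
        key = (read_id, db_id)
        if key in seen:
            raise ValueError(
                f"read {read_id!r} assigned more than once in db {db_id!r}"
            )
        seen.add(key)
        groups.setdefault((db_id, taxon_id), set()).add(read_id)
    detections = [
        TaxonDetection(
            predator_id=predator_id,
            db_id=db_id,
            taxon_id=taxon_id,
            rank="",  # filled below if taxonomy-aware caller wants it
            read_ids=frozenset(read_ids),
        )
        for (db_id, taxon_id), read_ids in groups.items()
    ]
    detections.sort(key=lambda d: (d.db_id, -d.read_count, d.taxon_id))
    return detections


# ---------------------------------------------------------------------------
# database-level driver


@dataclass
class IdentificationResult:
    """Bookkeeping for one database of one predator library."""

    predator_id: str
    db_id: str
    detections: list[TaxonDetection]
    host_read_ids: set[str]
    foreign_read_ids: set[str]
    excluded: list[ExcludedHit] = field(default_factory=list)


def identify_database_hits(
    hits: Sequence[AlignmentHit],
    db: ReferenceDatabase,
    taxonomy: Taxonomy,
    focal_predator: str,
    predator_id: Optional[str] = None,
    score_tolerance: float = 0.98,
    policy: Optional[MatchPolicy] = None,
) -> IdentificationResult:
    """Run the full per-database identification chain on raw hits."""
    predator_id = predator_id or focal_predator
    policy = policy or db.policy
    surviving = filter_hits(hits, policy)
    surviving, masked_out = exclude_masked(surviving, db.masked)
    excluded = list(masked_out)
    if policy.host_exclusion_rank is not None:
        lineage_out, surviving = exclude_host_lineage(
            surviving, taxonomy, focal_predator, policy.host_exclusion_rank
        )
        excluded.extend(lineage_out)
    host_hits, foreign_hits = separate_host(surviving, taxonomy, focal_predator)
    by_read: dict[str, list[AlignmentHit]] = {}
    for h in foreign_hits:
        by_read.setdefault(h.read_id, []).append(h)
    assignments = []
    ranks: dict[str, str] = {}
    for read_id, read_hits in by_read.items():
        taxon_id, rank = assign_taxon(read_hits, taxonomy, score_tolerance)
        assignments.append((read_id, db.db_id, taxon_id))
        ranks[taxon_id] = rank
    detections = tally_detections(assignments, predator_id)
    for det in detections:
        det.rank = ranks[det.taxon_id]
    return IdentificationResult(
        predator_id=predator_id,
        db_id=db.db_id,
        detections=detections,
        host_read_ids={h.read_id for h in host_hits},
        foreign_read_ids=set(by_read),
        excluded=excluded,
    )


def write_excluded(excluded: Iterable[ExcludedHit], path) -> None:
    """Excluded-hits TSV with reason codes, for audit."""
    with open(path, "w") as fh:
        fh.write(
            "#read_id\tdb_id\tseq_id\ttaxon_id\tpercent_identity\t"
            "alignment_length\treason\n"
        )
        for e in excluded:
            h = e.hit
            fh.write(
                f"{h.read_id}\t{h.db_id}\t{h.seq_id}\t{h.taxon_id or '-'}\t"
                f"{h.percent_identity:.3f}\t{h.alignment_length}\t{e.reason}\n"
            )


def write_detections(detections: Iterable[TaxonDetection], path) -> None:
    with open(path, "w") as fh:
        fh.write("#predator_id\tdb_id\ttaxon_id\trank\tread_count\n")
        for d in detections:
            fh.write(
                f"{d.predator_id}\t{d.db_id}\t{d.taxon_id}\t{d.rank}\t{d.read_count}\n"
            )


__all__ = [
    "TaxonDetection",
    "ExcludedHit",
    "IdentificationResult",
    "filter_hits",
    "exclude_masked",
    "exclude_host_lineage",
    "separate_host",
    "assign_taxon",
    "tally_detections",
    "identify_database_hits",
    "write_detections",
    "write_excluded",
]
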