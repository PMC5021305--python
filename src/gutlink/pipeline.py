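"""End-to-end pipeline: simulate/QC/match/identify one library, evaluate.

Ties the stages together for whole-library runs: quality control, matching
against every reference database, per-database identification, read-level
bookkeeping (host / foreign / excluded / unmatched always sum to the QC'd
total), truth-based precision and recall for simulated libraries, and the
identity-threshold sensitivity sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .filterid import (
    IdentificationResult,
    TaxonDetection,
    filter_hits,
    identify_database_hits,
)
from .match import AlignmentHit, ScreenBank, align_reads, build_seed_index
from .profiles import ReferenceSuite, scenario_for_predator
from .readqc import Read, quality_filter
from .refdb import MatchPolicy
from .synthetic import CommunityScenario, simulate_gut_reads
from .taxonomy import Taxonomy


@dataclass
class ReadAccounting:
    """Disjoint classification of every QC-passing read."""

    total_qc: int
    host: int
    foreign: int
    excluded: int
    unmatched: int

    def conserved(self) -> bool:
        return self.total_qc == self.host + self.foreign + self.excluded + self.unmatched


@dataclass
class LibraryResult:
    library_id: str
    focal_predator: str
    n_reads: int
    n_qc: int
    detections: list[TaxonDetection]
    per_db: dict[str, IdentificationResult]
    hits_by_db: dict[str, list[AlignmentHit]]
    accounting: ReadAccounting
    truth: Optional[pd.DataFrame] = None
    qc_read_ids: set[str] = field(default_factory=set)


def identify_library(
    reads: Sequence[Read],
    suite: ReferenceSuite,
    focal_predator: str,
    library_id: str = "lib",
    predator_id: Optional[str] = None,
    min_mean_phred: float = 20.0,
    truth: Optional[pd.DataFrame] = None,
) -> LibraryResult:
    """Run QC, matching and identification for one library of reads."""
    predator_id = predator_id or focal_predator
    qc_reads = quality_filter(reads, min_mean_phred)
    qc_ids = {r.read_id for r in qc_reads}

    hits_by_db: dict[str, list[AlignmentHit]] = {}
    per_db: dict[str, IdentificationResult] = {}
    detections: list[TaxonDetection] = []
    host_ids: set[str] = set()
    foreign_ids: set[str] = set()
    excluded_ids: set[str] = set()
    bank = getattr(suite, "_screen_bank", None)
    if bank is None:
        bank = ScreenBank([build_seed_index(db) for db in suite.databases.values()])
        suite._screen_bank = bank
    candidates = bank.candidates(qc_reads)
    for db_id, db in suite.databases.items():
        hits = align_reads(qc_reads, db, candidate_indices=candidates[db_id])
        hits_by_db[db_id] = hits
        result = identify_database_hits(
            hits, db, suite.taxonomy, focal_predator, predator_id=predator_id
        )
        per_db[db_id] = result
        detections.extend(result.detections)
        host_ids |= result.host_read_ids
        foreign_ids |= result.foreign_read_ids
        excluded_ids |= {e.hit.read_id for e in result.excluded}
    # disjoint classification with priority host > foreign > excluded
    foreign_only = foreign_ids - host_ids
    excluded_only = excluded_ids - host_ids - foreign_ids
    n_host = len(host_ids)
    n_foreign = len(foreign_only)
    n_excluded = len(excluded_only)
    accounting = ReadAccounting(
        total_qc=len(qc_reads),
        host=n_host,
        foreign=n_foreign,
        excluded=n_excluded,
        unmatched=len(qc_reads) - n_host - n_foreign - n_excluded,
    )
    return LibraryResult(
        library_id=library_id,
        focal_predator=focal_predator,
        n_reads=len(reads),
        n_qc=len(qc_reads),
        detections=detections,
        per_db=per_db,
        hits_by_db=hits_by_db,
        accounting=accounting,
        truth=truth,
        qc_read_ids=qc_ids,
    )


def run_scenario(
    scenario: CommunityScenario,
    suite: ReferenceSuite,
    predator_id: Optional[str] = None,
) -> LibraryResult:
    """Simulate a scenario against the suite's references and identify it."""
    reads, truth = simulate_gut_reads(scenario, suite.genomes)
    return identify_library(
        reads,
        suite,
        focal_predator=scenario.focal_predator,
        library_id=scenario.library_id,
        predator_id=predator_id or scenario.focal_predator,
        truth=truth,
    )


def run_survey_library(
    predator_name: str,
    suite: ReferenceSuite,
    n_reads: Optional[int] = None,
    seed: int = 0,
) -> LibraryResult:
    scenario = scenario_for_predator(predator_name, n_reads=n_reads, seed=seed)
    return run_scenario(scenario, suite, predator_id=predator_name)


# ---------------------------------------------------------------------------
# truth-based evaluation


@dataclass
class Evaluation:
    """Species/genus-level detection performance against simulation truth.

    A *specific* detection (rank species or genus) is a true positive when
    some true foreign source taxon of the library equals or descends from
    the detected taxon. Recall is measured over *recoverable* taxa: foreign
    members whose own genome is a reference in a database and that have at
    least ``min_reads`` truth reads surviving QC, the overlap gate and the
    masked regions.
    """

    true_positives: int
    false_positives: int
    recoverable: set[str]
    detected_recoverable: set[str]
    false_positive_taxa: list[str]

    @property
    def precision(self) -> float:
        n = self.true_positives + self.false_positives
        return self.true_positives / n if n else 1.0

    @property
    def recall(self) -> float:
        if not self.recoverable:
            return 1.0
        return len(self.detected_recoverable) / len(self.recoverable)


def evaluate_library(
    result: LibraryResult,
    suite: ReferenceSuite,
    min_reads: int = 5,
    min_overlap: int = 225,
) -> Evaluation:
    """Score a simulated library's detections against its truth table."""
    if result.truth is None:
        raise ValueError("library has no truth table")
    truth = result.truth
    taxonomy = suite.taxonomy
    foreign = truth[~truth.is_host.astype(bool)]
    truth_taxa = set(foreign.taxon_id.unique())

    tp = 0
    fp = 0
    fp_taxa = []
    for det in result.detections:
        if det.rank not in ("species", "genus"):
            continue
        if any(taxonomy.is_descendant(t, det.taxon_id) for t in truth_taxa):
            tp += 1
        else:
            fp += 1
            fp_taxa.append(det.taxon_id)

    # recoverable taxa: enough clean, long-enough, unmasked truth reads
    recoverable: set[str] = set()
    masks_by_db = {
        db_id: db.masked_by_seq() for db_id, db in suite.databases.items()
    }
    for seq_key, group in foreign.groupby("seq_id"):
        home = suite.home_refs.get(seq_key)
        if home is None:
            continue
        db_id, seq_id = home
        masks = masks_by_db[db_id].get(seq_id, [])
        ok = group[
            group.read_id.isin(result.qc_read_ids)
            & ((group.end - group.start) >= min_overlap)
        ]
        if masks:
            keep = pd.Series(True, index=ok.index)
            for m in masks:
                keep &= (ok.end <= m.start) | (ok.start >= m.end)
            ok = ok[keep]
        if len(ok) >= min_reads:
            recoverable.update(ok.taxon_id.unique())

    detected_specific = {
        det.taxon_id
        for det in result.detections
        if det.rank in ("species", "genus")
    }
    detected_recoverable = {
        t
        for t in recoverable
        if any(taxonomy.is_descendant(t, d) for d in detected_specific)
    }
    return Evaluation(
        true_positives=tp,
        false_positives=fp,
        recoverable=recoverable,
        detected_recoverable=detected_recoverable,
        false_positive_taxa=fp_taxa,
    )


# ---------------------------------------------------------------------------
# identity-threshold sensitivity sweep


def sweep_identity(
    result: LibraryResult,
    suite: ReferenceSuite,
    db_id: str = "insect_mitogenome",
    identities: Sequence[float] = (90.0, 98.0),
) -> dict[float, dict[str, int]]:
    """Re-filter one database's hits at alternative identity thresholds.

    Reports surviving foreign read and taxon counts per threshold. Looser
    thresholds admit spurious cross-species matches, so counts are
    monotonically non-increasing in the threshold.
    """
    db = suite.databases[db_id]
    out: dict[float, dict[str, int]] = {}
    for ident in identities:
        policy = MatchPolicy(
            min_identity=ident,
            min_overlap=db.policy.min_overlap,
            max_evalue=db.policy.max_evalue,
            max_targets=db.policy.max_targets,
            algorithm_hint=db.policy.algorithm_hint,
            host_exclusion_rank=db.policy.host_exclusion_rank,
        )
        res = identify_database_hits(
            result.hits_by_db[db_id],
            db,
            suite.taxonomy,
            result.focal_predator,
            predator_id=result.library_id,
            policy=policy,
        )
        out[ident] = {
            "foreign_reads": sum(d.read_count for d in res.detections),
            "foreign_taxa": len(res.detections),
        }
    return out


__all__ = [
    "ReadAccounting",
    "LibraryResult",
    "Evaluation",
    "identify_library",
    "run_scenario",
    "run_survey_library",
    "evaluate_library",
    "sweep_identity",
]
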