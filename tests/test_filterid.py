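import numpy as np
import pytest

from gutlink.filterid import (
    assign_taxon,
    exclude_host_lineage,
    exclude_masked,
    filter_hits,
    separate_host,
    tally_detections,
)
from gutlink.match import AlignmentHit
from gutlink.refdb import MaskedRegion, MatchPolicy

from ._oracles import brute_overlaps


def _hit(
    read_id="r1",
    seq_id="s1",
    taxon_id="speciesA",
    identity=99.0,
    length=250,
    s0=0,
    s1=250,
    score=240.0,
    db_id="mito",
):
    return AlignmentHit(
        read_id=read_id,
        db_id=db_id,
        seq_id=seq_id,
        taxon_id=taxon_id,
        percent_identity=identity,
        alignment_length=length,
        read_start=0,
        read_end=250,
        subject_start=s0,
        subject_end=s1,
        strand="+",
        raw_score=score,
        evalue=1e-50,
    )


MITO_POLICY = MatchPolicy(min_identity=98, min_overlap=225)
BACT_POLICY = MatchPolicy(min_identity=95, min_overlap=225)


# ---------------------------------------------------------------------------
# threshold filtering


def test_identity_just_below_mitogenome_threshold_discarded():
    assert filter_hits([_hit(identity=97.9, length=250)], MITO_POLICY) == []


def test_inclusive_bounds_on_both_thresholds():
    boundary = _hit(identity=95.0, length=225)
    assert filter_hits([boundary], BACT_POLICY) == [boundary]
    assert filter_hits([_hit(identity=95.0, length=224)], BACT_POLICY) == []


def test_filter_matches_brute_force_two_predicate_scan(rng):
    hits = [
        _hit(
            read_id=f"r{i}",
            identity=float(rng.uniform(80, 100)),
            length=int(rng.integers(100, 300)),
        )
        for i in range(1_000)
    ]
    survivors = filter_hits(hits, MITO_POLICY)
    expected = [
        h for h in hits
        if h.alignment_length >= 225 and h.percent_identity >= 98
    ]
    assert survivors == expected


def test_threshold_monotonicity(rng):
    """Raising identity or overlap thresholds never adds survivors."""
    hits = [
        _hit(
            read_id=f"r{i}",
            taxon_id=f"t{int(rng.integers(0, 8))}",
            identity=float(rng.uniform(85, 100)),
            length=int(rng.integers(150, 300)),
        )
        for i in range(500)
    ]
    prev_reads = prev_taxa = None
    for ident in (90, 95, 98, 99):
        surv = filter_hits(hits, MatchPolicy(ident, 225))
        n_reads = len({h.read_id for h in surv})
        n_taxa = len({h.taxon_id for h in surv})
        if prev_reads is not None:
            assert n_reads <= prev_reads
            assert n_taxa <= prev_taxa
        prev_reads, prev_taxa = n_reads, n_taxa
    prev = None
    for overlap in (150, 200, 225, 250):
        surv = filter_hits(hits, MatchPolicy(98, overlap))
        if prev is not None:
            assert len(surv) <= prev
        prev = len(surv)


# ---------------------------------------------------------------------------
# masked-region exclusion


def test_hit_overlapping_control_region_discarded():
    masks = [MaskedRegion("s1", 500, 1_500, "control_region")]
    kept, excluded = exclude_masked([_hit(s0=380, s1=600)], masks)
    assert kept == []
    assert excluded[0].reason == "masked:control_region"


def test_hit_on_unmasked_subject_kept():
    masks = [MaskedRegion("other", 0, 1_000, "ssr")]
    h = _hit(s0=0, s1=250)
    kept, excluded = exclude_masked([h], masks)
    assert kept == [h] and excluded == []


def test_touching_interval_is_not_overlap():
    masks = [MaskedRegion("s1", 250, 500, "ssr")]
    h = _hit(s0=0, s1=250)  # half-open: ends exactly where the mask begins
    kept, _ = exclude_masked([h], masks)
    assert kept == [h]


def test_masked_exclusion_matches_brute_force(rng):
    masks = [
        MaskedRegion("s1", int(a), int(a) + int(b), "ssr")
        for a, b in zip(rng.integers(0, 5_000, 40), rng.integers(1, 400, 40))
    ]
    mask_ivs = [(m.start, m.end) for m in masks]
    hits = []
    for i in range(500):
        a = int(rng.integers(0, 5_000))
        hits.append(_hit(read_id=f"r{i}", s0=a, s1=a + int(rng.integers(50, 400))))
    kept, excluded = exclude_masked(hits, masks)
    for h in hits:
        expect_excluded = brute_overlaps((h.subject_start, h.subject_end), mask_ivs)
        assert (h in kept) is (not expect_excluded)
    assert len(kept) + len(excluded) == len(hits)


# ---------------------------------------------------------------------------
# host-lineage exclusion


def test_rrna_hit_within_focal_tribe_excluded(taxonomy):
    h = _hit(taxon_id="Coleomegilla maculata", db_id="rrna")
    excluded, kept = exclude_host_lineage(
        [h], taxonomy, "Harmonia axyridis", "tribe"
    )
    assert kept == [] and excluded[0].hit is h


def test_distant_rrna_hit_kept(taxonomy):
    h = _hit(taxon_id="Ascomycota", db_id="rrna")
    excluded, kept = exclude_host_lineage(
        [h], taxonomy, "Harmonia axyridis", "tribe"
    )
    assert kept == [h] and excluded == []


def test_exclusion_monotonic_in_rank(taxonomy):
    """A rank above the pair's common ancestor excludes; below keeps."""
    h = _hit(taxon_id="Coccinella septempunctata")
    for rank, expect_excluded in [
        ("species", False),  # common ancestor is the tribe, above species
        ("genus", False),
        ("tribe", True),
        ("family", True),
        ("order", True),
    ]:
        excluded, kept = exclude_host_lineage(
            [h], taxonomy, "Harmonia axyridis", rank
        )
        assert bool(excluded) is expect_excluded


def test_unknown_rank_label_is_hard_error(taxonomy):
    with pytest.raises(ValueError):
        exclude_host_lineage([], taxonomy, "Harmonia axyridis", "cohort")


# ---------------------------------------------------------------------------
# host separation


def test_read_hitting_only_focal_mitogenome_is_host(taxonomy):
    host, foreign = separate_host(
        [_hit(taxon_id="Harmonia axyridis")], taxonomy, "Harmonia axyridis"
    )
    assert len(host) == 1 and foreign == []


def test_read_hitting_only_prey_is_foreign(taxonomy):
    host, foreign = separate_host(
        [_hit(taxon_id="Plutella xylostella")], taxonomy, "Doru luteipes"
    )
    assert host == [] and len(foreign) == 1


def test_equal_score_host_and_foreign_resolves_to_host(taxonomy):
    hits = [
        _hit(read_id="r", taxon_id="Harmonia axyridis", score=240.0),
        _hit(read_id="r", taxon_id="Doru luteipes", score=240.0),
    ]
    host, foreign = separate_host(hits, taxonomy, "Harmonia axyridis")
    assert len(host) == 2 and foreign == []


def test_better_foreign_score_wins(taxonomy):
    hits = [
        _hit(read_id="r", taxon_id="Harmonia axyridis", score=200.0),
        _hit(read_id="r", taxon_id="Doru luteipes", score=240.0),
    ]
    host, foreign = separate_host(hits, taxonomy, "Harmonia axyridis")
    assert host == [] and len(foreign) == 2


# ---------------------------------------------------------------------------
# LCA assignment


def test_single_best_hit_assigns_species(taxonomy):
    hits = [
        _hit(taxon_id="Aphis gossypii", score=245.0),
        _hit(taxon_id="Myzus persicae", score=200.0),  # far outside tolerance
    ]
    assert assign_taxon(hits, taxonomy) == ("Aphis gossypii", "species")


def test_equal_chalcid_hits_assign_superfamily(taxonomy):
    hits = [
        _hit(taxon_id="Pteromalus puparum", score=240.0),
        _hit(taxon_id="Aphelinus abdominalis", score=240.0),
    ]
    assert assign_taxon(hits, taxonomy) == ("Chalcidoidea", "superfamily")


def test_same_taxon_twice_is_idempotent(taxonomy):
    hits = [
        _hit(taxon_id="Aphis gossypii", score=240.0),
        _hit(taxon_id="Aphis gossypii", score=238.0),
    ]
    assert assign_taxon(hits, taxonomy) == ("Aphis gossypii", "species")


def test_runner_up_within_tolerance_broadens_assignment(taxonomy):
    hits = [
        _hit(taxon_id="Aphis gossypii", score=240.0),
        _hit(taxon_id="Aphis craccivora", score=236.0),  # within 2 %
    ]
    assert assign_taxon(hits, taxonomy) == ("Aphis", "genus")


def test_assign_requires_hits(taxonomy):
    with pytest.raises(ValueError):
        assign_taxon([], taxonomy)


# ---------------------------------------------------------------------------
# tallies


def test_tally_groups_counts_and_orders():
    assignments = (
        [(f"r{i}", "mito", "Doru luteipes") for i in range(7)]
        + [(f"q{i}", "mito", "Plutella xylostella") for i in range(3)]
        + [("z0", "cox1", "Plutella xylostella")]
    )
    dets = tally_detections(assignments, "pred")
    assert [(d.db_id, d.taxon_id, d.read_count) for d in dets] == [
        ("cox1", "Plutella xylostella", 1),
        ("mito", "Doru luteipes", 7),
        ("mito", "Plutella xylostella", 3),
    ]
    assert all(d.read_count == len(d.read_ids) for d in dets)


def test_tally_empty_assignments():
    assert tally_detections([], "pred") == []


def test_tally_rejects_duplicate_read_in_one_database():
    with pytest.raises(ValueError):
        tally_detections([("r1", "mito", "a"), ("r1", "mito", "b")], "pred")


def test_excluded_hits_tsv_has_reason_codes(tmp_path):
    from gutlink.filterid import ExcludedHit, write_excluded

    excluded = [ExcludedHit(_hit(), "masked:control_region")]
    path = tmp_path / "excluded.tsv"
    write_excluded(excluded, path)
    assert "masked:control_region" in path.read_text()
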