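import math

import numpy as np
import pytest
from scipy.optimize import bisect

from gutlink.match import (
    align_reads,
    build_seed_index,
    estimate_evalue,
    export_blast_tabular,
    import_blast_tabular,
)
from gutlink.refdb import MatchPolicy, ReferenceDatabase
from gutlink.synthetic import mutate_sequence, random_sequence

from ._oracles import mutate_with_rate, sw_score_full


def _db(seqs, min_identity=98, min_overlap=225, max_evalue=1e-5, max_targets=3):
    return ReferenceDatabase(
        "db",
        "insect_mitogenome",
        seqs,
        MatchPolicy(min_identity, min_overlap, max_evalue, max_targets),
    )


# ---------------------------------------------------------------------------
# seed index


def test_seed_count_on_short_sequence():
    db = _db([("x", "ACGTACGTACGTACGTACGT", "t")])  # 20 bp
    index = build_seed_index(db, k=12)
    assert index.n_forward_seeds == 9  # 20 - 12 + 1


def test_all_n_sequence_yields_no_seeds():
    db = _db([("x", "N" * 50, "t")])
    assert build_seed_index(db, k=12).n_forward_seeds == 0


def test_lookup_agrees_with_brute_scan(rng):
    seq = random_sequence(500, rng)
    db = _db([("x", seq, "t")])
    index = build_seed_index(db, k=12)
    kmer = seq[100:112]
    expected_fwd = [i for i in range(489) if seq[i : i + 12] == kmer]
    postings = index.lookup(kmer)
    fwd = [(p, s) for _sid, p, s in postings if s == "+"]
    assert sorted(p for p, _ in fwd) == expected_fwd
    # a k-mer occurring exactly once yields exactly one posting
    unique = [
        seq[i : i + 12]
        for i in range(489)
        if sum(seq[j : j + 12] == seq[i : i + 12] for j in range(489)) == 1
    ]
    if unique:
        hits = [h for h in index.lookup(unique[0]) if h[2] == "+"]
        assert len(hits) == 1


def test_lookup_reports_reverse_strand():
    seq = random_sequence(300, np.random.default_rng(3))
    db = _db([("x", seq, "t")])
    index = build_seed_index(db, k=12)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc_kmer = "".join(comp[c] for c in reversed(seq[50:62]))
    assert ("x", 50, "-") in index.lookup(rc_kmer)


def test_k_out_of_range_rejected():
    db = _db([("x", "ACGT" * 100, "t")])
    with pytest.raises(ValueError):
        build_seed_index(db, k=7)


# ---------------------------------------------------------------------------
# alignment


def test_verbatim_read_aligns_perfectly(rng):
    sub = random_sequence(3_000, rng)
    db = _db([("s1", sub, "t1")])
    hits = align_reads([("r", sub[500:750])], db)
    assert len(hits) == 1
    h = hits[0]
    assert h.percent_identity == 100.0
    assert h.alignment_length == 250
    assert (h.subject_start, h.subject_end) == (500, 750)
    assert h.strand == "+"


def test_five_substitutions_give_expected_identity_and_score(rng):
    sub = random_sequence(3_000, rng)
    db = _db([("s1", sub, "t1")])
    read = list(sub[1000:1250])
    for p in (10, 60, 110, 160, 210):
        read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
    read = "".join(read)
    h = align_reads([("r", read)], db)[0]
    assert h.percent_identity == pytest.approx(98.0)
    # +1 per match, -2 per mismatch: 245 - 10 = 235
    assert h.raw_score == 235
    assert h.raw_score == sw_score_full(read, sub)


def test_matching_stage_reports_below_threshold_hits(rng):
    """Identity filtering belongs downstream; a 10 %-divergent read is
    still reported here as long as its E-value passes."""
    sub = random_sequence(5_000, rng)
    db = _db([("s1", sub, "t1")], min_identity=98)
    read = mutate_sequence(sub[1000:1250], 0.10, rng)
    hits = align_reads([("r", read)], db)
    assert len(hits) == 1
    assert hits[0].percent_identity < 98


def test_strand_symmetry(rng):
    sub = random_sequence(3_000, rng)
    db = _db([("s1", sub, "t1")])
    read = mutate_sequence(sub[700:950], 0.02, rng)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[c] for c in reversed(read))
    h_fwd = align_reads([("f", read)], db)[0]
    h_rev = align_reads([("r", rc)], db)[0]
    assert h_fwd.raw_score == h_rev.raw_score
    assert h_fwd.percent_identity == h_rev.percent_identity
    assert (h_fwd.subject_start, h_fwd.subject_end) == (
        h_rev.subject_start, h_rev.subject_end,
    )
    assert {h_fwd.strand, h_rev.strand} == {"+", "-"}


def test_max_targets_and_tie_breaking(rng):
    base = random_sequence(2_000, rng)
    seqs = [(f"s{i}", base, f"t{i}") for i in range(5)]  # five identical refs
    db = _db(seqs, max_targets=3)
    hits = align_reads([("r", base[200:450])], db)
    assert len(hits) == 3
    # equal score and identity: lexicographic subject order
    assert [h.seq_id for h in hits] == ["s0", "s1", "s2"]


def test_no_seeds_no_hits(rng):
    db = _db([("s1", random_sequence(2_000, rng), "t1")])
    hits = align_reads([("r", random_sequence(250, np.random.default_rng(99)))], db)
    assert hits == []


def test_seed_and_extend_matches_dp_oracle(rng):
    """Raw scores equal the full-DP optimum for low-divergence reads."""
    agree = total = 0
    for trial in range(40):
        sub = random_sequence(int(rng.integers(2_000, 8_000)), rng)
        db = _db([("s1", sub, "t1")])
        start = int(rng.integers(0, len(sub) - 250))
        read = mutate_with_rate(sub[start : start + 250], 0.05, rng)
        hits = align_reads([("r", read)], db)
        total += 1
        if hits and hits[0].raw_score == sw_score_full(read, sub):
            agree += 1
    assert agree / total >= 0.99


# ---------------------------------------------------------------------------
# E-values


def test_evalue_formula_limits():
    assert estimate_evalue(0, 250, 1_000) == pytest.approx(0.1 * 250 * 1_000)
    e1 = estimate_evalue(100, 250, 10_000)
    e2 = estimate_evalue(100, 250, 20_000)
    assert e2 == pytest.approx(2 * e1)


def test_lambda_matches_bisection_oracle():
    def f(lam):
        return 0.25 * math.exp(lam) + 0.75 * math.exp(-2 * lam) - 1.0

    lam_oracle = bisect(f, 1e-9, 5.0, xtol=1e-12)
    e = estimate_evalue(10, 100, 100)
    lam_used = -math.log(e / (0.1 * 100 * 100)) / 10
    assert lam_used == pytest.approx(lam_oracle, abs=1e-6)


def test_non_negative_expected_score_has_no_lambda():
    with pytest.raises(ValueError):
        estimate_evalue(10, 100, 100, match=1, mismatch=0)


# ---------------------------------------------------------------------------
# outfmt 6 interoperability


def test_import_reverse_strand_coordinates(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text("read1\tsubj1\t98.222\t250\t4\t0\t1\t250\t100\t1\t1e-50\t400\n")
    hits = import_blast_tabular(path, "mito")
    assert len(hits) == 1
    h = hits[0]
    assert h.strand == "-"
    assert (h.subject_start, h.subject_end) == (0, 100)
    assert (h.read_start, h.read_end) == (0, 250)
    assert h.percent_identity == 98.222  # unrounded pass-through


def test_import_counts_rows_and_flags_bad_lines(tmp_path):
    good = "r{i}\ts\t99.0\t250\t2\t0\t1\t250\t1\t250\t1e-60\t450"
    path = tmp_path / "hits.tsv"
    path.write_text("\n".join(good.format(i=i) for i in range(12)) + "\n")
    assert len(import_blast_tabular(path, "db")) == 12

    bad = tmp_path / "bad.tsv"
    bad.write_text(good.format(i=0) + "\nr1\tonly_three\tcols\n")
    with pytest.raises(ValueError, match=":2"):
        import_blast_tabular(bad, "db")


def test_export_import_round_trip(rng):
    sub = random_sequence(2_000, rng)
    db = _db([("s1", sub, "t1")])
    read = mutate_sequence(sub[300:550], 0.01, rng)
    hits = align_reads([("r", read)], db)
    import tempfile, os

    with tempfile.TemporaryDirectory() as d:
        path = os.path.join(d, "h.tsv")
        export_blast_tabular(hits, path)
        back = import_blast_tabular(path, "db")
    assert len(back) == len(hits)
    for a, b in zip(hits, back):
        assert a.read_id == b.read_id
        assert a.alignment_length == b.alignment_length
        assert (a.subject_start, a.subject_end) == (b.subject_start, b.subject_end)
        assert a.strand == b.strand
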