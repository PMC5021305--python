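import io

import numpy as np
import pytest

from gutlink.profiles import scenario_for_predator
from gutlink.readqc import write_fastq
from gutlink.synthetic import (
    CommunityScenario,
    ErrorProfile,
    FragmentModel,
    Member,
    build_scenario,
    generate_genomes,
    pairwise_divergence,
    simulate_gut_reads,
)


def _two_taxon_scenario(divergence_pct, length=16_000, seed=7):
    members = [
        Member("taxA", "gA", 0.5, genome_length=length),
        Member("taxB", "gB", 0.5, genome_length=length),
    ]
    d = np.array([[0.0, divergence_pct], [divergence_pct, 0.0]])
    return CommunityScenario(
        focal_predator="taxA",
        members=members,
        n_reads=0,
        divergence=d,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# genome generation


def test_zero_divergence_gives_identical_sequences():
    genomes, realized = generate_genomes(_two_taxon_scenario(0.0))
    assert genomes["gA"] == genomes["gB"]
    assert realized[0, 1] == 0.0


def test_two_percent_target_realized_within_half_point():
    genomes, realized = generate_genomes(_two_taxon_scenario(2.0))
    direct = 100 * pairwise_divergence(genomes["gA"], genomes["gB"])
    assert direct == pytest.approx(realized[0, 1])
    assert abs(realized[0, 1] - 2.0) <= 0.5


@pytest.mark.parametrize("target", [5.0, 15.0, 30.0])
def test_larger_targets_still_realized(target):
    _, realized = generate_genomes(_two_taxon_scenario(target))
    assert abs(realized[0, 1] - target) <= 0.5


def test_star_model_with_three_taxa():
    members = [Member(t, t, 1 / 3, genome_length=16_000) for t in "ABC"]
    d = np.array([[0, 4, 6], [4, 0, 6], [6, 6, 0]], dtype=float)
    sc = CommunityScenario("A", members, 0, divergence=d, seed=3)
    _, realized = generate_genomes(sc)
    iu = np.triu_indices(3, 1)
    assert np.all(np.abs(realized[iu] - d[iu]) <= 0.5)


def test_negative_divergence_is_an_error():
    sc = _two_taxon_scenario(2.0)
    sc.divergence[0, 1] = -1.0
    with pytest.raises(ValueError):
        generate_genomes(sc)


def test_genome_generation_deterministic_under_seed():
    g1, _ = generate_genomes(_two_taxon_scenario(2.0, seed=11))
    g2, _ = generate_genomes(_two_taxon_scenario(2.0, seed=11))
    assert g1 == g2


# ---------------------------------------------------------------------------
# read simulation


def _simple_scenario(n_reads, host_mt=0.002, seed=5, foreign=()):
    members = list(foreign)
    return build_scenario(
        "hostX",
        members,
        host_mt_fraction=host_mt,
        n_reads=n_reads,
        host_genome_length=100_000,
        seed=seed,
    )


def _genomes_for(scenario, seed=5):
    rng = np.random.default_rng(seed)
    from gutlink.synthetic import random_sequence

    return {
        m.seq_key: random_sequence(m.genome_length, rng)
        for m in scenario.members
    }


def test_zero_reads_yield_empty_outputs():
    sc = _simple_scenario(0)
    reads, truth = simulate_gut_reads(sc, _genomes_for(sc))
    assert reads == []
    assert truth.empty


def test_host_mt_count_within_binomial_bounds():
    n = 200_000
    p = 0.002
    sc = _simple_scenario(n, host_mt=p)
    reads, truth = simulate_gut_reads(sc, _genomes_for(sc))
    mt = int((truth.seq_id == "hostX|mito").sum())
    sigma = (n * p * (1 - p)) ** 0.5
    assert abs(mt - n * p) <= 3 * sigma


def test_truth_conservation_and_alignment_with_reads():
    foreign = [
        Member("prey1", "prey1|g", 0.01, genome_length=16_000),
        Member(
            "prey2", "prey2|g", 0.01, genome_length=16_000,
            fragment=FragmentModel(mean=120, sd=40, max_len=200),
        ),
    ]
    sc = _simple_scenario(20_000, foreign=foreign)
    reads, truth = simulate_gut_reads(sc, _genomes_for(sc))
    assert len(reads) == 20_000
    assert len(truth) == 20_000
    assert [r.read_id for r in reads] == truth.read_id.tolist()
    by_source = truth.groupby("taxon_id").size()
    assert by_source.sum() == 20_000


def test_degraded_fragments_respect_hard_max():
    foreign = [
        Member(
            "prey", "prey|g", 0.5, genome_length=16_000,
            fragment=FragmentModel(mean=120, sd=40, max_len=200),
        )
    ]
    sc = _simple_scenario(5_000, foreign=foreign)
    reads, truth = simulate_gut_reads(sc, _genomes_for(sc))
    prey_ids = set(truth.read_id[truth.taxon_id == "prey"])
    lengths = [len(r) for r in reads if r.read_id in prey_ids]
    assert lengths and max(lengths) <= 200


def test_fragment_max_above_200_rejected_for_foreign_members():
    foreign = [
        Member(
            "prey", "prey|g", 0.01, genome_length=16_000,
            fragment=FragmentModel(max_len=240),
        )
    ]
    sc = _simple_scenario(100, foreign=foreign)
    with pytest.raises(ValueError, match="hard max"):
        sc.validate(enforce_host_mt_range=False)


def test_simulation_byte_identical_under_seed():
    sc = _simple_scenario(2_000, seed=42)
    genomes = _genomes_for(sc)
    out = []
    for _ in range(2):
        reads, _truth = simulate_gut_reads(sc, genomes)
        buf = io.StringIO()
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            buf.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")
        out.append(buf.getvalue())
    assert out[0] == out[1]


def test_phred_strings_consistent_with_error_rate():
    """Realised substitution rate tracks the quality model."""
    sc = _simple_scenario(30_000, seed=9)
    genomes = _genomes_for(sc)
    reads, truth = simulate_gut_reads(sc, genomes)
    host = genomes["hostX|nuclear"]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    errs = bases = 0
    for r, row in zip(reads[:5_000], truth.itertuples(index=False)):
        tpl = host[row.start : row.end]
        rc = "".join(comp[c] for c in reversed(tpl))
        mm = min(
            sum(a != b for a, b in zip(r.sequence, tpl)),
            sum(a != b for a, b in zip(r.sequence, rc)),
        )
        errs += mm
        bases += len(r)
    expected = np.mean(
        [10 ** (-int(q) / 10) for r in reads[:100] for q in r.qualities]
    )
    assert errs / bases == pytest.approx(expected, rel=0.25)


# ---------------------------------------------------------------------------
# survey profiles


def test_control_profile_has_no_foreign_members():
    sc = scenario_for_predator("control", n_reads=1_000)
    assert sc.foreign_members == []
    assert sc.focal_predator == "Harmonia axyridis"


def test_unknown_predator_rejected():
    with pytest.raises(ValueError, match="unknown predator"):
        scenario_for_predator("Coccinella undecimpunctata")


def test_doru_profile_host_mt_fraction_matches_survey():
    sc = scenario_for_predator("Doru luteipes", n_reads=1_000)
    assert sc.host_mt_fraction == pytest.approx(17_428 / 2_183_902)


def test_profile_fractions_sum_to_one():
    for name in ("Cycloneda sanguinea", "Doru luteipes", "control"):
        sc = scenario_for_predator(name, n_reads=10)
        assert sum(m.read_fraction for m in sc.members) == pytest.approx(1.0)


def test_foreign_insect_fraction_matches_order_of_magnitude():
    """~15 detectable foreign insect reads per 2.8M in the Cy. sanguinea
    library: the profile's full-length insect members carry that fraction."""
    sc = scenario_for_predator("Cycloneda sanguinea", n_reads=2_837_177)
    full_insect = sum(
        m.read_fraction
        for m in sc.foreign_members
        if m.seq_key.startswith("mito|") and m.fragment is None
    )
    assert full_insect * sc.n_reads == pytest.approx(10, abs=8)


def test_scenario_yaml_round_trip():
    from gutlink.synthetic import scenario_from_yaml, scenario_to_yaml

    sc = scenario_for_predator("Doru luteipes", n_reads=1_000, seed=2)
    back = scenario_from_yaml(scenario_to_yaml(sc))
    assert back.focal_predator == sc.focal_predator
    assert back.members == sc.members
    assert back.error_profile == sc.error_profile
    assert back.n_reads == sc.n_reads
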