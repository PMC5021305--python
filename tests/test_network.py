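import pytest

from gutlink.filterid import TaxonDetection
from gutlink.network import (
    AssociationRule,
    TrophicEdge,
    TrophicNetwork,
    build_direct_edges,
    build_network,
    export_network,
    import_network_tsv,
    infer_indirect_edges,
    merge_cross_database,
    summarize,
)
from gutlink.profiles import PREDATORS


def _det(predator, db_id, taxon, count, taxonomy):
    return TaxonDetection(
        predator_id=predator,
        db_id=db_id,
        taxon_id=taxon,
        rank=taxonomy.rank(taxon),
        read_ids=frozenset(f"{predator}|{db_id}|{taxon}|{i}" for i in range(count)),
    )


# ---------------------------------------------------------------------------
# cross-database merging


def test_genus_detection_merges_into_species_with_summed_support(taxonomy):
    dets = [
        _det("Harmonia axyridis", "cox1_barcode", "Aphis", 2, taxonomy),
        _det("Harmonia axyridis", "insect_mitogenome", "Aphis gossypii", 5, taxonomy),
        _det("Harmonia axyridis", "nuclear_genome", "Aphis gossypii", 5, taxonomy),
    ]
    merged = merge_cross_database(dets, taxonomy)
    assert len(merged) == 1
    m = merged[0]
    assert m.taxon_id == "Aphis gossypii"
    assert m.support_reads == 12
    assert len(m.evidence) == 3


def test_disjoint_taxa_unchanged(taxonomy):
    dets = [
        _det("p", "insect_mitogenome", "Doru luteipes", 3, taxonomy),
        _det("p", "insect_mitogenome", "Plutella xylostella", 4, taxonomy),
    ]
    merged = merge_cross_database(dets, taxonomy)
    assert {(m.taxon_id, m.support_reads) for m in merged} == {
        ("Doru luteipes", 3), ("Plutella xylostella", 4),
    }


def test_same_species_in_two_databases_merges_identically(taxonomy):
    dets = [
        _det("p", "insect_mitogenome", "Harmonia axyridis", 3, taxonomy),
        _det("p", "cox1_barcode", "Harmonia axyridis", 4, taxonomy),
    ]
    merged = merge_cross_database(dets, taxonomy)
    assert len(merged) == 1
    assert merged[0].support_reads == 7


# ---------------------------------------------------------------------------
# direct edges


def test_intraguild_edges_for_cycloneda(taxonomy):
    dets = [
        _det("Cycloneda sanguinea", "insect_mitogenome", "Doru luteipes", 3, taxonomy),
        _det("Cycloneda sanguinea", "insect_mitogenome", "Harmonia axyridis", 7, taxonomy),
    ]
    edges = build_direct_edges(
        merge_cross_database(dets, taxonomy), taxonomy, "Cycloneda sanguinea"
    )
    assert len(edges) == 2
    assert all(e.guild_class == "intraguild" for e in edges)
    assert all(e.edge_type == "direct" for e in edges)


def test_three_direct_edges_for_doru_including_family_rank(taxonomy):
    dets = [
        _det("Doru luteipes", "insect_mitogenome", "Plutella xylostella", 17, taxonomy),
        _det("Doru luteipes", "insect_mitogenome", "Harmonia axyridis", 7, taxonomy),
        _det("Doru luteipes", "insect_mitogenome", "Aphididae", 2, taxonomy),
    ]
    edges = build_direct_edges(
        merge_cross_database(dets, taxonomy), taxonomy, "Doru luteipes"
    )
    assert len(edges) == 3
    by_prey = {e.prey: e for e in edges}
    assert by_prey["Harmonia axyridis"].guild_class == "intraguild"
    assert by_prey["Aphididae"].guild_class == "extraguild"


def test_species_rank_parasitoid_prey_flagged_uncertain(taxonomy):
    dets = [
        _det(
            "Hippodamia convergens", "insect_mitogenome",
            "Dinocampus coccinellae", 58, taxonomy,
        )
    ]
    edges = build_direct_edges(
        merge_cross_database(dets, taxonomy), taxonomy, "Hippodamia convergens"
    )
    assert len(edges) == 1
    assert edges[0].notes == "role_uncertain"


def test_empty_detections_no_edges(taxonomy):
    assert build_direct_edges([], taxonomy, "Doru luteipes") == []


# ---------------------------------------------------------------------------
# inferred edges


def _rules():
    return [
        AssociationRule("aphid_specific_symbiont", "Aphididae", "symbiont"),
        AssociationRule("aphid_parasitoid", "Aphididae", "parasitoid"),
    ]


def test_symbiont_without_aphid_dna_infers_one_edge(taxonomy):
    dets = [
        _det("Cycloneda sanguinea", "bacterial_genome", "Hamiltonella", 20, taxonomy),
        _det("Cycloneda sanguinea", "bacterial_genome", "Spiroplasma", 1, taxonomy),
    ]
    edges = infer_indirect_edges(dets, _rules(), [], taxonomy)
    assert len(edges) == 1
    e = edges[0]
    assert (e.predator, e.prey, e.edge_type) == (
        "Cycloneda sanguinea", "Aphididae", "inferred",
    )
    assert e.support_reads == 20  # Spiroplasma is not aphid-specific


def test_existing_direct_aphid_edge_suppresses_inference(taxonomy):
    dets = [
        _det("Harmonia axyridis", "bacterial_genome", "Regiella insecticola", 233, taxonomy),
    ]
    direct = [
        TrophicEdge(
            "Harmonia axyridis", "Aphis gossypii", "direct", "extraguild", 12,
        )
    ]
    assert infer_indirect_edges(dets, _rules(), direct, taxonomy) == []


def test_parasitoid_evidence_counts_but_not_supports(taxonomy):
    dets = [
        _det("Hippodamia convergens", "bacterial_genome",
             "Regiella insecticola", 88, taxonomy),
        _det("Hippodamia convergens", "parasitoid_markers", "Aphidiinae", 20, taxonomy),
    ]
    edges = infer_indirect_edges(dets, _rules(), [], taxonomy)
    assert len(edges) == 1
    assert edges[0].support_reads == 88
    assert ("parasitoid_markers", "Aphidiinae", 20) in edges[0].evidence


def test_no_triggering_detections_no_edges(taxonomy):
    dets = [_det("p", "bacterial_genome", "Wolbachia", 100, taxonomy)]
    assert infer_indirect_edges(dets, _rules(), [], taxonomy) == []


def test_rebuilding_with_direct_edge_removes_inferred(
    taxonomy, fixture_detections, rules
):
    """Adding direct aphid evidence can only remove the inferred edge."""
    net1 = build_network(fixture_detections, taxonomy, rules,
                         focal_predators=PREDATORS)
    assert len(net1.edges_from("Cycloneda sanguinea", "inferred")) == 1
    extra = _det(
        "Cycloneda sanguinea", "insect_mitogenome", "Aphis gossypii", 3, taxonomy
    )
    net2 = build_network(
        fixture_detections + [extra], taxonomy, rules, focal_predators=PREDATORS
    )
    assert net2.edges_from("Cycloneda sanguinea", "inferred") == []
    assert len(net2.edges_from("Cycloneda sanguinea", "direct")) == 3


# ---------------------------------------------------------------------------
# network container invariants


def test_duplicate_edges_rejected(taxonomy):
    net = TrophicNetwork(nodes={"a": "focal_predator", "b": "herbivore"})
    e = TrophicEdge("a", "b", "direct", "extraguild", 1)
    net.add_edge(e)
    with pytest.raises(ValueError):
        net.add_edge(TrophicEdge("a", "b", "direct", "extraguild", 5))


def test_edge_endpoints_must_be_nodes():
    net = TrophicNetwork(nodes={"a": "focal_predator"})
    with pytest.raises(ValueError):
        net.add_edge(TrophicEdge("a", "ghost", "direct", "extraguild", 1))


def test_edge_support_conservation(taxonomy, fixture_detections, rules):
    net = build_network(fixture_detections, taxonomy, rules,
                        focal_predators=PREDATORS)
    for e in net.edges:
        if e.edge_type == "direct":
            assert e.support_reads == sum(c for _, _, c in e.evidence)


# ---------------------------------------------------------------------------
# summary statistics


def test_single_species_edge_gives_100_percent(taxonomy):
    net = TrophicNetwork(
        nodes={"Doru luteipes": "focal_predator",
               "Plutella xylostella": "herbivore"},
    )
    net.add_edge(
        TrophicEdge("Doru luteipes", "Plutella xylostella", "direct",
                    "extraguild", 17)
    )
    s = summarize(net, [], taxonomy)
    assert s.species_or_genus_fraction_pct == 100


# ---------------------------------------------------------------------------
# export / import


def test_tsv_round_trip_is_lossless(taxonomy, fixture_detections, rules, tmp_path):
    net = build_network(fixture_detections, taxonomy, rules,
                        focal_predators=PREDATORS)
    path = tmp_path / "net.tsv"
    export_network(net, path, "tsv")
    assert import_network_tsv(path) == net


def test_dot_styles_inferred_edges_dashed(taxonomy, fixture_detections, rules, tmp_path):
    net = build_network(fixture_detections, taxonomy, rules,
                        focal_predators=PREDATORS)
    path = tmp_path / "net.dot"
    export_network(net, path, "dot")
    text = path.read_text()
    assert "style=dashed" in text
    assert text.count("->") == len(net.edges)


def test_graphml_export_readable_by_networkx(taxonomy, fixture_detections, rules, tmp_path):
    import networkx as nx

    net = build_network(fixture_detections, taxonomy, rules,
                        focal_predators=PREDATORS)
    path = tmp_path / "net.graphml"
    export_network(net, path, "graphml")
    g = nx.read_graphml(path)
    assert g.number_of_edges() == len(net.edges)


def test_empty_network_exports_valid_documents(tmp_path):
    net = TrophicNetwork()
    for fmt in ("tsv", "dot", "graphml"):
        path = tmp_path / f"empty.{fmt}"
        export_network(net, path, fmt)
        assert path.exists()
    assert import_network_tsv(tmp_path / "empty.tsv") == net


def test_unknown_format_is_hard_error(tmp_path):
    with pytest.raises(ValueError):
        export_network(TrophicNetwork(), tmp_path / "x", "sif")


def test_summary_tsv_written(taxonomy, fixture_detections, rules, tmp_path):
    from gutlink.network import write_summary

    net = build_network(fixture_detections, taxonomy, rules,
                        focal_predators=PREDATORS)
    s = summarize(net, fixture_detections, taxonomy, rules)
    path = tmp_path / "summary.tsv"
    write_summary(s, path)
    text = path.read_text()
    assert "species_or_genus_fraction_pct=93" in text
    assert "Hippodamia convergens\t8\t1\t4\t3\t1" in text
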