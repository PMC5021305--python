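"""Qualitative trophic-network inference from per-database detections.

Detections from the insect-resolution databases (mitogenomes, cox1
barcodes, aphid nuclear genomes) become *direct* predation edges after
cross-database merging. Detections of obligate prey associates — aphid-
specific symbionts and aphid parasitoids — imply predation on the prey
group even when no prey DNA was recovered; these become *inferred* edges
(drawn dashed), supported by the symbiont read counts. Edges are classed
intraguild (prey is itself a predator of the assemblage) or extraguild.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx

from .filterid import TaxonDetection
from .taxonomy import Taxonomy

#: database ids whose detections support direct predation edges
INSECT_DB_CLASSES = ("insect_mitogenome", "cox1_barcode", "nuclear_genome")

#: guilds counted as "the focal guild" for intraguild classification
PREDATOR_GUILDS = ("focal_predator", "other_predator")


@dataclass(frozen=True)
class AssociationRule:
    """Detection of a tagged taxon implies predation on a prey group."""

    trigger_tag: str
    implied_prey_group: str
    evidence_type: str  # symbiont | parasitoid

    def __post_init__(self):
        if self.evidence_type not in ("symbiont", "parasitoid"):
            raise ValueError(f"unknown evidence_type {self.evidence_type!r}")


DEFAULT_RULES = (
    AssociationRule("aphid_specific_symbiont", "Aphididae", "symbiont"),
    AssociationRule("aphid_parasitoid", "Aphididae", "parasitoid"),
)


@dataclass(frozen=True)
class TrophicEdge:
    """A typed predator -> prey link with read support.

    ``evidence`` summarises the contributing detections as (db_id, taxon_id,
    read_count) triples. ``notes`` carries qualitative annotations, e.g.
    ``role_uncertain`` for species-rank parasitoid prey whose detection may
    reflect parasitism of the predator rather than predation.
    """

    predator: str
    prey: str
    edge_type: str  # direct | inferred
    guild_class: str  # intraguild | extraguild
    support_reads: int
    evidence: tuple[tuple[str, str, int], ...] = ()
    notes: str = ""

    def __post_init__(self):
        if self.edge_type not in ("direct", "inferred"):
            raise ValueError(f"unknown edge_type {self.edge_type!r}")
        if self.guild_class not in ("intraguild", "extraguild"):
            raise ValueError(f"unknown guild_class {self.guild_class!r}")
        if self.support_reads < 1:
            raise ValueError("support_reads must be >= 1")


@dataclass
class TrophicNetwork:
    """Taxa (with guild annotation) plus typed trophic edges."""

    nodes: dict[str, str] = field(default_factory=dict)  # taxon_id -> guild
    edges: list[TrophicEdge] = field(default_factory=list)

    def add_edge(self, edge: TrophicEdge) -> None:
        key = (edge.predator, edge.prey, edge.edge_type)
        if any((e.predator, e.prey, e.edge_type) == key for e in self.edges):
            raise ValueError(f"duplicate edge {key}")
        if edge.predator not in self.nodes or edge.prey not in self.nodes:
            raise ValueError("edge endpoints must be registered nodes")
        self.edges.append(edge)

    def edges_from(self, predator: str, edge_type: Optional[str] = None):
        return [
            e
            for e in self.edges
            if e.predator == predator
            and (edge_type is None or e.edge_type == edge_type)
        ]

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrophicNetwork):
            return NotImplemented
        return self.nodes == other.nodes and sorted(
            self.edges, key=lambda e: (e.predator, e.prey, e.edge_type)
        ) == sorted(other.edges, key=lambda e: (e.predator, e.prey, e.edge_type))


# ---------------------------------------------------------------------------
# cross-database merging


@dataclass
class MergedDetection:
    """One foreign taxon for one predator, pooled across insect databases."""

    predator_id: str
    taxon_id: str
    rank: str
    support_reads: int
    evidence: tuple[tuple[str, str, int], ...]


def merge_cross_database(
    detections: Sequence[TaxonDetection], taxonomy: Taxonomy
) -> list[MergedDetection]:
    """Merge insect-database detections of the same lineage per predator.

    Detections whose taxa are identical, or where one is an ancestor of the
    other (e.g. a genus-level barcode match alongside a species-level
    mitogenome match), collapse into the most specific taxon with summed
    read support. When an ancestor has several detected descendants it
    merges into the best-supported one (ties: lexicographic).
    """
    out: list[MergedDetection] = []
    by_pred: dict[str, list[TaxonDetection]] = {}
    for det in detections:
        by_pred.setdefault(det.predator_id, []).append(det)
    for predator_id, dets in by_pred.items():
        # pool read counts per taxon first (same taxon in several databases)
        taxa: dict[str, list[TaxonDetection]] = {}
        for det in dets:
            taxa.setdefault(det.taxon_id, []).append(det)
        # map every taxon to its most specific detected descendant
        resolved: dict[str, str] = {}
        for taxon in taxa:
            descendants = [
                other
                for other in taxa
                if other != taxon and taxonomy.is_descendant(other, taxon)
            ]
            if descendants:
                descendants.sort(
                    key=lambda t: (
                        -sum(d.read_count for d in taxa[t]),
                        t,
                    )
                )
                resolved[taxon] = descendants[0]
            else:
                resolved[taxon] = taxon
        # follow chains (genus -> species) to a fixed point
        def final(t: str) -> str:
            while resolved[t] != t:
                t = resolved[t]
            return t

        groups: dict[str, list[TaxonDetection]] = {}
        for taxon, det_list in taxa.items():
            groups.setdefault(final(taxon), []).extend(det_list)
        for taxon, det_list in groups.items():
            evidence = tuple(
                sorted((d.db_id, d.taxon_id, d.read_count) for d in det_list)
            )
            out.append(
                MergedDetection(
                    predator_id=predator_id,
                    taxon_id=taxon,
                    rank=taxonomy.rank(taxon),
                    support_reads=sum(d.read_count for d in det_list),
                    evidence=evidence,
                )
            )
    out.sort(key=lambda m: (m.predator_id, -m.support_reads, m.taxon_id))
    return out


# ---------------------------------------------------------------------------
# edge construction


def _guild_class(prey: str, taxonomy: Taxonomy) -> str:
    return (
        "intraguild" if taxonomy.guild(prey) in PREDATOR_GUILDS else "extraguild"
    )


def build_direct_edges(
    merged: Sequence[MergedDetection],
    taxonomy: Taxonomy,
    focal_predator: str,
) -> list[TrophicEdge]:
    """One direct predation edge per merged foreign insect taxon.

    Merged detections must already exclude the focal predator itself.
    Parasitoid taxa resolved only above genus rank never form direct edges
    (their reads reflect conserved markers, not an identifiable prey);
    species- or genus-rank parasitoids do, annotated ``role_uncertain``
    because ingestion of a free-living parasitoid, of a parasitized host,
    or parasitism of the predator itself cannot be separated.
    """
    edges = []
    for m in merged:
        if taxonomy.is_descendant(m.taxon_id, focal_predator):
            raise ValueError(
                f"merged detections must exclude the focal predator "
                f"({m.taxon_id} under {focal_predator})"
            )
        guild = taxonomy.guild(m.taxon_id)
        notes = ""
        if guild == "parasitoid":
            if m.rank not in ("species", "genus"):
                continue
            notes = "role_uncertain"
        edges.append(
            TrophicEdge(
                predator=focal_predator,
                prey=m.taxon_id,
                edge_type="direct",
                guild_class=_guild_class(m.taxon_id, taxonomy),
                support_reads=m.support_reads,
                evidence=m.evidence,
                notes=notes,
            )
        )
    return edges


def _taxon_has_tag(taxon: str, tag: str, taxonomy: Taxonomy) -> bool:
    return any(tag in taxonomy.tags(t) for t in taxonomy.lineage(taxon))


def infer_indirect_edges(
    detections: Sequence[TaxonDetection],
    rules: Sequence[AssociationRule],
    direct_edges: Sequence[TrophicEdge],
    taxonomy: Taxonomy,
) -> list[TrophicEdge]:
    """Inferred predation on a prey group via its obligate associates.

    For each predator and implied prey group with at least one rule-
    triggering detection and no direct edge to a taxon within the group,
    one inferred edge is emitted. Its read support is the sum of the
    triggering *symbiont* detections; parasitoid detections contribute
    evidence but not support counts.
    """
    for rule in rules:
        if rule.implied_prey_group not in taxonomy:
            raise ValueError(
                f"rule prey group {rule.implied_prey_group!r} not in taxonomy"
            )
    by_pred: dict[str, list[TaxonDetection]] = {}
    for det in detections:
        by_pred.setdefault(det.predator_id, []).append(det)
    edges: list[TrophicEdge] = []
    for predator_id, dets in sorted(by_pred.items()):
        groups: dict[str, list[tuple[AssociationRule, TaxonDetection]]] = {}
        for rule in rules:
            for det in dets:
                if _taxon_has_tag(det.taxon_id, rule.trigger_tag, taxonomy):
                    groups.setdefault(rule.implied_prey_group, []).append((rule, det))
        for group, triggers in sorted(groups.items()):
            has_direct = any(
                e.predator == predator_id
                and taxonomy.is_descendant(e.prey, group)
                for e in direct_edges
            )
            if has_direct:
                continue
            symbiont_reads = sum(
                det.read_count
                for rule, det in triggers
                if rule.evidence_type == "symbiont"
            )
            support = symbiont_reads or sum(det.read_count for _, det in triggers)
            evidence = tuple(
                sorted({(det.db_id, det.taxon_id, det.read_count) for _, det in triggers})
            )
            edges.append(
                TrophicEdge(
                    predator=predator_id,
                    prey=group,
                    edge_type="inferred",
                    guild_class=_guild_class(group, taxonomy),
                    support_reads=support,
                    evidence=evidence,
                )
            )
    return edges


def build_network(
    detections: Sequence[TaxonDetection],
    taxonomy: Taxonomy,
    rules: Sequence[AssociationRule] = DEFAULT_RULES,
    insect_db_ids: Optional[set[str]] = None,
    focal_predators: Optional[Sequence[str]] = None,
) -> TrophicNetwork:
    """Assemble the full network from all-database detections.

    ``insect_db_ids`` names the databases whose detections support direct
    edges (defaults to db ids equal to the insect marker classes).
    """
    insect_db_ids = insect_db_ids or set(INSECT_DB_CLASSES)
    predators = list(
        dict.fromkeys(
            focal_predators
            if focal_predators is not None
            else [d.predator_id for d in detections]
        )
    )
    net = TrophicNetwork()
    for p in predators:
        net.nodes[p] = taxonomy.guild(p)
    all_direct: list[TrophicEdge] = []
    for p in predators:
        insect_dets = [
            d
            for d in detections
            if d.predator_id == p
            and d.db_id in insect_db_ids
            and not taxonomy.is_descendant(d.taxon_id, p)
        ]
        merged = merge_cross_database(insect_dets, taxonomy)
        all_direct.extend(build_direct_edges(merged, taxonomy, p))
    inferred = infer_indirect_edges(detections, rules, all_direct, taxonomy)
    for e in all_direct + inferred:
        net.nodes.setdefault(e.prey, taxonomy.guild(e.prey))
        net.add_edge(e)
    return net


# ---------------------------------------------------------------------------
# summary statistics


@dataclass
class NetworkSummary:
    per_predator: dict[str, dict]
    species_or_genus_fraction_pct: int
    species_or_genus_linked_taxa: int
    total_direct_links: int
    total_inferred_links: int

    def as_dict(self) -> dict:
        return {
            "per_predator": self.per_predator,
            "species_or_genus_fraction_pct": self.species_or_genus_fraction_pct,
            "species_or_genus_linked_taxa": self.species_or_genus_linked_taxa,
            "total_direct_links": self.total_direct_links,
            "total_inferred_links": self.total_inferred_links,
        }


def summarize(
    network: TrophicNetwork,
    detections: Sequence[TaxonDetection],
    taxonomy: Taxonomy,
    rules: Sequence[AssociationRule] = DEFAULT_RULES,
    parasitoid_db_ids: Iterable[str] = ("parasitoid_markers",),
    focal_family: str = "Coccinellidae",
) -> NetworkSummary:
    """Per-predator link counts and pooled taxonomic-resolution statistics.

    The pooled species-or-genus fraction is computed over direct links only
    (family-rank prey count against it) and rounded to a whole percent. The
    linked-taxa count pools, deduplicated across predators: direct prey at
    species/genus rank, parasitoid-database detections at species/genus
    rank, and detected taxa bearing a symbiont rule tag.
    """
    predators = sorted({e.predator for e in network.edges}) or sorted(
        t for t, g in network.nodes.items() if g == "focal_predator"
    )
    per_pred = {}
    for p in predators:
        direct = network.edges_from(p, "direct")
        inferred = network.edges_from(p, "inferred")
        intraguild = [e for e in direct if e.guild_class == "intraguild"]
        in_family = [
            e
            for e in intraguild
            if focal_family in taxonomy.lineage(e.prey)
        ]
        per_pred[p] = {
            "direct_links": len(direct),
            "inferred_links": len(inferred),
            "intraguild_prey_richness": len(intraguild),
            "intraguild_focal_family_richness": len(in_family),
            "intraguild_other_richness": len(intraguild) - len(in_family),
        }
    direct_edges = [e for e in network.edges if e.edge_type == "direct"]
    n_direct = len(direct_edges)
    n_sg = sum(
        1 for e in direct_edges if taxonomy.rank(e.prey) in ("species", "genus")
    )
    fraction_pct = int(round(100.0 * n_sg / n_direct)) if n_direct else 0

    linked: set[str] = {
        e.prey
        for e in direct_edges
        if taxonomy.rank(e.prey) in ("species", "genus")
    }
    parasitoid_ids = set(parasitoid_db_ids)
    for det in detections:
        if det.db_id in parasitoid_ids and det.rank in ("species", "genus"):
            linked.add(det.taxon_id)
        for rule in rules:
            if rule.evidence_type == "symbiont" and _taxon_has_tag(
                det.taxon_id, rule.trigger_tag, taxonomy
            ):
                linked.add(det.taxon_id)
    return NetworkSummary(
        per_predator=per_pred,
        species_or_genus_fraction_pct=fraction_pct,
        species_or_genus_linked_taxa=len(linked),
        total_direct_links=n_direct,
        total_inferred_links=len(network.edges) - n_direct,
    )


def write_summary(summary: NetworkSummary, path: str | Path) -> None:
    """Per-predator and pooled network statistics as TSV."""
    with open(path, "w") as fh:
        fh.write(
            "#predator\tdirect_links\tinferred_links\tintraguild_richness\t"
            "intraguild_focal_family\tintraguild_other\n"
        )
        for predator, row in sorted(summary.per_predator.items()):
            fh.write(
                f"{predator}\t{row['direct_links']}\t{row['inferred_links']}\t"
                f"{row['intraguild_prey_richness']}\t"
                f"{row['intraguild_focal_family_richness']}\t"
                f"{row['intraguild_other_richness']}\n"
            )
        fh.write(
            f"#pooled\tspecies_or_genus_fraction_pct="
            f"{summary.species_or_genus_fraction_pct}\t"
            f"species_or_genus_linked_taxa={summary.species_or_genus_linked_taxa}\t"
            f"total_direct={summary.total_direct_links}\t"
            f"total_inferred={summary.total_inferred_links}\n"
        )


# ---------------------------------------------------------------------------
# association-rule IO


def load_rules(path: str | Path) -> list[AssociationRule]:
    rules = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns")
            rules.append(AssociationRule(parts[0], parts[1], parts[2]))
    return rules


def write_rules(rules: Iterable[AssociationRule], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#trigger_tag\timplied_prey_group\tevidence_type\n")
        for r in rules:
            fh.write(f"{r.trigger_tag}\t{r.implied_prey_group}\t{r.evidence_type}\n")


# ---------------------------------------------------------------------------
# export / import


def _evidence_str(evidence: tuple[tuple[str, str, int], ...]) -> str:
    return ";".join(f"{db}:{taxon}:{count}" for db, taxon, count in evidence)


def _parse_evidence(text: str) -> tuple[tuple[str, str, int], ...]:
    if not text:
        return ()
    out = []
    for item in text.split(";"):
        parts = item.split(":")
        out.append((parts[0], ":".join(parts[1:-1]), int(parts[-1])))
    return tuple(out)


def export_network(network: TrophicNetwork, path: str | Path, format: str = "tsv") -> None:
    """Write the network as tsv (lossless), graphml, or dot.

    The DOT rendering draws inferred edges dashed, matching the convention
    of distinguishing symbiont-implied predation from direct detections.
    """
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("#gutlink-network\tv1\n")
            for taxon in sorted(network.nodes):
                fh.write(f"N\t{taxon}\t{network.nodes[taxon]}\n")
            for e in sorted(
                network.edges, key=lambda e: (e.predator, e.prey, e.edge_type)
            ):
                fh.write(
                    f"E\t{e.predator}\t{e.prey}\t{e.edge_type}\t{e.guild_class}\t"
                    f"{e.support_reads}\t{_evidence_str(e.evidence)}\t{e.notes}\n"
                )
    elif format == "graphml":
        g = nx.DiGraph()
        for taxon, guild in network.nodes.items():
            g.add_node(taxon, guild=guild)
        for e in network.edges:
            g.add_edge(
                e.predator,
                e.prey,
                type=e.edge_type,
                guild_class=e.guild_class,
                support=e.support_reads,
                notes=e.notes,
            )
        nx.write_graphml(g, path)
    elif format == "dot":
        lines = ["digraph trophic {"]
        for taxon, guild in sorted(network.nodes.items()):
            lines.append(f'  "{taxon}" [guild="{guild}"];')
        for e in sorted(
            network.edges, key=lambda e: (e.predator, e.prey, e.edge_type)
        ):
            style = "dashed" if e.edge_type == "inferred" else "solid"
            lines.append(
                f'  "{e.predator}" -> "{e.prey}" '
                f'[style={style}, label="{e.support_reads}"];'
            )
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def import_network_tsv(path: str | Path) -> TrophicNetwork:
    net = TrophicNetwork()
    edges = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "N":
                net.nodes[parts[1]] = parts[2]
            elif parts[0] == "E":
                notes = parts[7] if len(parts) > 7 else ""
                edges.append(
                    TrophicEdge(
                        predator=parts[1],
                        prey=parts[2],
                        edge_type=parts[3],
                        guild_class=parts[4],
                        support_reads=int(parts[5]),
                        evidence=_parse_evidence(parts[6]),
                        notes=notes,
                    )
                )
            else:
                raise ValueError(f"{path}:{ln}: unknown record type {parts[0]!r}")
    for e in edges:
        net.add_edge(e)
    return net


__all__ = [
    "AssociationRule",
    "TrophicEdge",
    "TrophicNetwork",
    "MergedDetection",
    "DEFAULT_RULES",
    "merge_cross_database",
    "build_direct_edges",
    "infer_indirect_edges",
    "build_network",
    "summarize",
    "NetworkSummary",
    "export_network",
    "import_network_tsv",
    "load_rules",
    "write_summary",
    "write_rules",
]
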