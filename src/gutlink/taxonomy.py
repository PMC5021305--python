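"""Taxonomy table: ranked lineages, guilds, association tags, and LCA queries.

The identification stage assigns each read to the lowest taxonomic level that
can be reliably distinguished, which requires rank-ordered lineages and a
lowest-common-ancestor operation over the near-best reference matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

# Ranks ordered from most specific to least specific. ``root`` is the implicit
# top of every lineage.
RANK_ORDER = (
    "species",
    "genus",
    "tribe",
    "subfamily",
    "family",
    "superfamily",
    "order",
    "class",
    "phylum",
    "kingdom",
    "root",
)

RANK_INDEX = {rank: i for i, rank in enumerate(RANK_ORDER)}

#: Association labels recognised by the network rules.
TAG_VOCABULARY = frozenset(
    {
        "aphid_specific_symbiont",
        "aphid_parasitoid",
        "coccinellid_parasitoid",
    }
)

GUILDS = frozenset(
    {
        "focal_predator",
        "other_predator",
        "herbivore",
        "parasitoid",
        "symbiont",
        "plant",
        "fungus",
        "other",
    }
)


@dataclass(frozen=True)
class TaxonRecord:
    """One node of the taxonomy: a taxon with rank, parent, guild and tags."""

    taxon_id: str
    rank: str
    parent_id: Optional[str]
    guild: str = "other"
    tags: frozenset[str] = field(default_factory=frozenset)


class Taxonomy:
    """A rooted taxonomy with rank-consistency checks and LCA queries."""

    def __init__(self, records: Iterable[TaxonRecord]):
        self._records: dict[str, TaxonRecord] = {}
        for rec in records:
            if rec.taxon_id in self._records:
                raise ValueError(f"duplicate taxon_id {rec.taxon_id!r}")
            self._records[rec.taxon_id] = rec
        self._lineage_cache: dict[str, tuple[str, ...]] = {}

    # -- basic access ------------------------------------------------------

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._records

    def __iter__(self):
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def get(self, taxon_id: str) -> TaxonRecord:
        try:
            return self._records[taxon_id]
        except KeyError:
            raise KeyError(f"unknown taxon_id {taxon_id!r}") from None

    def rank(self, taxon_id: str) -> str:
        return self.get(taxon_id).rank

    def guild(self, taxon_id: str) -> str:
        return self.get(taxon_id).guild

    def tags(self, taxon_id: str) -> frozenset[str]:
        return self.get(taxon_id).tags

    # -- lineage queries ---------------------------------------------------

    def lineage(self, taxon_id: str) -> tuple[str, ...]:
        """Ordered ancestor list from the root down to ``taxon_id`` itself."""
        cached = self._lineage_cache.get(taxon_id)
        if cached is not None:
            return cached
        chain = []
        cur: Optional[str] = taxon_id
        seen = set()
        while cur is not None:
            if cur in seen:
                raise ValueError(f"taxonomy cycle at {cur!r}")
            seen.add(cur)
            chain.append(cur)
            cur = self.get(cur).parent_id
        result = tuple(reversed(chain))
        self._lineage_cache[taxon_id] = result
        return result

    def is_descendant(self, taxon_id: str, ancestor_id: str) -> bool:
        """True if ``taxon_id`` equals or descends from ``ancestor_id``."""
        return ancestor_id in self.lineage(taxon_id)

    def lca(self, taxon_ids: Iterable[str]) -> str:
        """Lowest common ancestor of one or more taxa."""
        ids = list(dict.fromkeys(taxon_ids))
        if not ids:
            raise ValueError("lca of empty taxon set")
        common = self.lineage(ids[0])
        for tid in ids[1:]:
            other = self.lineage(tid)
            n = 0
            for a, b in zip(common, other):
                if a != b:
                    break
                n += 1
            common = common[:n]
            if not common:
                raise ValueError(f"taxa {ids!r} share no common ancestor")
        return common[-1]

    def shares_ancestor_at_or_below(
        self, taxon_a: str, taxon_b: str, rank: str
    ) -> bool:
        """True if the two taxa share an ancestor at or below ``rank``.

        Used by the host-lineage exclusion rule: a reference hit is
        non-diagnostic when its taxon is this close to the focal predator
        (e.g. same tribe for rRNA markers that do not separate predator from
        close relatives).
        """
        if rank not in RANK_INDEX:
            raise ValueError(f"unknown rank {rank!r}")
        la, lb = self.lineage(taxon_a), self.lineage(taxon_b)
        shared = None
        for a, b in zip(la, lb):
            if a != b:
                break
            shared = a
        if shared is None:
            return False
        shared_rank = self.get(shared).rank
        if shared_rank not in RANK_INDEX:
            return False
        return RANK_INDEX[shared_rank] <= RANK_INDEX[rank]

    # -- validation --------------------------------------------------------

    def validate(self) -> list[str]:
        """Return a list of human-readable consistency problems (empty if ok)."""
        problems: list[str] = []
        for rec in self._records.values():
            if rec.rank not in RANK_INDEX:
                problems.append(f"taxon {rec.taxon_id!r}: unknown rank {rec.rank!r}")
                continue
            if rec.guild not in GUILDS:
                problems.append(
                    f"taxon {rec.taxon_id!r}: unknown guild {rec.guild!r}"
                )
            for tag in rec.tags:
                if tag not in TAG_VOCABULARY:
                    problems.append(
                        f"taxon {rec.taxon_id!r}: tag {tag!r} not in rule vocabulary"
                    )
            if rec.parent_id is not None:
                if rec.parent_id not in self._records:
                    problems.append(
                        f"taxon {rec.taxon_id!r}: unresolvable parent "
                        f"{rec.parent_id!r}"
                    )
                    continue
                parent = self._records[rec.parent_id]
                if parent.rank in RANK_INDEX and (
                    RANK_INDEX[parent.rank] <= RANK_INDEX[rec.rank]
                ):
                    problems.append(
                        f"taxon {rec.taxon_id!r} (rank {rec.rank}) has parent "
                        f"{rec.parent_id!r} whose rank {parent.rank} is not "
                        f"strictly higher"
                    )
        return problems


def load_taxonomy(path: str | Path) -> Taxonomy:
    """Load a taxonomy from a TSV of (taxon_id, rank, parent_id, guild, tags).

    ``parent_id`` empty or '-' means root; ``tags`` is a comma-separated list
    (may be empty).
    """
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >=3 columns")
            taxon_id, rank, parent = parts[0], parts[1], parts[2]
            guild = parts[3] if len(parts) > 3 and parts[3] else "other"
            tags = (
                frozenset(t for t in parts[4].split(",") if t)
                if len(parts) > 4
                else frozenset()
            )
            parent_id = None if parent in ("", "-") else parent
            records.append(TaxonRecord(taxon_id, rank, parent_id, guild, tags))
    return Taxonomy(records)


def write_taxonomy(taxonomy: Taxonomy, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#taxon_id\trank\tparent_id\tguild\ttags\n")
        for rec in taxonomy:
            fh.write(
                f"{rec.taxon_id}\t{rec.rank}\t{rec.parent_id or '-'}\t"
                f"{rec.guild}\t{','.join(sorted(rec.tags))}\n"
            )
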