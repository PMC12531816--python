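"""Recursive construction of the hierarchical classifier tree.

Starting from the kingdom, each node routes records one rank deeper
(phylum → class → order → family).  A child taxon whose species count reaches
the grouping threshold T gets its own sub-classifier one rank down; the
remaining small taxa are merged into a single "Other" class that is classified
*directly to species*.  Family is the deepest routing rank: its members are
always species-level leaves, so genus is never a routing rank (the genus of a
prediction falls out of the species → lineage map).

When every child of a node falls below T there is nothing left to route and
the node collapses to one direct species-level leaf spanning all its species
(this is why, at reference scale, species-rich classes whose orders are all
small appear as ``<class>_c2s`` leaves).

Node names follow the ``<taxon>_<from-letter>2<to-letter>`` convention
(``Fungi2p``, ``Ascomycota_p2c``, ``Cortinariaceae_f2s``, ``other_p2s``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .seqio import Dataset, SeqRecord
from .taxonomy import RANK_LETTERS, RANKS

OTHER_LABEL = "Other"

#: Ranks that may be routed into; genus is deliberately absent.
ROUTING_TARGETS = ("phylum", "class", "order", "family")


@dataclass
class HierarchyConfig:
    """T is counted in species (species hypotheses), the unit the recursive
    grouping rule uses; ``threshold_unit="sequences"`` switches to record
    counts."""

    group_threshold: float = 1000
    deepest_routing_rank: str = "family"
    max_leaf_classes: Optional[int] = None
    threshold_unit: str = "species"

    def __post_init__(self) -> None:
        if self.group_threshold < 1:
            raise ValueError("group_threshold must be ≥ 1")
        if self.deepest_routing_rank not in ROUTING_TARGETS:
            raise ValueError(
                f"deepest_routing_rank must be one of {ROUTING_TARGETS}"
            )
        if self.threshold_unit not in ("species", "sequences"):
            raise ValueError("threshold_unit must be 'species' or 'sequences'")


@dataclass
class HierarchyNode:
    """One sub-classifier: a routing node or a species-level leaf.

    ``class_labels`` are the training labels of this node's forest: child
    taxon names plus "Other"/"Other1"… at routing nodes, species names at
    leaves.  ``other_species_labels`` maps each species reachable through a
    merged small taxon to its "Other…" class label.
    """

    name: str
    taxon_path: Tuple[str, ...]
    rank_from: str
    target_rank: str
    class_labels: List[str]
    is_leaf: bool
    species_set: frozenset
    children: Dict[str, "HierarchyNode"] = field(default_factory=dict)
    small_taxa: frozenset = frozenset()
    other_species_labels: Dict[str, str] = field(default_factory=dict)

    @property
    def needs_forest(self) -> bool:
        """Single-label nodes route deterministically; no forest is trained."""
        return len(self.class_labels) >= 2

    def walk(self):
        yield self
        for child in self.children.values():
            yield from child.walk()

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "taxon_path": list(self.taxon_path),
            "rank_from": self.rank_from,
            "target_rank": self.target_rank,
            "class_labels": self.class_labels,
            "is_leaf": self.is_leaf,
            "species_set": sorted(self.species_set),
            "small_taxa": sorted(self.small_taxa),
            "other_species_labels": dict(sorted(self.other_species_labels.items())),
            "children": {label: c.to_dict() for label, c in sorted(self.children.items())},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HierarchyNode":
        return cls(
            name=d["name"],
            taxon_path=tuple(d["taxon_path"]),
            rank_from=d["rank_from"],
            target_rank=d["target_rank"],
            class_labels=list(d["class_labels"]),
            is_leaf=d["is_leaf"],
            species_set=frozenset(d["species_set"]),
            small_taxa=frozenset(d["small_taxa"]),
            other_species_labels=dict(d["other_species_labels"]),
            children={k: cls.from_dict(v) for k, v in d["children"].items()},
        )


def _records_under(dataset: Dataset, taxon_path: Tuple[str, ...]) -> List[SeqRecord]:
    return [r for r in dataset if r.lineage.startswith(taxon_path)]


def count_species(dataset: Dataset, taxon_path: Tuple[str, ...], rank: str) -> Dict[str, int]:
    """Distinct species per child taxon at ``rank`` among records matching
    ``taxon_path``.  A species name reused on two different paths (homonym) is
    counted once per path."""
    if rank not in RANKS:
        raise ValueError(f"unknown or sub-species rank {rank!r}")
    seen: Dict[str, set] = {}
    for r in _records_under(dataset, taxon_path):
        child = r.lineage.name_at(rank)
        if child is None:
            continue
        seen.setdefault(child, set()).add(r.lineage.prefix("species"))
    return {taxon: len(paths) for taxon, paths in seen.items()}


def _size(records: List[SeqRecord], unit: str) -> int:
    if unit == "sequences":
        return len(records)
    return len({r.lineage.prefix("species") for r in records})


def _species_names(records: List[SeqRecord]) -> frozenset:
    return frozenset(r.lineage.species for r in records)


def _node_prefix(taxon_path: Tuple[str, ...], rank: str) -> str:
    taxon = taxon_path[-1]
    if rank == "kingdom":
        return taxon  # root style: "Fungi2p", not "Fungi_k2p"
    return f"{taxon}_{RANK_LETTERS[rank]}"


def build_hierarchy(dataset: Dataset, config: HierarchyConfig = None) -> HierarchyNode:
    """Build the sub-classifier tree from a curated dataset's lineages.

    Deterministic and order-independent: children are processed in sorted
    order and every label set is sorted.
    """
    config = config or HierarchyConfig()
    for r in dataset:
        if not r.lineage.is_full:
            raise ValueError(f"record {r.id!r} lacks a full 7-rank lineage")
    kingdoms = sorted({r.lineage.kingdom for r in dataset})
    if len(kingdoms) != 1:
        raise ValueError(f"expected exactly one kingdom, found {kingdoms}")
    return _expand(dataset, (kingdoms[0],), "kingdom", config)


def _expand(
    dataset: Dataset, taxon_path: Tuple[str, ...], rank: str, config: HierarchyConfig
) -> HierarchyNode:
    records = _records_under(dataset, taxon_path)
    species = _species_names(records)
    prefix = _node_prefix(taxon_path, rank)

    if rank == config.deepest_routing_rank:
        return _leaf(f"{prefix}2s", taxon_path, rank, species)

    child_rank = RANKS[RANKS.index(rank) + 1]
    groups: Dict[str, List[SeqRecord]] = {}
    for r in records:
        groups.setdefault(r.lineage.name_at(child_rank), []).append(r)
    big = sorted(t for t, recs in groups.items() if _size(recs, config.threshold_unit) >= config.group_threshold)
    small = sorted(set(groups) - set(big))

    if not big:
        # Nothing left to route: direct species-level classification.
        return _leaf(f"{prefix}2s", taxon_path, rank, species)

    letter = RANK_LETTERS[child_rank]
    children: Dict[str, HierarchyNode] = {}
    class_labels = list(big)
    other_species_labels: Dict[str, str] = {}
    for taxon in big:
        children[taxon] = _expand(dataset, taxon_path + (taxon,), child_rank, config)
    if small:
        small_records = [r for t in small for r in groups[t]]
        small_species = sorted(_species_names(small_records))
        other_base = (
            f"other_{letter}2s" if rank == "kingdom"
            else f"{prefix}_other_{letter}2s"
        )
        chunks = _chunk_species(small_species, config.max_leaf_classes)
        for i, chunk in enumerate(chunks):
            if len(chunks) == 1:
                label, leaf_name = OTHER_LABEL, other_base
            else:
                label = f"{OTHER_LABEL}{i + 1}"
                leaf_name = other_base.replace("other_", f"other{i + 1}_")
            class_labels.append(label)
            children[label] = _leaf(
                leaf_name, taxon_path, rank, frozenset(chunk), small=frozenset(small)
            )
            for sp in chunk:
                other_species_labels[sp] = label

    return HierarchyNode(
        name=f"{prefix}2{letter}",
        taxon_path=taxon_path,
        rank_from=rank,
        target_rank=child_rank,
        class_labels=class_labels,
        is_leaf=False,
        species_set=species,
        children=children,
        small_taxa=frozenset(small),
        other_species_labels=other_species_labels,
    )


def _leaf(
    name: str,
    taxon_path: Tuple[str, ...],
    rank: str,
    species: frozenset,
    small: frozenset = frozenset(),
) -> HierarchyNode:
    return HierarchyNode(
        name=name,
        taxon_path=taxon_path,
        rank_from=rank,
        target_rank="species",
        class_labels=sorted(species),
        is_leaf=True,
        species_set=species,
        small_taxa=small,
    )


def _chunk_species(species: List[str], max_leaf_classes: Optional[int]) -> List[List[str]]:
    if max_leaf_classes is None or len(species) <= max_leaf_classes:
        return [species]
    n_chunks = math.ceil(len(species) / max_leaf_classes)
    size = math.ceil(len(species) / n_chunks)
    return [species[i : i + size] for i in range(0, len(species), size)]


def node_label(record: SeqRecord, node: HierarchyNode) -> str:
    """The training label of ``record`` at ``node``: a child taxon name, an
    "Other…" label, or (at a leaf) the species name."""
    if not record.lineage.startswith(node.taxon_path):
        raise ValueError(
            f"record {record.id!r} is not under node {node.name!r} "
            f"(path {node.taxon_path})"
        )
    if node.is_leaf:
        return record.lineage.species
    child = record.lineage.name_at(node.target_rank)
    if child in node.children:
        return child
    if child in node.small_taxa:
        return node.other_species_labels[record.lineage.species]
    raise ValueError(
        f"record {record.id!r}: taxon {child!r} unknown at node {node.name!r}"
    )
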