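"""Knowledge triples, weighted knowledge networks, and network analytics.

A knowledge triple is two normalized entities plus a label for their
underlying relationship, with provenance (document, sentence position,
character spans).  A knowledge network is the undirected graph over the
entities that take part in at least one triple: one node per normalized
(label, type), one edge per unordered label pair.  Edge weight is document
frequency — the number of distinct documents in which the pair is related —
and edges are classed GREY (seen in a single document) or BLACK (seen in
more than one), the convention used when plotting these networks.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .annotate import EntityType, RelationMention
from .normalize import Normalizer

__all__ = [
    "KnowledgeTriple",
    "KnowledgeNetwork",
    "NetworkSummary",
    "SetComparison",
    "TriplesParseError",
    "EntityTypeConflictError",
    "TRIPLE_COLUMNS",
    "to_triples",
    "write_triples_csv",
    "read_triples_csv",
    "build_network",
    "summarize",
    "first_order_neighbors",
    "centroid",
    "compare_first_order",
    "export_cytoscape",
    "export_sif",
]

GREY = "GREY"
BLACK = "BLACK"

TRIPLE_COLUMNS = (
    "relationship_id",
    "relation_type",
    "subject_mention",
    "subject_label",
    "subject_type",
    "object_mention",
    "object_label",
    "object_type",
    "doc_id",
    "sentence_position",
    "source_pos",
    "target_pos",
)


class TriplesParseError(ValueError):
    """Raised on malformed triple CSV rows (carries the line number)."""


class EntityTypeConflictError(ValueError):
    """Raised when one normalized label is used with two entity types."""


@dataclass(frozen=True)
class KnowledgeTriple:
    relationship_id: str
    relation_type: str
    subject_mention: str
    subject_label: str
    subject_type: EntityType
    object_mention: str
    object_label: str
    object_type: EntityType
    doc_id: str
    sentence_position: int
    source_pos: str
    target_pos: str

    def __post_init__(self) -> None:
        if self.subject_label == self.object_label:
            raise ValueError(
                f"triple {self.relationship_id!r} joins a label with itself"
            )


def to_triples(
    relations: Sequence[RelationMention], normalizer: Normalizer
) -> list[KnowledgeTriple]:
    """Normalize relation endpoints into triples.

    Relations whose endpoints normalize to the same label (e.g. two forms
    of one gene family collapsing onto the family name) are dropped —
    self-loops carry no network information.  Output preserves input order.
    """
    triples: list[KnowledgeTriple] = []
    for rel in relations:
        subject_label = normalizer(rel.source.preferred_label)
        object_label = normalizer(rel.target.preferred_label)
        if subject_label == object_label:
            continue
        triples.append(
            KnowledgeTriple(
                relationship_id=rel.relation_id,
                relation_type=rel.relation_type,
                subject_mention=rel.source.surface,
                subject_label=subject_label,
                subject_type=rel.source.entity_type,
                object_mention=rel.target.surface,
                object_label=object_label,
                object_type=rel.target.entity_type,
                doc_id=rel.source.doc_id,
                sentence_position=rel.source.sentence_index,
                source_pos=f"{rel.source.start}-{rel.source.end}",
                target_pos=f"{rel.target.start}-{rel.target.end}",
            )
        )
    return triples


def write_triples_csv(
    triples: Sequence[KnowledgeTriple], path: str | Path
) -> None:
    """Write triples with the exact canonical column order."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(TRIPLE_COLUMNS)
        for t in triples:
            writer.writerow(
                [
                    t.relationship_id,
                    t.relation_type,
                    t.subject_mention,
                    t.subject_label,
                    t.subject_type.value,
                    t.object_mention,
                    t.object_label,
                    t.object_type.value,
                    t.doc_id,
                    t.sentence_position,
                    t.source_pos,
                    t.target_pos,
                ]
            )


def read_triples_csv(path: str | Path) -> list[KnowledgeTriple]:
    """Read a triple CSV; malformed rows raise with their line number."""
    triples: list[KnowledgeTriple] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        header = next(reader, None)
        if header is None or tuple(header) != TRIPLE_COLUMNS:
            raise TriplesParseError(
                f"{path}:1: header does not match {TRIPLE_COLUMNS}"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(TRIPLE_COLUMNS):
                raise TriplesParseError(
                    f"{path}:{line_no}: expected {len(TRIPLE_COLUMNS)} fields, "
                    f"got {len(row)}"
                )
            try:
                triples.append(
                    KnowledgeTriple(
                        relationship_id=row[0],
                        relation_type=row[1],
                        subject_mention=row[2],
                        subject_label=row[3],
                        subject_type=EntityType(row[4]),
                        object_mention=row[5],
                        object_label=row[6],
                        object_type=EntityType(row[7]),
                        doc_id=row[8],
                        sentence_position=int(row[9]),
                        source_pos=row[10],
                        target_pos=row[11],
                    )
                )
            except ValueError as exc:
                raise TriplesParseError(f"{path}:{line_no}: {exc}") from None
    return triples


class KnowledgeNetwork:
    """Undirected co-occurrence network over normalized entities.

    Thin wrapper around a :class:`networkx.Graph`; nodes carry an
    ``entity_type`` attribute, edges carry ``doc_ids``, ``relation_types``,
    ``weight`` (document frequency) and ``color_class``.
    """

    def __init__(self, graph: Optional[nx.Graph] = None) -> None:
        self.graph = graph if graph is not None else nx.Graph()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def labels(self) -> set[str]:
        return set(self.graph.nodes)

    def entity_type(self, label: str) -> EntityType:
        return self.graph.nodes[label]["entity_type"]

    def has_label(self, label: str) -> bool:
        return label in self.graph

    def __contains__(self, label: str) -> bool:
        return label in self.graph

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"KnowledgeNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass(frozen=True)
class NetworkSummary:
    """Node/edge counts, overall and per entity type."""

    n_nodes: int
    n_edges: int
    nodes_by_type: Mapping[EntityType, int]

    def __post_init__(self) -> None:
        if self.n_nodes != sum(self.nodes_by_type.values()):
            raise ValueError(
                "n_nodes must equal the sum of the per-type node counts"
            )


@dataclass(frozen=True)
class SetComparison:
    """Label sets A and B plus their difference A \\ B."""

    set_a: frozenset[str]
    set_b: frozenset[str]
    difference: frozenset[str]

    def __post_init__(self) -> None:
        if self.difference != self.set_a - self.set_b:
            raise ValueError("difference must equal set_a minus set_b")


def build_network(
    triples: Sequence[KnowledgeTriple],
    weight_by_mentions: bool = False,
) -> KnowledgeNetwork:
    """Aggregate triples into a knowledge network.

    Only entities with at least one relationship become nodes; multiple
    relation types between the same label pair collapse onto one edge that
    carries the type set.  ``weight_by_mentions`` switches the edge weight
    from document frequency (default) to raw mention-pair counts; the
    GREY/BLACK class always follows the displayed weight.
    """
    types: dict[str, EntityType] = {}
    conflicts: list[str] = []

    def register(label: str, etype: EntityType) -> None:
        previous = types.get(label)
        if previous is None:
            types[label] = etype
        elif previous is not etype:
            conflicts.append(
                f"{label!r}: {previous.value} vs {etype.value}"
            )

    edges: dict[tuple[str, str], dict] = {}
    for t in triples:
        register(t.subject_label, t.subject_type)
        register(t.object_label, t.object_type)
        key = tuple(sorted((t.subject_label, t.object_label)))
        data = edges.setdefault(
            key, {"doc_ids": set(), "relation_types": set(), "mentions": 0}
        )
        data["doc_ids"].add(t.doc_id)
        data["relation_types"].add(t.relation_type)
        data["mentions"] += 1
    if conflicts:
        raise EntityTypeConflictError(
            "labels with conflicting entity types: " + "; ".join(sorted(set(conflicts)))
        )

    graph = nx.Graph()
    for (u, v), data in edges.items():
        weight = data["mentions"] if weight_by_mentions else len(data["doc_ids"])
        graph.add_node(u, entity_type=types[u])
        graph.add_node(v, entity_type=types[v])
        graph.add_edge(
            u,
            v,
            doc_ids=frozenset(data["doc_ids"]),
            relation_types=frozenset(data["relation_types"]),
            weight=weight,
            color_class=GREY if weight == 1 else BLACK,
        )
    return KnowledgeNetwork(graph)


def summarize(network: KnowledgeNetwork) -> NetworkSummary:
    counts = {etype: 0 for etype in EntityType}
    for _, data in network.graph.nodes(data=True):
        counts[data["entity_type"]] += 1
    return NetworkSummary(
        n_nodes=network.n_nodes,
        n_edges=network.n_edges,
        nodes_by_type=counts,
    )


def first_order_neighbors(
    network: KnowledgeNetwork, focus_labels: Iterable[str]
) -> set[tuple[str, EntityType]]:
    """Union of the direct neighbors of the focus labels (focus excluded)."""
    focus = set(focus_labels)
    present = focus & network.labels()
    if not present:
        raise KeyError(
            f"none of the focus labels {sorted(focus)} occur in the network"
        )
    neighbors: set[str] = set()
    for label in present:
        neighbors.update(network.graph.neighbors(label))
    neighbors -= focus
    return {(label, network.entity_type(label)) for label in neighbors}


def centroid(network: KnowledgeNetwork) -> tuple[str, int]:
    """Node with the most distinct first-order neighbors.

    Ties break to the lexicographically smallest label so the result is
    deterministic.
    """
    if network.n_nodes == 0:
        raise ValueError("centroid of an empty network is undefined")
    best = min(
        ((-network.graph.degree(label), label) for label in network.graph.nodes),
    )
    return best[1], -best[0]


def compare_first_order(
    network_a: KnowledgeNetwork,
    network_b: KnowledgeNetwork,
    focus_labels: Iterable[str],
) -> SetComparison:
    """Compare first-order neighbor label sets of two networks.

    Focus labels missing from ``network_b`` entirely yield an empty set B
    (the comparison is then just set A).
    """
    focus = set(focus_labels)
    set_a = frozenset(label for label, _ in first_order_neighbors(network_a, focus))
    if focus & network_b.labels():
        set_b = frozenset(
            label for label, _ in first_order_neighbors(network_b, focus)
        )
    else:
        set_b = frozenset()
    return SetComparison(set_a=set_a, set_b=set_b, difference=set_a - set_b)


def export_cytoscape(
    network: KnowledgeNetwork,
    edge_path: str | Path,
    node_path: str | Path,
) -> None:
    """Write edge and node CSVs suitable for Cytoscape import.

    Rows are sorted, sets are ";"-joined sorted, so repeated exports of the
    same network are byte-identical.
    """
    edge_rows = []
    for u, v, data in network.graph.edges(data=True):
        source, target = sorted((u, v))
        edge_rows.append(
            [
                source,
                target,
                ";".join(sorted(data["relation_types"])),
                data["weight"],
                data["color_class"],
                ";".join(sorted(data["doc_ids"])),
            ]
        )
    edge_rows.sort(key=lambda r: (r[0], r[1]))
    with open(edge_path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(
            ["source", "target", "relation_types", "weight", "color_class", "doc_ids"]
        )
        writer.writerows(edge_rows)

    node_rows = sorted(
        (label, data["entity_type"].value)
        for label, data in network.graph.nodes(data=True)
    )
    with open(node_path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["label", "entity_type"])
        writer.writerows(node_rows)


def export_sif(network: KnowledgeNetwork, path: str | Path) -> None:
    """Simple interaction format: ``source<TAB>relation<TAB>target``."""
    rows = []
    for u, v, data in network.graph.edges(data=True):
        source, target = sorted((u, v))
        for rel in sorted(data["relation_types"]):
            rows.append((source, rel, target))
    rows.sort()
    with open(path, "w", encoding="utf-8") as handle:
        for source, rel, target in rows:
            handle.write(f"{source}\t{rel}\t{target}\n")
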