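"""Time-resolved proximity analysis over cumulative yearly knowledge networks.

The idea: build one knowledge network per year y from *all* documents
published up to y (so the yearly series is nested — each network is a
subgraph of the next), pick a set of trait nodes that collectively stand
for the trait of interest (the "flesh color nodes" in the potato use
case), and track, for every entity that eventually becomes a direct
neighbor of that trait set, its unweighted shortest-path distance to the
nearest trait node in every year.  A node's distance can only decrease as
the corpus accumulates; the year its distance first reaches 1 is its
"transition year" — the moment the literature first states the association
outright, often years after the network already placed the node in close
proximity (distance 2).

Distances are hop counts; document-frequency edge weights play no role in
path length.  A cell is ABSENT (rendered ``x``) when the node is not yet
in that year's network or has no path to any trait node.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .annotate import Lexicon, annotate_corpus
from .corpus_io import Corpus, subset_by_year
from .normalize import Normalizer
from .triples_network import (
    KnowledgeNetwork,
    build_network,
    first_order_neighbors,
    to_triples,
)

__all__ = [
    "ABSENT",
    "DEFAULT_FLESH_LABELS",
    "FleshNodeSet",
    "YearlySeries",
    "DistanceTable",
    "TransitionReport",
    "LabelTransitions",
    "YearDiff",
    "MasterTableParseError",
    "MonotonicityWarning",
    "build_series",
    "eventual_direct_neighbors",
    "distance_table",
    "detect_transitions",
    "year_diff",
    "write_master_table",
    "read_master_table",
    "write_year_diff_csv",
    "lead_time",
]

logger = logging.getLogger(__name__)

#: Sentinel for "node absent from the network or unreachable from every
#: flesh color node"; rendered as ``x`` in master tables.
ABSENT = None

#: The ten trait labels that collectively stand for potato tuber flesh
#: color in the reference use case.
DEFAULT_FLESH_LABELS = (
    "COLOR",
    "FLESH",
    "FLESH COLOR",
    "FLESH TRAIT",
    "ORANGE FLESH COLOR",
    "TUBER COLOR",
    "TUBER FLESH",
    "TUBER FLESH COLOR",
    "WHITE FLESH COLOR",
    "YELLOW-ORANGE FLESH COLOR",
)


class MasterTableParseError(ValueError):
    """Raised on malformed master-table cells (carries row/column)."""


class MonotonicityWarning(UserWarning):
    """An externally supplied table row has an increasing distance."""


@dataclass(frozen=True)
class FleshNodeSet:
    """Non-empty set of normalized trait labels standing for one trait."""

    labels: frozenset[str]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("flesh node set must be non-empty")

    @classmethod
    def of(cls, *labels: str) -> "FleshNodeSet":
        return cls(labels=frozenset(labels))


@dataclass(frozen=True)
class YearlySeries:
    """Cumulative networks keyed by year; later years are supersets."""

    years: tuple[int, ...]
    networks: Mapping[int, KnowledgeNetwork]

    def __post_init__(self) -> None:
        if tuple(sorted(self.years)) != self.years:
            raise ValueError("years must be sorted ascending")
        missing = [y for y in self.years if y not in self.networks]
        if missing:
            raise ValueError(f"missing networks for years {missing}")

    @property
    def final_year(self) -> int:
        return self.years[-1]

    @property
    def final_network(self) -> KnowledgeNetwork:
        return self.networks[self.final_year]


class DistanceTable:
    """Tracked-node × year matrix of shortest-path distances to a trait set."""

    def __init__(
        self,
        tracked_labels: Sequence[str],
        years: Sequence[int],
        cells: Mapping[tuple[str, int], Optional[int]],
    ) -> None:
        self.tracked_labels = tuple(tracked_labels)
        self.years = tuple(years)
        self._cells = {
            (label, year): cells.get((label, year), ABSENT)
            for label in self.tracked_labels
            for year in self.years
        }

    def get(self, label: str, year: int) -> Optional[int]:
        return self._cells[(label, year)]

    def row(self, label: str) -> list[Optional[int]]:
        return [self._cells[(label, year)] for year in self.years]

    def is_monotone(self) -> bool:
        """True iff every row, once numeric, stays numeric and non-increasing."""
        for label in self.tracked_labels:
            previous: Optional[int] = None
            for value in self.row(label):
                if previous is not None:
                    if value is ABSENT or value > previous:
                        return False
                if value is not ABSENT:
                    previous = value
        return True

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DistanceTable):
            return NotImplemented
        return (
            self.tracked_labels == other.tracked_labels
            and self.years == other.years
            and self._cells == other._cells
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"DistanceTable({len(self.tracked_labels)} labels x "
            f"{len(self.years)} years)"
        )


@dataclass(frozen=True)
class LabelTransitions:
    """Per-label transition years extracted from a distance table."""

    label: str
    first_year_observed: Optional[int]
    first_year_within: Mapping[int, Optional[int]]
    direct_year: Optional[int]


@dataclass(frozen=True)
class TransitionReport:
    """Transition years for every tracked label of a distance table."""

    ks: tuple[int, ...]
    per_label: Mapping[str, LabelTransitions]

    def __getitem__(self, label: str) -> LabelTransitions:
        return self.per_label[label]


def build_series(
    corpus: Corpus,
    lexicon: Lexicon,
    triggers: Optional[Mapping[str, str]],
    normalizer: Normalizer,
    years: Sequence[int],
) -> YearlySeries:
    """One cumulative network per requested year.

    Each network is built from the documents published up to that year,
    run through the full annotate → normalize → triple → network pipeline.
    """
    years = tuple(years)
    if tuple(sorted(years)) != years:
        raise ValueError("years must be sorted ascending")
    networks: dict[int, KnowledgeNetwork] = {}
    for year in years:
        sub = subset_by_year(corpus, year)
        _, relations = annotate_corpus(sub, lexicon, triggers)
        triples = to_triples(relations, normalizer)
        networks[year] = build_network(triples)
    return YearlySeries(years=years, networks=networks)


def eventual_direct_neighbors(
    series: YearlySeries, flesh: FleshNodeSet
) -> set[str]:
    """Labels directly connected to a flesh node in the final year's network."""
    final = series.final_network
    if not (flesh.labels & final.labels()):
        raise KeyError(
            f"no flesh color label {sorted(flesh.labels)} in the final network"
        )
    return {
        label
        for label, _ in first_order_neighbors(final, flesh.labels)
    }


def _min_distances_to(
    network: KnowledgeNetwork, sources: Iterable[str]
) -> dict[str, int]:
    """Minimum hop count from any source label to every reachable node."""
    best: dict[str, int] = {}
    for source in sources:
        if source not in network:
            continue
        lengths = nx.single_source_shortest_path_length(network.graph, source)
        for node, dist in lengths.items():
            if node not in best or dist < best[node]:
                best[node] = dist
    return best


def distance_table(
    series: YearlySeries,
    tracked: Iterable[str],
    flesh: FleshNodeSet,
) -> DistanceTable:
    """Shortest-path distance of each tracked node to the nearest flesh node,
    per year.

    Tracked labels must exist in the final network.  A tracked label that
    is itself a flesh label is dropped with a warning — its distance would
    trivially be zero.
    """
    tracked_list = []
    for label in tracked:
        if label in flesh.labels:
            logger.warning(
                "tracked label %r is a flesh color node; dropping it", label
            )
            continue
        tracked_list.append(label)
    final_labels = series.final_network.labels()
    missing = [t for t in tracked_list if t not in final_labels]
    if missing:
        raise KeyError(
            f"tracked labels missing from the final network: {sorted(missing)}"
        )
    cells: dict[tuple[str, int], Optional[int]] = {}
    for year in series.years:
        network = series.networks[year]
        dist = _min_distances_to(network, flesh.labels)
        for label in tracked_list:
            cells[(label, year)] = dist.get(label, ABSENT)
    return DistanceTable(tracked_list, series.years, cells)


def detect_transitions(
    table: DistanceTable, ks: Sequence[int] = (1, 2)
) -> TransitionReport:
    """First year each tracked label comes within k hops of the trait set.

    ``direct_year`` is the k=1 case (always computed).  Labels that never
    reach a threshold report ``None`` for it.
    """
    ks = tuple(ks)
    if any(k < 1 for k in ks):
        raise ValueError("thresholds must be positive")
    all_ks = tuple(sorted(set(ks) | {1}))
    per_label: dict[str, LabelTransitions] = {}
    for label in table.tracked_labels:
        first_observed: Optional[int] = None
        first_within: dict[int, Optional[int]] = {k: None for k in all_ks}
        for year in table.years:
            value = table.get(label, year)
            if value is ABSENT:
                continue
            if first_observed is None:
                first_observed = year
            for k in all_ks:
                if value <= k and first_within[k] is None:
                    first_within[k] = year
        per_label[label] = LabelTransitions(
            label=label,
            first_year_observed=first_observed,
            first_year_within={k: first_within[k] for k in ks},
            direct_year=first_within[1],
        )
    return TransitionReport(ks=ks, per_label=per_label)


@dataclass(frozen=True)
class YearDiff:
    """Distance changes between two consecutive years.

    ``changes`` holds one row per (tracked label, individual flesh node)
    whose distance changed: (tracked_label, flesh_label, old, new).
    """

    from_year: int
    to_year: int
    changes: tuple[tuple[str, str, Optional[int], Optional[int]], ...]

    def __post_init__(self) -> None:
        if self.to_year != self.from_year + 1:
            raise ValueError("year diff must span consecutive years")


def year_diff(
    series: YearlySeries,
    tracked: Iterable[str],
    flesh: FleshNodeSet,
    to_year: int,
) -> YearDiff:
    """Per-flesh-node distance changes from ``to_year - 1`` to ``to_year``."""
    from_year = to_year - 1
    if to_year not in series.years or from_year not in series.years:
        raise ValueError(
            f"both {from_year} and {to_year} must be in the series years"
        )
    tracked_list = sorted(set(tracked) - flesh.labels)
    changes = []
    old_net = series.networks[from_year]
    new_net = series.networks[to_year]
    for flesh_label in sorted(flesh.labels):
        old_d = _min_distances_to(old_net, [flesh_label])
        new_d = _min_distances_to(new_net, [flesh_label])
        for label in tracked_list:
            old = old_d.get(label, ABSENT)
            new = new_d.get(label, ABSENT)
            if old != new:
                changes.append((label, flesh_label, old, new))
    return YearDiff(from_year=from_year, to_year=to_year, changes=tuple(changes))


def write_year_diff_csv(diff: YearDiff, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(
            ["from_year", "to_year", "tracked_label", "flesh_label", "old", "new"]
        )
        for label, flesh_label, old, new in diff.changes:
            writer.writerow(
                [
                    diff.from_year,
                    diff.to_year,
                    label,
                    flesh_label,
                    "x" if old is ABSENT else old,
                    "x" if new is ABSENT else new,
                ]
            )


def write_master_table(table: DistanceTable, path: str | Path) -> None:
    """Master table CSV: ``node,<year1>,...,<yearN>``, ``x`` for absence."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["node"] + [str(y) for y in table.years])
        for label in table.tracked_labels:
            writer.writerow(
                [label]
                + ["x" if v is ABSENT else str(v) for v in table.row(label)]
            )


def read_master_table(path: str | Path) -> DistanceTable:
    """Parse a master table CSV.

    Cells must be positive integers or ``x``; anything else raises
    :class:`MasterTableParseError` with its row and column.  Rows whose
    distances increase over time violate the cumulative-corpus model; the
    input being external, these are reported as :class:`MonotonicityWarning`
    rather than errors.
    """
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        header = next(reader, None)
        if header is None or header[0] != "node":
            raise MasterTableParseError(f"{path}:1: header must start with 'node'")
        try:
            years = [int(y) for y in header[1:]]
        except ValueError:
            raise MasterTableParseError(
                f"{path}:1: year columns must be integers"
            ) from None
        tracked: list[str] = []
        cells: dict[tuple[str, int], Optional[int]] = {}
        for row_no, row in enumerate(reader, start=2):
            if not row:
                continue
            label = row[0]
            if len(row) != len(years) + 1:
                raise MasterTableParseError(
                    f"{path}:{row_no}: expected {len(years) + 1} fields, "
                    f"got {len(row)}"
                )
            tracked.append(label)
            for col, (year, cell) in enumerate(zip(years, row[1:]), start=2):
                cell = cell.strip()
                if cell == "x":
                    cells[(label, year)] = ABSENT
                    continue
                try:
                    value = int(cell)
                except ValueError:
                    raise MasterTableParseError(
                        f"{path}:{row_no}:{col}: cell {cell!r} is neither a "
                        "positive integer nor 'x'"
                    ) from None
                if value < 1:
                    raise MasterTableParseError(
                        f"{path}:{row_no}:{col}: distance must be positive, "
                        f"got {value}"
                    )
                cells[(label, year)] = value
    table = DistanceTable(tracked, years, cells)
    if not table.is_monotone():
        warnings.warn(
            f"{path}: some rows have increasing or lapsing distances over time",
            MonotonicityWarning,
            stacklevel=2,
        )
    return table


def lead_time(proximity_year: int, evidence_year: int) -> int:
    """Years by which network proximity anticipated explicit evidence.

    Both anchor years are caller-supplied: ``proximity_year`` is typically
    the last year a node sat at distance 2 (or its transition year), and
    ``evidence_year`` the publication year of the experimental evidence.
    """
    return evidence_year - proximity_year
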