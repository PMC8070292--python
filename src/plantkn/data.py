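"""Packaged reference data for the potato tuber flesh color use case.

Two small transcribed reference tables ship with the package:

* ``flesh_color_neighbor_sets.csv`` — the first-order neighbors of the
  tuber flesh-color trait nodes in a knowledge network built from 34
  full-text potato articles (Set A), the same for abstracts only (Set B),
  and the printed difference column (Set A − Set B).
* ``flesh_color_distance_table.csv`` — the master distance table of the
  time analysis on a 4023-abstract Solanaceae corpus: 21 eventual direct
  neighbors of the flesh color nodes × years 2000–2016, each cell the
  shortest-path distance at the time to the nearest flesh color node
  (``x`` = absent/unreachable).

Also packaged: a synonym table covering every entity named in those
tables, a small demonstration lexicon, and the default trigger table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .annotate import Lexicon, RelationRegistry
from .normalize import SynonymTable
from .time_analysis import DistanceTable, read_master_table

__all__ = [
    "NeighborSets",
    "load_neighbor_sets",
    "load_reference_distance_table",
    "load_reference_synonyms",
    "load_demo_lexicon",
    "load_default_triggers",
]


@dataclass(frozen=True)
class NeighborSets:
    """The three transcribed neighbor-set columns, in printed order.

    Note: the tabulation's narrative claims 20 entries in the difference
    column, but the transcribed columns contain |A| = 38, |B| = 17 and
    |A − B| = 21 — which is exactly consistent as set arithmetic.  The
    transcription preserves the columns as printed and flags, rather than
    resolves, the narrative discrepancy.
    """

    set_a: tuple[str, ...]
    set_b: tuple[str, ...]
    difference: tuple[str, ...]


def _data_path(name: str):
    return resources.files("plantkn").joinpath("data", name)


def load_neighbor_sets() -> NeighborSets:
    columns: dict[str, list[str]] = {"set_a": [], "set_b": [], "set_a_minus_set_b": []}
    with _data_path("flesh_color_neighbor_sets.csv").open(
        newline="", encoding="utf-8"
    ) as handle:
        reader = csv.DictReader(handle)
        for row in reader:
            for key in columns:
                value = (row.get(key) or "").strip()
                if value:
                    columns[key].append(value)
    return NeighborSets(
        set_a=tuple(columns["set_a"]),
        set_b=tuple(columns["set_b"]),
        difference=tuple(columns["set_a_minus_set_b"]),
    )


def load_reference_distance_table() -> DistanceTable:
    with resources.as_file(_data_path("flesh_color_distance_table.csv")) as path:
        return read_master_table(path)


def load_reference_synonyms() -> SynonymTable:
    with resources.as_file(_data_path("synonyms_flesh_color.tsv")) as path:
        return SynonymTable.from_tsv(path)


def load_demo_lexicon() -> Lexicon:
    rows = []
    with _data_path("lexicon_flesh_color.tsv").open(
        newline="", encoding="utf-8"
    ) as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if row and not row[0].startswith("#"):
                rows.append((row[0], row[1], row[2]))
    return Lexicon.from_rows(rows)


def load_default_triggers(
    registry: RelationRegistry = RelationRegistry(),
) -> dict[str, str]:
    triggers: dict[str, str] = {}
    with _data_path("triggers_default.tsv").open(
        newline="", encoding="utf-8"
    ) as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[1] not in registry:
                raise ValueError(f"trigger type {row[1]!r} not in registry")
            triggers[row[0].strip().lower()] = row[1].strip()
    return triggers
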