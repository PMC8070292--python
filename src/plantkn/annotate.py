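"""Dictionary-based NER and within-sentence relation extraction.

The type system is deliberately small: three entity classes
(gene/protein — merged because the literature uses them interchangeably —
metabolite, and trait) and a registry of exactly seven relation classes.
Most extracted relations carry the generic ``RELATED_TO`` label; trigger
keywords found between two mentions upgrade the label (``encodes``,
``part of``).  Relations are only ever formed between mentions of the same
sentence — co-reference across sentences is out of scope.

Matching is case-insensitive and token-boundary aware.  Tokens are runs of
alphanumerics glued by internal hyphens and apostrophes, and by commas or
periods between digits, so hyphen/digit-rich metabolite names like
``lutein-5,6-epoxide`` behave as single token sequences and ``carotene``
does not match inside ``beta-carotene-like``.  Among overlapping candidate
matches the leftmost-longest wins.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .corpus_io import Corpus, Sentence, segment_sentences, DEFAULT_ABBREVIATIONS

__all__ = [
    "EntityType",
    "RelationRegistry",
    "DEFAULT_RELATIONS",
    "RELATED_TO",
    "Lexicon",
    "LexiconError",
    "EntityMention",
    "RelationMention",
    "load_lexicon",
    "load_triggers",
    "token_spans",
    "find_mentions",
    "extract_relations",
    "annotate_corpus",
    "write_mentions_tsv",
    "write_relations_tsv",
]


class EntityType(str, Enum):
    """The closed three-class entity system."""

    GENE_PROTEIN = "GENE_PROTEIN"
    METABOLITE = "METABOLITE"
    TRAIT = "TRAIT"


RELATED_TO = "RELATED_TO"

#: The seven-relation registry.  RELATED_TO is the catch-all co-occurrence
#: label; ENCODES and PART_OF are upgraded by trigger keywords; the four
#: GENERIC_* slots are configurable placeholders that never fire unless a
#: trigger table maps keywords onto them.
DEFAULT_RELATIONS = (
    RELATED_TO,
    "ENCODES",
    "PART_OF",
    "GENERIC_1",
    "GENERIC_2",
    "GENERIC_3",
    "GENERIC_4",
)


@dataclass(frozen=True)
class RelationRegistry:
    """Closed registry of exactly seven relation type names."""

    names: tuple[str, ...] = DEFAULT_RELATIONS

    def __post_init__(self) -> None:
        if len(self.names) != 7:
            raise ValueError(f"relation registry must have 7 entries, got {len(self.names)}")
        if len(set(self.names)) != 7:
            raise ValueError("relation registry entries must be distinct")
        if RELATED_TO not in self.names:
            raise ValueError(f"{RELATED_TO!r} must be in the relation registry")

    def __contains__(self, name: str) -> bool:
        return name in self.names


class LexiconError(ValueError):
    """Raised on malformed or conflicting lexicon tables."""


@dataclass(frozen=True)
class Lexicon:
    """Case-folded surface form → (preferred label, entity type)."""

    entries: Mapping[str, tuple[str, EntityType]]

    @classmethod
    def from_rows(
        cls, rows: Iterable[tuple[str, str, str]]
    ) -> "Lexicon":
        entries: dict[str, tuple[str, EntityType]] = {}
        for surface, preferred, type_name in rows:
            key = surface.strip().lower()
            if not key:
                raise LexiconError("empty surface form in lexicon")
            try:
                etype = EntityType(type_name.strip())
            except ValueError:
                raise LexiconError(
                    f"invalid entity type {type_name!r} for surface {surface!r}"
                ) from None
            previous = entries.get(key)
            if previous is not None and previous[1] is not etype:
                raise LexiconError(
                    f"surface {key!r} maps to conflicting entity types "
                    f"{previous[1].value} and {etype.value}"
                )
            entries[key] = (preferred.strip(), etype)
        return cls(entries=entries)

    def surfaces(self) -> list[str]:
        return sorted(self.entries)

    def preferred_labels(self) -> frozenset[str]:
        return frozenset(label for label, _ in self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class EntityMention:
    """A typed span within one sentence (offsets are sentence-relative)."""

    doc_id: str
    sentence_index: int
    start: int
    end: int
    surface: str
    entity_type: EntityType
    preferred_label: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("mention span must be non-empty")


@dataclass(frozen=True)
class RelationMention:
    """A typed pair of mentions from the same sentence."""

    relation_id: str
    relation_type: str
    source: EntityMention
    target: EntityMention

    def __post_init__(self) -> None:
        if (
            self.source.doc_id != self.target.doc_id
            or self.source.sentence_index != self.target.sentence_index
        ):
            raise ValueError("relation endpoints must share a sentence")
        if self.source.preferred_label == self.target.preferred_label:
            raise ValueError("relation endpoints must have distinct labels")


def load_lexicon(*paths: str | Path) -> Lexicon:
    """Load lexicon TSVs: ``surface<TAB>preferred_label<TAB>entity_type``."""
    rows = []
    for path in paths:
        with open(path, newline="", encoding="utf-8") as handle:
            for line_no, row in enumerate(csv.reader(handle, delimiter="\t"), 1):
                if not row or row[0].startswith("#"):
                    continue
                if len(row) < 3:
                    raise LexiconError(
                        f"{path}:{line_no}: expected surface<TAB>label<TAB>type"
                    )
                rows.append((row[0], row[1], row[2]))
    return Lexicon.from_rows(rows)


def load_triggers(
    path: str | Path, registry: RelationRegistry = RelationRegistry()
) -> dict[str, str]:
    """Load trigger TSV ``keyword<TAB>relation_type``, validated vs registry."""
    triggers: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as handle:
        for line_no, row in enumerate(csv.reader(handle, delimiter="\t"), 1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{line_no}: expected keyword<TAB>type")
            keyword, rel_type = row[0].strip().lower(), row[1].strip()
            if rel_type not in registry:
                raise ValueError(
                    f"{path}:{line_no}: relation type {rel_type!r} not in registry"
                )
            triggers[keyword] = rel_type
    return triggers


_ALNUM_RE = re.compile(r"[^\W_]+", re.UNICODE)  # letters (any script) + digits


def token_spans(text: str) -> list[tuple[int, int]]:
    """Token spans: alphanumeric runs merged across internal connectors.

    Hyphens and apostrophes glue neighbouring runs unconditionally; commas
    and periods glue only when flanked by digits (decimal/locant notation).
    """
    runs = [m.span() for m in _ALNUM_RE.finditer(text)]
    merged: list[tuple[int, int]] = []
    for start, end in runs:
        if merged and merged[-1][1] + 1 == start:
            gap = text[merged[-1][1]]
            if gap in "-'’" or (
                gap in ".,"
                and text[merged[-1][1] - 1].isdigit()
                and text[start].isdigit()
            ):
                merged[-1] = (merged[-1][0], end)
                continue
        merged.append((start, end))
    return merged


def find_mentions(sentence: Sentence, lexicon: Lexicon) -> list[EntityMention]:
    """Locate all lexicon surfaces in a sentence.

    Case-insensitive; matches must begin at a token start and end at a
    token end; overlapping candidates are resolved leftmost-longest (equal
    length: earlier start wins).  Returned mentions are non-overlapping and
    ordered by start offset.
    """
    text = sentence.text
    low = text.lower()
    spans = token_spans(text)
    starts = {s for s, _ in spans}
    ends = {e for _, e in spans}

    candidates: list[tuple[int, int, str, EntityType]] = []
    for surface, (label, etype) in lexicon.entries.items():
        pos = low.find(surface)
        while pos != -1:
            end = pos + len(surface)
            if pos in starts and end in ends:
                candidates.append((pos, end, label, etype))
            pos = low.find(surface, pos + 1)

    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0]), c[2]))
    mentions: list[EntityMention] = []
    cursor = 0
    for start, end, label, etype in candidates:
        if start >= cursor:
            mentions.append(
                EntityMention(
                    doc_id=sentence.doc_id,
                    sentence_index=sentence.index,
                    start=start,
                    end=end,
                    surface=text[start:end],
                    entity_type=etype,
                    preferred_label=label,
                )
            )
            cursor = end
    return mentions


def _trigger_type(
    gap_text: str, triggers: Mapping[str, str]
) -> str:
    """Relation type from the first trigger found in the inter-mention gap.

    Longest keywords are tried first (then alphabetically) so that a
    multiword trigger is not shadowed by one of its words.
    """
    low = gap_text.lower()
    for keyword in sorted(triggers, key=lambda k: (-len(k), k)):
        if re.search(
            rf"(?<![0-9a-z]){re.escape(keyword)}(?![0-9a-z])", low
        ):
            return triggers[keyword]
    return RELATED_TO


def extract_relations(
    mentions: Sequence[EntityMention],
    sentence: Sentence,
    triggers: Optional[Mapping[str, str]] = None,
) -> list[RelationMention]:
    """All-pairs co-occurrence relations among one sentence's mentions.

    One relation per unordered pair of mentions with distinct preferred
    labels (self-loop suppression); the relation type is upgraded from
    ``RELATED_TO`` when a trigger keyword occurs between the two spans.
    Relation ids are deterministic: ``<doc>.s<sentence>.r<ordinal>``.
    """
    triggers = triggers or {}
    for m in mentions:
        if m.doc_id != sentence.doc_id or m.sentence_index != sentence.index:
            raise ValueError(
                f"mention {m.surface!r} does not belong to sentence "
                f"{sentence.doc_id}#{sentence.index}"
            )
    ordered = sorted(mentions, key=lambda m: m.start)
    relations: list[RelationMention] = []
    ordinal = 0
    for i, first in enumerate(ordered):
        for second in ordered[i + 1 :]:
            if first.preferred_label == second.preferred_label:
                continue
            gap = sentence.text[first.end : second.start]
            relations.append(
                RelationMention(
                    relation_id=(
                        f"{sentence.doc_id}.s{sentence.index}.r{ordinal}"
                    ),
                    relation_type=_trigger_type(gap, triggers),
                    source=first,
                    target=second,
                )
            )
            ordinal += 1
    return relations


def annotate_corpus(
    corpus: Corpus,
    lexicon: Lexicon,
    triggers: Optional[Mapping[str, str]] = None,
    abbreviations: Iterable[str] = DEFAULT_ABBREVIATIONS,
) -> tuple[list[EntityMention], list[RelationMention]]:
    """Segment, match and pair over a whole corpus, in corpus order.

    Mentions without any relation are retained in the mention list; they
    simply never reach the network stage, where only related entities
    become nodes.
    """
    all_mentions: list[EntityMention] = []
    all_relations: list[RelationMention] = []
    for doc in corpus:
        for sentence in segment_sentences(doc, abbreviations):
            mentions = find_mentions(sentence, lexicon)
            all_mentions.extend(mentions)
            if len(mentions) > 1:
                all_relations.extend(
                    extract_relations(mentions, sentence, triggers)
                )
    return all_mentions, all_relations


_MENTION_COLUMNS = (
    "doc_id",
    "sentence_index",
    "start",
    "end",
    "surface",
    "entity_type",
    "preferred_label",
)

_RELATION_COLUMNS = (
    "relation_id",
    "relation_type",
    "doc_id",
    "sentence_index",
    "source_label",
    "source_start",
    "source_end",
    "target_label",
    "target_start",
    "target_end",
)


def write_mentions_tsv(
    mentions: Sequence[EntityMention], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_MENTION_COLUMNS)
        for m in mentions:
            writer.writerow(
                [
                    m.doc_id,
                    m.sentence_index,
                    m.start,
                    m.end,
                    m.surface,
                    m.entity_type.value,
                    m.preferred_label,
                ]
            )


def write_relations_tsv(
    relations: Sequence[RelationMention], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_RELATION_COLUMNS)
        for r in relations:
            writer.writerow(
                [
                    r.relation_id,
                    r.relation_type,
                    r.source.doc_id,
                    r.source.sentence_index,
                    r.source.preferred_label,
                    r.source.start,
                    r.source.end,
                    r.target.preferred_label,
                    r.target.start,
                    r.target.end,
                ]
            )
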