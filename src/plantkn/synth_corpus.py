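"""Synthetic yearly corpora with planted relations and a known answer key.

The generator emulates the structure the time analysis assumes: yearly
batches of short documents whose sentences mention dictionary entities,
with pairwise relations planted on a known emergence schedule.  Everything
the pipeline should recover is computable in closed form from the schedule
— in particular the expected tracked-node × year distance table, produced
by an independent breadth-first search on the cumulative planted edge set
(plain dict/set BFS, deliberately not sharing any code with the pipeline's
networkx path).

Distractor sentences carry at most one entity, so they can never create a
relation and the planted graph stays exactly controllable.  ``noise_rate``
optionally injects off-schedule random pair sentences; extra edges can
only shorten paths, so recovered transition years are never later than the
planted ones.  Surfaces include normalization stressors (species prefixes,
Greek letters, gene-family digits) that the dictionary and synonym table
resolve back to canonical labels.
"""

from __future__ import annotations

import random
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import csv

from .annotate import (
    EntityType,
    Lexicon,
    RELATED_TO,
)
from .corpus_io import Corpus, Document
from .evaluation import GoldAnnotation
from .normalize import Normalizer, SynonymTable
from .time_analysis import ABSENT, DistanceTable

__all__ = [
    "PlantedEvent",
    "PlantedSchedule",
    "GeneratorConfig",
    "GoldRelation",
    "SyntheticBundle",
    "GeneratorConfigError",
    "GENERATOR_ENTITIES",
    "generate",
    "expected_distances",
    "write_bundle",
    "read_schedule_tsv",
]


class GeneratorConfigError(ValueError):
    """Raised on invalid generator configuration or schedules."""


#: Canonical label -> (entity type, surface variants).  Variants include
#: species-prefixed, Greek-letter and family-digit forms so generated text
#: stresses matching and normalization.
GENERATOR_ENTITIES: dict[str, tuple[EntityType, tuple[str, ...]]] = {
    "ZEAXANTHIN EPOXIDASE": (
        EntityType.GENE_PROTEIN,
        ("zeaxanthin epoxidase", "ZEP", "StZEP"),
    ),
    "BETA-CAROTENE HYDROXYLASE": (
        EntityType.GENE_PROTEIN,
        ("beta-carotene hydroxylase", "BCH1", "BCH2"),
    ),
    "PHYTOENE SYNTHASE": (EntityType.GENE_PROTEIN, ("phytoene synthase", "PSY")),
    "AN1": (EntityType.GENE_PROTEIN, ("AN1", "StAN1")),
    "LYCOPENE E-CYCLASE": (EntityType.GENE_PROTEIN, ("lycopene e-cyclase",)),
    "BETA-CAROTENE": (
        EntityType.METABOLITE,
        ("beta-carotene", "b-carotene", "β-carotene"),
    ),
    "ZEAXANTHIN": (EntityType.METABOLITE, ("zeaxanthin",)),
    "VIOLAXANTHIN": (EntityType.METABOLITE, ("violaxanthin",)),
    "CAROTENOID": (EntityType.METABOLITE, ("carotenoid", "carotenoids")),
    "ANTHOCYANIN": (EntityType.METABOLITE, ("anthocyanin",)),
    "LUTEIN": (EntityType.METABOLITE, ("lutein",)),
    "FLESH COLOR": (EntityType.TRAIT, ("flesh color",)),
    "TUBER FLESH COLOR": (EntityType.TRAIT, ("tuber flesh color",)),
    "TUBER COLOR": (EntityType.TRAIT, ("tuber color",)),
}

#: Alias rows resolving short/stressor forms back to canonical labels.
GENERATOR_SYNONYMS: tuple[tuple[str, str, str], ...] = (
    ("ZEP", "ZEAXANTHIN EPOXIDASE", "generator"),
    ("BCH", "BETA-CAROTENE HYDROXYLASE", "generator"),
    ("PSY", "PHYTOENE SYNTHASE", "generator"),
    ("B-CAROTENE", "BETA-CAROTENE", "generator"),
    ("ANTHOCYANIN 1", "AN1", "generator"),
)

DEFAULT_TRIGGERS: dict[str, str] = {"encodes": "ENCODES", "part of": "PART_OF"}

#: Templates keyed by planted relation type.  {A} always precedes {B}; the
#: ENCODES / PART_OF templates contain the matching trigger keyword between
#: the two slots so extraction recovers the planted type.
DEFAULT_TEMPLATES: dict[str, tuple[str, ...]] = {
    RELATED_TO: (
        "In potato tubers, {A} is associated with {B}.",
        "Levels of {A} correlated strongly with {B} in this cultivar.",
        "Analysis suggested that {A} may influence {B} in yellow-fleshed lines.",
    ),
    "ENCODES": ("Our results show that {A} encodes {B}.",),
    "PART_OF": ("It is well established that {A} is part of {B}.",),
}

DISTRACTOR_TEMPLATES: tuple[str, ...] = (
    "The authors additionally measured {X} in several cultivars.",
    "Expression of {X} was quantified across developmental stages.",
)

NO_ENTITY_DISTRACTORS: tuple[str, ...] = (
    "Field trials were repeated over two consecutive seasons.",
    "All measurements were performed in triplicate.",
)

NOISE_TEMPLATE = "Unexpectedly, {A} co-occurred with {B} in one report."


@dataclass(frozen=True)
class PlantedEvent:
    """One scheduled relationship: first stated in ``year``."""

    year: int
    subject_label: str
    relation_type: str
    object_label: str

    def __post_init__(self) -> None:
        if self.subject_label == self.object_label:
            raise GeneratorConfigError(
                f"event in {self.year} relates {self.subject_label!r} to itself"
            )


@dataclass(frozen=True)
class PlantedSchedule:
    """Emergence schedule plus the trait labels standing for the target trait."""

    events: tuple[PlantedEvent, ...]
    flesh_labels: frozenset[str]


@dataclass(frozen=True)
class GeneratorConfig:
    year_range: tuple[int, int] = (2000, 2016)
    docs_per_year: int = 3
    distractor_sentences_per_doc: int = 2
    noise_rate: float = 0.0
    seed: int = 0
    templates: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES)
    )
    distractor_templates: tuple[str, ...] = DISTRACTOR_TEMPLATES

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_rate <= 1.0:
            raise GeneratorConfigError("noise_rate must be within [0, 1]")
        if self.docs_per_year < 0:
            raise GeneratorConfigError("docs_per_year must be >= 0")
        if self.year_range[0] > self.year_range[1]:
            raise GeneratorConfigError("year_range must be increasing")
        for rel_type, templates in self.templates.items():
            for template in templates:
                if "{A}" not in template or "{B}" not in template:
                    raise GeneratorConfigError(
                        f"template {template!r} for {rel_type} must contain "
                        "both {A} and {B} slots"
                    )
                if template.index("{A}") > template.index("{B}"):
                    raise GeneratorConfigError(
                        f"template {template!r}: {{A}} must precede {{B}}"
                    )


@dataclass(frozen=True)
class GoldRelation:
    """Ground-truth relation planted in one sentence."""

    doc_id: str
    sentence_index: int
    source_label: str
    target_label: str
    relation_type: str


@dataclass(frozen=True)
class SyntheticBundle:
    """A generated corpus plus everything needed to check the pipeline."""

    corpus: Corpus
    gold_mentions: tuple[GoldAnnotation, ...]
    gold_relations: tuple[GoldRelation, ...]
    expected_table: DistanceTable
    lexicon: Lexicon
    synonym_table: SynonymTable
    triggers: Mapping[str, str]
    normalizer: Normalizer
    schedule: PlantedSchedule
    config: GeneratorConfig


def _build_lexicon() -> Lexicon:
    rows = []
    for label, (etype, surfaces) in GENERATOR_ENTITIES.items():
        for surface in surfaces:
            rows.append((surface, label, etype.value))
    return Lexicon.from_rows(rows)


@dataclass
class _SentencePlan:
    text: str
    mentions: list[tuple[int, int, str, EntityType]]
    relation: Optional[tuple[str, str, str]]  # (subject, target, type)


def _realize_pair(
    template: str,
    surface_a: str,
    surface_b: str,
) -> tuple[str, tuple[int, int], tuple[int, int]]:
    ia = template.index("{A}")
    ib = template.index("{B}")
    pre = template[:ia]
    mid = template[ia + 3 : ib]
    post = template[ib + 3 :]
    text = pre + surface_a + mid + surface_b + post
    span_a = (len(pre), len(pre) + len(surface_a))
    start_b = len(pre) + len(surface_a) + len(mid)
    span_b = (start_b, start_b + len(surface_b))
    return text, span_a, span_b


def _pair_plan(
    rng: random.Random,
    subject: str,
    target: str,
    rel_type: str,
    templates: Mapping[str, tuple[str, ...]],
) -> _SentencePlan:
    options = templates.get(rel_type)
    if not options:
        raise GeneratorConfigError(
            f"no sentence template for relation type {rel_type!r}"
        )
    template = rng.choice(options)
    type_a, surfaces_a = GENERATOR_ENTITIES[subject]
    type_b, surfaces_b = GENERATOR_ENTITIES[target]
    surface_a = rng.choice(surfaces_a)
    surface_b = rng.choice(surfaces_b)
    text, span_a, span_b = _realize_pair(template, surface_a, surface_b)
    return _SentencePlan(
        text=text,
        mentions=[
            (span_a[0], span_a[1], subject, type_a),
            (span_b[0], span_b[1], target, type_b),
        ],
        relation=(subject, target, rel_type),
    )


def generate(config: GeneratorConfig, schedule: PlantedSchedule) -> SyntheticBundle:
    """Generate a corpus realizing the schedule, with gold and answer key.

    Deterministic under (config, schedule): all sampling flows from one
    seeded generator.  Each event is realized as at least one template
    sentence in a document of its year; distractors never relate entities.
    """
    for event in schedule.events:
        for label in (event.subject_label, event.object_label):
            if label not in GENERATOR_ENTITIES:
                raise GeneratorConfigError(
                    f"schedule label {label!r} not in the generator lexicon"
                )
        if not config.year_range[0] <= event.year <= config.year_range[1]:
            raise GeneratorConfigError(
                f"event year {event.year} outside range {config.year_range}"
            )
    for label in schedule.flesh_labels:
        if label not in GENERATOR_ENTITIES:
            raise GeneratorConfigError(
                f"flesh label {label!r} not in the generator lexicon"
            )

    rng = random.Random(config.seed)
    years = list(range(config.year_range[0], config.year_range[1] + 1))
    events_by_year: dict[int, list[PlantedEvent]] = {}
    for event in schedule.events:
        events_by_year.setdefault(event.year, []).append(event)

    all_labels = sorted(GENERATOR_ENTITIES)
    documents: list[Document] = []
    gold_mentions: list[GoldAnnotation] = []
    gold_relations: list[GoldRelation] = []
    noise_events: list[PlantedEvent] = []

    for year in years:
        year_events = events_by_year.get(year, [])
        n_docs = config.docs_per_year
        if n_docs == 0 and year_events:
            n_docs = 1
        for d in range(n_docs):
            doc_id = f"Y{year}D{d:02d}"
            plans: list[_SentencePlan] = []
            for i, event in enumerate(year_events):
                if i % n_docs == d:
                    plans.append(
                        _pair_plan(
                            rng,
                            event.subject_label,
                            event.object_label,
                            event.relation_type,
                            config.templates,
                        )
                    )
            if config.noise_rate and rng.random() < config.noise_rate:
                a, b = rng.sample(all_labels, 2)
                plans.append(
                    _pair_plan(
                        rng, a, b, RELATED_TO, {RELATED_TO: (NOISE_TEMPLATE,)}
                    )
                )
                noise_events.append(PlantedEvent(year, a, RELATED_TO, b))
            for _ in range(config.distractor_sentences_per_doc):
                if rng.random() < 0.6:
                    label = rng.choice(all_labels)
                    etype, surfaces = GENERATOR_ENTITIES[label]
                    surface = rng.choice(surfaces)
                    template = rng.choice(config.distractor_templates)
                    idx = template.index("{X}")
                    text = template.replace("{X}", surface)
                    plans.append(
                        _SentencePlan(
                            text=text,
                            mentions=[(idx, idx + len(surface), label, etype)],
                            relation=None,
                        )
                    )
                else:
                    plans.append(
                        _SentencePlan(
                            text=rng.choice(NO_ENTITY_DISTRACTORS),
                            mentions=[],
                            relation=None,
                        )
                    )
            rng.shuffle(plans)
            documents.append(
                Document(
                    doc_id=doc_id,
                    year=year,
                    text=" ".join(plan.text for plan in plans),
                )
            )
            for index, plan in enumerate(plans):
                for start, end, label, etype in plan.mentions:
                    gold_mentions.append(
                        GoldAnnotation(
                            doc_id=doc_id,
                            sentence_index=index,
                            start=start,
                            end=end,
                            entity_type=etype,
                        )
                    )
                if plan.relation is not None:
                    subject, target, rel_type = plan.relation
                    gold_relations.append(
                        GoldRelation(
                            doc_id=doc_id,
                            sentence_index=index,
                            source_label=subject,
                            target_label=target,
                            relation_type=rel_type,
                        )
                    )

    lexicon = _build_lexicon()
    synonym_table = SynonymTable(GENERATOR_SYNONYMS)
    normalizer = Normalizer(
        table=synonym_table, known=frozenset(GENERATOR_ENTITIES)
    )
    expected_table = expected_distances(schedule, schedule.flesh_labels, years)

    if noise_events:
        noisy_schedule = PlantedSchedule(
            events=schedule.events + tuple(noise_events),
            flesh_labels=schedule.flesh_labels,
        )
        noisy = expected_distances(
            noisy_schedule, schedule.flesh_labels, years,
            tracked=expected_table.tracked_labels,
        )
        for label in expected_table.tracked_labels:
            for year, planted, with_noise in zip(
                years, expected_table.row(label), noisy.row(label)
            ):
                assert with_noise is not ABSENT or planted is ABSENT, (
                    label,
                    year,
                )
                if planted is not ABSENT and with_noise is not ABSENT:
                    assert with_noise <= planted, (label, year)

    return SyntheticBundle(
        corpus=Corpus(documents),
        gold_mentions=tuple(gold_mentions),
        gold_relations=tuple(gold_relations),
        expected_table=expected_table,
        lexicon=lexicon,
        synonym_table=synonym_table,
        triggers=dict(DEFAULT_TRIGGERS),
        normalizer=normalizer,
        schedule=schedule,
        config=config,
    )


def _bfs_distances(
    adjacency: Mapping[str, set[str]], sources: Iterable[str]
) -> dict[str, int]:
    """Plain breadth-first search from a source set (hand-rolled oracle)."""
    dist: dict[str, int] = {}
    queue: deque[str] = deque()
    for source in sources:
        if source in adjacency and source not in dist:
            dist[source] = 0
            queue.append(source)
    while queue:
        node = queue.popleft()
        for neighbor in adjacency[node]:
            if neighbor not in dist:
                dist[neighbor] = dist[node] + 1
                queue.append(neighbor)
    return dist


def expected_distances(
    schedule: PlantedSchedule,
    flesh_labels: Iterable[str],
    years: Sequence[int],
    tracked: Optional[Sequence[str]] = None,
) -> DistanceTable:
    """Answer key: per-year BFS distances on the cumulative planted edges.

    Tracked labels default to every non-flesh label of the schedule (so the
    key covers nodes that never connect as well as eventual neighbors).
    Independent of the pipeline: adjacency sets and a hand-rolled BFS.
    """
    flesh = set(flesh_labels)
    if tracked is None:
        labels = {e.subject_label for e in schedule.events} | {
            e.object_label for e in schedule.events
        }
        tracked = sorted(labels - flesh)
    cells: dict[tuple[str, int], Optional[int]] = {}
    for year in years:
        adjacency: dict[str, set[str]] = {}
        for event in schedule.events:
            if event.year <= year:
                adjacency.setdefault(event.subject_label, set()).add(
                    event.object_label
                )
                adjacency.setdefault(event.object_label, set()).add(
                    event.subject_label
                )
        dist = _bfs_distances(adjacency, flesh)
        for label in tracked:
            cells[(label, year)] = dist.get(label, ABSENT)
    return DistanceTable(tracked, years, cells)


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> None:
    """Materialize a bundle on disk: corpus dir, metadata, gold, answer key."""
    from .time_analysis import write_master_table

    out = Path(out_dir)
    corpus_dir = out / "corpus"
    corpus_dir.mkdir(parents=True, exist_ok=True)
    for doc in bundle.corpus:
        (corpus_dir / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
    with open(out / "metadata.tsv", "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["doc_id", "year"])
        for doc in bundle.corpus:
            writer.writerow([doc.doc_id, doc.year])
    with open(out / "lexicon.tsv", "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for surface in bundle.lexicon.surfaces():
            label, etype = bundle.lexicon.entries[surface]
            writer.writerow([surface, label, etype.value])
    with open(out / "synonyms.tsv", "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for alias, preferred, source in GENERATOR_SYNONYMS:
            writer.writerow([alias, preferred, source])
    with open(out / "triggers.tsv", "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for keyword, rel_type in sorted(bundle.triggers.items()):
            writer.writerow([keyword, rel_type])
    with open(
        out / "gold_mentions.tsv", "w", newline="", encoding="utf-8"
    ) as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["doc_id", "sentence_index", "start", "end", "entity_type"])
        for g in bundle.gold_mentions:
            writer.writerow(
                [g.doc_id, g.sentence_index, g.start, g.end, g.entity_type.value]
            )
    with open(
        out / "gold_relations.tsv", "w", newline="", encoding="utf-8"
    ) as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["doc_id", "sentence_index", "source_label", "target_label", "relation_type"]
        )
        for r in bundle.gold_relations:
            writer.writerow(
                [
                    r.doc_id,
                    r.sentence_index,
                    r.source_label,
                    r.target_label,
                    r.relation_type,
                ]
            )
    with open(out / "schedule.tsv", "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["year", "subject_label", "relation_type", "object_label"])
        for event in bundle.schedule.events:
            writer.writerow(
                [event.year, event.subject_label, event.relation_type, event.object_label]
            )
    write_master_table(bundle.expected_table, out / "expected_table.csv")


def read_schedule_tsv(
    path: str | Path, flesh_labels: Iterable[str]
) -> PlantedSchedule:
    """Load a schedule TSV: year, subject_label, relation_type, object_label."""
    events = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            events.append(
                PlantedEvent(
                    year=int(row[0]),
                    subject_label=row[1],
                    relation_type=row[2],
                    object_label=row[3],
                )
            )
    return PlantedSchedule(
        events=tuple(events), flesh_labels=frozenset(flesh_labels)
    )
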