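import random

import pytest
from hypothesis import settings

from plantkn.annotate import EntityType, Lexicon, RELATED_TO
from plantkn.corpus_io import Document, Sentence
from plantkn.data import load_demo_lexicon, load_reference_synonyms
from plantkn.normalize import Normalizer
from plantkn.synth_corpus import (
    GENERATOR_ENTITIES,
    GeneratorConfig,
    PlantedEvent,
    PlantedSchedule,
    generate,
)
from plantkn.triples_network import KnowledgeTriple

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_sentence(text, doc_id="d1", index=0, start=0):
    return Sentence(
        doc_id=doc_id, index=index, start=start, end=start + len(text), text=text
    )


def make_document(text, doc_id="d1", year=2000):
    return Document(doc_id=doc_id, year=year, text=text)


def make_triple(
    subject,
    obj,
    subject_type=EntityType.GENE_PROTEIN,
    object_type=EntityType.METABOLITE,
    doc_id="D1",
    relation_type=RELATED_TO,
    relationship_id=None,
    sentence_position=0,
):
    return KnowledgeTriple(
        relationship_id=relationship_id or f"{doc_id}.{subject}-{obj}",
        relation_type=relation_type,
        subject_mention=subject.lower(),
        subject_label=subject,
        subject_type=subject_type,
        object_mention=obj.lower(),
        object_label=obj,
        object_type=object_type,
        doc_id=doc_id,
        sentence_position=sentence_position,
        source_pos="0-1",
        target_pos="2-3",
    )


def random_schedule(rng: random.Random, year_range=(2000, 2006)) -> PlantedSchedule:
    """A small random emergence schedule over the generator's entity set."""
    flesh = frozenset({"FLESH COLOR"})
    non_flesh = sorted(set(GENERATOR_ENTITIES) - flesh)
    relation_types = [RELATED_TO, RELATED_TO, "ENCODES", "PART_OF"]
    events = []
    for _ in range(rng.randint(1, 6)):
        year = rng.randint(*year_range)
        if rng.random() < 0.5:
            subject = rng.choice(non_flesh)
            obj = "FLESH COLOR"
        else:
            subject, obj = rng.sample(non_flesh, 2)
        events.append(
            PlantedEvent(year, subject, rng.choice(relation_types), obj)
        )
    return PlantedSchedule(events=tuple(events), flesh_labels=flesh)


@pytest.fixture(scope="session")
def reference_synonyms():
    return load_reference_synonyms()


@pytest.fixture(scope="session")
def demo_lexicon():
    return load_demo_lexicon()


@pytest.fixture(scope="session")
def reference_normalizer(reference_synonyms, demo_lexicon):
    return Normalizer(
        table=reference_synonyms, known=demo_lexicon.preferred_labels()
    )


@pytest.fixture()
def small_bundle():
    schedule = PlantedSchedule(
        events=(
            PlantedEvent(2001, "ZEAXANTHIN EPOXIDASE", RELATED_TO, "ZEAXANTHIN"),
            PlantedEvent(2003, "ZEAXANTHIN", RELATED_TO, "FLESH COLOR"),
            PlantedEvent(2005, "ZEAXANTHIN EPOXIDASE", "ENCODES", "FLESH COLOR"),
            PlantedEvent(2002, "AN1", RELATED_TO, "ANTHOCYANIN"),
        ),
        flesh_labels=frozenset({"FLESH COLOR"}),
    )
    config = GeneratorConfig(year_range=(2000, 2006), docs_per_year=2, seed=11)
    return generate(config, schedule)
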