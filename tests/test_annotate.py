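"""Dictionary matching, token boundaries and within-sentence relations."""

import pytest
from hypothesis import assume, given, strategies as st

from plantkn.annotate import (
    EntityType,
    Lexicon,
    LexiconError,
    RELATED_TO,
    RelationRegistry,
    annotate_corpus,
    extract_relations,
    find_mentions,
    load_lexicon,
    token_spans,
)
from plantkn.corpus_io import Corpus

from conftest import make_document, make_sentence


def lexicon_of(*rows):
    return Lexicon.from_rows(rows)


GP = EntityType.GENE_PROTEIN.value
MET = EntityType.METABOLITE.value
TRAIT = EntityType.TRAIT.value


class TestLexicon:
    def test_load_from_tsv(self, tmp_path):
        path = tmp_path / "lex.tsv"
        path.write_text(
            "ZEP\tZEAXANTHIN EPOXIDASE\tGENE_PROTEIN\n"
            "zeaxanthin epoxidase\tZEAXANTHIN EPOXIDASE\tGENE_PROTEIN\n"
            "b-carotene\tBETA-CAROTENE\tMETABOLITE\n"
            "beta-carotene\tBETA-CAROTENE\tMETABOLITE\n"
            "flesh color\tFLESH COLOR\tTRAIT\n"
        )
        lexicon = load_lexicon(path)
        assert len(lexicon) == 5
        assert len(lexicon.preferred_labels()) == 3
        # spelling variants share one canonical label
        assert (
            lexicon.entries["b-carotene"][0]
            == lexicon.entries["beta-carotene"][0]
            == "BETA-CAROTENE"
        )

    def test_conflicting_entity_types_rejected(self):
        with pytest.raises(LexiconError, match="conflicting"):
            lexicon_of(("zep", "ZEP", GP), ("ZEP", "X", MET))

    def test_empty_surface_rejected(self):
        with pytest.raises(LexiconError, match="empty"):
            lexicon_of(("", "X", GP))

    def test_invalid_entity_type_rejected(self):
        with pytest.raises(LexiconError, match="invalid entity type"):
            lexicon_of(("zep", "ZEP", "GENE"))


class TestRelationRegistry:
    def test_default_registry_is_seven_with_related_to(self):
        registry = RelationRegistry()
        assert len(registry.names) == 7
        assert RELATED_TO in registry

    @pytest.mark.parametrize(
        "names",
        [
            ("RELATED_TO",) * 7,  # not distinct
            ("A", "B", "C", "D", "E", "F", "G"),  # RELATED_TO missing
            ("RELATED_TO", "A", "B"),  # wrong size
        ],
    )
    def test_invalid_registries_rejected(self, names):
        with pytest.raises(ValueError):
            RelationRegistry(names=names)


class TestTokenSpans:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("lutein-5,6-epoxide", [(0, 18)]),
            ("beta-carotene-like compound", [(0, 18), (19, 27)]),
            ("ZEP, and BCH.", [(0, 3), (5, 8), (9, 12)]),
            ("3',5'-hydroxylase", [(0, 1), (3, 4), (6, 17)]),
        ],
    )
    def test_internal_connectors(self, text, expected):
        assert token_spans(text) == expected


class TestFindMentions:
    lexicon = lexicon_of(
        ("zeaxanthin epoxidase", "ZEAXANTHIN EPOXIDASE", GP),
        ("zeaxanthin", "ZEAXANTHIN", MET),
        ("color", "COLOR", TRAIT),
        ("carotene", "CAROTENE", MET),
    )

    def test_leftmost_longest_wins(self):
        sentence = make_sentence("Zeaxanthin epoxidase controls color.")
        mentions = find_mentions(sentence, self.lexicon)
        assert [(m.surface, m.preferred_label) for m in mentions] == [
            ("Zeaxanthin epoxidase", "ZEAXANTHIN EPOXIDASE"),
            ("color", "COLOR"),
        ]

    def test_no_lexicon_word_means_no_mentions(self):
        assert find_mentions(make_sentence("Nothing relevant here."), self.lexicon) == []

    def test_no_match_inside_hyphenated_token(self):
        sentence = make_sentence("A beta-carotene-like compound appeared.")
        assert [
            m.surface
            for m in find_mentions(sentence, self.lexicon)
            if m.preferred_label == "CAROTENE"
        ] == []

    def test_case_insensitive_with_surface_preserved(self):
        sentence = make_sentence("ZEAXANTHIN accumulates.")
        (mention,) = find_mentions(sentence, self.lexicon)
        assert mention.surface == "ZEAXANTHIN"
        assert mention.preferred_label == "ZEAXANTHIN"

    def test_mentions_never_overlap_and_are_ordered(self):
        sentence = make_sentence(
            "zeaxanthin epoxidase and zeaxanthin change color and color."
        )
        mentions = find_mentions(sentence, self.lexicon)
        for first, second in zip(mentions, mentions[1:]):
            assert first.end <= second.start

    def test_removing_nested_surface_can_split_a_match(self):
        # intended leftmost-longest behaviour: dropping the long surface
        # frees its nested components, so the mention count may rise
        with_long = self.lexicon
        without_long = lexicon_of(
            ("zeaxanthin", "ZEAXANTHIN", MET),
            ("epoxidase", "EPOXIDASE", GP),
        )
        sentence = make_sentence("zeaxanthin epoxidase accumulates.")
        assert len(find_mentions(sentence, with_long)) == 1
        assert len(find_mentions(sentence, without_long)) == 2

    @given(
        st.data(),
        st.lists(
            st.sampled_from(
                ["zep", "bch", "psy", "lut", "vio", "antho"]
            ),
            min_size=1,
            max_size=4,
            unique=True,
        ),
    )
    def test_removing_entries_never_adds_mentions_without_nesting(
        self, data, surfaces
    ):
        # with no surface nested in another, dropping a dictionary entry
        # can only remove matches
        full = lexicon_of(*((s, s.upper(), MET) for s in surfaces))
        words = data.draw(
            st.lists(
                st.sampled_from(surfaces + ["filler", "and", "tuber"]),
                min_size=1,
                max_size=8,
            )
        )
        sentence = make_sentence(" ".join(words))
        full_count = len(find_mentions(sentence, full))
        for removed in surfaces:
            reduced = lexicon_of(
                *((s, s.upper(), MET) for s in surfaces if s != removed)
            )
            assert len(find_mentions(sentence, reduced)) <= full_count


class TestExtractRelations:
    lexicon = lexicon_of(
        ("zep", "ZEP", GP),
        ("bch", "BCH", GP),
        ("zeaxanthin", "ZEAXANTHIN", MET),
        ("flesh color", "FLESH COLOR", TRAIT),
    )

    def test_single_pair_defaults_to_related_to(self):
        sentence = make_sentence("ZEP alters flesh color.")
        mentions = find_mentions(sentence, self.lexicon)
        (relation,) = extract_relations(mentions, sentence)
        assert relation.relation_type == RELATED_TO
        assert relation.source.preferred_label == "ZEP"
        assert relation.target.preferred_label == "FLESH COLOR"

    def test_trigger_between_spans_upgrades_type(self):
        sentence = make_sentence("ZEP encodes zeaxanthin here.")
        mentions = find_mentions(sentence, self.lexicon)
        (relation,) = extract_relations(
            mentions, sentence, {"encodes": "ENCODES"}
        )
        assert relation.relation_type == "ENCODES"

    def test_trigger_outside_gap_does_not_fire(self):
        sentence = make_sentence("encodes ZEP and zeaxanthin.")
        mentions = find_mentions(sentence, self.lexicon)
        (relation,) = extract_relations(
            mentions, sentence, {"encodes": "ENCODES"}
        )
        assert relation.relation_type == RELATED_TO

    def test_three_mentions_make_three_pairs(self):
        sentence = make_sentence("ZEP, BCH and zeaxanthin interact.")
        mentions = find_mentions(sentence, self.lexicon)
        relations = extract_relations(mentions, sentence)
        assert len(relations) == 3
        assert len({r.relation_id for r in relations}) == 3

    def test_same_label_pair_suppressed(self):
        lexicon = lexicon_of(("zep", "ZEP", GP), ("stzep", "ZEP", GP))
        sentence = make_sentence("ZEP and StZEP are alleles.")
        mentions = find_mentions(sentence, lexicon)
        assert len(mentions) == 2
        assert extract_relations(mentions, sentence) == []

    def test_foreign_mention_rejected(self):
        sentence = make_sentence("ZEP alters flesh color.")
        other = make_sentence("BCH too.", index=5)
        mentions = find_mentions(sentence, self.lexicon)
        foreign = find_mentions(other, self.lexicon)
        with pytest.raises(ValueError, match="does not belong"):
            extract_relations(mentions + foreign, sentence)

    def test_relation_ids_are_deterministic(self):
        sentence = make_sentence("ZEP, BCH and zeaxanthin interact.")
        mentions = find_mentions(sentence, self.lexicon)
        first = [r.relation_id for r in extract_relations(mentions, sentence)]
        second = [r.relation_id for r in extract_relations(mentions, sentence)]
        assert first == second == ["d1.s0.r0", "d1.s0.r1", "d1.s0.r2"]


class TestAnnotateCorpus:
    lexicon = TestExtractRelations.lexicon

    def test_one_sentence_two_entities(self):
        corpus = Corpus([make_document("ZEP alters flesh color.")])
        mentions, relations = annotate_corpus(corpus, self.lexicon)
        assert len(mentions) == 2
        assert len(relations) == 1

    def test_entities_split_across_sentences_make_no_relation(self):
        corpus = Corpus(
            [make_document("ZEP is expressed. Flesh color varies.")]
        )
        mentions, relations = annotate_corpus(corpus, self.lexicon)
        assert len(mentions) == 2
        assert relations == []

    def test_empty_corpus(self):
        assert annotate_corpus(Corpus([]), self.lexicon) == ([], [])

    def test_relations_never_join_different_sentences(self, small_bundle):
        _, relations = annotate_corpus(
            small_bundle.corpus, small_bundle.lexicon, small_bundle.triggers
        )
        assert relations  # the planted schedule produces some
        for r in relations:
            assert r.source.doc_id == r.target.doc_id
            assert r.source.sentence_index == r.target.sentence_index
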