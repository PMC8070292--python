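"""Triples, network construction, analytics and exports."""

import random

import pytest
from hypothesis import given, strategies as st

from plantkn.annotate import (
    EntityType,
    Lexicon,
    RELATED_TO,
    extract_relations,
    find_mentions,
)
from plantkn.triples_network import (
    BLACK,
    GREY,
    EntityTypeConflictError,
    NetworkSummary,
    SetComparison,
    TRIPLE_COLUMNS,
    TriplesParseError,
    build_network,
    centroid,
    compare_first_order,
    export_cytoscape,
    export_sif,
    first_order_neighbors,
    read_triples_csv,
    summarize,
    to_triples,
    write_triples_csv,
)

from conftest import make_sentence, make_triple

GP = EntityType.GENE_PROTEIN
MET = EntityType.METABOLITE
TRAIT = EntityType.TRAIT


def relations_from(text, lexicon_rows, triggers=None):
    lexicon = Lexicon.from_rows(lexicon_rows)
    sentence = make_sentence(text)
    return extract_relations(find_mentions(sentence, lexicon), sentence, triggers)


class TestToTriples:
    def test_species_prefix_normalized_in_subject(self, reference_normalizer):
        relations = relations_from(
            "StAN1 regulates anthocyanin levels.",
            [
                ("stan1", "StAN1", GP.value),
                ("anthocyanin", "ANTHOCYANIN", MET.value),
            ],
        )
        (triple,) = to_triples(relations, reference_normalizer)
        assert triple.subject_label == "AN1"
        assert triple.subject_mention == "StAN1"
        assert triple.object_label == "ANTHOCYANIN"

    def test_pair_collapsing_to_one_label_is_dropped(self, reference_normalizer):
        relations = relations_from(
            "BCH1 resembles BCH2 in function.",
            [
                ("bch1", "BCH1", GP.value),
                ("bch2", "BCH2", GP.value),
            ],
        )
        assert len(relations) == 1
        assert to_triples(relations, reference_normalizer) == []

    def test_empty_input(self, reference_normalizer):
        assert to_triples([], reference_normalizer) == []


class TestTriplesCsv:
    def make_many(self, n):
        return [
            make_triple(f"G{i}", f"M{i % 7}", doc_id=f"D{i % 5}", sentence_position=i)
            for i in range(n)
        ]

    def test_three_triples_make_four_lines(self, tmp_path):
        path = tmp_path / "t.csv"
        write_triples_csv(self.make_many(3), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 4
        assert lines[0] == ",".join(TRIPLE_COLUMNS)

    def test_round_trip_identity(self, tmp_path):
        triples = self.make_many(50)
        path = tmp_path / "t.csv"
        write_triples_csv(triples, path)
        assert read_triples_csv(path) == triples

    def test_short_row_reports_line_number(self, tmp_path):
        path = tmp_path / "t.csv"
        write_triples_csv(self.make_many(2), path)
        lines = path.read_text().splitlines()
        lines[2] = ",".join(lines[2].split(",")[:11])  # 11 fields
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TriplesParseError, match=":3:"):
            read_triples_csv(path)

    def test_wrong_header_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("a,b,c\n")
        with pytest.raises(TriplesParseError, match="header"):
            read_triples_csv(path)


class TestBuildNetwork:
    def test_repeated_pair_across_documents_is_black(self):
        triples = [
            make_triple("ZEP", "ZEAXANTHIN", doc_id="D1"),
            make_triple("ZEP", "ZEAXANTHIN", doc_id="D2"),
        ]
        network = build_network(triples)
        data = network.graph.edges["ZEP", "ZEAXANTHIN"]
        assert data["weight"] == 2
        assert data["color_class"] == BLACK
        assert data["doc_ids"] == frozenset({"D1", "D2"})

    def test_single_document_edge_is_grey(self):
        network = build_network([make_triple("ZEP", "ZEAXANTHIN")])
        assert network.graph.edges["ZEP", "ZEAXANTHIN"]["color_class"] == GREY

    def test_chain_has_no_isolated_nodes(self):
        network = build_network(
            [make_triple("A", "B"), make_triple("B", "C", subject_type=MET)]
        )
        assert network.n_nodes == 3
        assert network.n_edges == 2
        assert all(d > 0 for _, d in network.graph.degree)

    def test_same_pair_in_one_document_counts_once(self):
        triples = [
            make_triple("ZEP", "ZEAXANTHIN", doc_id="D1", relationship_id="r1"),
            make_triple("ZEP", "ZEAXANTHIN", doc_id="D1", relationship_id="r2"),
        ]
        assert build_network(triples).graph.edges["ZEP", "ZEAXANTHIN"]["weight"] == 1

    def test_mention_count_weighting_flag(self):
        triples = [
            make_triple("ZEP", "ZEAXANTHIN", doc_id="D1", relationship_id="r1"),
            make_triple("ZEP", "ZEAXANTHIN", doc_id="D1", relationship_id="r2"),
        ]
        network = build_network(triples, weight_by_mentions=True)
        assert network.graph.edges["ZEP", "ZEAXANTHIN"]["weight"] == 2

    def test_relation_types_collapse_to_edge_attribute(self):
        triples = [
            make_triple("ZEP", "ZEAXANTHIN", relation_type=RELATED_TO),
            make_triple("ZEP", "ZEAXANTHIN", relation_type="ENCODES", doc_id="D2"),
        ]
        network = build_network(triples)
        assert network.n_edges == 1
        assert network.graph.edges["ZEP", "ZEAXANTHIN"]["relation_types"] == frozenset(
            {RELATED_TO, "ENCODES"}
        )

    def test_entity_type_conflict_is_a_hard_error(self):
        triples = [
            make_triple("ZEP", "X"),
            make_triple("ZEP", "Y", subject_type=MET),
        ]
        with pytest.raises(EntityTypeConflictError, match="ZEP"):
            build_network(triples)

    @given(st.randoms(use_true_random=False))
    def test_invariant_to_triple_order(self, rng):
        triples = [
            make_triple(f"G{i}", f"M{i % 3}", doc_id=f"D{i % 2}") for i in range(8)
        ]
        base = build_network(triples)
        shuffled = list(triples)
        rng.shuffle(shuffled)
        other = build_network(shuffled)
        assert set(base.graph.nodes) == set(other.graph.nodes)
        assert {
            (tuple(sorted(e)), frozenset(d["doc_ids"]), d["weight"], d["color_class"])
            for *e, d in base.graph.edges(data=True)
        } == {
            (tuple(sorted(e)), frozenset(d["doc_ids"]), d["weight"], d["color_class"])
            for *e, d in other.graph.edges(data=True)
        }

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 6), st.integers(0, 6), st.sampled_from("AB")
            ),
            min_size=0,
            max_size=20,
        )
    )
    def test_structural_invariants_on_random_inputs(self, pairs):
        triples = [
            make_triple(f"N{a}", f"M{b}", doc_id=f"D{doc}")
            for a, b, doc in pairs
        ]
        network = build_network(triples)
        for u, v, data in network.graph.edges(data=True):
            assert u != v
            assert data["weight"] == len(data["doc_ids"]) >= 1
            assert (data["color_class"] == GREY) == (data["weight"] == 1)
        assert all(d > 0 for _, d in network.graph.degree)


class TestSummaryAndNeighbors:
    def star(self, center="X", leaves=("a", "b", "c")):
        return build_network(
            [make_triple(center, leaf, object_type=MET) for leaf in leaves]
        )

    def test_summary_counts_are_consistent(self):
        network = build_network(
            [make_triple("G1", "M1"), make_triple("G2", "T1", object_type=TRAIT)]
        )
        summary = summarize(network)
        assert summary.n_nodes == 4
        assert summary.nodes_by_type[GP] == 2
        assert summary.nodes_by_type[MET] == 1
        assert summary.nodes_by_type[TRAIT] == 1

    def test_empty_network_summary_is_all_zeros(self):
        summary = summarize(build_network([]))
        assert summary.n_nodes == summary.n_edges == 0

    def test_inconsistent_summary_rejected(self):
        with pytest.raises(ValueError):
            NetworkSummary(n_nodes=5, n_edges=1, nodes_by_type={GP: 1, MET: 1, TRAIT: 1})

    def test_star_neighbors(self):
        assert {
            label for label, _ in first_order_neighbors(self.star(), {"X"})
        } == {"a", "b", "c"}

    def test_focus_members_excluded_from_neighbors(self):
        assert {
            label for label, _ in first_order_neighbors(self.star(), {"X", "a"})
        } == {"b", "c"}

    def test_absent_focus_label_is_an_error(self):
        with pytest.raises(KeyError):
            first_order_neighbors(self.star(), {"missing"})

    def test_centroid_of_star_is_its_center(self):
        assert centroid(self.star(leaves=("a", "b", "c", "d", "e"))) == ("X", 5)

    def test_centroid_tie_breaks_lexicographically(self):
        network = build_network(
            [
                make_triple("AAA", "m1"),
                make_triple("AAA", "m2"),
                make_triple("BBB", "m3"),
                make_triple("BBB", "m4"),
            ]
        )
        label, degree = centroid(network)
        assert (label, degree) == ("AAA", 2)

    def test_centroid_of_empty_network_is_an_error(self):
        with pytest.raises(ValueError):
            centroid(build_network([]))

    def test_identical_networks_have_empty_difference(self):
        comparison = compare_first_order(self.star(), self.star(), {"X"})
        assert comparison.difference == frozenset()

    def test_difference_of_disjoint_neighbor_sets(self):
        a = self.star(leaves=("p", "q"))
        b = self.star(leaves=("r",))
        comparison = compare_first_order(a, b, {"X"})
        assert comparison.difference == {"p", "q"}

    def test_focus_absent_from_network_b_gives_empty_set_b(self):
        a = self.star()
        b = build_network([make_triple("Y", "z")])
        comparison = compare_first_order(a, b, {"X"})
        assert comparison.set_b == frozenset()
        assert comparison.difference == comparison.set_a

    def test_set_comparison_invariant_enforced(self):
        with pytest.raises(ValueError):
            SetComparison(
                set_a=frozenset("ab"),
                set_b=frozenset("b"),
                difference=frozenset("abc"),
            )


class TestExports:
    def test_cytoscape_export_shapes_and_colors(self, tmp_path):
        network = build_network(
            [
                make_triple("A", "B", doc_id="D1"),
                make_triple("A", "B", doc_id="D2"),
                make_triple("B", "C", subject_type=MET),
            ]
        )
        edge_path, node_path = tmp_path / "e.csv", tmp_path / "n.csv"
        export_cytoscape(network, edge_path, node_path)
        edge_lines = edge_path.read_text().splitlines()
        assert len(edge_lines) == 3
        assert "BLACK" in edge_lines[1] and "D1;D2" in edge_lines[1]
        assert len(node_path.read_text().splitlines()) == 4

    def test_re_export_is_byte_identical(self, tmp_path):
        network = build_network(
            [make_triple(f"G{i}", f"M{i % 2}", doc_id=f"D{i}") for i in range(6)]
        )
        paths = [(tmp_path / f"e{i}.csv", tmp_path / f"n{i}.csv") for i in (1, 2)]
        for e, n in paths:
            export_cytoscape(network, e, n)
        assert paths[0][0].read_bytes() == paths[1][0].read_bytes()
        assert paths[0][1].read_bytes() == paths[1][1].read_bytes()

    def test_sif_export(self, tmp_path):
        network = build_network([make_triple("A", "B", relation_type="ENCODES")])
        path = tmp_path / "net.sif"
        export_sif(network, path)
        assert path.read_text() == "A\tENCODES\tB\n"


class TestAgainstBruteForceOracle:
    """Neighbor sets and hop distances vs a hand-rolled adjacency/BFS."""

    def random_network(self, seed, max_nodes=50):
        rng = random.Random(seed)
        n = rng.randint(2, max_nodes)
        labels = [f"N{i}" for i in range(n)]
        triples = []
        for _ in range(rng.randint(1, 3 * n)):
            u, v = rng.sample(labels, 2)
            triples.append(
                make_triple(u, v, subject_type=MET, doc_id=f"D{rng.randint(0, 9)}")
            )
        return build_network(triples)

    @staticmethod
    def oracle_adjacency(network):
        adj = {u: set() for u in network.graph.nodes}
        for u, v in network.graph.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    @staticmethod
    def oracle_bfs(adj, source):
        dist = {source: 0}
        frontier = [source]
        while frontier:
            nxt = []
            for node in frontier:
                for nb in adj[node]:
                    if nb not in dist:
                        dist[nb] = dist[node] + 1
                        nxt.append(nb)
            frontier = nxt
        return dist

    @pytest.mark.parametrize("seed", range(20))
    def test_neighbors_and_distances_match_oracle(self, seed):
        import networkx as nx

        network = self.random_network(seed)
        adj = self.oracle_adjacency(network)
        focus = sorted(network.graph.nodes)[0]
        expected = adj[focus]
        got = {label for label, _ in first_order_neighbors(network, {focus})}
        assert got == expected

        oracle = self.oracle_bfs(adj, focus)
        lengths = nx.single_source_shortest_path_length(network.graph, focus)
        assert dict(lengths) == oracle
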