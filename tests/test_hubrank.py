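import networkx as nx
import pytest

import oracles
from mirhub import hubrank, syndata
from mirhub.hubrank import (EnrichmentResult, aggregate_hubs, enrichment_map,
                            score_nodes, set_similarity, term_enrichment, top_k)


def graph(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


class TestScoreNodes:
    def test_mcc_triangle(self):
        t = score_nodes(nx.complete_graph(3), "MCC")
        assert all(v == 2.0 for v in t.scores.values())

    def test_dmnc_triangle(self):
        t = score_nodes(nx.complete_graph(3), "DMNC")
        assert all(v == pytest.approx(1 / 2 ** 1.7) for v in t.scores.values())

    def test_betweenness_path3_unnormalized(self):
        t = score_nodes(nx.path_graph(3), "Betweenness")
        assert t.scores == {0: 0.0, 1: 1.0, 2: 0.0}

    def test_isolated_nodes_score_zero_for_neighborhood_methods(self):
        g = graph([(0, 1)], nodes=[2])
        for method in ("MCC", "DMNC", "MNC", "ClusteringCoefficient"):
            assert score_nodes(g, method).scores[2] == 0.0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            score_nodes(nx.path_graph(3), "PageRank")

    @pytest.mark.parametrize("method", list(hubrank.METHODS) + ["BottleNeck"])
    def test_matches_bruteforce_oracle_on_random_family(self, method):
        """Every scoring method equals its exhaustive oracle on 200 seeded
        random graphs of at most 8 nodes."""
        realizations = 200
        for nodes, edges in oracles.random_graph_family(200, seed=5):
            g = graph(edges, nodes)
            got = score_nodes(g, method, seed=17, epc_realizations=realizations).scores
            if method == "EPC":
                want = oracles.epc(nodes, edges, realizations, seed=17)
            else:
                want = oracles.ORACLES[method](nodes, edges)
            for v in nodes:
                assert got[v] == pytest.approx(want[v], abs=1e-9), (method, edges, v)

    def test_epc_close_to_exact_expectation(self):
        """10,000 seeded percolation draws land within 2% of the exact
        all-subset expectation on a 6-node graph."""
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0), (1, 4)]
        nodes = list(range(6))
        exact = oracles.epc_exact(nodes, edges)
        got = score_nodes(graph(edges), "EPC", seed=42, epc_realizations=10000).scores
        for v in nodes:
            assert abs(got[v] - exact[v]) / exact[v] < 0.02


class TestTopKAndHubs:
    def test_truncates_to_network_size(self):
        t = score_nodes(nx.path_graph(3), "Degree")
        assert len(top_k(t, 10)) == 3

    def test_ties_are_id_sorted(self):
        t = hubrank.NodeScoreTable("Degree", {"b": 1.0, "a": 1.0, "c": 1.0})
        assert top_k(t, 2) == ["a", "b"]

    def test_star_degree_top1_is_center(self):
        t = score_nodes(nx.star_graph(4), "Degree")
        assert top_k(t, 1) == [0]

    def test_occurrence_counting_and_order(self):
        lists = {f"m{i}": (["hub", "x"] if i < 11 else ["y"]) for i in range(12)}
        hubs = aggregate_hubs(lists, n_hubs=3)
        assert hubs[0].node == "hub" and hubs[0].occurrence == 11
        assert [h.node for h in hubs[:2]] == ["hub", "x"]

    def test_invariant_to_list_order(self):
        lists = {"a": ["n1", "n2"], "b": ["n2"], "c": ["n2", "n3"]}
        fwd = aggregate_hubs(lists)
        rev = aggregate_hubs(dict(reversed(list(lists.items()))))
        assert [(h.node, h.occurrence) for h in fwd] == [(h.node, h.occurrence) for h in rev]

    def test_planted_super_hub_ranks_first(self):
        net = syndata.make_bipartite_network(20, 100, 150, 3.0, seed=2)
        lists = {m: top_k(score_nodes(net, m, seed=1), 10) for m in hubrank.METHODS}
        hubs = aggregate_hubs(lists, n_hubs=5)
        # with skew 3 the rank-1 target g0001 collects a dominant share of edges
        assert hubs[0].node == "g0001"
        assert hubs[0].occurrence >= 9


class TestTermEnrichment:
    def test_exact_tail_example(self):
        universe = [f"g{i}" for i in range(10)]
        res = term_enrichment(universe[:3], {"T": universe[:5]}, universe,
                              significant_only=False)
        assert res[0].p_value == pytest.approx(1 / 12)

    def test_term_covering_universe_has_p_one(self):
        universe = [f"g{i}" for i in range(8)]
        res = term_enrichment(universe[:2], {"ALL": universe}, universe,
                              significant_only=False)
        assert res[0].p_value == pytest.approx(1.0)

    def test_disjoint_term_not_reported(self):
        universe = [f"g{i}" for i in range(10)]
        res = term_enrichment(universe[:3], {"T": universe[5:]}, universe,
                              significant_only=False)
        assert res == []          # zero-overlap terms are not tested

    def test_bh_adjusted_monotone_and_above_raw(self):
        universe = [f"g{i}" for i in range(40)]
        ann = {f"T{k}": universe[k:k + 12] for k in range(0, 24, 3)}
        res = term_enrichment(universe[:8], ann, universe, significant_only=False)
        assert all(r.adjusted_p >= r.p_value for r in res)
        by_raw = sorted(res, key=lambda r: r.p_value)
        adj = [r.adjusted_p for r in by_raw]
        assert adj == sorted(adj)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            term_enrichment([], {"T": ["a"]}, ["a"])


class TestEnrichmentMap:
    def test_jaccard_and_overlap_values(self):
        assert set_similarity("ABC", "BCD", "jaccard") == pytest.approx(0.5)
        assert set_similarity("ABC", "BCD", "overlap") == pytest.approx(2 / 3)

    def test_identical_sets_weight_one(self):
        g = enrichment_map({"a": (["x", "y"], 0.01), "b": (["x", "y"], 0.02)})
        assert g["a"]["b"]["weight"] == pytest.approx(1.0)

    def test_disjoint_sets_no_edge(self):
        g = enrichment_map({"a": (["x"], 0.01), "b": (["y"], 0.02)}, cutoff=0.1)
        assert g.number_of_edges() == 0
        assert g.nodes["a"]["size"] == 1
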