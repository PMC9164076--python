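"""Tripartite network construction, centralities, and the double filter."""

import itertools
import math

import networkx as nx
import pandas as pd
import pytest

from netpharm.errors import StructureError
from netpharm.graphs import (
    betweenness_table,
    build_pta,
    centrality_table,
    degree_table,
    hub_from_centrality_tables,
    isolate_hub,
    layer_degree_summary,
    top_fraction_filter,
)
from netpharm.ingest import EdgeList
from netpharm.simulate import SynthConfig, gen_hub_graph, gen_pta_mappings


def brute_force_betweenness(graph: nx.Graph) -> dict:
    """Independent oracle: enumerate all shortest paths between all pairs."""
    n = graph.number_of_nodes()
    bc = {node: 0.0 for node in graph}
    for s, t in itertools.combinations(graph.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for inner in path[1:-1]:
                bc[inner] += 1.0 / len(paths)
    scale = (n - 1) * (n - 2) / 2 if n > 2 else 1.0
    return {node: value / scale for node, value in bc.items()}


class TestBuildPta:
    def test_hand_enumeration(self):
        graph = build_pta([("p1", "t1")], [("t1", "d1"), ("t1", "d2")])
        assert graph.number_of_nodes() == 4
        assert graph.number_of_edges() == 3
        assert graph.degree("t1") == 3
        assert graph.nodes["p1"]["role"] == "pathway"
        assert graph.nodes["d2"]["role"] == "drug"

    def test_empty(self):
        graph = build_pta([], [])
        assert graph.number_of_nodes() == 0

    def test_unlinked_candidates_excluded(self):
        # only entities referenced by a pair become nodes
        graph = build_pta([("p1", "t1")], [("t1", "d1")])
        assert set(graph.nodes) == {"p1", "t1", "d1"}

    def test_layer_clash_raises(self):
        with pytest.raises(StructureError):
            build_pta([("p1", "t1")], [("p1", "d1")])  # p1 in two layers

    def test_study_layer_sizes_give_48_nodes(self):
        pt, td = gen_pta_mappings(7, 11, 30, seed=0)
        graph = build_pta(pt, td)
        assert graph.number_of_nodes() == 48
        roles = nx.get_node_attributes(graph, "role")
        counts = {layer: sum(1 for r in roles.values() if r == layer) for layer in ("pathway", "target", "drug")}
        assert counts == {"pathway": 7, "target": 11, "drug": 30}

    def test_layer_summary_breakdown(self):
        graph = build_pta([("p1", "t1"), ("p2", "t1")], [("t1", "d1")])
        summary = layer_degree_summary(graph)
        assert summary["target"]["max_degree"] == 3
        assert summary["target"]["breakdown"]["t1"] == {"pathway_degree": 2, "drug_degree": 1}


class TestDegreeTable:
    def test_star(self):
        graph = nx.star_graph(4)  # center 0, four leaves
        table = degree_table(graph)
        assert table.set_index("node")["dc"][0] == 4

    def test_empty(self):
        assert len(degree_table(nx.Graph())) == 0

    def test_cycle_handshake(self):
        table = degree_table(nx.cycle_graph(5))
        assert list(table["dc"]) == [2] * 5
        assert table["dc"].sum() == 2 * 5

    def test_handshake_on_generated_graphs(self):
        for seed in range(5):
            graph = nx.gnp_random_graph(12, 0.3, seed=seed)
            assert degree_table(graph)["dc"].sum() == 2 * graph.number_of_edges()


class TestBetweenness:
    def test_path_sole_intermediary(self):
        table = betweenness_table(nx.path_graph(3))
        assert table.set_index("node")["bc"][1] == pytest.approx(1.0)

    def test_complete_graph_all_zero(self):
        table = betweenness_table(nx.complete_graph(4))
        assert (table["bc"] == 0).all()

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_matches_oracle_on_all_connected_graphs(self, n):
        edges_all = list(itertools.combinations(range(n), 2))
        for mask in range(1 << len(edges_all)):
            edges = [e for i, e in enumerate(edges_all) if mask >> i & 1]
            graph = nx.Graph(edges)
            graph.add_nodes_from(range(n))
            if not nx.is_connected(graph):
                continue
            expected = brute_force_betweenness(graph)
            got = betweenness_table(graph).set_index("node")["bc"]
            for node in graph:
                assert got[node] == pytest.approx(expected[node], abs=1e-12)

    def test_matches_oracle_sampled_graphs(self):
        for n, seed in [(6, 0), (6, 1), (7, 2), (7, 3)]:
            graph = nx.gnp_random_graph(n, 0.5, seed=seed)
            expected = brute_force_betweenness(graph)
            got = betweenness_table(graph).set_index("node")["bc"]
            for node in graph:
                assert got[node] == pytest.approx(expected[node], abs=1e-12)


class TestTopFractionFilter:
    def test_published_dc_column_selects_five(self, ppi_table):
        outcome = top_fraction_filter(ppi_table, "dc", 0.30)
        assert outcome.selected_set == {"GRIN2B", "NOS2", "APP", "NOS3", "FYN"}
        assert outcome.cutoff == math.ceil(0.30 * 13) == 4
        assert outcome.boundary_value == 2
        assert outcome.n_zero_excluded == 4

    def test_published_bc_column_isolates_hub(self, subnetwork_table):
        outcome = top_fraction_filter(subnetwork_table, "bc", 0.30)
        assert outcome.selected == ("GRIN2B",)

    def test_hand_ranked(self):
        table = pd.DataFrame({"node": list("ABCDE"), "dc": [5, 4, 3, 2, 1]})
        outcome = top_fraction_filter(table, "dc", 0.3)
        assert outcome.cutoff == 2
        assert outcome.selected == ("A", "B")

    def test_all_zero_warns_empty(self, caplog):
        table = pd.DataFrame({"node": ["A", "B"], "dc": [0, 0]})
        with caplog.at_level("WARNING"):
            outcome = top_fraction_filter(table, "dc", 0.3)
        assert outcome.selected == ()

    def test_boundary_ties_all_or_none(self):
        table = pd.DataFrame({"node": list("ABCDEF"), "dc": [9, 5, 5, 5, 1, 0]})
        outcome = top_fraction_filter(table, "dc", 0.3)  # cutoff 2, boundary 5
        assert outcome.selected_set == {"A", "B", "C", "D"}
        without = top_fraction_filter(table, "dc", 0.3, include_ties=False)
        assert len(without.selected) == 2

    def test_keep_zeros_option(self):
        table = pd.DataFrame({"node": list("ABC"), "dc": [1, 0, 0]})
        kept = top_fraction_filter(table, "dc", 1.0, keep_zeros=True)
        assert kept.selected_set == {"A", "B", "C"}

    def test_downward_closed_in_rank(self):
        for seed in range(10):
            rng = nx.utils.create_random_state(seed)
            values = [int(rng.randint(0, 6)) for _ in range(15)]
            table = pd.DataFrame({"node": [f"N{i}" for i in range(15)], "dc": values})
            outcome = top_fraction_filter(table, "dc", 0.3)
            selected = outcome.selected_set
            metric = dict(zip(table["node"], table["dc"]))
            floor = min((metric[n] for n in selected), default=None)
            for node, value in metric.items():
                if node not in selected and floor is not None:
                    assert value <= floor  # no unselected node beats a selected one
                if floor is not None and value == floor:
                    assert (node in selected) == (value > 0)  # boundary ties all-in


class TestIsolateHub:
    def test_star_center(self):
        edges = frozenset(tuple(sorted(("HUB", f"L{i}"))) for i in range(9))
        result = isolate_hub(EdgeList(edges=edges))
        assert result.hub == ("HUB",)

    def test_two_cliques_bridge(self):
        cfg = SynthConfig(seed=13, clique_sizes=(5, 5), n_isolated=4)
        edge_list, planted = gen_hub_graph(cfg)
        result = isolate_hub(edge_list)
        assert result.hub == (planted,)
        # stage 2 recomputes centralities inside the subnetwork
        assert result.sub_table is not None
        assert set(result.sub_table["node"]) == set(result.stage1.selected)

    def test_from_published_tables(self, ppi_table, subnetwork_table):
        result = hub_from_centrality_tables(ppi_table, subnetwork_table, 0.30)
        assert result.hub == ("GRIN2B",)
        assert result.stage1.selected_set == set(subnetwork_table["node"])

    def test_mismatched_subnetwork_table_rejected(self, ppi_table):
        bad = pd.DataFrame({"node": ["GRIN2B"], "dc": [1], "bc": [1.0]})
        with pytest.raises(StructureError):
            hub_from_centrality_tables(ppi_table, bad, 0.30)

    def test_empty_graph_rejected(self):
        with pytest.raises(StructureError):
            isolate_hub(nx.Graph())

    def test_all_zero_degree_returns_empty_hub(self):
        graph = nx.Graph()
        graph.add_nodes_from(["A", "B"])
        result = isolate_hub(graph)
        assert result.hub == ()
        assert result.stage2 is None
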