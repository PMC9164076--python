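"""Format readers/writers and symbol normalization."""

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpharm.errors import FormatError, MalformedRecordError, SchemaError
from netpharm.ingest import (
    EdgeList,
    ascii_minus,
    normalize_symbol,
    read_edge_list,
    read_gmt,
    read_graphml,
    read_prediction_table,
    read_symbol_list,
    write_edge_list,
    write_gmt,
    write_graphml,
    write_symbol_list,
)


class TestNormalizeSymbol:
    @pytest.mark.parametrize(
        "raw, expected",
        [(" grin2b ", "GRIN2B"), ("NOS3", "NOS3"), ("Sigmar1", "SIGMAR1"), ("\tapp\n", "APP")],
    )
    def test_normalizes(self, raw, expected):
        assert normalize_symbol(raw) == expected

    @pytest.mark.parametrize("raw", ["", "   ", "\t\n"])
    def test_empty_after_trim_is_malformed(self, raw):
        with pytest.raises(MalformedRecordError):
            normalize_symbol(raw)

    @given(st.text(alphabet=st.characters(categories=["Lu", "Ll", "Nd"]), min_size=1))
    @settings(max_examples=100, derandomize=True)
    def test_idempotent(self, raw):
        once = normalize_symbol(raw)
        assert normalize_symbol(once) == once


def test_ascii_minus_variants():
    assert ascii_minus("−6.0") == "-6.0"
    assert float(ascii_minus("−7.3")) == -7.3


class TestPredictionTable:
    def _write(self, tmp_path, text, name="pred.tsv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    def test_exact_duplicates_collapse(self, tmp_path):
        path = self._write(tmp_path, "drug\ttarget\nd1\tNOS3\nd1\tNOS3\nd2\tAPP\n")
        table = read_prediction_table(path, "sea")
        assert len(table.pairs) == 2

    def test_case_variants_collapse_after_normalization(self, tmp_path):
        path = self._write(tmp_path, "drug\ttarget\nd1\tgrin2b\nd1\tGRIN2B\n")
        table = read_prediction_table(path, "sea")
        assert table.pairs == frozenset({("d1", "GRIN2B")})

    def test_header_only_gives_empty_set(self, tmp_path, caplog):
        path = self._write(tmp_path, "drug\ttarget\n")
        with caplog.at_level("WARNING"):
            table = read_prediction_table(path, "sea")
        assert table.pairs == frozenset()
        assert any("empty" in rec.message for rec in caplog.records)

    def test_missing_column_names_it(self, tmp_path):
        path = self._write(tmp_path, "drug\tgene\nd1\tNOS3\n")
        with pytest.raises(SchemaError, match="target"):
            read_prediction_table(path, "sea")

    def test_comma_delimiter_autodetected(self, tmp_path):
        path = self._write(tmp_path, "drug,target\nd1,NOS3\n", "pred.csv")
        assert read_prediction_table(path, "stp").pairs == frozenset({("d1", "NOS3")})

    def test_probability_threshold_filters_rows(self, tmp_path):
        path = self._write(tmp_path, "drug\ttarget\tprob\nd1\tNOS3\t0.9\nd1\tAPP\t0.2\n")
        table = read_prediction_table(path, "stp", probability_col="prob", min_probability=0.5)
        assert table.targets == frozenset({"NOS3"})

    def test_roster_mismatch_raises(self, tmp_path):
        path = self._write(tmp_path, "drug\ttarget\nd9\tNOS3\n")
        with pytest.raises(MalformedRecordError, match="d9"):
            read_prediction_table(path, "sea", roster=["d1", "d2"])


class TestGmt:
    def test_member_count_is_background_size(self, tmp_path):
        members = "\t".join(f"GENE{i}" for i in range(21))
        path = tmp_path / "p.gmt"
        path.write_text(f"hsa00220\tArginine biosynthesis\t{members}\n")
        db = read_gmt(path)
        assert db["hsa00220"].background_size == 21
        assert len(db["hsa00220"].genes) == 21

    def test_size_override_widens_background(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("hsa04080\tNeuroactive\tGRIN2B\tOPRM1\n")
        db = read_gmt(path, size_overrides={"hsa04080": 330})
        assert db["hsa04080"].background_size == 330

    def test_duplicate_id_raises_naming_it(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("pw1\tx\tA\npw1\ty\tB\n")
        with pytest.raises(FormatError, match="pw1"):
            read_gmt(path)

    def test_short_line_raises_with_line_number(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("pw1\tdesc\tA\npw2\tno-members\n")
        with pytest.raises(FormatError, match=":2"):
            read_gmt(path)

    def test_minimal_single_member_line(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("pw1\tdesc\tA\n")
        db = read_gmt(path)
        assert len(db) == 1 and db["pw1"].background_size == 1

    def test_round_trip(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("pw1\tdesc\tB\tA\npw2\tother\tC\n")
        db = read_gmt(path)
        out = tmp_path / "out.gmt"
        write_gmt(db, out)
        again = read_gmt(out)
        assert {e.pathway_id: e.genes for e in again} == {e.pathway_id: e.genes for e in db}


class TestEdgeList:
    def _write(self, tmp_path, text):
        path = tmp_path / "edges.tsv"
        path.write_text(text)
        return path

    def test_undirected_dedup(self, tmp_path):
        path = self._write(tmp_path, "node1\tnode2\nA\tB\nB\tA\n")
        el = read_edge_list(path)
        assert el.edges == frozenset({("A", "B")})

    def test_self_loop_dropped(self, tmp_path, caplog):
        path = self._write(tmp_path, "node1\tnode2\nA\tA\nA\tB\n")
        with caplog.at_level("INFO"):
            el = read_edge_list(path)
        assert el.edges == frozenset({("A", "B")})
        assert any("self-loop" in rec.message for rec in caplog.records)

    def test_confidence_threshold(self, tmp_path):
        path = self._write(
            tmp_path, "node1\tnode2\tcombined_score\nA\tB\t0.2\nA\tC\t0.5\nB\tC\t0.9\n"
        )
        assert len(read_edge_list(path, min_confidence=0.4).edges) == 2

    def test_missing_score_column_means_full_confidence(self, tmp_path):
        path = self._write(tmp_path, "node1\tnode2\nA\tB\n")
        el = read_edge_list(path, min_confidence=0.99)
        assert el.confidence[("A", "B")] == 1.0

    def test_string_scale_scores_normalized(self, tmp_path):
        path = self._write(tmp_path, "node1\tnode2\tcombined_score\nA\tB\t900\n")
        assert read_edge_list(path).confidence[("A", "B")] == pytest.approx(0.9)

    def test_non_numeric_score_raises(self, tmp_path):
        path = self._write(tmp_path, "node1\tnode2\tcombined_score\nA\tB\thigh\n")
        with pytest.raises(FormatError):
            read_edge_list(path)

    def test_round_trip(self, tmp_path):
        el = EdgeList(
            edges=frozenset({("A", "B"), ("B", "C")}),
            confidence={("A", "B"): 0.5, ("B", "C"): 0.75},
        )
        out = tmp_path / "e.tsv"
        write_edge_list(el, out)
        again = read_edge_list(out)
        assert again.edges == el.edges
        assert again.confidence[("B", "C")] == pytest.approx(0.75)

    @given(
        st.lists(
            st.tuples(st.sampled_from("ABCDEFG"), st.sampled_from("ABCDEFG")),
            max_size=30,
        )
    )
    @settings(max_examples=60, derandomize=True)
    def test_never_self_loops_or_duplicates(self, tmp_path_factory, pairs):
        tmp = tmp_path_factory.mktemp("edges")
        lines = "node1\tnode2\n" + "".join(f"{a}\t{b}\n" for a, b in pairs)
        path = tmp / "e.tsv"
        path.write_text(lines)
        el = read_edge_list(path)
        for a, b in el.edges:
            assert a != b
            assert a < b  # canonical orientation => no duplicate unordered pairs


class TestGraphml:
    def test_round_trip_preserves_roles(self, tmp_path):
        graph = nx.Graph()
        graph.add_node("pw1", role="pathway")
        graph.add_node("T1", role="target")
        graph.add_node("d1", role="drug")
        graph.add_node("d2", role="drug")
        graph.add_edges_from([("pw1", "T1"), ("T1", "d1"), ("T1", "d2")])
        path = tmp_path / "g.graphml"
        write_graphml(graph, path)
        again = read_graphml(path)
        assert nx.is_isomorphic(graph, again, node_match=lambda a, b: a["role"] == b["role"])
        assert dict(again.nodes(data="role")) == dict(graph.nodes(data="role"))

    def test_empty_graph_round_trips(self, tmp_path):
        path = tmp_path / "g.graphml"
        write_graphml(nx.Graph(), path)
        assert read_graphml(path).number_of_nodes() == 0

    def test_missing_role_rejected(self, tmp_path):
        graph = nx.Graph()
        graph.add_node("X")
        with pytest.raises(SchemaError):
            write_graphml(graph, tmp_path / "g.graphml")


def test_symbol_list_round_trip(tmp_path):
    path = tmp_path / "targets.txt"
    write_symbol_list(["GRIN2B", "NOS3"], path)
    assert read_symbol_list(path) == ["GRIN2B", "NOS3"]
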