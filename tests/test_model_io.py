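"""Data model, file formats and adjacency construction."""

import warnings

import networkx as nx
import numpy as np
import pytest
from hypothesis import given

from cldsynth import (
    CausalDiagram,
    CldError,
    Edge,
    ParseError,
    SynonymMap,
    SynonymMapError,
    read_diagram,
    to_adjacency,
    write_diagram,
)
from cldsynth.io import read_synonym_map, to_dot, write_synonym_map
from cldsynth.model import label_key, normalize_label, slugify

from conftest import diagram_from_edges, random_digraph, small_diagrams


class TestModel:
    def test_slug_and_label_normalisation(self):
        assert normalize_label("  Fast   Food \n") == "Fast Food"
        assert label_key("Fast  FOOD") == "fast food"
        assert slugify("  Fast   Food ") == "fast_food"

    def test_polarity_must_be_unit_signed(self):
        with pytest.raises(CldError, match="polarity"):
            Edge(source="a", target="b", polarity=2)

    def test_edges_require_declared_endpoints(self):
        d = CausalDiagram("d")
        d.add_variable("a")
        with pytest.raises(CldError, match="not a declared variable"):
            d.add_edge("a", "ghost", 1)

    def test_first_label_casing_wins_per_id(self):
        d = CausalDiagram("d")
        d.add_variable("Sugar Craving")
        d.add_variable("sugar  craving")
        assert d.n_variables == 1
        assert d.variables["sugar_craving"].label == "Sugar Craving"

    def test_self_loop_allowed_with_warning(self):
        d = CausalDiagram("d")
        d.add_variable("a")
        with pytest.warns(UserWarning, match="self-loop"):
            d.add_edge("a", "a", 1)
        assert d.n_edges == 1


class TestCsvEdgelist:
    def test_basic_rows_transcribed(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("source,target,polarity\nA,B,+\nB,C,-\n")
        d = read_diagram(path)
        assert d.n_variables == 3
        assert {(e.source, e.target, e.polarity) for e in d.edges} == {
            ("a", "b", 1),
            ("b", "c", -1),
        }

    def test_header_only_gives_empty_diagram(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("source,target,polarity\n")
        d = read_diagram(path)
        assert d.n_variables == 0 and d.n_edges == 0

    def test_unknown_polarity_token_names_line(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("source,target,polarity\nA,B,+\nB,C,up\n")
        with pytest.raises(ParseError, match="polarity token 'up'.*:3"):
            read_diagram(path)

    def test_short_row_names_line(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("source,target,polarity\nA,B\n")
        with pytest.raises(ParseError, match=":2"):
            read_diagram(path)

    def test_duplicate_rows_deduplicated_with_warning(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("source,target,polarity\nA,B,+\nA,B,+1\n")
        with pytest.warns(UserWarning, match="duplicate edge"):
            d = read_diagram(path)
        assert d.n_edges == 1


class TestJsonAndRoundTrips:
    def test_json_auto_declares_edge_only_variables(self, tmp_path):
        path = tmp_path / "d.json"
        path.write_text(
            '{"diagram_id": "x", "problem": "p", "variables": [],'
            ' "edges": [{"source": "a", "target": "b", "polarity": -1}]}'
        )
        d = read_diagram(path)
        assert d.variables["a"].label == "a"  # label = id when auto-declared
        assert d.n_edges == 1

    @given(d=small_diagrams())
    def test_json_round_trip_is_lossless(self, tmp_path_factory, d):
        path = tmp_path_factory.mktemp("rt") / "d.json"
        write_diagram(d, path)
        assert read_diagram(path).same_structure(d)

    @given(d=small_diagrams())
    def test_csv_round_trip_preserves_all_connected_structure(
        self, tmp_path_factory, d
    ):
        # an edge list cannot carry isolated variables; everything else survives
        path = tmp_path_factory.mktemp("rt") / "d.csv"
        write_diagram(d, path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            back = read_diagram(path)
        incident = {v for e in d.edges for v in (e.source, e.target)}
        assert back.edges == d.edges
        assert back.variables == {
            vid: var for vid, var in d.variables.items() if vid in incident
        }

    def test_graphml_carries_polarity(self, tmp_path):
        d = diagram_from_edges([("a", "b", -1)])
        path = tmp_path / "d.graphml"
        write_diagram(d, path)
        g = nx.read_graphml(path)
        assert g.edges["a", "b"]["polarity"] == -1


class TestDotExport:
    def test_positive_edge_is_solid(self):
        d = diagram_from_edges([("a", "b", 1)])
        assert '"a" -> "b" [style=solid' in to_dot(d)

    def test_inverse_edge_is_dashed(self):
        d = diagram_from_edges([("a", "b", -1)])
        assert "style=dashed" in to_dot(d)

    def test_positions_are_pinned_when_given(self):
        d = diagram_from_edges([("a", "b", 1)])
        out = to_dot(d, positions={"a": (0.0, 0.0), "b": (1.0, 2.0)})
        assert 'pos="1.0000,2.0000!"' in out


class TestAdjacency:
    def test_modes_on_toy_edges(self):
        d = diagram_from_edges([("a", "b", -1)])
        signed, order = to_adjacency(d, mode="signed")
        absolute, _ = to_adjacency(d, mode="absolute")
        assert order == ["a", "b"]
        assert signed.tolist() == [[0, -1], [0, 0]]
        assert absolute.tolist() == [[0, 1], [0, 0]]

    def test_matches_per_edge_lookup_oracle(self, rng):
        d = random_digraph(rng, 6, p=0.4)
        a, order = to_adjacency(d, mode="signed")
        index = {vid: i for i, vid in enumerate(order)}
        lookup = {(e.source, e.target): e.polarity for e in d.edges}
        for s in order:
            for t in order:
                assert a[index[s], index[t]] == lookup.get((s, t), 0)

    @given(small_diagrams())
    def test_nonzero_count_and_deterministic_ordering(self, d):
        a1, o1 = to_adjacency(d, mode="absolute")
        a2, o2 = to_adjacency(d, mode="absolute")
        assert o1 == o2 == sorted(d.variables)
        assert int(np.count_nonzero(a1)) == len({e.key for e in d.edges})
        assert np.array_equal(a1, a2)

    def test_rejects_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            to_adjacency(diagram_from_edges([("a", "b", 1)]), mode="weighted")


class TestSynonymMapIO:
    def test_round_trip(self, tmp_path):
        m = SynonymMap([("proximity to fast food", "fast food access")])
        path = tmp_path / "map.csv"
        write_synonym_map(m, path)
        m2 = read_synonym_map(path)
        assert m2.canonical("Proximity To Fast Food") == "fast food access"

    def test_non_functional_map_rejected(self):
        with pytest.raises(SynonymMapError, match="maps to both"):
            SynonymMap([("x", "a"), ("X ", "b")])

    def test_identity_rows_allowed_and_unmapped_pass_through(self):
        m = SynonymMap([("price", "price")])
        assert m.canonical("price") == "price"
        assert m.canonical("unrelated label") == "unrelated label"
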