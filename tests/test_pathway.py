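"""Pathway parsing, terminal identification, and circuit decomposition."""

import json

import networkx as nx
import pytest

from circact.pathway import (ACTIVATION, INHIBITION, DecompositionError,
                             PathwayError, decompose_circuits,
                             identify_terminals, load_function_annotations,
                             load_pathway, map_effectors_to_functions)
from circact.simulate import generate_synthetic_pathway

from conftest import make_pathway

KGML_DOC = """<?xml version="1.0"?>
<pathway name="path:test01" title="toy kgml">
  <entry id="1" type="gene" name="hsa:10 hsa:11"/>
  <entry id="2" type="gene" name="hsa:20"/>
  <entry id="3" type="gene" name="hsa:30"/>
  <entry id="4" type="group">
    <component id="2"/><component id="3"/>
  </entry>
  <entry id="5" type="compound" name="cpd:C00001"/>
  <relation entry1="1" entry2="4" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
  <relation entry1="4" entry2="2" type="PPrel">
    <subtype name="inhibition" value="--|"/>
  </relation>
  <relation entry1="1" entry2="2" type="GErel">
    <subtype name="expression" value="--&gt;"/>
  </relation>
  <relation entry1="1" entry2="3" type="PPrel">
    <subtype name="binding/association" value="---"/>
  </relation>
</pathway>
"""


class TestLoadPathway:
    def test_native_json_round_trip(self, native_json_file):
        p = load_pathway(native_json_file, "native_json")
        assert set(p.nodes) == {"A", "B", "C"}
        assert p.nodes["B"].node_type == "complex"
        assert p.nodes["B"].genes == ("g2", "g3")
        assert len(p.edges) == 2
        assert all(e.sign == ACTIVATION for e in p.edges)

    def test_edge_to_missing_node_rejected(self, tmp_path):
        doc = {"pathway_id": "bad", "nodes": [{"id": "A", "genes": ["g"]}],
               "edges": [{"source": "A", "target": "Z", "sign": "activation"}]}
        f = tmp_path / "bad.json"
        f.write_text(json.dumps(doc))
        with pytest.raises(PathwayError, match="missing node"):
            load_pathway(f, "native_json")

    def test_malformed_json_names_line(self, tmp_path):
        f = tmp_path / "broken.json"
        f.write_text('{"pathway_id": "x",\n "nodes": [}')
        with pytest.raises(PathwayError, match="line 2"):
            load_pathway(f, "native_json")

    def test_unknown_dialect(self, native_json_file):
        with pytest.raises(PathwayError, match="dialect"):
            load_pathway(native_json_file, "sbml")

    def test_kgml_subtype_mapping_and_groups(self, tmp_path, caplog):
        f = tmp_path / "toy.xml"
        f.write_text(KGML_DOC)
        with caplog.at_level("WARNING"):
            p = load_pathway(f, "kgml")
        # group entry 4 becomes a complex node holding both components' genes
        assert p.nodes["4"].node_type == "complex"
        assert set(p.nodes["4"].genes) == {"hsa:20", "hsa:30"}
        signs = {(e.source, e.target): e.sign for e in p.edges}
        assert signs[("1", "4")] == ACTIVATION
        assert signs[("4", "2")] == INHIBITION
        assert signs[("1", "2")] == ACTIVATION  # "expression" maps to activation
        # unsigned binding/association relation is dropped, with a warning
        assert ("1", "3") not in signs
        assert any("unsigned" in r.message for r in caplog.records)


class TestTerminals:
    def test_chain(self, chain_pathway):
        receptors, effectors = identify_terminals(chain_pathway)
        assert (receptors, effectors) == ({"A"}, {"C"})

    def test_diamond(self, diamond_pathway):
        receptors, effectors = identify_terminals(diamond_pathway)
        assert (receptors, effectors) == ({"A"}, {"D"})

    def test_pure_cycle_has_no_terminals(self):
        p = make_pathway("cyc", {"B": ["g1"], "C": ["g2"]},
                         [("B", "C", "+"), ("C", "B", "+")])
        assert identify_terminals(p) == (set(), set())


def simple_path_nodes(p, r, e):
    """Enumeration oracle: nodes on any simple directed path r -> e."""
    g = p.to_networkx()
    return {n for path in nx.all_simple_paths(g, r, e) for n in path} | (
        {r} if r == e else set())


class TestDecomposition:
    def test_chain_one_circuit(self, chain_pathway):
        canonical, effectors = decompose_circuits(chain_pathway)
        assert len(canonical) == 1 and len(effectors) == 1
        c = canonical[0]
        assert (c.receptor, c.effector) == ("A", "C")
        assert c.member_nodes == frozenset("ABC")
        assert effectors[0].member_nodes == frozenset("ABC")

    def test_two_receptors_one_effector(self):
        p = make_pathway("v", {"A": ["g1"], "B": ["g2"], "C": ["g3"]},
                         [("A", "C", "+"), ("B", "C", "+")])
        canonical, effectors = decompose_circuits(p)
        assert len(canonical) == 2
        assert len(effectors) == 1
        assert effectors[0].member_nodes == frozenset("ABC")
        for c in canonical:
            assert c.member_nodes == simple_path_nodes(p, c.receptor, c.effector)

    def test_diamond_single_pair_circuit(self, diamond_pathway):
        canonical, effectors = decompose_circuits(diamond_pathway)
        assert len(canonical) == 1
        assert canonical[0].member_nodes == frozenset("ABCD")
        assert canonical[0].member_nodes == simple_path_nodes(diamond_pathway, "A", "D")
        assert len(effectors) == 1

    def test_no_terminals_raises(self):
        p = make_pathway("cyc", {"B": ["g1"], "C": ["g2"]},
                         [("B", "C", "+"), ("C", "B", "+")])
        with pytest.raises(DecompositionError, match="cyc"):
            decompose_circuits(p)

    def test_members_match_enumeration_oracle_on_dags(self):
        # pair-based member sets equal the union of simple paths on acyclic
        # pathways (cycle augmentation cannot add anything in a DAG)
        for seed in range(5):
            p = generate_synthetic_pathway(10, seed=seed)
            canonical, _ = decompose_circuits(p)
            assert canonical
            for c in canonical:
                assert c.member_nodes == simple_path_nodes(p, c.receptor, c.effector)

    def test_cycle_attached_to_route_is_kept(self):
        # D hangs off the A->B->C route in a feedback loop: it can reach the
        # effector and is reached from the receptor, so it belongs
        p = make_pathway(
            "loopy", {x: [f"g{x}"] for x in "ABCD"},
            [("A", "B", "+"), ("B", "C", "+"), ("B", "D", "+"), ("D", "B", "-")])
        canonical, _ = decompose_circuits(p)
        (c,) = canonical
        assert c.member_nodes == frozenset("ABCD")
        assert any(e.source == "D" and e.target == "B" for e in c.member_edges)

    def test_effector_union_property_and_determinism(self):
        for seed in (1, 7):
            p = generate_synthetic_pathway(
                14, loop_fraction=0.1, inhibition_fraction=0.3, seed=seed)
            canonical, effectors = decompose_circuits(p)
            by_id = {c.circuit_id: c for c in canonical}
            for ec in effectors:
                union = frozenset().union(
                    *(by_id[cid].member_nodes for cid in ec.canonical_circuit_ids))
                assert ec.member_nodes == union
            again = decompose_circuits(p)
            assert [c.circuit_id for c in again[0]] == [c.circuit_id for c in canonical]
            assert [c.member_nodes for c in again[0]] == [c.member_nodes for c in canonical]


class TestFunctionAnnotations:
    def test_gmt_round_trip(self, tmp_path):
        f = tmp_path / "fun.gmt"
        f.write_text("F1\tdesc one\tG1\tG2\nF2\tdesc two\tG3\n")
        anns = load_function_annotations(f)
        assert [a.function_id for a in anns] == ["F1", "F2"]
        assert anns[0].annotated_genes == frozenset({"G1", "G2"})

    def test_duplicate_ids_rejected(self, tmp_path):
        f = tmp_path / "dup.gmt"
        f.write_text("F1\td\tG1\nF1\td\tG2\n")
        with pytest.raises(PathwayError, match="duplicate"):
            load_function_annotations(f)

    def test_empty_set_skipped_and_empty_file(self, tmp_path, caplog):
        f = tmp_path / "odd.gmt"
        f.write_text("F1\tdesc\t\t\nF2\tdesc\tG9\n")
        with caplog.at_level("WARNING"):
            anns = load_function_annotations(f)
        assert [a.function_id for a in anns] == ["F2"]
        empty = tmp_path / "none.gmt"
        empty.write_text("")
        assert load_function_annotations(empty) == []

    def test_effector_function_mapping(self, chain_pathway):
        from circact.pathway import FunctionAnnotation
        anns = [FunctionAnnotation("F1", "x", frozenset({"gc", "zz"})),
                FunctionAnnotation("F2", "y", frozenset({"nothing"}))]
        mapping = map_effectors_to_functions(chain_pathway, anns)
        assert mapping == {"F1": {"C"}}

    def test_two_effectors_share_function(self):
        p = make_pathway("w", {"A": ["g1"], "B": ["shared"], "C": ["shared", "g3"]},
                         [("A", "B", "+"), ("A", "C", "+")])
        from circact.pathway import FunctionAnnotation
        mapping = map_effectors_to_functions(
            p, [FunctionAnnotation("F", "f", frozenset({"shared"}))])
        assert mapping == {"F": {"B", "C"}}
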