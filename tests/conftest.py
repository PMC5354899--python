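import json
from types import SimpleNamespace

import numpy as np
import pytest

from circact.pathway import (ACTIVATION, INHIBITION, Pathway, PathwayEdge,
                             PathwayNode)


def make_pathway(pid, node_genes, edges, complex_nodes=()):
    """Terse pathway builder: node_genes maps node id -> gene list,
    edges are (source, target, sign) triples with sign '+'/'-'."""
    nodes = {
        nid: PathwayNode(nid, tuple(genes),
                         "complex" if nid in complex_nodes else "plain")
        for nid, genes in node_genes.items()
    }
    pe = [
        PathwayEdge(s, t, ACTIVATION if sign == "+" else INHIBITION)
        for s, t, sign in edges
    ]
    return Pathway(pid, pid, nodes, pe)


def make_circuit(edges, receptors, effector, signs=None):
    """Free-standing circuit object for propagation tests.

    ``edges`` are (source, target) pairs; ``signs`` maps a pair to '-' for
    inhibition (default activation).  Receptors are seeded explicitly so
    arbitrary graphs (not only pathway decompositions) can be exercised.
    """
    signs = signs or {}
    pe = tuple(
        PathwayEdge(s, t, INHIBITION if signs.get((s, t)) == "-" else ACTIVATION)
        for s, t in edges
    )
    nodes = frozenset({n for e in pe for n in (e.source, e.target)} | set(receptors)
                      | {effector})
    return SimpleNamespace(circuit_id="test-circuit", member_nodes=nodes,
                           member_edges=pe, receptors=frozenset(receptors),
                           effector=effector)


def random_dag_circuit(rng, max_nodes=30):
    """Random acyclic circuit with random signs; receptors = in-degree-0 nodes."""
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"n{i}" for i in range(n)]
    edges = []
    for j in range(1, n):
        for i in rng.choice(j, size=min(j, int(rng.integers(1, 3))), replace=False):
            edges.append((names[int(i)], names[j]))
    signs = {e: ("-" if rng.random() < 0.3 else "+") for e in edges}
    targets = {t for _, t in edges}
    receptors = [x for x in names if x not in targets]
    values = {x: float(rng.random()) for x in names}
    return make_circuit(edges, receptors, names[-1], signs), values


@pytest.fixture
def chain_pathway():
    return make_pathway("chain", {"A": ["ga"], "B": ["gb"], "C": ["gc"]},
                        [("A", "B", "+"), ("B", "C", "+")])


@pytest.fixture
def diamond_pathway():
    return make_pathway(
        "diamond", {x: [f"g{x.lower()}"] for x in "ABCD"},
        [("A", "B", "+"), ("A", "C", "+"), ("B", "D", "+"), ("C", "D", "+")])


@pytest.fixture
def native_json_file(tmp_path):
    doc = {
        "pathway_id": "toy", "name": "toy pathway",
        "nodes": [{"id": "A", "genes": ["g1"]},
                  {"id": "B", "genes": ["g2", "g3"], "type": "complex"},
                  {"id": "C", "genes": ["g4"]}],
        "edges": [{"source": "A", "target": "B", "sign": "activation"},
                  {"source": "B", "target": "C", "sign": "activation"}],
    }
    path = tmp_path / "toy.json"
    path.write_text(json.dumps(doc))
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
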