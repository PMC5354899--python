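"""Signaling pathways as directed signed graphs, and their circuit decomposition.

A pathway is a directed graph whose nodes are gene products (a node may hold
several genes: *plain* nodes hold alternative proteins, *complex* nodes hold
the members of a protein complex) and whose edges are signed interactions,
either activations or inhibitions.  Receptors are nodes with no incoming
edges; effectors are nodes with no outgoing edges.  A *canonical circuit* is
the sub-graph carrying signal from one receptor to one effector; an
*effector circuit* is the union of all canonical circuits ending in the same
effector.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

ACTIVATION = "activation"
INHIBITION = "inhibition"

#: default mapping from KGML relation subtypes to edge signs; subtypes absent
#: from this table (e.g. "binding/association") carry no sign and are dropped.
KGML_SUBTYPE_SIGNS: dict[str, str] = {
    "activation": ACTIVATION,
    "expression": ACTIVATION,
    "inhibition": INHIBITION,
    "repression": INHIBITION,
}


class PathwayError(ValueError):
    """Malformed pathway file or invalid pathway structure."""


class DecompositionError(PathwayError):
    """Pathway cannot be decomposed into receptor-effector circuits."""


@dataclass(frozen=True)
class PathwayNode:
    """One pathway node: one or more gene products, plain or complex."""

    node_id: str
    genes: tuple[str, ...]
    node_type: str = "plain"  # "plain" | "complex"

    def __post_init__(self) -> None:
        if not self.genes:
            raise PathwayError(f"node {self.node_id!r} has an empty gene list")
        if self.node_type not in ("plain", "complex"):
            raise PathwayError(
                f"node {self.node_id!r}: unknown node_type {self.node_type!r}"
            )


@dataclass(frozen=True)
class PathwayEdge:
    """Directed signed interaction between two nodes."""

    source: str
    target: str
    sign: str

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, INHIBITION):
            raise PathwayError(
                f"edge {self.source!r}->{self.target!r}: sign must be "
                f"{ACTIVATION!r} or {INHIBITION!r}, got {self.sign!r}"
            )


@dataclass
class Pathway:
    """A directed signed graph of :class:`PathwayNode` and :class:`PathwayEdge`."""

    pathway_id: str
    name: str
    nodes: dict[str, PathwayNode]
    edges: list[PathwayEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.source not in self.nodes or e.target not in self.nodes:
                raise PathwayError(
                    f"pathway {self.pathway_id!r}: edge {e.source!r}->{e.target!r} "
                    "references a missing node"
                )

    @property
    def genes(self) -> set[str]:
        return {g for n in self.nodes.values() for g in n.genes}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(pathway_id=self.pathway_id)
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign)
        return g


@dataclass(frozen=True)
class CanonicalCircuit:
    """Sub-pathway carrying signal from one receptor to one effector.

    Member nodes are every node both reachable from the receptor and able to
    reach the effector; member edges are the edges induced on that set.  This
    keeps convergent parallel branches — which recombine under the
    propagation rule — inside one circuit, and keeps loops attached to the
    route instead of clipping them out.
    """

    circuit_id: str
    pathway_id: str
    receptor: str
    effector: str
    member_nodes: frozenset[str]
    member_edges: tuple[PathwayEdge, ...]

    @property
    def receptors(self) -> frozenset[str]:
        return frozenset({self.receptor})


@dataclass(frozen=True)
class EffectorCircuit:
    """Union of all canonical circuits of a pathway ending in one effector."""

    effector_circuit_id: str
    pathway_id: str
    effector: str
    canonical_circuit_ids: tuple[str, ...]
    receptors: frozenset[str]
    member_nodes: frozenset[str]
    member_edges: tuple[PathwayEdge, ...]


@dataclass(frozen=True)
class FunctionAnnotation:
    """A named gene set (Uniprot keyword, GO biological-process term, ...)."""

    function_id: str
    label: str
    annotated_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.annotated_genes:
            raise PathwayError(f"function {self.function_id!r} has no genes")


# ---------------------------------------------------------------------------
# loading


def load_pathway(path, dialect: str = "native_json",
                 subtype_signs: dict[str, str] | None = None) -> Pathway:
    """Load a pathway from ``path``.

    ``dialect`` is ``"native_json"`` (the package's own JSON graph format) or
    ``"kgml"`` (KEGG pathway XML).  For KGML, ``subtype_signs`` overrides the
    relation-subtype → sign table; unmapped subtypes are dropped with a
    warning, never silently signed.
    """
    if dialect == "native_json":
        return _load_native_json(path)
    if dialect == "kgml":
        return _load_kgml(path, subtype_signs or KGML_SUBTYPE_SIGNS)
    raise PathwayError(f"unknown pathway dialect {dialect!r}")


def _load_native_json(path) -> Pathway:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise PathwayError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    try:
        nodes = {}
        for nd in doc["nodes"]:
            node = PathwayNode(str(nd["id"]), tuple(nd["genes"]), nd.get("type", "plain"))
            if node.node_id in nodes:
                raise PathwayError(f"{path}: duplicate node id {node.node_id!r}")
            nodes[node.node_id] = node
        edges = [
            PathwayEdge(str(e["source"]), str(e["target"]), e["sign"])
            for e in doc["edges"]
        ]
        return Pathway(str(doc["pathway_id"]), str(doc.get("name", doc["pathway_id"])),
                       nodes, edges)
    except KeyError as exc:
        raise PathwayError(f"{path}: missing required field {exc}") from exc


def _load_kgml(path, subtype_signs: dict[str, str]) -> Pathway:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise PathwayError(f"{path}: malformed KGML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "pathway":
        raise PathwayError(f"{path}: root element is <{root.tag}>, expected <pathway>")
    pathway_id = root.get("name", root.get("number", "kgml"))
    name = root.get("title", pathway_id)

    gene_entries: dict[str, tuple[str, ...]] = {}
    groups: dict[str, list[str]] = {}
    for entry in root.iter("entry"):
        eid, etype = entry.get("id"), entry.get("type")
        if eid is None:
            raise PathwayError(f"{path}: <entry> without id attribute")
        if etype == "gene":
            gene_entries[eid] = tuple(entry.get("name", "").split())
        elif etype == "group":
            groups[eid] = [c.get("id") for c in entry.iter("component")]
        # compound / map / ortholog entries are not modelled

    nodes: dict[str, PathwayNode] = {}
    for eid, genes in gene_entries.items():
        if genes:
            nodes[eid] = PathwayNode(eid, genes, "plain")
    for gid, members in groups.items():
        genes = tuple(g for m in members for g in gene_entries.get(m, ()))
        if genes:
            nodes[gid] = PathwayNode(gid, genes, "complex")
        else:
            logger.warning("%s: group entry %s has no gene components; skipped", path, gid)

    edges: list[PathwayEdge] = []
    seen: set[tuple[str, str, str]] = set()
    for rel in root.iter("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        if e1 not in nodes or e2 not in nodes:
            logger.warning("%s: relation %s->%s touches a non-gene entry; dropped",
                           path, e1, e2)
            continue
        subtypes = [s.get("name", "") for s in rel.iter("subtype")]
        signs = {subtype_signs[s] for s in subtypes if s in subtype_signs}
        unmapped = [s for s in subtypes if s not in subtype_signs]
        if unmapped and not signs:
            logger.warning("%s: relation %s->%s has only unsigned subtypes %s; dropped",
                           path, e1, e2, unmapped)
            continue
        if not subtypes:
            logger.warning("%s: relation %s->%s has no subtype; dropped", path, e1, e2)
            continue
        for sign in sorted(signs):
            key = (e1, e2, sign)
            if key not in seen:
                seen.add(key)
                edges.append(PathwayEdge(e1, e2, sign))
    return Pathway(pathway_id, name, nodes, edges)


# ---------------------------------------------------------------------------
# decomposition


def identify_terminals(p: Pathway) -> tuple[set[str], set[str]]:
    """Return ``(receptors, effectors)``: nodes with in-degree 0 / out-degree 0."""
    g = p.to_networkx()
    receptors = {n for n in g if g.in_degree(n) == 0}
    effectors = {n for n in g if g.out_degree(n) == 0}
    return receptors, effectors


def decompose_circuits(p: Pathway) -> tuple[list[CanonicalCircuit], list[EffectorCircuit]]:
    """Decompose a pathway into canonical circuits and effector circuits.

    One canonical circuit per (receptor, effector) pair joined by a directed
    path; one effector circuit per effector reachable from at least one
    receptor.  Circuit ids are deterministic functions of the pathway.
    """
    receptors, effectors = identify_terminals(p)
    if not receptors or not effectors:
        raise DecompositionError(
            f"pathway {p.pathway_id!r} has no "
            f"{'receptor' if not receptors else 'effector'} node"
        )
    g = p.to_networkx()
    canonical: list[CanonicalCircuit] = []
    for r in sorted(receptors):
        downstream = nx.descendants(g, r) | {r}
        for e in sorted(effectors):
            if e == r:
                members = frozenset({r})
            elif e in downstream:
                members = frozenset(downstream & (nx.ancestors(g, e) | {e}))
            else:
                continue
            medges = tuple(
                edge for edge in p.edges
                if edge.source in members and edge.target in members
            )
            canonical.append(CanonicalCircuit(
                circuit_id=f"{p.pathway_id}:{r}->{e}",
                pathway_id=p.pathway_id,
                receptor=r, effector=e,
                member_nodes=members, member_edges=medges,
            ))

    effector_circuits: list[EffectorCircuit] = []
    for e in sorted(effectors):
        mine = [c for c in canonical if c.effector == e]
        if not mine:
            continue
        nodes = frozenset().union(*(c.member_nodes for c in mine))
        edge_set = {ed for c in mine for ed in c.member_edges}
        medges = tuple(ed for ed in p.edges if ed in edge_set)
        effector_circuits.append(EffectorCircuit(
            effector_circuit_id=f"{p.pathway_id}:->{e}",
            pathway_id=p.pathway_id,
            effector=e,
            canonical_circuit_ids=tuple(c.circuit_id for c in mine),
            receptors=frozenset(c.receptor for c in mine),
            member_nodes=nodes, member_edges=medges,
        ))
    return canonical, effector_circuits


# ---------------------------------------------------------------------------
# function annotations


def load_function_annotations(path) -> list[FunctionAnnotation]:
    """Read GMT gene sets: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    out: list[FunctionAnnotation] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
                logger.warning("%s:%d: gene set %r is empty; skipped",
                               path, lineno, parts[0] if parts else "")
                continue
            fid, label = parts[0], parts[1]
            if fid in seen:
                raise PathwayError(f"{path}:{lineno}: duplicate function id {fid!r}")
            seen.add(fid)
            out.append(FunctionAnnotation(
                fid, label, frozenset(g for g in parts[2:] if g.strip())
            ))
    return out


def map_effectors_to_functions(
    p: Pathway, annotations: list[FunctionAnnotation]
) -> dict[str, set[str]]:
    """Map function ids to the pathway's effector nodes whose genes they annotate.

    An effector belongs to a function iff the effector's gene set intersects
    the function's annotated genes.
    """
    _, effectors = identify_terminals(p)
    mapping: dict[str, set[str]] = {}
    for ann in annotations:
        hit = {e for e in effectors
               if set(p.nodes[e].genes) & ann.annotated_genes}
        if hit:
            mapping[ann.function_id] = hit
    return mapping
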