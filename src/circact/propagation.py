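"""Signal propagation across circuit sub-graphs.

Every node n holds a presence value v_n in [0,1].  Receptors receive one
virtual activation input of 1, so S_receptor = v_receptor.  Every other node
combines its incoming signals as

    S_n = v_n * (1 - prod_a (1 - s_a)) * prod_i (1 - s_i)

where the first product runs over incoming activation signals and the second
over incoming inhibition signals; a node with no activation inputs uses
activation factor 1 (inhibition-only nodes still transmit v_n * prod(1 - s_i)).
The state is reached by worklist fixed-point iteration, which makes the rule
well defined on cyclic topologies; a single topological-order pass
(`propagate_dag_oracle`) is exact on acyclic circuits and serves as the
reference implementation.

Values may be scalars or 1-D numpy arrays (one entry per sample); the update
rule is elementwise, so all samples propagate in one sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .pathway import ACTIVATION, CanonicalCircuit, EffectorCircuit

logger = logging.getLogger(__name__)


class PropagationError(RuntimeError):
    pass


@dataclass
class PropagationConfig:
    """Stopping rule for the fixed-point iteration.

    convergence_threshold: per-node change below which a node is quiescent.
    max_passes: sweeps over the worklist before giving up.
    non_convergence_policy: "warn_return_last" returns the last state with
        converged=False (pure negative-feedback cycles can oscillate forever);
        "error" raises naming the oscillating nodes.
    """

    convergence_threshold: float = 1e-6
    max_passes: int = 100
    non_convergence_policy: str = "warn_return_last"

    def __post_init__(self) -> None:
        if self.convergence_threshold <= 0:
            raise ValueError("convergence_threshold must be positive")
        if self.max_passes < 1:
            raise ValueError("max_passes must be >= 1")
        if self.non_convergence_policy not in ("warn_return_last", "error"):
            raise ValueError(
                f"unknown non_convergence_policy {self.non_convergence_policy!r}"
            )


@dataclass
class SignalState:
    """Per-node signal intensities after propagation."""

    signals: dict[str, np.ndarray | float]
    converged: bool
    passes_used: int
    oscillating: tuple[str, ...] = field(default=())


def _check_values(circuit, node_values) -> None:
    for n in circuit.member_nodes:
        if n not in node_values:
            raise PropagationError(
                f"circuit {_cid(circuit)}: node {n!r} has no value"
            )
        v = np.asarray(node_values[n], dtype=float)
        if np.any(v < 0) or np.any(v > 1):
            raise PropagationError(
                f"circuit {_cid(circuit)}: node {n!r} value outside [0,1]"
            )


def _cid(circuit) -> str:
    return getattr(circuit, "circuit_id", None) or circuit.effector_circuit_id


def _incoming(circuit):
    """node -> (activation sources, inhibition sources), deterministic order."""
    inc: dict[str, tuple[list[str], list[str]]] = {
        n: ([], []) for n in circuit.member_nodes
    }
    for e in circuit.member_edges:
        inc[e.target][0 if e.sign == ACTIVATION else 1].append(e.source)
    return inc


def _combine(v, act_signals, inh_signals):
    act = 1.0
    if act_signals:
        miss = 1.0
        for s in act_signals:
            miss = miss * (1.0 - s)
        act = 1.0 - miss
    inh = 1.0
    for s in inh_signals:
        inh = inh * (1.0 - s)
    return v * act * inh


def propagate(
    circuit: CanonicalCircuit | EffectorCircuit,
    node_values: dict,
    cfg: PropagationConfig | None = None,
    update_order: list[str] | None = None,
) -> SignalState:
    """Fixed-point propagation over the circuit sub-graph.

    Receptors are seeded with a virtual activation of 1; all other signals
    start at 0 and nodes are re-evaluated while any of their inputs changed by
    more than the threshold.  ``update_order`` overrides the (sorted,
    deterministic) sweep order; the converged state does not depend on it.
    """
    cfg = cfg or PropagationConfig()
    _check_values(circuit, node_values)
    receptors = set(circuit.receptors)
    inc = _incoming(circuit)
    succ: dict[str, list[str]] = {n: [] for n in circuit.member_nodes}
    for e in circuit.member_edges:
        succ[e.source].append(e.target)

    vals = {n: np.asarray(node_values[n], dtype=float) for n in circuit.member_nodes}
    signals: dict[str, np.ndarray] = {}
    for n in circuit.member_nodes:
        signals[n] = vals[n].copy() if n in receptors else np.zeros_like(vals[n])

    order = update_order or sorted(circuit.member_nodes)
    pending = [n for n in order if n not in receptors]
    passes = 0
    while pending and passes < cfg.max_passes:
        passes += 1
        changed: set[str] = set()
        for n in pending:
            acts, inhs = inc[n]
            new = _combine(vals[n], [signals[s] for s in acts],
                           [signals[s] for s in inhs])
            if np.max(np.abs(new - signals[n]), initial=0.0) > cfg.convergence_threshold:
                changed.add(n)
            signals[n] = new
        marked = {t for n in changed for t in succ[n] if t not in receptors}
        pending = [n for n in order if n in marked]

    converged = not pending
    oscillating = tuple(sorted(pending))
    if not converged:
        if cfg.non_convergence_policy == "error":
            raise PropagationError(
                f"circuit {_cid(circuit)}: no convergence after {passes} passes; "
                f"oscillating nodes: {', '.join(oscillating)}"
            )
        logger.warning("circuit %s: returning non-converged state after %d passes "
                       "(oscillating: %s)", _cid(circuit), passes, oscillating)
    out = {n: (s.item() if s.ndim == 0 else s) for n, s in signals.items()}
    return SignalState(out, converged, passes, oscillating)


def propagate_dag_oracle(
    circuit: CanonicalCircuit | EffectorCircuit, node_values: dict
) -> SignalState:
    """Exact single-pass propagation in topological order; acyclic circuits only."""
    _check_values(circuit, node_values)
    g = nx.DiGraph()
    g.add_nodes_from(circuit.member_nodes)
    g.add_edges_from((e.source, e.target) for e in circuit.member_edges)
    try:
        topo = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible as exc:
        raise PropagationError(
            f"circuit {_cid(circuit)} is cyclic; the single-pass oracle "
            "applies only to acyclic circuits"
        ) from exc
    receptors = set(circuit.receptors)
    inc = _incoming(circuit)
    signals: dict[str, np.ndarray] = {}
    for n in topo:
        v = np.asarray(node_values[n], dtype=float)
        if n in receptors:
            signals[n] = v.copy()
        else:
            acts, inhs = inc[n]
            signals[n] = _combine(v, [signals[s] for s in acts],
                                  [signals[s] for s in inhs])
    out = {n: (s.item() if s.ndim == 0 else s) for n, s in signals.items()}
    return SignalState(out, converged=True, passes_used=1)


def effector_signal(state: SignalState, effector: str):
    """Signal intensity arriving at the effector node."""
    try:
        return state.signals[effector]
    except KeyError:
        raise KeyError(f"node {effector!r} not in propagated state") from None
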