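"""Per-sample activity matrices at three levels: circuits, effector circuits, functions."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pathway import Pathway, decompose_circuits, map_effectors_to_functions
from .propagation import PropagationConfig, effector_signal, propagate

logger = logging.getLogger(__name__)

LEVELS = ("circuit", "effector", "function")


@dataclass
class ActivityMatrix:
    """Features x samples signal intensities in [0,1] at one decomposition level."""

    values: pd.DataFrame
    level: str
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown activity level {self.level!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids in activity matrix")


def _activities_for(circuits, node_values: pd.DataFrame, cfg, id_attr: str):
    samples = node_values.columns
    vals = {n: node_values.loc[n].to_numpy(dtype=float) for n in node_values.index}
    rows, meta = [], []
    for c in circuits:
        try:
            state = propagate(c, vals, cfg)
        except Exception as exc:
            raise type(exc)(f"[{getattr(c, id_attr)}] {exc}") from exc
        rows.append(np.asarray(effector_signal(state, c.effector), dtype=float))
        meta.append(state.converged)
    idx = [getattr(c, id_attr) for c in circuits]
    return pd.DataFrame(rows, index=idx, columns=samples), meta


def compute_circuit_activities(
    pathways: list[Pathway],
    node_values: dict[str, pd.DataFrame],
    cfg: PropagationConfig | None = None,
) -> tuple[ActivityMatrix, ActivityMatrix]:
    """Propagate every canonical and effector circuit of every pathway.

    ``node_values`` maps pathway id to that pathway's nodes x samples matrix
    (see :func:`circact.expression.summarize_nodes`).  Returns the canonical
    circuit-level and the effector circuit-level activity matrices; metadata
    rows record pathway, receptor(s), effector, member genes and whether the
    fixed-point iteration converged.
    """
    cfg = cfg or PropagationConfig()
    circ_frames, eff_frames = [], []
    circ_meta, eff_meta = [], []
    for p in pathways:
        nv = node_values[p.pathway_id]
        canonical, effectors = decompose_circuits(p)
        cdf, cconv = _activities_for(canonical, nv, cfg, "circuit_id")
        edf, econv = _activities_for(effectors, nv, cfg, "effector_circuit_id")
        circ_frames.append(cdf)
        eff_frames.append(edf)
        for c, ok in zip(canonical, cconv):
            circ_meta.append({
                "feature": c.circuit_id, "pathway": p.pathway_id,
                "receptor": c.receptor, "effector": c.effector,
                "genes": ";".join(sorted({g for n in c.member_nodes
                                          for g in p.nodes[n].genes})),
                "converged": ok,
            })
        for c, ok in zip(effectors, econv):
            eff_meta.append({
                "feature": c.effector_circuit_id, "pathway": p.pathway_id,
                "receptor": ";".join(sorted(c.receptors)), "effector": c.effector,
                "genes": ";".join(sorted({g for n in c.member_nodes
                                          for g in p.nodes[n].genes})),
                "converged": ok,
            })
    circ = ActivityMatrix(pd.concat(circ_frames), "circuit",
                          pd.DataFrame(circ_meta).set_index("feature"))
    eff = ActivityMatrix(pd.concat(eff_frames), "effector",
                         pd.DataFrame(eff_meta).set_index("feature"))
    return circ, eff


def effector_function_map(
    pathways: list[Pathway], annotations
) -> dict[str, set[str]]:
    """Map function ids to effector-circuit ids across a pathway collection."""
    mapping: dict[str, set[str]] = {}
    for p in pathways:
        for fid, effs in map_effectors_to_functions(p, annotations).items():
            mapping.setdefault(fid, set()).update(
                f"{p.pathway_id}:->{e}" for e in effs
            )
    return mapping


def compute_function_activities(
    effector_acts: ActivityMatrix, eff2fun: dict[str, set[str]]
) -> ActivityMatrix:
    """Combine effector-circuit signals into cell-function activities.

    Each effector->function link is treated as an activation onto a virtual
    function node of value 1, so the function receives
    ``1 - prod_e (1 - S_e)`` over its effector circuits — at least as active
    as its most active effector.  Functions whose effectors carry no computed
    activity are excluded with a warning.
    """
    if effector_acts.level != "effector":
        raise ValueError("compute_function_activities expects effector-level input")
    vals = effector_acts.values
    rows, idx = [], []
    for fid in sorted(eff2fun):
        effs = sorted(e for e in eff2fun[fid] if e in vals.index)
        if not effs:
            logger.warning("function %s: no effector circuit with computed "
                           "activity; excluded", fid)
            continue
        miss = (1.0 - vals.loc[effs].to_numpy(dtype=float)).prod(axis=0)
        rows.append(1.0 - miss)
        idx.append(fid)
    df = pd.DataFrame(rows, index=idx, columns=vals.columns)
    meta = pd.DataFrame(
        {"effector_circuits": [";".join(sorted(e for e in eff2fun[f]
                                               if e in vals.index)) for f in idx]},
        index=pd.Index(idx, name="feature"),
    )
    return ActivityMatrix(df, "function", meta)
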