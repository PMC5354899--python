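"""Scale gene expression to [0,1] protein-presence proxies and summarize node values.

Matrices are pandas DataFrames, genes (or nodes) in rows, samples in columns.
Plain nodes take the 90th percentile of their member-gene values (an "any of
the alternative proteins suffices" reading); complex nodes take the minimum
(the limiting component of the complex).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .pathway import Pathway

logger = logging.getLogger(__name__)

PLAIN_PERCENTILE = 90.0


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene id, header of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene ids")
    return df.astype(float)


def scale_to_unit(m: pd.DataFrame, truncation_quantile: float = 0.99) -> pd.DataFrame:
    """Per-gene min-to-quantile scaling into [0,1].

    Each gene g is mapped by ``clamp((x - min_g) / (q_g - min_g), 0, 1)`` where
    ``q_g`` is the per-gene ``truncation_quantile`` quantile; values above the
    truncation point saturate at 1, so a handful of extreme samples cannot
    compress everyone else onto a sliver of the scale.  Constant genes carry
    no ordering information and map to the signal-neutral value 0.5.
    """
    if not 0.5 < truncation_quantile <= 1.0:
        raise ValueError("truncation_quantile must lie in (0.5, 1]")
    if m.shape[1] == 0:
        raise ValueError("expression matrix has no samples")
    vals = m.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("expression matrix contains non-finite values")
    if m.shape[1] == 1:
        logger.warning("single-sample matrix: per-gene scaling undefined, all 0.5")
        return pd.DataFrame(0.5, index=m.index, columns=m.columns)
    lo = vals.min(axis=1, keepdims=True)
    hi = np.quantile(vals, truncation_quantile, axis=1, keepdims=True)
    span = hi - lo
    constant = span <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.clip((vals - lo) / np.where(constant, 1.0, span), 0.0, 1.0)
    scaled = np.where(constant, 0.5, scaled)
    return pd.DataFrame(scaled, index=m.index, columns=m.columns)


def summarize_nodes(
    p: Pathway,
    m: pd.DataFrame,
    missing_node_value: float | None = 0.5,
) -> pd.DataFrame:
    """Summarize a scaled [0,1] gene matrix into node values for one pathway.

    Plain node = 90th percentile (linear interpolation between order
    statistics) of its measured member genes; complex node = minimum.  Genes
    absent from ``m`` are ignored; a node with no measured gene at all gets
    ``missing_node_value`` (pass ``None`` to make that an error).  Raises if
    the pathway shares no gene with the matrix.
    """
    vals = m.to_numpy(dtype=float)
    if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
        raise ValueError("summarize_nodes expects a matrix already scaled to [0,1]")
    measured = set(m.index)
    if not (p.genes & measured):
        raise ValueError(
            f"pathway {p.pathway_id!r}: none of its genes appear in the matrix"
        )
    rows = np.empty((len(p.nodes), m.shape[1]))
    for i, node in enumerate(p.nodes.values()):
        present = [g for g in node.genes if g in measured]
        if not present:
            if missing_node_value is None:
                raise ValueError(
                    f"node {node.node_id!r} of pathway {p.pathway_id!r} "
                    "has no measured genes"
                )
            logger.warning("node %s of %s has no measured genes; defaulting to %g",
                           node.node_id, p.pathway_id, missing_node_value)
            rows[i] = missing_node_value
            continue
        sub = m.loc[present].to_numpy(dtype=float)
        if node.node_type == "complex":
            rows[i] = sub.min(axis=0)
        else:
            rows[i] = np.percentile(sub, PLAIN_PERCENTILE, axis=0)
    return pd.DataFrame(rows, index=list(p.nodes), columns=m.columns)
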