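"""Synthetic pathways and cohorts, and the specificity / sensitivity protocols.

Specificity (false-positive rate): a cohort of statistically identical
individuals is split at random into two halves and the full pipeline is run;
any circuit called differentially activated is a false positive.  Cohorts
come in three flavours: resampling columns of a template matrix, per-gene
normal draws matching a template's empirical mean/variance, or every value
i.i.d. Normal(mean 0.5, variance 0.05) clamped to [0,1].

Sensitivity (true-positive rate): a known fold-change is injected into the
member genes of chosen circuits of designated pathways; the TPR is the
fraction of designated pathways with at least one significantly
differentially activated circuit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffstats import compare_groups
from .expression import scale_to_unit, summarize_nodes
from .pathway import ACTIVATION, INHIBITION, Pathway, PathwayEdge, PathwayNode
from .profiles import ActivityMatrix, compute_circuit_activities
from .propagation import PropagationConfig

SCENARIOS = ("empirical_resample", "gene_wise_normal", "flat_normal")
FLAT_MEAN = 0.5
FLAT_VARIANCE = 0.05  # i.e. SD ~0.2236


@dataclass
class CohortSpec:
    """Recipe for one simulated cohort of expression profiles."""

    scenario: str
    n_samples: int
    genes: tuple[str, ...] = ()
    template: pd.DataFrame | None = None
    mean: float = FLAT_MEAN
    variance: float = FLAT_VARIANCE
    clamp: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_samples < 4:
            raise ValueError("cohort needs n_samples >= 4")
        if self.variance <= 0:
            raise ValueError("variance must be positive")
        if self.scenario in ("empirical_resample", "gene_wise_normal") \
                and self.template is None:
            raise ValueError(f"scenario {self.scenario!r} requires a template matrix")
        if self.scenario == "flat_normal" and not self.genes:
            raise ValueError("flat_normal requires an explicit gene universe")


@dataclass
class BenchmarkReport:
    """Outcome of a specificity or sensitivity run."""

    kind: str  # "fpr" | "tpr"
    repetitions: int
    per_repetition: list[float]
    rate: float
    ci_low: float
    ci_high: float
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "repetitions": self.repetitions,
            "rate": self.rate, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "per_repetition": self.per_repetition, "config": self.config,
        }


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort per ``spec``; bit-reproducible given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    if spec.scenario == "flat_normal":
        vals = rng.normal(spec.mean, np.sqrt(spec.variance),
                          size=(len(spec.genes), spec.n_samples))
        genes = list(spec.genes)
    elif spec.scenario == "gene_wise_normal":
        t = spec.template.to_numpy(dtype=float)
        mu = t.mean(axis=1, keepdims=True)
        sd = t.std(axis=1, ddof=1, keepdims=True)
        vals = rng.normal(0.0, 1.0, size=(t.shape[0], spec.n_samples)) * sd + mu
        genes = list(spec.template.index)
    else:  # empirical_resample
        t = spec.template.to_numpy(dtype=float)
        cols = rng.integers(0, t.shape[1], size=spec.n_samples)
        vals = t[:, cols]
        genes = list(spec.template.index)
    if spec.clamp:
        vals = np.clip(vals, 0.0, 1.0)
    samples = [f"S{i:04d}" for i in range(spec.n_samples)]
    return pd.DataFrame(vals, index=genes, columns=samples)


def generate_synthetic_pathway(
    n_nodes: int,
    loop_fraction: float = 0.0,
    inhibition_fraction: float = 0.0,
    seed: int = 0,
    pathway_id: str | None = None,
    n_receptors: int = 2,
    n_effectors: int = 2,
    extra_edge_density: float = 0.5,
    gene_pool=None,
    max_genes_per_node: int = 3,
) -> Pathway:
    """Random connected pathway with designated receptor and effector layers.

    Nodes 0..n_receptors-1 never gain incoming edges; the last ``n_effectors``
    nodes never gain outgoing edges, so the graph always has at least one
    receptor and one effector and decomposition succeeds.
    ``inhibition_fraction`` of edges are signed as inhibitions;
    ``loop_fraction`` adds that fraction of back-edges along existing paths
    between interior nodes, creating cycles.  Deterministic given ``seed``.
    """
    if n_nodes < 3:
        raise ValueError("need n_nodes >= 3")
    if not 0 <= loop_fraction <= 1 or not 0 <= inhibition_fraction <= 1:
        raise ValueError("loop_fraction and inhibition_fraction must lie in [0,1]")
    n_receptors = min(n_receptors, max(1, (n_nodes - 1) // 3))
    n_effectors = min(n_effectors, max(1, (n_nodes - 1) // 3))
    if n_receptors + n_effectors >= n_nodes:
        raise ValueError("too many terminals for the node count")
    rng = np.random.default_rng(seed)
    pid = pathway_id or f"synthP{seed}"
    node_ids = [f"{pid}_n{i:02d}" for i in range(n_nodes)]
    first_interior, first_effector = n_receptors, n_nodes - n_effectors

    edges: set[tuple[str, str]] = set()
    # backbone: every non-receptor gets one parent among earlier non-effectors
    for j in range(n_receptors, n_nodes):
        upper = min(j, first_effector)
        i = int(rng.integers(0, upper))
        edges.add((node_ids[i], node_ids[j]))
    # every receptor must feed the graph
    for i in range(n_receptors):
        if not any(s == node_ids[i] for s, _ in edges):
            j = int(rng.integers(first_interior, n_nodes))
            edges.add((node_ids[i], node_ids[j]))
    # extra forward edges thicken the routing
    n_extra = int(round(extra_edge_density * n_nodes))
    for _ in range(n_extra * 4):
        if n_extra <= 0:
            break
        i = int(rng.integers(0, first_effector))
        j = int(rng.integers(max(i + 1, first_interior), n_nodes))
        if (node_ids[i], node_ids[j]) not in edges:
            edges.add((node_ids[i], node_ids[j]))
            n_extra -= 1

    # feedback edges: reverse of an existing interior->interior reachability
    n_back = int(round(loop_fraction * len(edges)))
    if loop_fraction > 0:
        n_back = max(1, n_back)
    interior_edges = [
        (s, t) for (s, t) in sorted(edges)
        if node_ids.index(s) >= first_interior and node_ids.index(t) < first_effector
    ]
    if n_back > 0 and not interior_edges:
        raise ValueError("loop_fraction > 0 infeasible: no interior edge to reverse")
    back_added = 0
    for _ in range(n_back * 4):
        if back_added >= n_back or not interior_edges:
            break
        s, t = interior_edges[int(rng.integers(0, len(interior_edges)))]
        if (t, s) not in edges:
            edges.add((t, s))
            back_added += 1

    ordered = sorted(edges)
    n_inh = int(round(inhibition_fraction * len(ordered)))
    inh_idx = set(rng.choice(len(ordered), size=n_inh, replace=False)) if n_inh else set()
    pathway_edges = [
        PathwayEdge(s, t, INHIBITION if k in inh_idx else ACTIVATION)
        for k, (s, t) in enumerate(ordered)
    ]

    pool = list(gene_pool) if gene_pool is not None else None
    nodes: dict[str, PathwayNode] = {}
    cursor = 0
    for k, nid in enumerate(node_ids):
        n_genes = int(rng.integers(1, max_genes_per_node + 1))
        if pool is not None:
            take = [pool[(cursor + j) % len(pool)] for j in range(n_genes)]
            cursor += n_genes
        else:
            take = [f"{pid}_g{k:02d}_{j}" for j in range(n_genes)]
        ntype = "complex" if (n_genes >= 2 and rng.random() < 0.4) else "plain"
        nodes[nid] = PathwayNode(nid, tuple(take), ntype)
    return Pathway(pid, pid, nodes, pathway_edges)


def inject_fold_change(m: pd.DataFrame, genes, fold: float) -> pd.DataFrame:
    """Multiply the rows of ``genes`` by ``fold`` (pre-scaling effect injection)."""
    out = m.copy()
    present = [g for g in genes if g in out.index]
    out.loc[present] = out.loc[present] * fold
    return out


def run_activity_pipeline(
    pathways: list[Pathway],
    expression: pd.DataFrame,
    scale: bool = False,
    cfg: PropagationConfig | None = None,
) -> tuple[ActivityMatrix, ActivityMatrix]:
    """Expression -> (optional unit scaling) -> node values -> circuit activities."""
    expr = scale_to_unit(expression) if scale else expression
    node_values = {p.pathway_id: summarize_nodes(p, expr) for p in pathways}
    return compute_circuit_activities(pathways, node_values, cfg)


def _wilson_ci(successes: float, trials: float) -> tuple[float, float]:
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(round(successes), max(round(trials), 1),
                                method="wilson")
    return float(lo), float(hi)


def estimate_fpr(
    pathways: list[Pathway],
    spec: CohortSpec,
    repetitions: int = 100,
    alpha: float = 0.05,
) -> BenchmarkReport:
    """Specificity protocol: random half-splits of homogeneous cohorts.

    Per repetition a fresh cohort is drawn, split at random into two equal
    groups, and the full pipeline (node summarization, propagation,
    per-circuit Wilcoxon test with BH adjustment) is run; the fraction of
    canonical circuits with adjusted p < alpha is a false-positive fraction.
    The report's rate is the mean fraction across repetitions.
    """
    if spec.n_samples % 2:
        raise ValueError("estimate_fpr needs an even cohort size")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(repetitions)
    fractions: list[float] = []
    total_sig = total_circ = 0
    for child in children:
        draw_seed, split_seed = child.generate_state(2) >> 1  # keep below 2**31
        rep_spec = CohortSpec(spec.scenario, spec.n_samples, spec.genes,
                              spec.template, spec.mean, spec.variance,
                              spec.clamp, int(draw_seed))
        cohort = generate_cohort(rep_spec)
        rng = np.random.default_rng(int(split_seed))
        perm = rng.permutation(cohort.columns.to_numpy())
        half = len(perm) // 2
        design = pd.Series(
            ["g1"] * half + ["g2"] * half, index=perm.tolist()
        )
        circ, _ = run_activity_pipeline(pathways, cohort)
        res = compare_groups(circ, design, reference="g1")
        n_sig = int((res["fdr"] < alpha).sum())
        fractions.append(n_sig / len(res))
        total_sig += n_sig
        total_circ += len(res)
    rate = float(np.mean(fractions))
    lo, hi = _wilson_ci(total_sig, total_circ)
    return BenchmarkReport(
        "fpr", repetitions, fractions, rate, lo, hi,
        config={"scenario": spec.scenario, "n_samples": spec.n_samples,
                "n_genes": len(spec.genes) if spec.genes else
                (spec.template.shape[0] if spec.template is not None else 0),
                "alpha": alpha, "seed": spec.seed,
                "n_pathways": len(pathways)},
    )


def benchmark_pathways(
    n_pathways: int = 3,
    n_nodes: int = 15,
    genes: tuple[str, ...] = (),
    seed: int = 0,
    inhibition_fraction: float = 0.2,
    loop_fraction_first: float = 0.1,
) -> list[Pathway]:
    """Standard synthetic pathway set for the benchmark protocols.

    ``n_pathways`` pathways of ``n_nodes`` nodes with mixed activation and
    inhibition edges; the first one carries a feedback cycle so the loop
    handling of the propagation engine is exercised.  Each pathway draws its
    node genes from a disjoint 40-gene slice of ``genes``.
    """
    if len(genes) < n_pathways * 40:
        raise ValueError("gene universe too small for the pathway set")
    return [
        generate_synthetic_pathway(
            n_nodes,
            loop_fraction=(loop_fraction_first if k == 0 else 0.0),
            inhibition_fraction=inhibition_fraction,
            seed=seed * 1000 + k,
            pathway_id=f"P{k}",
            gene_pool=genes[k * 40:(k + 1) * 40],
        )
        for k in range(n_pathways)
    ]


def specificity_benchmark(
    seed: int,
    n_pathways: int = 3,
    n_nodes: int = 15,
    n_genes: int = 1000,
    n_samples: int = 40,
    repetitions: int = 100,
    alpha: float = 0.05,
) -> BenchmarkReport:
    """The self-contained specificity protocol at desk scale.

    Homogeneous flat-normal cohorts (every value i.i.d. Normal(0.5,
    variance 0.05), clamped) are split at random into two halves and the
    full differential-activation pipeline is run over a standard synthetic
    pathway set; the mean fraction of circuits called significant at
    ``alpha`` estimates the false-positive rate.
    """
    genes = tuple(f"G{i:04d}" for i in range(n_genes))
    pathways = benchmark_pathways(n_pathways, n_nodes, genes, seed)
    spec = CohortSpec("flat_normal", n_samples, genes, seed=seed)
    return estimate_fpr(pathways, spec, repetitions, alpha)


def estimate_tpr(
    pathways: list[Pathway],
    case_matrix: pd.DataFrame,
    control_matrix: pd.DataFrame,
    cancer_pathway_ids: list[str],
    alpha: float = 0.05,
    scale: bool = True,
) -> BenchmarkReport:
    """Sensitivity protocol: fraction of designated pathways recovered.

    Runs the pipeline on case vs control and reports the fraction of
    ``cancer_pathway_ids`` whose pathways contain at least one circuit with
    BH-adjusted p < alpha.  Case and control are scaled jointly (effects are
    injected on the raw scale).
    """
    ids = {p.pathway_id for p in pathways}
    unknown = set(cancer_pathway_ids) - ids
    if unknown:
        raise ValueError(f"designated pathways not supplied: {sorted(unknown)}")
    if not cancer_pathway_ids:
        raise ValueError("empty designated pathway list")
    case = case_matrix.add_prefix("case_")
    ctrl = control_matrix.add_prefix("ctrl_")
    combined = pd.concat([case, ctrl], axis=1)
    design = pd.Series(
        ["case"] * case.shape[1] + ["control"] * ctrl.shape[1],
        index=list(combined.columns),
    )
    circ, _ = run_activity_pipeline(pathways, combined, scale=scale)
    res = compare_groups(circ, design, reference="control")
    meta = circ.metadata
    hit_per_pathway = {
        pid: bool((res.loc[meta.index[meta["pathway"] == pid], "fdr"] < alpha).any())
        for pid in cancer_pathway_ids
    }
    hits = [float(hit_per_pathway[pid]) for pid in cancer_pathway_ids]
    rate = float(np.mean(hits))
    lo, hi = _wilson_ci(sum(hits), len(hits))
    return BenchmarkReport(
        "tpr", 1, hits, rate, lo, hi,
        config={"alpha": alpha, "n_case": case.shape[1], "n_control": ctrl.shape[1],
                "designated": list(cancer_pathway_ids)},
    )
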