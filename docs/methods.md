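# Methods

## Pathway model and circuit decomposition

A pathway is a directed graph. Nodes hold one or more gene products:
*plain* nodes represent interchangeable alternatives, *complex* nodes
represent protein complexes. Edges carry exactly one of two signs,
activation or inhibition; relations without a sign (e.g. KGML
"binding/association") are dropped with a warning rather than guessed,
and the KGML subtype→sign table ("activation"/"expression" → activation,
"inhibition"/"repression" → inhibition) is configurable. Receptors and
effectors are defined purely topologically: in-degree 0 and out-degree 0
respectively. No attempt is made to fetch pathways from a remote service;
inputs are local KGML files or the native JSON dialect.

One canonical circuit is built per (receptor, effector) pair joined by a
directed path. Its member set is the intersection of the receptor's
descendants and the effector's ancestors (both inclusive), with the induced
edges. Two consequences are intended:

* Parallel branches between the same pair belong to one circuit, not
  several. Convergent branches recombine under the propagation rule, so
  they must be evaluated jointly; counting each simple path separately
  would double-count shared segments and make the "combination of
  activations" semantics unreachable.
* Cycles whose nodes are both reachable from the receptor and able to
  reach the effector stay inside the circuit. The propagation engine is
  loop-tolerant precisely so that feedback does not have to be clipped.

Effector circuits are unions of the canonical circuits sharing an effector.
Circuit identifiers are deterministic (`pathway:receptor->effector`,
`pathway:->effector`), so repeated runs over the same files produce
identical feature sets.

Cell functions are GMT gene sets (Uniprot keywords, GO biological process
terms, or anything else in GMT form). A function is linked to every
effector whose gene set intersects it; no ontology-hierarchy propagation is
performed — term sets are taken flat.

## Node values

Expression is scaled per gene by `clamp((x − min)/(q99 − min), 0, 1)` where
`q99` is the per-gene 0.99 quantile. Truncating at a high quantile instead
of the maximum keeps one outlier sample from compressing the rest of the
cohort toward 0; the quantile is a parameter (`truncation_quantile`,
default 0.99, set to 1.0 for plain min–max). Only the high tail is
truncated. Constant genes map to 0.5 everywhere — they carry no ordering
information, and 0.5 is signal-neutral under the propagation rule. A
single-sample matrix cannot be scaled and degenerates to all 0.5 with a
warning.

Node summarization: plain nodes take the 90th percentile of member-gene
values, computed with linear interpolation between order statistics (the
interpolation scheme is fixed so results are bit-stable across runs);
complex nodes take the minimum. Genes absent from the matrix are ignored;
a node with no measured gene defaults to 0.5 with a warning (configurable
to raise instead), and a pathway with no measured gene at all is an error.

## Variant integration

A gene is considered broken in a sample when a variant is deleterious per
se (consequence stop gain, stop loss, or splicing disruption) or when its
pathogenicity and conservation annotations are jointly beyond their
cutoffs: SIFT-like ≤ 0.05 *or* PolyPhen-like ≥ 0.85, *and* phastCons-like
≥ 0.95. These defaults follow the scores' conventional damaging ranges and
are all configurable (`IntegrityThresholds`). The inheritance mode gates
the call: dominant needs any single qualifying variant; recessive needs a
homozygous one or two distinct heterozygous ones in the same gene
(compound heterozygosity, phase ignored — phasing information is rarely
available in practice). Broken genes multiply expression by 0, nothing
else changes; integrity application is idempotent. Unknown consequence
strings are treated as non-deleterious with a warning, never as damaging.

## Signal propagation

Receptors are seeded with one virtual activation input of 1, so a
receptor's signal equals its node value. Every other node applies

    S_n = v_n · (1 − ∏_a (1 − s_a)) · ∏_i (1 − s_i)

A node with inhibition inputs but no activation inputs uses activation
factor 1 rather than the literal empty-product value 0: otherwise an
inhibition edge into a pass-through node could never transmit anything and
would be dead syntax. All quantities stay in [0,1] by construction.

The fixed point is found by worklist iteration: non-receptor signals start
at 0; nodes whose inputs changed by more than `convergence_threshold`
(default 1e-6) are re-evaluated, sweeping in sorted node order, until
quiescent or `max_passes` (default 100) is reached. On acyclic circuits
this reproduces the exact single topological pass
(`propagate_dag_oracle`); on circuits with feedback it converges whenever
the loop gain damps (e.g. the negative-feedback chain A→B→C with C⊣B and
values (1, 1, 0.5) settles at S_B = 2/3, S_C = 1/3). Undamped inhibition
cycles driven at full strength can oscillate forever; the default policy
returns the last state flagged `converged=False` with the oscillating
nodes listed (policy `error` raises instead). The defaults were chosen so
toy fixtures converge to well below the reported precision while runaway
loops still terminate quickly. The update rule is elementwise, so node
values may be vectors — one entry per sample — and a whole cohort
propagates in a single sweep.

Each canonical circuit is propagated on its own subgraph; signals are not
shared across circuits of the same pathway. Effector circuits propagate on
the union subgraph with all their receptors seeded.

Function activity combines effector-circuit signals as 1 − ∏(1 − S_e),
i.e. the effector→function links are treated as activations onto a virtual
function node of value 1. GMT inputs carry no inhibitory annotation, so no
sign choice is available at this layer; the consequence is that a function
is always at least as active as its most active effector circuit.

## Differential activation

Per feature, the two groups are compared with the two-sided Wilcoxon
rank-sum test: exact when the combined n ≤ 20 and values are tie-free,
otherwise the normal approximation with continuity and mid-rank tie
correction. Constant features get p = 1. Benjamini–Hochberg correction is
applied within each activity level (circuits, effector circuits, functions
separately), matching how significant counts are reported per level; the
significance filter uses strict inequality on the adjusted p. Direction is
the sign of the case-minus-control median difference and is left undefined
on equal medians. A two-sided t-test on logit-transformed activities is
available as a parametric alternative (`method="logit_t"`); the rank test
is the default because activities are bounded and often skewed.

## Survival

For each feature and each side, the `fraction` (default 10%) of samples
with the most extreme activity — round-half-up with a minimum of one
sample, ties at the cut broken by stable sample order — is compared to the
remaining samples with the log-rank test on Kaplan–Meier curves. Both
sides (high and low) are always tested and jointly BH-corrected across all
(feature, side) pairs; correcting only the side of interest would
understate multiplicity. The prognosis label calls the extreme stratum
"bad" when its survival curve lies below the rest's at the pooled median
follow-up time — a single-timepoint summary chosen for robustness over
curve-crossing heuristics. No Cox regression or covariate adjustment is
attempted.

## Synthetic data and benchmark protocols

`generate_cohort` supports three null-cohort scenarios: resampling columns
of a template matrix with replacement; per-gene normal draws matching a
template's empirical mean and variance; and the fully synthetic flat
scenario where every value is i.i.d. Normal(mean 0.5, **variance** 0.05,
i.e. SD ≈ 0.224) — the 0.05 is read as a variance, consistent with the
σ²-notation of the gene-wise scenario. Draws are clamped to [0,1] because
the propagation rule requires bounded values; clamping is configurable.
All generators take explicit seeds and are bit-reproducible.

`generate_synthetic_pathway` builds a random connected digraph with a
designated receptor layer (never gains in-edges) and effector layer (never
gains out-edges), so decomposition always succeeds. A requested fraction of
edges is signed inhibitory; feedback is created by reversing existing
interior edges, which guarantees each added back-edge closes a cycle. These
graphs emulate the topology of curated signaling pathways (scale ~15 nodes,
mixed signs, occasional feedback) but not their biology: gene membership is
arbitrary, there is no hub structure, and node gene counts (1–3) are
smaller than real complexes. Null-cohort results therefore speak to the
statistical calibration of the pipeline, not to biological recall on real
pathways.

**Specificity (FPR).** A homogeneous cohort is drawn, split at random into
two halves, and the full pipeline is run; any circuit called significant is
a false positive. The shipped configuration uses 3 pathways (~15 nodes, one
with a feedback loop), cohorts of 40 samples × 1000 genes, 100 repetitions,
Wilcoxon + BH at α = 0.05; simulated cohorts are already on the [0,1]
scale and enter node summarization directly. The repetition count is a
parameter — 100 gives a Monte-Carlo standard error comfortably below the
0.05 bound being checked, and the protocol scales linearly for users who
want more. Observed rates sit near 2.5×10⁻³, far below the nominal level,
because BH across circuits of null cohorts rarely lets anything through.

**Sensitivity (TPR).** A fold-change (default 1.5×) is injected,
pre-scaling, into the member genes of one circuit per designated pathway;
case and control are then scaled jointly and compared. TPR is the fraction
of designated pathways with at least one circuit at adjusted p < α. The
injected circuit is the pathway's largest canonical circuit (its principal
route): in a minimal circuit whose receptor directly inhibits the effector,
raising all member genes jointly shifts v_receptor and v_effector in
near-perfect cancellation (dS ≈ (1−v_r)dv_e − v_e dv_r ≈ 0), so tiny
inhibition-dominated circuits are not a meaningful perturbation target —
coordinated up-regulation of a principal route is what a genuinely
activated pathway looks like. With n = 100 vs 100 the injected circuit
ranks first by adjusted p and TPR reaches 1 on the designated set.

## Numerical and interface choices

* Matrices are pandas DataFrames (genes/nodes/features × samples)
  throughout; TSV on disk, with a `#`-comment header carrying the config
  hash so outputs are traceable to their run configuration.
* Oracle equivalence between the iterative engine and the topological-pass
  reference is asserted to within 10× the convergence threshold.
* Decile size rounding is round-half-up with a minimum of one sample.
* Seeds: every stochastic entry point takes an explicit integer seed;
  repetition seeds are spawned from a root `SeedSequence` so repetitions
  are independent yet reproducible.

## Known limitations

* mRNA abundance is a proxy for protein presence and activation;
  post-translational regulation is invisible to the model.
* The activation-combination rule treats parallel inputs as independent
  evidence; cooperative or competitive binding is not modelled.
* Undamped oscillatory feedback has no steady state under this rule; such
  circuits are reported, not resolved.
* The KGML reader covers gene and group entries and signed PPrel/GErel
  relations; compound-mediated indirect links are not modelled.
* Synthetic benchmarks certify calibration and power mechanics, not
  biological ground truth.
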