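# Methods

## Pipeline model and assumptions

The pipeline assumes that disease-relevant genes are a small minority of
the measured transcriptome, that they vary more across a mixed
healthy/patient cohort than unrelated genes, and that they organize into
co-expression modules — groups of genes whose expression profiles are
strongly linearly related (in absolute value, so mutual inhibition counts
as linkage). Under these assumptions a descending curve of per-gene
variability shows two regimes (variable disease-linked genes, then a
noise floor), the absolute-correlation matrix of the retained genes is
approximately block-structured, and each block contains a hub whose
profile tracks the module's shared signal most faithfully. The hub is
proposed as the module's biomarker, and the vector of hub expressions is
treated as a sufficient description of a sample for staging.

## Critical-point detection

A ranked (descending) curve y₁ ≥ … ≥ y_n is split at index s into
segments 1..s and s+1..n, each fitted by its own least-squares line; the
breakpoint is the s (2 ≤ s ≤ n−2) minimizing the total SSE, computed in
O(n) from prefix/suffix sums. Ties within a 1e-9 relative tolerance go
to the smallest rank. The detector is invariant under positive affine
transformations of the values. When the best two-segment fit improves on
a single line by less than 5 %, the result carries a `confident=False`
flag — on a genuinely linear curve the breakpoint is arbitrary. A
maximum-distance-to-chord knee detector is available as an alternative
(`method="knee"`). The selection rule is inclusive: genes (or gene
pairs) whose measure **equals** the value at the breakpoint are kept, so
the gene sitting exactly at the critical point is counted among the
sensitive genes.

Screening defaults: variance with the sample (n−1) denominator; the
`log2_shifted` transform (log₂(x+1)) for raw microarray intensities,
`none` for data already on a log-like scale (the pipeline picks `none`
automatically for non-exponentiated simulations). The
label-informativeness measure is the information gain of the stage label
under a median split of the gene; it is an explicitly pluggable scoring
hook with a stable interface, ranked but not used downstream by default.

## Network construction

Edges are absolute Pearson correlations across all pooled samples
(per-group matrices are available via `group=`). Constant gene rows are
excluded, not assigned zero, to avoid fabricating edges. The edge
threshold is the critical point of the ranked off-diagonal correlations;
edge weight is the raw retained correlation (no soft-power transform),
because downstream degree is defined as the plain sum of weights. Genes
left without edges are excluded from module detection and reported.

## Module detection

K-means (in-house Lloyd iterations: seeded random centers, 10 restarts,
relative movement tolerance 1e-6, 300 iteration cap, empty-cluster
re-seeding to the farthest point, per-iteration inertia monotonicity
asserted) clusters genes embedded as their correlation profiles. Both
k-means and the gap statistic operate in a PCA embedding of those
profiles (components explaining 90 % of variance, capped at 20): raw
profiles have one dimension per gene, and in that space the gap
statistic's uniform reference loses only ≈ 2/d·log((k+1)/k) of log W per
extra cluster, so its stop rule can never fire; the embedding preserves
the cluster geometry (distances are rotation-invariant) while giving the
reference a meaningful dimensionality.

Gap statistic: W_k pools within-cluster *unsquared* pairwise distances
(Σ_r Σ_{i<i′∈r} d_{ii′}/n_r) over k-means partitions; with squared
distances the k=1 term is dominated by between-cluster spread and the
rule fires immediately — the unsquared form is the long-standing default
of the reference R implementation, against which this one was
cross-checked on a shared fixture. References are uniform draws in the
bounding box aligned to the principal axes of the centered features
(`reference="box"` gives the plain box); B = 50 draws by default (the
pipeline uses B = 20 at its problem sizes), references clustered with
the same number of restarts as the data. Selection: smallest k with
Gap(k) ≥ Gap(k+1) − s_{k+1}; if never satisfied, argmax Gap with a
warning. Known limitation: for cluster layouts symmetric about the
centroid the sequential rule can stop at k = 1.

Modularity is computed from its defining sum over ordered node pairs,
S = (1/2W) Σ_{ij} [C_ij − k_i k_j / 2W] μ(i,j), with W the total edge
weight — the all-in-one partition scores exactly 0, a testable anchor.
The Louvain route runs the standard greedy phases, then finishes every
restart with an exact single-node local-move pass (a partition is only
accepted once no single node prefers another or a fresh community), and
keeps the best of 16 restarts, half of them started from random
partitions; on graphs of ≤ 12 nodes, where coordinated two-node moves
trap every greedy trajectory, 64 restarts are used (they are nearly
free). Deterministic given the seed.

## Representatives

Inter-module edges are cut; statistics are computed on the largest
connected component of each module subgraph (ties by smallest member
id), mirroring the treatment of fragmented modules as dominated by their
main body. Weighted degree is the sum of incident edge weights; ASPL is
the mean hop-count shortest path to the other component members
(`paths="weighted"` uses 1 − w as edge length). The representative
minimizes the sum of its degree rank (descending) and ASPL rank
(ascending, min-ranks); ties go to smaller ASPL, then to the smaller
gene id; a `conflict` flag records whenever the degree and ASPL optima
are different genes, since nothing guarantees one gene wins both.

## Subtyping

Features are the representatives' expression in patient samples
(configurable `exclude_groups`, default healthy), z-scored per column
because hub genes sit on very different intensity scales (raw mode
available; a constant feature column is an error at this step). The four
clustering algorithms:

- **k-means** on samples — same Lloyd core as module detection.
- **SOM** — online Kohonen training on a rows×cols grid (default 2×3):
  prototypes initialized from random samples, Gaussian grid
  neighborhood, 200 epochs, learning rate 0.5 decaying linearly to 0,
  radius max(rows, cols) decaying linearly to 1; samples assigned to
  their best-matching unit. Unit occupancy and per-unit label
  composition let a stage group be split into data-driven sub-types.
- **competitive network** — winner-take-all updates (no neighborhood);
  prototypes seeded farthest-point style so single clouds do not capture
  several units.
- **hierarchical** — scipy average-linkage agglomeration cut at K
  clusters; deterministic, so repeated runs have zero spread.

Clusters are mapped to stage labels by plurality vote; clusters sharing
a plurality class merge, so there are never more predicted classes than
true ones; exact ties go to the class that is rarer overall (logged).
Evaluation is one-vs-rest: precision TP/(TP+FP), recall TP/(TP+FN), F1
their harmonic mean (0 when undefined, with an `undefined_precision`
flag when a class receives no predictions); accuracy is micro accuracy —
the fraction of correctly labelled samples — giving one number per
algorithm next to the per-class metrics. Experiments repeat 50 times
with consecutive seeds; mean and standard deviation are reported.

## Synthetic cohorts

The generator is a linear latent-factor model. Module m has a factor
f_{m,s} = γ·p_m(group(s)) + ε_s, ε_s ~ N(0,1); gene g of module m reads
λ_g f_{m,s} + σ η, with the hub loading λ_hub = 0.95 above the member
loading λ = 0.6 and gene noise σ = 0.5. Noise genes are pure N(0, 0.5²).
Defaults: 5 modules × 30 genes + 850 noise genes; 31 samples in groups
9 (healthy) / 7 (incipient) / 8 (moderate) / 7 (severe). Expected
within-module correlation has the closed form
λ_a λ_b / √((λ_a²+σ²)(λ_b²+σ²)), which the tests verify empirically at
large sample counts.

Stage effects: each module's group-shift pattern p_m is a unit direction
in the 3-dimensional space of group contrasts (with four groups only
three orthogonal non-constant contrasts exist, so five or more modules
with stage effects are necessarily coupled); directions follow the
icosahedral packing, bounding any two modules' shared stage signal at
|cos| = 1/√5 and keeping every patient-group pair well separated in hub
space. The effect scale γ (`group_effect`) defaults to 1.5 — a moderate
shift of 1.5× the residual factor noise, the regime in which both the
module structure and the stage structure are recoverable: much smaller
and the variance curve's critical point blurs into the noise floor, much
larger and within-module correlations saturate, which erodes the hub's
degree margin. The strong-separation regime used for the
perfect-subtyping study sets γ = 3.0 = 6× the gene noise sd. Values can
be exponentiated (2^(x+8)) to mimic raw microarray intensities and
exercise the log₂ screening transform.

What the simulator does *not* emulate: probe-level multiplicity,
platform/batch artifacts, heavy-tailed intensity noise, and
non-linear gene relations. Passing recovery tests therefore shows the
pipeline is correct under its own model assumptions, not that those
assumptions hold for any particular real cohort.

## Problem sizes and determinism

The bundled studies (test suite and `scripts/acceptance.py`) use the
default 1,000-gene × 31-sample cohort over 20 simulation seeds, gap
B = 20 with k ∈ 1..10, and 5–10 subtyping repetitions per seed; the
library defaults (B = 50, 50 repetitions) are used for single analyses.
One global seed hash-derives independent per-stage seeds, so any stage
reproduces in isolation and identical seeds give byte-identical stage
artifacts.

## Known limitations

- **Hub recovery is noise-limited at small sample counts.** With 30
  genes per module, hub/member loadings 0.95/0.6 and σ = 0.5, the hub's
  *expected* weighted degree exceeds every member's, but at n = 31
  samples its margin over the best of 29 equal-loading members
  (≈ 0.1–0.4 correlation units, shrinking as stage effects saturate the
  correlations) is comparable to the sampling noise of summed
  correlation estimates. Monte-Carlo over the exact generator shows the
  true hub tops the degree ranking in only ~56–85 % of modules depending
  on effect size, with no setting reaching 90 %; at n = 100 recovery is
  complete. This is a property of the statistic at that cohort size, not
  of the implementation.
- The sequential gap rule can return K = 1 for symmetric cluster
  layouts, and occasionally splits a module (K = 6) when a handful of
  noise genes pass screening.
- Probe collapsing assigns multi-symbol probes to every listed gene by
  default (configurable to drop them); no normalization or batch
  correction is performed.
- The evaluation protocol label-maps clusters by plurality against the
  clinical stages; with very unbalanced clusters the mapped accuracy can
  exceed what the clustering structure alone would justify.
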