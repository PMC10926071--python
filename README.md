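# netmarker

Network-based biomarker discovery from gene expression data.

`netmarker` implements a pipeline for extracting a compact set of candidate
biomarker genes from a genes × samples expression matrix, and for
classifying patient samples into disease subtypes from those genes alone.
It was built around a case study on Alzheimer's disease microarray cohorts
(healthy / incipient / moderate / severe stage groups, GPL96-style probe
annotation), but every stage is generic. It is aimed at computational
biologists who want an automatic, threshold-free route from an expression
matrix to module hub genes and subtype calls.

## The method

1. **Screening.** Each gene g gets a sensitivity score — by default its
   sample variance Var(xₘ) across all samples (optionally on the
   log₂(x+1) scale), or a label-informativeness score. Scores are sorted
   in descending order and the *critical point* of the curve is detected
   as the breakpoint of the best two-segment piecewise-linear
   least-squares fit: the split index minimizing total SSE over both
   segments. Genes at or above the value at the breakpoint are the
   *sensitive genes*.
2. **Co-expression network.** For sensitive genes n₁, n₂ the edge
   strength is the absolute Pearson correlation
   C(n₁,n₂) = |corr(x_{n₁}, x_{n₂})| ∈ [0,1].
   The off-diagonal correlations are themselves ranked and thresholded at
   their critical point; surviving pairs form a weighted undirected graph.
3. **Modules.** The network is partitioned by k-means on a PCA embedding
   of the correlation profiles, with the module count K chosen by the gap
   statistic (Gap(k) = E*[log W_k] − log W_k, uniform PCA-box reference,
   smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1}); Louvain maximization of
   weighted modularity S = (1/2W) Σ_{ij} [C_ij − k_i k_j / 2W] μ(i,j) is
   available as an alternative.
4. **Representatives.** Inter-module edges are cut; within each module
   every gene's weighted degree k_i = Σ_j w_ij and average shortest path
   length (ASPL, hop counts) are computed on the largest connected
   component. The module representative — the proposed biomarker — has
   the largest degree and smallest ASPL (rank-sum resolution when the two
   criteria disagree).
5. **Subtyping.** Patient samples (healthy excluded) are described by the
   z-scored expression vector of the representatives and clustered with
   k-means (K = 3 or 5), a 2×3 self-organizing map, a competitive
   network, and average-linkage hierarchical clustering. Clusters map to
   clinical stages by plurality vote; precision, recall, F1 and micro
   accuracy are reported per class, aggregated over 50 repeated runs.

A latent-factor simulator (`netmarker.synthetic`) generates cohorts with
planted sensitive genes, hub-anchored modules and stage effects, so every
stage can be validated against ground truth.

## Worked example

```python
from netmarker import SimulationConfig
from netmarker.pipeline import PipelineConfig, run

config = PipelineConfig(
    simulation=SimulationConfig(),        # 5 planted modules, 31 samples
    algorithms=(("som", {"rows": 2, "cols": 3}), ("kmeans", {"k": 3})),
    n_runs=50,
    seed=7,
)
result = run(config)
```

prints (via the returned report):

```text
critical point: rank 150, threshold 0.914
sensitive genes: 150 of 1000
network: 150 nodes, 2190 edges (|r| >= 0.635)
modules: 5
representatives: M01_HUB, M02_HUB, M03_HUB, M04_HUB, M05_HUB
som_2x3: accuracy 0.998 +- 0.009
kmeans_3: accuracy 1.000 +- 0.000
hub recovery vs planted truth: 1.0
```

Reading: the variance curve breaks exactly at rank 150 (the 150 planted
sensitive genes), the thresholded network keeps essentially the
within-module correlations, the gap statistic finds the 5 planted
modules, and the selected representative of every module is its planted
hub. The SOM then recovers the three patient stage groups from the five
hub genes with near-perfect mean accuracy over 50 runs.

The same pipeline runs from the shell:

```bash
netmarker simulate --seed 3 --out data
netmarker screen --expression data/expression.tsv \
    --annotation data/annotation.tsv --transform none --out screen_out
netmarker network --expression screen_out/sensitive_genes.tsv --out edges.tsv
netmarker modules --expression screen_out/sensitive_genes.tsv \
    --edges edges.tsv --k auto --seed 1 --out modules.tsv
netmarker representatives --edges edges.tsv --partition modules.tsv --out reps.tsv
netmarker subtype --expression screen_out/sensitive_genes.tsv \
    --annotation data/annotation.tsv --representatives reps.tsv \
    --algorithm som --grid 2x3 --runs 50 --out subtype.tsv
```

or end-to-end with `netmarker run --config pipeline.yaml`. Real cohorts
are read with `--dialect series_matrix` plus a platform probe→gene
annotation TSV (probe rows mapping to the same symbol are averaged).

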