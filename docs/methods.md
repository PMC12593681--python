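# Methods

## Scope and assumptions

`omicsplex` models a single cohort (one condition) described by L gene-level
omics matrices over possibly different but overlapping gene sets, plus a
curated drug-target table. Gene identifiers are matched exactly across
layers — no alias resolution — so callers must harmonize IDs upstream. The
model assumes that biologically coupled genes leave statistical footprints
within each layer (correlated abundance, co-occurring events) and that a
diffusion process over the coupled layers integrates those footprints into
a single proximity measure in which functional neighbours, including drugs
acting on them, concentrate.

## Preprocessing

Methylation exports that store β − 0.5 are shifted back onto the β scale;
post-offset values outside [0, 1] are an error rather than clipped
silently (only rounding noise of ≤1e−12 is tolerated). Missing entries are
imputed with the gene's median over observed samples; genes with no
observation are dropped and logged with reason code
`DROP_GENE_ALL_MISSING`. The same median imputation is available, opt-in,
for quantitative matrices. Every dropped gene, drug or skipped pair is
logged with a reason code so that final network sizes can be audited from
the log alone.

## Per-layer network inference

**Correlation layers.** All unordered pairs among non-constant genes are
tested. p-values come from the t-transform t = ρ·√((n−2)/(1−ρ²)) with n−2
degrees of freedom; for Spearman this is applied to rank-transformed data
(the standard large-sample approximation — exact permutation would add
nothing at the intended sample sizes). The BH-FDR family is the set of
tested pairs *within the layer*: each layer is an independently interpreted
network, so mixing families across layers would couple unrelated tests. An
edge requires both |ρ| ≥ `min_abs_cor` (default 0.5) and adjusted p <
`max_fdr` (default 0.05); the absolute value is used so strong negative
associations are kept, with the sign stored separately.

**Event layers.** Methylation β values are called methylated at β ≥
`beta_threshold` (default 0.3, a common call cutoff); signed CNV calls are
split into separate amplification (>0) and deletion (<0) event matrices, so
the two derived networks are built from disjoint binarizations. For each
unordered pair of non-constant genes the 2×2 joint-status table is tested
with a two-sided Fisher exact test (sum of hypergeometric point
probabilities ≤ the observed one, with a 1e−7 relative tie tolerance; point
probabilities are cached per margin triple, which makes the all-pairs scan
fast because real event matrices repeat margins heavily). The Bonferroni
factor is the number of *actually tested* pairs. Pairs passing
`bonferroni_alpha` enter a post hoc: each of the four cells is compared to
its independence expectation r<sub>i</sub>c<sub>j</sub>/n with a one-df χ²
on the (cell, rest) split, Bonferroni-adjusted across the four cells; the
edge is kept only when the joint-presence cell is a significant **excess**
(`posthoc_alpha`). Mutually exclusive pairs — significant Fisher but a
joint-presence deficit — are deliberately discarded: the networks encode
co-occurrence, not dependence of any kind. The edge weight is the
joint-presence cell's χ² statistic, a non-negative effect-size-like
quantity.

## Multiplex assembly

Layers are defined over the sorted union of gene labels; genes absent from
a layer become isolated projections so every gene exists in every layer.
Two coupling strategies exist: `node_coupling` joins each gene only to its
own projections (|Genes|·L(L−1)/2 unit-weight edges, the default, matching
the published bookkeeping at cohort scale), and `neighborhood_coupling`
additionally joins gene *i* in layer α to the projections of its layer-α
first-order neighbours in every other layer, deduplicated against the
reverse contribution. Intra-layer weights are flattened to 1 by default
(`weighted_intra=False`); the inferred weights are retained on the network
objects either way. Drugs whose targets all fall outside the multiplex are
dropped before attachment — an isolated drug would trap restart mass during
diffusion. Each surviving bipartite edge is replicated to the target's
projection in every layer with unit weight, giving |E_bipartite|·L
drug-gene edges and a node universe of |Genes|·L + |Drugs|.

## Transition matrix

The column for gene projection g@α distributes: λ to g's drug neighbours
(uniformly) *only if g has any* — otherwise λ-mass would leak from
drug-free genes; the remainder splits (1−δ) over intra-layer neighbours
(weight-proportional when `weighted`, else uniform) and δ over inter-layer
coupled projections (uniform). A projection lacking one of the two
neighbourhoods passes that share to the other; a projection with neither
keeps the remainder as a self-loop. A drug's column sends λ uniformly over
its targets' L projections and keeps 1−λ as a self-loop — there is no
drug-drug layer, so renormalizing the remainder into the bipartite would
change λ's meaning. Any column that would otherwise be empty becomes a
self-loop, so H is column-stochastic for every δ, λ ∈ [0, 1] (fuzz-tested
over the full grid).

## Diffusion and similarity

Power iteration starts at the restart distribution and stops when the L1
change falls below `tol` (1e−10) or after `max_iter` (1000) steps;
non-convergence is flagged and logged, not fatal. With r ≥ 0.1 the
iteration contracts by (1−r) per step, so convergence takes a few dozen
iterations. r = 1 short-circuits to the restart vector. Gene seeds restart
across their L projections with weights τ (uniform 1/L by default); drug
seeds restart wholly at the drug node, since τ is defined over omics
layers. Defaults r = 0.7, δ = 0.5, λ = 0.5 keep the walk local while
letting mass traverse layers and the bipartite freely.

Each stationary vector is collapsed to length |Genes|+|Drugs| by a
geometric mean over layers (default; arithmetic and sum are available) and
rescaled to a probability vector — the rescaling makes columns comparable
across seeds. A geometric mean touching a zero layer stays exactly zero (no
pseudo-count), keeping the similarity sparse and interpretable. The
similarity matrix is built seed-by-seed with independent iterations, so it
is deterministic and embarrassingly parallel over seeds. The trace-back of
a pair's proximity to layers is the renormalized L-vector of the target
gene's projection values in the seed's stationary vector; drugs have a
single compartment and are rejected as trace-back targets.

## Embedding, clustering, enrichment

The default embedding is a truncated SVD of log(1 + S/s̄) (s̄ = mean
positive similarity): the log compresses the heavy-tailed diffusion scores
and the SVD de-noises. A deterministic spectral embedding was chosen over a
stochastic network-embedding procedure because the step is optional for
the model and a deterministic default makes every downstream result
reproducible; factor signs are fixed by making each component's
largest-absolute loading positive. The default dimensionality is 128, sized
for desk-scale runs (the full-rank embedding is an isometry of the
transformed matrix, which the tests exploit). Clustering offers seeded
k-means, average-linkage hierarchical clustering and DBSCAN (noise label
−1); distances are euclidean throughout, matching the evaluation metric.
Over-representation of a gene cluster against a GMT term is the
hypergeometric upper tail of the overlap given cluster size, term∩universe
size and universe size, BH-adjusted across terms; drug nodes are excluded
from universes but participate in clustering and k-NN queries (ties in
k-NN break lexicographically by node ID, making results reproducible).

## Evaluation

Functional recovery is scored with a per-anchor binary silhouette: a = mean
distance to the anchor's co-participants (genes sharing ≥ 1 term; for a
drug anchor, genes in any of its pathways), b = mean distance to the
remaining annotated nodes, score = (b−a)/max(a, b) ∈ [−1, 1]. Unannotated
nodes are excluded both as anchors and as comparison points, keeping
embedding-based and PPI-shortest-path-based scores on the same node
universe. Unreachable PPI pairs are excluded from the means rather than
capped — a cap would introduce an arbitrary constant. Anchors lacking
either class are skipped with a recorded reason; a = b = 0 scores 0 by
convention. The score is invariant to global distance scaling and its mean
under label permutation is ≈ 0, both property-tested.

## Synthetic scenarios

The generator emulates four modalities with planted co-varying modules.
Quantitative blocks use a shared latent factor: gene = √ρ·f + √(1−ρ)·ε
gives expected within-module correlation exactly ρ, so the generator is
testable against a closed form. Event layers draw a hidden per-sample
module event (probability 0.3) that switches all module genes on with a 5%
per-gene miss rate; background genes fire independently at 5%. CNV module
events are amplification or deletion with probability 0.15 each per sample.
β values are drawn from [0.6, 0.95] in event samples and [0.05, 0.25]
otherwise, with 2% missing entries to exercise the imputation path.
Defaults — 150 genes, 3 modules of 20, 200 samples per omics, 12 drugs (8
aligned to modules, 3 targets each), correlation target 0.8, seed 17 —
are the reference scenario for all end-to-end checks.

What the generator does **not** emulate: batch effects, sample subtype
structure, layer-specific missingness patterns, overlapping or nested
modules, hub-dominated degree distributions, or realistic effect-size
gradients. Passing end-to-end tests therefore demonstrates the pipeline's
correctness and its ability to recover clean planted structure at desk
scale, not performance on tumor-cohort data.

## Numerical choices and degenerate inputs

Correlations are clipped to [−1, 1] before the t-transform and |ρ| = 1
maps to p = 0. Constant-status and zero-variance genes are excluded before
the multiple-testing family is counted, keeping the family honest, and are
reported in `inference_meta`. Geometric aggregation uses exp-mean-log on
strictly positive layer tuples to avoid underflow. The pinned tiny fixture
(2 layers, 4 genes, 1 drug) has a hand-enumerated transition matrix and a
stationary vector frozen from the independent linear solve
(I − (1−r)H)p = r·p_RS; power iteration must reproduce it to 1e−8.
k-means runs 50 k-means++ restarts by default: embeddings with many diffuse
background nodes create competing local minima whose inertias differ only
slightly, and few-restart runs land in the worse one on some seeds.

## Problem sizes

End-to-end checks run the 150-gene scenario (762-node heterogeneous
network, 162 diffusions, ~1 s); oracle-equivalence checks use 60-gene
matrices and ≤200-node random networks; the bookkeeping check assembles
empty-layer multiplexes at 19,929×5 and 19,592×4 scale, which only
exercises label union and coupling-edge generation. These sizes were chosen
so the whole suite gives fast, deterministic feedback during development.

## Known limitations

- Exact-match gene IDs: cross-platform identifier drift silently shrinks
  the multiplex union.
- The co-occurrence post hoc realizes a per-cell goodness-of-fit reading of
  "joint-presence excess"; other multiple-comparison contrasts over the
  2×2 cells would admit slightly different edge sets.
- The spectral embedding is not equivalent to stochastic network-embedding
  procedures; absolute factor geometries differ even where downstream
  cluster structure agrees.
- The all-pairs inference is quadratic in gene count; cohort-scale runs
  (~20k genes) need the same chunked strategies as any all-pairs
  correlation scan and are outside the tested envelope.
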