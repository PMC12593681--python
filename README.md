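# omicsplex

Disease-specific, multi-omics views of gene and drug relationships from
nothing but per-cohort omics matrices and a drug-target table.
`omicsplex` infers one gene network per omics layer with statistics suited
to each modality, stacks the layers into a multiplex heterogeneous network
joined to drug nodes, diffuses from every node with a random walk with
restart, and embeds the resulting similarity profiles into a shared latent
space where genes and drugs can be clustered, annotated, and searched by
neighborhood. It is aimed at systems-biology and pharmacology researchers
who want condition-aware gene-gene and gene-drug association maps without
relying on generic interaction databases.

## Model

**Per-layer networks.** Quantitative layers (expression, proteome) get
correlation networks: an edge between genes *i*, *j* iff |ρ<sub>ij</sub>| ≥
ρ<sub>min</sub> and the BH-adjusted correlation-test p < α (Pearson or
Spearman). Event layers (methylation calls, CNV amplification and deletion)
get co-occurrence networks: a two-sided Fisher exact test on each pair's
2×2 joint-status table, Bonferroni-adjusted over tested pairs, followed by a
per-cell χ² goodness-of-fit post hoc that keeps a pair only when the
joint-presence cell is a significant *excess* over its independence
expectation.

**Multiplex heterogeneous network.** The L layer networks share a unified
gene label set (missing genes become isolated projections). Each gene is
coupled to its own projections in the other layers with unit-weight edges
(optionally also to projections of its first-order neighbours), giving
|Genes|·L(L−1)/2 inter-layer edges under node coupling. Drug nodes attach
to every layer projection of their target genes.

**Diffusion.** With column-stochastic transition matrix **H**, restart
probability *r*, layer restart weights **τ**, inter-layer jump probability
δ and gene↔drug transition probability λ, the walk iterates

&nbsp;&nbsp;&nbsp;&nbsp;p<sub>t+1</sub> = (1 − r)·**H**·p<sub>t</sub> + r·p<sub>RS</sub>

to its stationary distribution for every seed node. Per-gene layer values
are collapsed (geometric mean by default) and the rescaled vectors are
concatenated column-wise into the similarity matrix, whose truncated-SVD
embedding supports clustering, hypergeometric over-representation analysis,
k-NN neighborhood search, and a per-anchor binary silhouette evaluation
against functional gene sets. The per-layer slice of a stationary vector
also attributes any pairwise proximity to the omics layers that carry it.

## Worked example

```python
from omicsplex import (RunConfig, SyntheticScenario, generate_multiomics,
                       generate_drug_targets, planted_annotation,
                       run_pipeline, cluster_nodes, evaluate_embedding)
from sklearn.metrics import adjusted_rand_score

s = SyntheticScenario()                     # 150 genes, 3 planted modules, 12 drugs
result = run_pipeline(
    generate_multiomics(s), generate_drug_targets(s),
    RunConfig(correlation_methods={"proteome": "spearman"}),
)
genes = result.embedding.subset("gene")
labels = cluster_nodes(genes, "kmeans", {"n_clusters": 4}, seed=0).labels
module_of = s.module_of()
mod_genes = [g for g in genes.nodes if g in module_of]
print("ARI:", adjusted_rand_score([module_of[g] for g in mod_genes],
                                  [labels[g] for g in mod_genes]))
print("mean silhouette:",
      evaluate_embedding(result.embedding, planted_annotation(s), "gene").mean_score)
```

prints

```
ARI: 1.0
mean silhouette: 0.11224042327371746
```

The five inferred layers (co-expression, co-abundance, co-methylation,
co-amplification, co-deletion) each recover exactly the 570 planted
within-module pairs; clustering the embedded similarity space separates the
three planted modules perfectly (adjusted Rand index 1.0), and genes from
the same module sit measurably closer together than unrelated genes (mean
per-gene silhouette 0.11 > 0; randomly permuted labels score ≈ 0).

The same dataset can be produced and analysed from the shell:

```bash
omicsplex simulate --out data/ --seed 17
omicsplex run --data-dir data/ --out results/ --gmt data/modules.gmt
```

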