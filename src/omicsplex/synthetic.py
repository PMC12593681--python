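"""Synthetic multi-omics scenarios with planted gene modules and aligned drugs.

Correlated quantitative blocks use a shared latent factor per module:
gene_i = sqrt(rho) * f_module + sqrt(1 - rho) * eps_i gives an expected
pairwise within-module correlation of exactly rho, so the generator itself
is testable against a closed form.  Binary layers use a hidden per-sample
module event that switches all module genes on together (with a small miss
probability), yielding a controllable Fisher-test signal; background genes
fire independently at a low rate.  Drugs are either module-aligned (all
targets drawn from one module) or background (targets drawn uniformly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .io import AnnotationSet, DrugGeneBipartite, OmicsMatrix
from .multiplex import MHNetwork, build_mh_network, build_multiplex
from .inference import OmicsNetwork
import pandas as pd


@dataclass
class SyntheticScenario:
    """Defaults: 150 genes, 3 planted modules of 20, 200 samples per omics,
    12 drugs of which 8 are module-aligned, within-module correlation 0.8."""

    n_genes: int = 150
    n_samples: int = 200
    n_modules: int = 3
    module_size: int = 20
    correlation_target: float = 0.8
    event_prob: float = 0.3
    background_event_prob: float = 0.05
    event_miss_prob: float = 0.05
    methylation_missing_rate: float = 0.02
    n_drugs: int = 12
    n_aligned_drugs: int = 8
    targets_per_drug: int = 3
    seed: int = 17

    def __post_init__(self):
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("module sizes exceed the gene universe")
        if not (0 <= self.correlation_target < 1):
            raise ValueError("correlation_target must be in [0, 1)")
        for p in (self.event_prob, self.background_event_prob,
                  self.event_miss_prob, self.methylation_missing_rate):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")
        if self.n_aligned_drugs > self.n_drugs:
            raise ValueError("n_aligned_drugs exceeds n_drugs")
        if self.targets_per_drug > self.module_size:
            raise ValueError("targets_per_drug exceeds module_size")

    @property
    def gene_ids(self) -> list:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    @property
    def sample_ids(self) -> list:
        return [f"S{i + 1:03d}" for i in range(self.n_samples)]

    def modules(self) -> dict:
        """Planted module membership: term -> gene set (background genes unlabelled)."""
        genes = self.gene_ids
        return {
            f"module_{m + 1}": frozenset(
                genes[m * self.module_size:(m + 1) * self.module_size]
            )
            for m in range(self.n_modules)
        }

    def module_of(self) -> dict:
        out = {}
        for term, gs in self.modules().items():
            for g in gs:
                out[g] = term
        return out


def _correlated_matrix(s: SyntheticScenario, rng, location: float, scale: float) -> np.ndarray:
    rho = s.correlation_target
    vals = rng.normal(size=(s.n_genes, s.n_samples))
    for m in range(s.n_modules):
        f = rng.normal(size=s.n_samples)
        rows = slice(m * s.module_size, (m + 1) * s.module_size)
        vals[rows] = np.sqrt(rho) * f + np.sqrt(1 - rho) * vals[rows]
    return location + scale * vals


def _event_matrix(s: SyntheticScenario, rng, module_event_prob: float) -> np.ndarray:
    events = rng.random((s.n_genes, s.n_samples)) < s.background_event_prob
    for m in range(s.n_modules):
        mod_event = rng.random(s.n_samples) < module_event_prob
        miss = rng.random((s.module_size, s.n_samples)) < s.event_miss_prob
        rows = slice(m * s.module_size, (m + 1) * s.module_size)
        events[rows] = mod_event[None, :] & ~miss
    return events


def generate_multiomics(s: SyntheticScenario) -> list:
    """Expression, proteome, methylation (beta) and CNV matrices for the scenario.

    Same seed gives byte-identical matrices.  The methylation matrix carries
    a small fraction of missing entries for the imputation path to handle.
    """
    rng = np.random.default_rng(s.seed)
    genes, samples = s.gene_ids, s.sample_ids

    expression = OmicsMatrix(
        genes, samples, _correlated_matrix(s, rng, location=6.0, scale=1.5),
        "expression", "quantitative",
    )
    proteome = OmicsMatrix(
        genes, samples, _correlated_matrix(s, rng, location=0.0, scale=1.0),
        "proteome", "quantitative",
    )

    meth_events = _event_matrix(s, rng, s.event_prob)
    beta = np.where(
        meth_events,
        rng.uniform(0.6, 0.95, size=meth_events.shape),
        rng.uniform(0.05, 0.25, size=meth_events.shape),
    )
    if s.methylation_missing_rate > 0:
        beta[rng.random(beta.shape) < s.methylation_missing_rate] = np.nan
    methylation = OmicsMatrix(genes, samples, beta, "methylation", "beta")

    # per sample a module is amplified, deleted, or quiet
    u = rng.random((s.n_modules, s.n_samples))
    cnv = np.zeros((s.n_genes, s.n_samples))
    bg = rng.random((s.n_genes, s.n_samples))
    cnv[bg < s.background_event_prob / 2] = 1.0
    cnv[bg > 1 - s.background_event_prob / 2] = -1.0
    miss = rng.random((s.n_genes, s.n_samples)) < s.event_miss_prob
    for m in range(s.n_modules):
        rows = slice(m * s.module_size, (m + 1) * s.module_size)
        amp = (u[m] < s.event_prob / 2)[None, :] & ~miss[rows]
        dele = (u[m] > 1 - s.event_prob / 2)[None, :] & ~miss[rows]
        block = np.zeros((s.module_size, s.n_samples))
        block[amp] = 1.0
        block[dele] = -1.0
        cnv[rows] = block
    cnv_matrix = OmicsMatrix(genes, samples, cnv, "cnv", "cnv")

    return [expression, proteome, methylation, cnv_matrix]


def generate_drug_targets(s: SyntheticScenario) -> DrugGeneBipartite:
    """Module-aligned drugs target a single module; background drugs target uniformly."""
    rng = np.random.default_rng(s.seed + 1)
    genes = s.gene_ids
    modules = list(s.modules().values())
    edges = set()
    for i in range(s.n_drugs):
        drug = f"D{i + 1:02d}"
        if i < s.n_aligned_drugs and s.n_modules > 0:
            pool = sorted(modules[i % s.n_modules])
        else:
            pool = genes
        targets = rng.choice(pool, size=s.targets_per_drug, replace=False)
        edges.update((drug, str(g)) for g in targets)
    return DrugGeneBipartite(frozenset(edges))


def aligned_drug_modules(s: SyntheticScenario) -> dict:
    """Ground-truth module term for each module-aligned drug."""
    terms = sorted(s.modules())
    return {
        f"D{i + 1:02d}": terms[i % s.n_modules] for i in range(s.n_aligned_drugs)
    }


def planted_annotation(s: SyntheticScenario) -> AnnotationSet:
    """One term per planted module; the ground truth for enrichment and silhouette checks."""
    return AnnotationSet(
        s.modules(), {t: "planted module" for t in s.modules()}
    )


def random_mh_network(rng, n_genes=None, n_layers=None, n_drugs=None,
                      edge_prob: float = 0.15) -> MHNetwork:
    """Random MH fixture for fuzz and oracle tests (not a study condition)."""
    n_genes = int(n_genes if n_genes is not None else rng.integers(4, 25))
    n_layers = int(n_layers if n_layers is not None else rng.integers(1, 5))
    n_drugs = int(n_drugs if n_drugs is not None else rng.integers(0, 5))
    genes = [f"g{i}" for i in range(n_genes)]
    nets = []
    for layer in range(n_layers):
        recs = []
        for i in range(n_genes):
            for j in range(i + 1, n_genes):
                if rng.random() < edge_prob:
                    recs.append((genes[i], genes[j], rng.uniform(0.1, 1.0), 1, 0.0, 0.01))
        edges = pd.DataFrame(
            recs, columns=["source", "target", "weight", "sign", "statistic", "adjusted_p"]
        )
        nets.append(OmicsNetwork(f"layer{layer}", genes, edges))
    strategy = "node_coupling" if rng.random() < 0.5 else "neighborhood_coupling"
    mx = build_multiplex(nets, strategy=strategy, weighted_intra=bool(rng.random() < 0.5))
    edges = set()
    for d in range(n_drugs):
        k = int(rng.integers(1, max(2, n_genes // 3)))
        for g in rng.choice(genes, size=min(k, n_genes), replace=False):
            edges.add((f"d{d}", str(g)))
    return build_mh_network(mx, DrugGeneBipartite(frozenset(edges)))


def tiny_mh_example():
    """Fixed hand-checkable fixture: 2 layers, 4 genes, 1 drug.

    Layer 1 links G1-G2 and G2-G3; layer 2 links G1-G3 and G3-G4; drug D1
    targets G1.  Returns the MH network plus the reference diffusion
    parameters (r=0.5, delta=0.5, lambda=0.5, uniform tau, unweighted,
    node coupling) under which the transition matrix is hand-enumerable.
    """
    genes = ["G1", "G2", "G3", "G4"]

    def net(name, pairs):
        edges = pd.DataFrame(
            [(a, b, 1.0, 1, 1.0, 0.01) for a, b in pairs],
            columns=["source", "target", "weight", "sign", "statistic", "adjusted_p"],
        )
        return OmicsNetwork(name, genes, edges)

    mx = build_multiplex(
        [net("alpha", [("G1", "G2"), ("G2", "G3")]), net("beta", [("G1", "G3"), ("G3", "G4")])],
        strategy="node_coupling",
        weighted_intra=False,
    )
    mh = build_mh_network(mx, DrugGeneBipartite(frozenset({("D1", "G1")})))
    params = RunConfig(r=0.5, delta=0.5, lam=0.5, weighted=False)
    return mh, params
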