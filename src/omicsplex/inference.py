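"""Per-layer gene network inference.

Quantitative layers (expression, proteome) yield correlation networks:
Pearson or Spearman coefficients over all unordered gene pairs, tested with
the t-distribution transform and BH-FDR adjusted within the layer.

Binary layers (methylation calls, amplification, deletion) yield
co-occurrence networks: an exact two-sided Fisher test on every pair's 2x2
joint-status table, Bonferroni-adjusted over the tested pairs, followed by a
per-cell chi-square goodness-of-fit post hoc that keeps a pair only when the
joint-presence cell is a significant excess over its independence
expectation.  Edge weights are non-negative statistics; association sign is
stored separately so diffusion never sees negative weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .io import OmicsMatrix

logger = logging.getLogger("omicsplex")

EDGE_COLUMNS = ["source", "target", "weight", "sign", "statistic", "adjusted_p"]


@dataclass
class OmicsNetwork:
    """Undirected weighted gene network inferred from a single omics layer.

    ``edges`` holds one record per unordered significant pair with columns
    source, target, weight (non-negative), sign (+1/-1), statistic (raw test
    statistic) and adjusted_p.  ``nodes`` lists every gene profiled in the
    layer, including genes left isolated by the significance filter.
    """

    layer_name: str
    nodes: list
    edges: pd.DataFrame
    inference_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = list(self.nodes)
        if self.edges is None or len(self.edges) == 0:
            self.edges = pd.DataFrame(columns=EDGE_COLUMNS)
        self.edges = self.edges.reset_index(drop=True)
        if list(self.edges.columns) != EDGE_COLUMNS:
            raise ValueError(f"edge table must have columns {EDGE_COLUMNS}")
        if len(self.edges):
            if (self.edges["source"] == self.edges["target"]).any():
                raise ValueError("self-loops are not allowed")
            pairs = {frozenset((s, t)) for s, t in zip(self.edges["source"], self.edges["target"])}
            if len(pairs) != len(self.edges):
                raise ValueError("duplicate records for an unordered gene pair")
            w = self.edges["weight"].to_numpy(dtype=float)
            if not np.isfinite(w).all() or (w < 0).any():
                raise ValueError("edge weights must be finite and non-negative")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self, genes=None, weighted: bool = True) -> sparse.csr_matrix:
        """Symmetric adjacency over ``genes`` order (defaults to ``self.nodes``)."""
        genes = list(genes) if genes is not None else self.nodes
        idx = {g: i for i, g in enumerate(genes)}
        n = len(genes)
        if not len(self.edges):
            return sparse.csr_matrix((n, n))
        rows = [idx[g] for g in self.edges["source"]]
        cols = [idx[g] for g in self.edges["target"]]
        vals = self.edges["weight"].to_numpy(dtype=float) if weighted else np.ones(len(rows))
        a = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
        return (a + a.T).tocsr()


def write_edge_list(networks, path) -> None:
    """Serialize one or more networks as a TSV edge list (source, target, layer, ...)."""
    if isinstance(networks, OmicsNetwork):
        networks = [networks]
    frames = []
    for net in networks:
        df = net.edges.copy()
        df.insert(2, "layer", net.layer_name)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str, "layer": str})
    nets = []
    for layer, sub in df.groupby("layer", sort=False):
        edges = sub.drop(columns="layer").reset_index(drop=True)
        nodes = sorted(set(edges["source"]) | set(edges["target"]))
        nets.append(OmicsNetwork(layer, nodes, edges))
    return nets


# ---------------------------------------------------------------------------
# Correlation networks (quantitative layers)
# ---------------------------------------------------------------------------

def infer_correlation_network(
    m: OmicsMatrix,
    method: str = "pearson",
    min_abs_cor: float = 0.5,
    max_fdr: float = 0.05,
) -> OmicsNetwork:
    """Correlation network: edge iff |rho| >= min_abs_cor and BH-adjusted p < max_fdr.

    p-values use the t-transform t = rho * sqrt((n-2)/(1-rho^2)) (for Spearman
    this is the standard large-sample approximation on ranks).  Zero-variance
    genes are excluded from testing and reported in ``inference_meta``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be pearson|spearman")
    if m.modality != "quantitative":
        raise ValueError(f"correlation inference requires a quantitative layer, got {m.modality}")
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation test")
    if not (0 < min_abs_cor < 1):
        raise ValueError("min_abs_cor must be in (0, 1)")
    if m.has_missing:
        raise ValueError("missing values present; impute before correlation inference")

    X = m.values
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
    sd = X.std(axis=1)
    keep = sd > 0
    excluded = [g for g, k in zip(m.gene_ids, keep) if not k]
    for g in excluded:
        logger.info("SKIP_GENE_ZERO_VARIANCE layer=%s gene=%s", m.layer_name, g)
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    n = m.n_samples
    meta = {
        "test": f"{method} correlation (t-transform)",
        "min_abs_cor": min_abs_cor,
        "max_fdr": max_fdr,
        "n_samples": n,
        "excluded_genes": excluded,
    }
    if len(genes) < 2:
        return OmicsNetwork(m.layer_name, list(m.gene_ids), None, meta)

    R = np.corrcoef(X[keep])
    iu, ju = np.triu_indices(len(genes), k=1)
    rho = np.clip(R[iu, ju], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1 - rho**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1 - 1e-15] = 0.0
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    meta["n_tested_pairs"] = len(p)

    mask = (np.abs(rho) >= min_abs_cor) & (p_adj < max_fdr)
    edges = pd.DataFrame(
        {
            "source": [genes[i] for i in iu[mask]],
            "target": [genes[j] for j in ju[mask]],
            "weight": np.abs(rho[mask]),
            "sign": np.sign(rho[mask]).astype(int),
            "statistic": rho[mask],
            "adjusted_p": p_adj[mask],
        }
    )
    return OmicsNetwork(m.layer_name, list(m.gene_ids), edges, meta)


# ---------------------------------------------------------------------------
# Binarization helpers
# ---------------------------------------------------------------------------

def binarize_methylation(m: OmicsMatrix, beta_threshold: float = 0.3) -> OmicsMatrix:
    """Call methylation status: 1 iff beta >= threshold."""
    if m.modality != "beta":
        raise ValueError("binarize_methylation requires a beta matrix")
    if not (0 < beta_threshold < 1):
        raise ValueError("beta_threshold must be in (0, 1)")
    if m.has_missing:
        raise ValueError("missing values present; impute before binarization")
    vals = (m.values >= beta_threshold).astype(float)
    return OmicsMatrix(m.gene_ids, m.sample_ids, vals, m.layer_name, "binary")


def split_cnv(m: OmicsMatrix):
    """Split signed copy-number calls into amplification (>0) and deletion (<0) event matrices."""
    if m.modality != "cnv":
        raise ValueError("split_cnv requires a cnv matrix")
    if m.has_missing:
        raise ValueError("missing values present; impute before splitting")
    amp = OmicsMatrix(
        m.gene_ids, m.sample_ids, (m.values > 0).astype(float),
        f"{m.layer_name}_amplification", "binary",
    )
    dele = OmicsMatrix(
        m.gene_ids, m.sample_ids, (m.values < 0).astype(float),
        f"{m.layer_name}_deletion", "binary",
    )
    return amp, dele


# ---------------------------------------------------------------------------
# Fisher exact test and co-occurrence networks (binary layers)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=100_000)
def _hypergeom_pmf(n: int, r1: int, c1: int):
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    ks = np.arange(lo, hi + 1)
    return lo, stats.hypergeom.pmf(ks, n, r1, c1)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities <= the observed one."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(t, np.round(t)):
        raise ValueError("counts must be integers")
    a, b, c, d = (int(round(x)) for x in t.ravel())
    n = a + b + c + d
    if n == 0:
        raise ValueError("table total must be positive")
    r1, c1 = a + b, a + c
    lo, pmf = _hypergeom_pmf(n, r1, c1)
    p_obs = pmf[a - lo]
    # relative tolerance guards against ties lost to floating-point noise
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def _posthoc_joint_presence(a: int, r1: int, c1: int, n: int, alpha: float):
    """Per-cell chi-square goodness-of-fit of the 2x2 table against independence.

    Each observed cell count is compared with its expectation r_i*c_j/n via a
    one-df chi-square on the (cell, rest) split, Bonferroni-adjusted across
    the four cells.  Returns (keep, statistic) where keep is True iff the
    joint-presence cell is a significant excess.
    """
    obs = np.array([a, r1 - a, c1 - a, n - r1 - c1 + a], dtype=float)
    exp = np.array(
        [r1 * c1, r1 * (n - c1), (n - r1) * c1, (n - r1) * (n - c1)], dtype=float
    ) / n
    stat = (obs - exp) ** 2 * n / (exp * (n - exp))
    p_cells = stats.chi2.sf(stat, df=1)
    p_adj = np.minimum(1.0, 4 * p_cells)
    keep = bool(obs[0] > exp[0] and p_adj[0] < alpha)
    return keep, float(stat[0])


def infer_cooccurrence_network(
    m: OmicsMatrix,
    bonferroni_alpha: float = 0.05,
    posthoc_alpha: float = 0.05,
) -> OmicsNetwork:
    """Co-occurrence network from a binary event matrix.

    Every unordered pair of non-constant genes is Fisher-tested on its 2x2
    joint-status table; the Bonferroni family is the set of actually tested
    pairs.  Surviving pairs pass to the joint-presence excess post hoc; the
    edge weight is the joint-presence cell's chi-square statistic.
    """
    if m.modality != "binary":
        raise ValueError("co-occurrence inference requires a binary matrix")
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if m.has_missing:
        raise ValueError("missing values present; impute before inference")

    B = m.values.astype(np.int64)
    n = m.n_samples
    s = B.sum(axis=1)
    keep = (s > 0) & (s < n)
    skipped = [g for g, k in zip(m.gene_ids, keep) if not k]
    for g in skipped:
        logger.info("SKIP_GENE_CONSTANT_STATUS layer=%s gene=%s", m.layer_name, g)
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    meta = {
        "test": "fisher exact + joint-presence chi-square post hoc",
        "bonferroni_alpha": bonferroni_alpha,
        "posthoc_alpha": posthoc_alpha,
        "n_samples": n,
        "skipped_genes": skipped,
    }
    if len(genes) < 2:
        return OmicsNetwork(m.layer_name, list(m.gene_ids), None, meta)

    Bk = B[keep]
    sk = s[keep]
    joint = Bk @ Bk.T
    iu, ju = np.triu_indices(len(genes), k=1)
    n_pairs = len(iu)
    meta["n_tested_pairs"] = n_pairs

    records = []
    for i, j in zip(iu, ju):
        a, r1, c1 = int(joint[i, j]), int(sk[i]), int(sk[j])
        lo, pmf = _hypergeom_pmf(n, r1, c1)
        p = float(min(1.0, pmf[pmf <= pmf[a - lo] * (1 + 1e-7)].sum()))
        p_bonf = min(1.0, p * n_pairs)
        if p_bonf >= bonferroni_alpha:
            continue
        ok, stat = _posthoc_joint_presence(a, r1, c1, n, posthoc_alpha)
        if not ok:
            logger.info(
                "SKIP_PAIR_NO_JOINT_EXCESS layer=%s pair=%s,%s", m.layer_name, genes[i], genes[j]
            )
            continue
        records.append((genes[i], genes[j], stat, 1, stat, p_bonf))
    edges = pd.DataFrame(records, columns=EDGE_COLUMNS)
    return OmicsNetwork(m.layer_name, list(m.gene_ids), edges, meta)
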