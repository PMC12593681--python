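"""Embedding of the similarity matrix, 2-D reduction, clustering, enrichment, neighborhoods.

The default embedding is a deterministic truncated SVD of the log-scaled
similarity matrix (log(1 + S / s_bar), s_bar = mean positive entry), with
factor signs fixed so the largest-absolute loading of each component is
positive.  Dimensionality reduction offers PCA (deterministic, sign-fixed),
UMAP and t-SNE (seeded).  Cluster annotation uses a local hypergeometric
over-representation test against user-supplied gene sets with BH adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN, KMeans, AgglomerativeClustering
from statsmodels.stats.multitest import multipletests

from .io import AnnotationSet
from .rwr import SimilarityMatrix


@dataclass
class Embedding:
    nodes: list
    node_types: list  # "gene" | "drug" per node
    factors: np.ndarray  # n_nodes x d
    method: str
    d: int

    def __post_init__(self):
        self.factors = np.asarray(self.factors, dtype=float)
        if self.factors.shape[0] != len(self.nodes):
            raise ValueError("factor row count must equal node count")
        if not np.isfinite(self.factors).all():
            raise ValueError("factors must be finite")

    def row(self, node) -> np.ndarray:
        return self.factors[self.nodes.index(node)]

    def subset(self, keep_type: str) -> "Embedding":
        mask = [t == keep_type for t in self.node_types]
        return Embedding(
            [n for n, k in zip(self.nodes, mask) if k],
            [keep_type] * sum(mask),
            self.factors[np.asarray(mask)],
            self.method,
            self.d,
        )


@dataclass
class ClusterAssignment:
    labels: dict  # node -> int (DBSCAN noise = -1)
    method: str
    params: dict = field(default_factory=dict)


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-absolute entry is positive (first index on ties)."""
    U = U.copy()
    for k in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, k])))
        if U[i, k] < 0:
            U[:, k] = -U[:, k]
    return U


def embed_similarity(S: SimilarityMatrix, d: int = 128, method: str = "svd",
                     node_types=None) -> Embedding:
    """Embed similarity columns into a d-factor latent space.

    ``svd`` de-noises via truncated SVD of log(1 + S/s_bar); ``passthrough``
    uses the raw similarity columns as coordinates (d ignored).
    """
    if method not in ("svd", "passthrough"):
        raise ValueError("method must be svd|passthrough")
    n = S.n_nodes
    if node_types is None:
        node_types = ["gene"] * n
    if method == "passthrough":
        return Embedding(list(S.nodes), list(node_types), S.values.T.copy(), method, n)
    if d > n:
        raise ValueError(f"d={d} exceeds node count {n}")
    pos = S.values[S.values > 0]
    s_bar = pos.mean() if pos.size else 1.0
    T = np.log1p(S.values / s_bar)
    U, sv, _ = np.linalg.svd(T, full_matrices=False)
    U = _fix_signs(U[:, :d])
    return Embedding(list(S.nodes), list(node_types), U * sv[:d], method, d)


def reduce_dimensions(e: Embedding, method: str = "pca", k: int = 2, seed: int = 0) -> pd.DataFrame:
    """Reduce factors to k coordinates; PCA is deterministic, UMAP/t-SNE are seeded."""
    if k > e.factors.shape[1]:
        raise ValueError(f"k={k} exceeds factor count {e.factors.shape[1]}")
    X = e.factors
    if method == "pca":
        Xc = X - X.mean(axis=0)
        U, sv, _ = np.linalg.svd(Xc, full_matrices=False)
        coords = _fix_signs(U[:, :k]) * sv[:k]
    elif method == "umap":
        import umap

        coords = umap.UMAP(n_components=k, random_state=seed).fit_transform(X)
    elif method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max(2.0, (len(e.nodes) - 1) / 3.0))
        coords = TSNE(
            n_components=k, random_state=seed, init="pca", perplexity=perplexity
        ).fit_transform(X)
    else:
        raise ValueError("method must be pca|umap|tsne")
    df = pd.DataFrame(coords, columns=[f"dim{i + 1}" for i in range(k)])
    df.insert(0, "node", [str(n) for n in e.nodes])
    df.insert(1, "type", e.node_types)
    return df


def cluster_nodes(e: Embedding, method: str = "kmeans", params=None, seed: int = 0) -> ClusterAssignment:
    """Cluster nodes in factor space; every node receives a label (noise is -1)."""
    params = dict(params or {})
    X = e.factors
    if method == "kmeans":
        k = params.pop("n_clusters", 8)
        if k > len(e.nodes):
            raise ValueError(f"n_clusters={k} exceeds node count {len(e.nodes)}")
        # many k-means++ restarts: diffuse background nodes create competing
        # local minima that few-restart runs fall into
        n_init = params.pop("n_init", 50)
        labels = KMeans(n_clusters=k, random_state=seed, n_init=n_init, **params).fit_predict(X)
    elif method == "hierarchical":
        k = params.pop("n_clusters", 8)
        if k > len(e.nodes):
            raise ValueError(f"n_clusters={k} exceeds node count {len(e.nodes)}")
        params.setdefault("linkage", "average")
        params.setdefault("metric", "euclidean")
        labels = AgglomerativeClustering(n_clusters=k, **params).fit_predict(X)
    elif method == "dbscan":
        labels = DBSCAN(**params).fit_predict(X)
    else:
        raise ValueError("method must be kmeans|hierarchical|dbscan")
    return ClusterAssignment({n: int(l) for n, l in zip(e.nodes, labels)}, method, params)


def enrich_cluster(cluster_genes, ann: AnnotationSet, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene cluster against each term.

    p = upper tail P(overlap >= observed) given cluster size, term-in-universe
    size and universe size; BH-adjusted across terms, sorted by adjusted p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    cluster = set(cluster_genes)
    if not cluster <= universe:
        raise ValueError("cluster genes must be a subset of the universe")
    M, n_cluster = len(universe), len(cluster)
    records = []
    for term, genes in ann.terms.items():
        term_in_univ = genes & universe
        K = len(term_in_univ)
        if K == 0:
            continue
        overlap = len(cluster & term_in_univ)
        p = float(stats.hypergeom.sf(overlap - 1, M, K, n_cluster))
        records.append((term, overlap, K, n_cluster, M, p))
    df = pd.DataFrame(
        records, columns=["term", "overlap", "term_size", "cluster_size", "universe_size", "p"]
    )
    if len(df):
        _, p_adj, _, _ = multipletests(df["p"], method="fdr_bh")
        df["p_adj"] = np.maximum(p_adj, df["p"])
        df = df.sort_values(["p_adj", "p", "term"], kind="stable").reset_index(drop=True)
    else:
        df["p_adj"] = []
    return df


def knn_neighborhood(e: Embedding, node, k: int) -> pd.DataFrame:
    """k nearest nodes by euclidean factor distance; ties broken by node ID."""
    if node not in e.nodes:
        raise KeyError(f"unknown node {node!r}")
    if k >= len(e.nodes):
        raise ValueError(f"k={k} must be smaller than node count {len(e.nodes)}")
    x = e.row(node)
    dist = np.linalg.norm(e.factors - x, axis=1)
    order = sorted(
        (i for i, nd in enumerate(e.nodes) if nd != node),
        key=lambda i: (dist[i], str(e.nodes[i])),
    )[:k]
    return pd.DataFrame(
        {
            "node": [str(e.nodes[i]) for i in order],
            "type": [e.node_types[i] for i in order],
            "distance": [float(dist[i]) for i in order],
        }
    )
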