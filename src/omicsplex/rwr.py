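"""Random walk with restart on the multiplex heterogeneous network.

The walker iterates p_{t+1} = (1 - r) H p_t + r p_RS on a column-stochastic
transition matrix H over the |Genes|*L + |Drugs| node universe.  From a gene
projection, mass lambda goes to the gene's drug neighbours (only when it has
any), and the remainder splits (1 - delta) over intra-layer neighbours
(weight-proportional when requested) and delta over inter-layer coupled
projections.  A projection missing one of those neighbourhoods passes that
share to the other; a node with no outgoing support becomes a self-loop.
From a drug, mass lambda spreads uniformly over its target-gene projections
in all layers and the remainder stays as a self-loop (there is no
drug-drug layer).

Each node of the network is used as a seed in turn; the stationary
distributions, collapsed over layers by a geometric mean (or arithmetic
mean or sum) and rescaled, are concatenated column-wise into the similarity
matrix.  The per-layer slice of a stationary vector also yields the
layer-contribution trace-back for any node pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy import sparse

from .config import RunConfig
from .multiplex import MHNetwork

logger = logging.getLogger("omicsplex")


@dataclass
class TransitionMatrix:
    """Column-stochastic transition matrix with its node addressing.

    Gene projections are addressed ``(gene_id, layer_index)`` and occupy
    index ``layer * n_genes + gene_rank``; drugs follow as bare IDs.
    """

    H: sparse.csc_matrix
    genes: list
    layer_names: list
    drugs: list
    delta: float
    lam: float
    weighted: bool

    @property
    def n_genes(self):
        return len(self.genes)

    @property
    def n_layers(self):
        return len(self.layer_names)

    @property
    def n_nodes(self):
        return self.H.shape[0]

    def node_index(self, node):
        """Index of a ``(gene, layer)`` projection or a drug ID."""
        if isinstance(node, tuple):
            g, layer = node
            return layer * self.n_genes + self.genes.index(g)
        return self.n_genes * self.n_layers + self.drugs.index(node)

    @property
    def aggregated_nodes(self) -> list:
        return list(self.genes) + list(self.drugs)


@dataclass
class SeedProfile:
    seed_id: object
    p_rs: np.ndarray

    def __post_init__(self):
        self.p_rs = np.asarray(self.p_rs, dtype=float)
        if (self.p_rs < 0).any() or abs(self.p_rs.sum() - 1) > 1e-9:
            raise ValueError("restart distribution must be non-negative and sum to 1")


@dataclass
class ProximityVector:
    seed_id: object
    p: np.ndarray
    iterations: int
    converged: bool


@dataclass
class SimilarityMatrix:
    """Column-wise assembly of aggregated stationary distributions (genes then drugs)."""

    nodes: list
    values: np.ndarray  # (n_genes + n_drugs) square, column j = seed j
    aggregation: str
    convergence: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_nodes(self):
        return len(self.nodes)

    def column(self, node) -> np.ndarray:
        return self.values[:, self.nodes.index(node)]


def build_transition_matrix(
    mh: MHNetwork, delta: float = 0.5, lam: float = 0.5, weighted: bool = False
) -> TransitionMatrix:
    """Build the column-normalized transition matrix of the MH network."""
    if not (0 <= delta <= 1) or not (0 <= lam <= 1):
        raise ValueError("delta and lam must lie in [0, 1]")
    mx = mh.multiplex
    genes, L, N, D = mx.genes, mx.n_layers, mx.n_genes, mh.n_drugs
    n = N * L + D
    gidx = {g: i for i, g in enumerate(genes)}
    didx = {d: i for i, d in enumerate(mh.drugs)}

    # inter-layer neighbour lists per gene-projection index
    inter_nbrs = [[] for _ in range(N * L)]
    for (la, ga), (lb, gb) in mx.inter_layer_edges:
        u = la * N + gidx[ga]
        v = lb * N + gidx[gb]
        inter_nbrs[u].append(v)
        inter_nbrs[v].append(u)

    adj = [a.tocsr() for a in mx.adjacency]
    rows, cols, vals = [], [], []

    def put(col, idxs, masses):
        cols.extend([col] * len(idxs))
        rows.extend(idxs)
        vals.extend(masses)

    for layer in range(L):
        A = adj[layer]
        for gi in range(N):
            col = layer * N + gi
            gene = genes[gi]
            drug_ids = [N * L + didx[d] for d in mh.gene_to_drugs.get(gene, [])]
            lam_eff = lam if drug_ids else 0.0
            if drug_ids and lam_eff > 0:
                put(col, drug_ids, [lam_eff / len(drug_ids)] * len(drug_ids))
            rest = 1.0 - lam_eff
            lo, hi = A.indptr[gi], A.indptr[gi + 1]
            intra_idx = A.indices[lo:hi] + layer * N
            intra_w = A.data[lo:hi] if weighted else np.ones(hi - lo)
            inter_idx = inter_nbrs[col]
            has_intra, has_inter = len(intra_idx) > 0, len(inter_idx) > 0
            if rest > 0:
                if has_intra and has_inter:
                    intra_share, inter_share = rest * (1 - delta), rest * delta
                elif has_intra:
                    intra_share, inter_share = rest, 0.0
                elif has_inter:
                    intra_share, inter_share = 0.0, rest
                else:
                    put(col, [col], [rest])
                    intra_share = inter_share = 0.0
                if intra_share > 0:
                    put(col, list(intra_idx), list(intra_share * intra_w / intra_w.sum()))
                if inter_share > 0:
                    put(col, inter_idx, [inter_share / len(inter_idx)] * len(inter_idx))
            elif not drug_ids:
                put(col, [col], [1.0])

    for d in mh.drugs:
        col = N * L + didx[d]
        targets = mh.bipartite.targets_of(d)
        proj = [layer * N + gidx[g] for layer in range(L) for g in targets]
        if lam > 0 and proj:
            put(col, proj, [lam / len(proj)] * len(proj))
            if lam < 1:
                put(col, [col], [1.0 - lam])
        else:
            put(col, [col], [1.0])

    H = sparse.csc_matrix((vals, (rows, cols)), shape=(n, n))
    # any column that collected no mass (cannot happen by construction, but be safe)
    colsums = np.asarray(H.sum(axis=0)).ravel()
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        H = H + sparse.csc_matrix(
            (np.ones(zero.size), (zero, zero)), shape=(n, n)
        )
    return TransitionMatrix(H, genes, mx.layer_names, mh.drugs, delta, lam, weighted)


def seed_profile(T: TransitionMatrix, seed_id, tau=None) -> SeedProfile:
    """Restart distribution: a gene restarts over its L projections weighted by tau;
    a drug restarts wholly at its own node."""
    p0 = np.zeros(T.n_nodes)
    if seed_id in T.genes:
        gi = T.genes.index(seed_id)
        if tau is None:
            tau = np.full(T.n_layers, 1.0 / T.n_layers)
        tau = np.asarray(tau, dtype=float)
        if len(tau) != T.n_layers or (tau < 0).any():
            raise ValueError("tau needs one non-negative entry per layer")
        if tau.sum() <= 0:
            raise ValueError("tau must have positive total mass")
        for layer in range(T.n_layers):
            p0[layer * T.n_genes + gi] = tau[layer]
        p0 /= p0.sum()
    elif seed_id in T.drugs:
        p0[T.node_index(seed_id)] = 1.0
    else:
        raise KeyError(f"unknown seed node {seed_id!r}")
    return SeedProfile(seed_id, p0)


def rwr_from_seed(
    T: TransitionMatrix,
    seed: SeedProfile,
    r: float = 0.7,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> ProximityVector:
    """Power-iterate the restart recursion to its stationary proximity vector."""
    if not (0 < r <= 1):
        raise ValueError("r must be in (0, 1]")
    if r == 1.0:
        return ProximityVector(seed.seed_id, seed.p_rs.copy(), 1, True)
    H = T.H
    p = seed.p_rs.copy()
    for it in range(1, max_iter + 1):
        p_next = (1 - r) * (H @ p) + r * seed.p_rs
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < tol:
            return ProximityVector(seed.seed_id, p, it, True)
    logger.warning("RWR_NOT_CONVERGED seed=%s iterations=%d l1=%.3g", seed.seed_id, max_iter, delta)
    return ProximityVector(seed.seed_id, p, max_iter, False)


def aggregate_proximity(pv: ProximityVector, T: TransitionMatrix, method: str = "geometric") -> np.ndarray:
    """Collapse a stationary vector's L gene projections per gene and rescale to sum 1.

    The geometric mean of layer values containing a zero is zero (no epsilon),
    keeping the similarity sparse.
    """
    if method not in ("geometric", "arithmetic", "sum"):
        raise ValueError("method must be geometric|arithmetic|sum")
    N, L = T.n_genes, T.n_layers
    gene_part = pv.p[: N * L].reshape(L, N)
    if method == "arithmetic":
        agg = gene_part.mean(axis=0)
    elif method == "sum":
        agg = gene_part.sum(axis=0)
    else:
        positive = (gene_part > 0).all(axis=0)
        agg = np.zeros(N)
        if positive.any():
            agg[positive] = np.exp(np.log(gene_part[:, positive]).mean(axis=0))
    out = np.concatenate([agg, pv.p[N * L:]])
    total = out.sum()
    if total > 0:
        out = out / total
    return out


def build_similarity_matrix(mh: MHNetwork, config: RunConfig) -> SimilarityMatrix:
    """One RWR per node of the MH network, aggregated and assembled column-wise."""
    T = build_transition_matrix(mh, config.delta, config.lam, config.weighted)
    nodes = T.aggregated_nodes
    S = np.zeros((len(nodes), len(nodes)))
    conv = []
    for j, node in enumerate(nodes):
        sp = seed_profile(T, node, config.tau if node in T.genes else None)
        pv = rwr_from_seed(T, sp, config.r, config.tol, config.max_iter)
        S[:, j] = aggregate_proximity(pv, T, config.aggregation)
        conv.append((str(node), pv.iterations, pv.converged))
    report = pd.DataFrame(conv, columns=["seed", "iterations", "converged"])
    n_bad = int((~report["converged"]).sum())
    if n_bad:
        logger.warning("SIMILARITY_NONCONVERGED_SEEDS n=%d", n_bad)
    return SimilarityMatrix(nodes, S, config.aggregation, report)


def layer_contribution(pv: ProximityVector, T: TransitionMatrix, node2) -> np.ndarray:
    """Fraction of node2's proximity carried by each omics layer in the seed's vector."""
    if node2 not in T.genes:
        raise ValueError(
            "layer contributions are defined for gene targets only; "
            "drugs occupy a single compartment - read the raw proximity instead"
        )
    gi = T.genes.index(node2)
    slice_ = pv.p[[layer * T.n_genes + gi for layer in range(T.n_layers)]]
    total = slice_.sum()
    if total == 0:
        logger.warning("LAYER_CONTRIBUTION_ZERO seed=%s target=%s", pv.seed_id, node2)
        return np.zeros(T.n_layers)
    return slice_ / total


def write_similarity(S: SimilarityMatrix, h5_path, nodes_path) -> None:
    """Dense HDF5 container plus a node-order TSV."""
    with h5py.File(h5_path, "w") as fh:
        fh.create_dataset("similarity", data=S.values)
        fh.attrs["aggregation"] = S.aggregation
    pd.DataFrame({"node": [str(n) for n in S.nodes]}).to_csv(nodes_path, sep="\t", index=False)


def read_similarity(h5_path, nodes_path) -> SimilarityMatrix:
    with h5py.File(h5_path, "r") as fh:
        values = fh["similarity"][...]
        aggregation = fh.attrs["aggregation"]
    nodes = pd.read_csv(nodes_path, sep="\t", dtype=str)["node"].tolist()
    return SimilarityMatrix(nodes, values, str(aggregation))
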