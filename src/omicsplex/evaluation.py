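"""Functional evaluation: silhouette of co-participation labels against distances.

Genes are labelled co-participants when they share at least one functional
term; a drug's co-participants are the genes appearing in any of its
associated pathways.  For each eligible anchor the binary silhouette is
(b - a) / max(a, b), with a the mean distance to co-participants and b the
mean distance to the remaining annotated nodes.  Distances come either from
the embedding space (euclidean) or from shortest paths in a reference PPI
network; infinite path distances are excluded from the means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .embedding import Embedding
from .io import AnnotationSet

logger = logging.getLogger("omicsplex")


@dataclass
class CoParticipationMatrix:
    """Binary label matrix: rows are anchors, columns are comparison nodes."""

    row_nodes: list
    col_nodes: list
    values: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=int)
        if self.values.shape != (len(self.row_nodes), len(self.col_nodes)):
            raise ValueError("matrix shape must match node orders")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("entries must be binary")


@dataclass
class SilhouetteReport:
    scores: pd.DataFrame  # anchor, type, score, n_within, n_between
    skipped: list  # (anchor, reason)
    distance_source: str
    summary: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.scores):
            s = self.scores["score"].to_numpy()
            if (s < -1 - 1e-12).any() or (s > 1 + 1e-12).any():
                raise ValueError("silhouette scores must lie in [-1, 1]")
            self.summary = {
                "n_anchors": int(len(s)),
                "mean": float(np.mean(s)),
                "median": float(np.median(s)),
                "q25": float(np.percentile(s, 25)),
                "q75": float(np.percentile(s, 75)),
            }

    @property
    def mean_score(self) -> float:
        return self.summary.get("mean", float("nan"))


def coparticipation_matrix(ann: AnnotationSet, nodes) -> CoParticipationMatrix:
    """Gene-by-gene co-participation: 1 iff the pair shares >= 1 term; diagonal 0."""
    nodes = list(nodes)
    terms = list(ann.terms.values())
    M = np.zeros((len(nodes), len(terms)), dtype=int)
    for j, genes in enumerate(terms):
        for i, g in enumerate(nodes):
            if g in genes:
                M[i, j] = 1
    C = ((M @ M.T) > 0).astype(int)
    np.fill_diagonal(C, 0)
    return CoParticipationMatrix(nodes, nodes, C, source="gene-term")


def drug_gene_coparticipation(drug_pathways: dict, nodes) -> CoParticipationMatrix:
    """Drug-by-gene matrix: 1 iff the gene appears in any of the drug's pathway gene sets."""
    nodes = list(nodes)
    drugs = sorted(drug_pathways)
    V = np.zeros((len(drugs), len(nodes)), dtype=int)
    for i, d in enumerate(drugs):
        union = set()
        for gs in drug_pathways[d]:
            union |= set(gs)
        if not union:
            logger.info("SKIP_DRUG_NO_PATHWAYS drug=%s", d)
        for j, g in enumerate(nodes):
            if g in union:
                V[i, j] = 1
    return CoParticipationMatrix(drugs, nodes, V, source="drug-pathway")


def node_silhouette(distances: np.ndarray, labels: np.ndarray, self_index: int | None = None):
    """Binary silhouette of one anchor.

    ``distances``: anchor-to-comparison distances (inf allowed, excluded);
    ``labels``: binary co-participation flags aligned with distances;
    ``self_index``: position of the anchor itself, excluded if given.
    Returns (score, n_within, n_between) or (None, reason) via ValueError-free skip.
    """
    distances = np.asarray(distances, dtype=float)
    labels = np.asarray(labels, dtype=int)
    mask = np.isfinite(distances)
    if self_index is not None:
        mask[self_index] = False
    within = distances[mask & (labels == 1)]
    between = distances[mask & (labels == 0)]
    if within.size == 0:
        return None, "no co-participant with finite distance"
    if between.size == 0:
        return None, "no non-co-participant with finite distance"
    a, b = within.mean(), between.mean()
    if a == 0 and b == 0:
        logger.warning("SILHOUETTE_DEGENERATE a=b=0")
        return (0.0, int(within.size), int(between.size)), None
    return (float((b - a) / max(a, b)), int(within.size), int(between.size)), None


def shortest_path_distances(edges, nodes) -> pd.DataFrame:
    """Hop-count distances over an unweighted undirected PPI; unreachable pairs are inf."""
    G = nx.Graph()
    G.add_edges_from((str(u), str(v)) for u, v in edges)
    nodes = [str(n) for n in nodes]
    D = np.full((len(nodes), len(nodes)), np.inf)
    np.fill_diagonal(D, 0.0)
    idx = {n: i for i, n in enumerate(nodes)}
    for n in nodes:
        if n not in G:
            continue
        for other, d in nx.single_source_shortest_path_length(G, n).items():
            if other in idx:
                D[idx[n], idx[other]] = d
    if np.isinf(D).any():
        logger.info("PPI_DISCONNECTED_PAIRS n=%d", int(np.isinf(D).sum()))
    return pd.DataFrame(D, index=nodes, columns=nodes)


def _silhouette_over_anchors(dist: np.ndarray, labels: CoParticipationMatrix,
                             anchor_types, self_map, source: str) -> SilhouetteReport:
    records, skipped = [], []
    for i, anchor in enumerate(labels.row_nodes):
        res, reason = node_silhouette(dist[i], labels.values[i], self_map(i))
        if res is None:
            skipped.append((anchor, reason))
            logger.info("SKIP_ANCHOR anchor=%s reason=%s", anchor, reason)
        else:
            score, nw, nb = res
            records.append((str(anchor), anchor_types[i], score, nw, nb))
    scores = pd.DataFrame(records, columns=["anchor", "type", "score", "n_within", "n_between"])
    return SilhouetteReport(scores, skipped, source)


def evaluate_embedding(
    e: Embedding,
    ann: AnnotationSet,
    mode: str = "gene",
    drug_pathways: dict | None = None,
) -> SilhouetteReport:
    """Silhouette of co-participation labels against euclidean factor distances.

    ``gene`` mode anchors every annotated gene against the other annotated
    genes; ``drug`` mode anchors drugs (with pathway annotations) against
    annotated genes.  Unannotated nodes are excluded both as anchors and as
    comparison points.
    """
    if mode not in ("gene", "drug"):
        raise ValueError("mode must be gene|drug")
    gene_nodes = [n for n, t in zip(e.nodes, e.node_types) if t == "gene"]
    annotated = [g for g in gene_nodes if ann.terms_of(g)]
    if mode == "gene":
        if len(annotated) < 2:
            raise ValueError("need at least 2 annotated genes")
        X = np.stack([e.row(g) for g in annotated])
        dist = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
        labels = coparticipation_matrix(ann, annotated)
        return _silhouette_over_anchors(
            dist, labels, ["gene"] * len(annotated), lambda i: i, "embedding"
        )
    if not drug_pathways:
        raise ValueError("drug mode requires drug_pathways")
    if not annotated:
        raise ValueError("no annotated genes to compare against")
    drug_nodes = [n for n, t in zip(e.nodes, e.node_types) if t == "drug"]
    drugs = [d for d in sorted(drug_pathways) if d in drug_nodes]
    labels = drug_gene_coparticipation({d: drug_pathways[d] for d in drugs}, annotated)
    Xd = np.stack([e.row(d) for d in labels.row_nodes])
    Xg = np.stack([e.row(g) for g in annotated])
    dist = np.linalg.norm(Xd[:, None, :] - Xg[None, :, :], axis=2)
    return _silhouette_over_anchors(
        dist, labels, ["drug"] * len(labels.row_nodes), lambda i: None, "embedding"
    )


def evaluate_shortest_path(edges, ann: AnnotationSet, nodes=None) -> SilhouetteReport:
    """Gene silhouette using PPI shortest-path hop distances as the metric."""
    genes = sorted(ann.genes()) if nodes is None else [g for g in nodes if ann.terms_of(g)]
    if len(genes) < 2:
        raise ValueError("need at least 2 annotated genes")
    D = shortest_path_distances(edges, genes).to_numpy()
    labels = coparticipation_matrix(ann, genes)
    return _silhouette_over_anchors(
        D, labels, ["gene"] * len(genes), lambda i: i, "shortest-path"
    )


def permuted_annotation(ann: AnnotationSet, nodes, rng) -> AnnotationSet:
    """Permute which nodes carry which labels (term sizes and overlaps preserved)."""
    nodes = list(nodes)
    perm = {a: b for a, b in zip(nodes, rng.permutation(nodes))}
    return AnnotationSet(
        {t: frozenset(perm[g] for g in gs if g in perm) for t, gs in ann.terms.items()},
        dict(ann.descriptions),
    )


def write_silhouette_report(report: SilhouetteReport, tsv_path, json_path=None) -> None:
    report.scores.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        import json

        payload = dict(report.summary)
        payload["distance_source"] = report.distance_source
        payload["skipped"] = [list(s) for s in report.skipped]
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)
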