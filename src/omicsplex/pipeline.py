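"""End-to-end orchestration: infer layers, assemble, diffuse, embed."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .config import RunConfig
from .embedding import Embedding, embed_similarity
from .inference import (
    OmicsNetwork,
    binarize_methylation,
    infer_cooccurrence_network,
    infer_correlation_network,
    split_cnv,
)
from .io import DrugGeneBipartite, OmicsMatrix, impute_median, preprocess_methylation
from .multiplex import MHNetwork, build_mh_network, build_multiplex, filter_bipartite
from .rwr import SimilarityMatrix, build_similarity_matrix

logger = logging.getLogger("omicsplex")


@dataclass
class PipelineResult:
    networks: list
    mh: MHNetwork
    similarity: SimilarityMatrix
    embedding: Embedding
    config: RunConfig
    dropped: dict = field(default_factory=dict)


def infer_layer_networks(matrices, config: RunConfig) -> list:
    """Dispatch each matrix to its modality's inference route.

    quantitative -> correlation network (Pearson unless overridden per layer
    in ``config.correlation_methods``); beta -> binarize then co-occurrence;
    cnv -> split into amplification/deletion co-occurrence networks.
    """
    networks = []
    for m in matrices:
        if m.modality == "quantitative":
            if m.has_missing:
                m = impute_median(m)
            method = config.correlation_methods.get(m.layer_name, "pearson")
            networks.append(
                infer_correlation_network(m, method, config.min_abs_cor, config.max_fdr)
            )
        elif m.modality == "beta":
            if m.has_missing:
                m = preprocess_methylation(m, offset=0.0, impute=True)
            binary = binarize_methylation(m, config.beta_threshold)
            networks.append(
                infer_cooccurrence_network(binary, config.bonferroni_alpha, config.posthoc_alpha)
            )
        elif m.modality == "cnv":
            for part in split_cnv(m):
                networks.append(
                    infer_cooccurrence_network(part, config.bonferroni_alpha, config.posthoc_alpha)
                )
        elif m.modality == "binary":
            networks.append(
                infer_cooccurrence_network(m, config.bonferroni_alpha, config.posthoc_alpha)
            )
        else:  # pragma: no cover - OmicsMatrix already validates
            raise ValueError(f"unknown modality {m.modality}")
    return networks


def run_pipeline(matrices, drug_table: DrugGeneBipartite, config: RunConfig | None = None) -> PipelineResult:
    """Full run: inference -> multiplex -> MH network -> RWR similarity -> embedding."""
    config = config or RunConfig()
    networks = infer_layer_networks(matrices, config)
    mx = build_multiplex(networks, strategy=config.strategy, weighted_intra=config.weighted)
    db = filter_bipartite(drug_table, mx.genes)
    mh = build_mh_network(mx, db)
    similarity = build_similarity_matrix(mh, config)
    node_types = ["gene"] * mx.n_genes + ["drug"] * mh.n_drugs
    d = min(config.embedding_d, similarity.n_nodes)
    embedding = embed_similarity(similarity, d=d, method=config.embedding_method,
                                 node_types=node_types)
    return PipelineResult(networks, mh, similarity, embedding, config)
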