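"""Multiplex omics network assembly and attachment of the drug-target bipartite.

The L single-omics networks are stacked into a multiplex whose layers all
carry the same unified gene label set (genes absent from a layer appear as
isolated projections).  Layers are coupled either by linking each gene to
its own projections only (``node_coupling``) or additionally to the
projections of its first-order intra-layer neighbours
(``neighborhood_coupling``); coupling edges have unit weight.  Drug nodes
attach through the filtered drug-target bipartite: each bipartite edge is
replicated to the gene's projection in every layer with unit weight.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .inference import OmicsNetwork
from .io import DrugGeneBipartite

logger = logging.getLogger("omicsplex")


@dataclass
class MultiplexNetwork:
    """L-layer multiplex over a unified gene set.

    ``inter_layer_edges`` stores each coupling edge once as a canonical pair
    ``((layer_a, gene_a), (layer_b, gene_b))`` with ``layer_a < layer_b``.
    """

    genes: list
    layer_names: list
    networks: list  # original OmicsNetwork objects
    adjacency: list  # one symmetric csr per layer, over `genes` order
    inter_layer_edges: set
    strategy: str
    weighted_intra: bool

    @property
    def n_layers(self) -> int:
        return len(self.layer_names)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_intra_edges(self) -> int:
        return int(sum(a.nnz // 2 for a in self.adjacency))

    @property
    def n_inter_edges(self) -> int:
        return len(self.inter_layer_edges)


@dataclass
class MHNetwork:
    """Multiplex heterogeneous network: gene multiplex plus drug nodes.

    The bipartite must already be filtered so every target gene belongs to
    the multiplex.  Node universe size is ``n_genes * L + n_drugs``.
    """

    multiplex: MultiplexNetwork
    bipartite: DrugGeneBipartite
    gene_to_drugs: dict = field(init=False)

    def __post_init__(self):
        missing = set(self.bipartite.target_genes) - set(self.multiplex.genes)
        if missing:
            raise ValueError(
                f"bipartite not filtered: target genes absent from multiplex: {sorted(missing)[:5]}"
            )
        g2d = {}
        for d, g in self.bipartite.edges:
            g2d.setdefault(g, []).append(d)
        self.gene_to_drugs = {g: sorted(ds) for g, ds in g2d.items()}

    @property
    def drugs(self) -> list:
        return self.bipartite.drugs

    @property
    def n_drugs(self) -> int:
        return len(self.bipartite.drugs)

    @property
    def n_gene_nodes(self) -> int:
        return self.multiplex.n_genes * self.multiplex.n_layers

    @property
    def n_nodes(self) -> int:
        return self.n_gene_nodes + self.n_drugs

    @property
    def n_drug_gene_edges(self) -> int:
        # each bipartite edge is replicated to all L gene projections
        return self.bipartite.n_edges * self.multiplex.n_layers


def build_multiplex(
    networks,
    strategy: str = "node_coupling",
    weighted_intra: bool = False,
) -> MultiplexNetwork:
    """Assemble single-omics networks into a multiplex over the union of gene labels."""
    networks = list(networks)
    if not networks:
        raise ValueError("at least one omics network is required")
    if strategy not in ("node_coupling", "neighborhood_coupling"):
        raise ValueError("strategy must be node_coupling|neighborhood_coupling")

    genes = sorted(set().union(*(set(n.nodes) for n in networks)))
    idx = {g: i for i, g in enumerate(genes)}
    L = len(networks)
    adjacency = [n.adjacency(genes, weighted=weighted_intra) for n in networks]

    inter = set()
    for a in range(L):
        for b in range(a + 1, L):
            inter.update(((a, g), (b, g)) for g in genes)
    if strategy == "neighborhood_coupling":
        for a, A in enumerate(adjacency):
            coo = sparse.triu(A, k=1).tocoo()
            for i, j in zip(coo.row, coo.col):
                gi, gj = genes[i], genes[j]
                for b in range(L):
                    if b == a:
                        continue
                    if a < b:
                        inter.add(((a, gi), (b, gj)))
                        inter.add(((a, gj), (b, gi)))
                    else:
                        inter.add(((b, gj), (a, gi)))
                        inter.add(((b, gi), (a, gj)))

    mx = MultiplexNetwork(
        genes=genes,
        layer_names=[n.layer_name for n in networks],
        networks=networks,
        adjacency=adjacency,
        inter_layer_edges=inter,
        strategy=strategy,
        weighted_intra=weighted_intra,
    )
    logger.info(
        "MULTIPLEX_BUILT layers=%d genes=%d intra_edges=%d inter_edges=%d strategy=%s",
        L, mx.n_genes, mx.n_intra_edges, mx.n_inter_edges, strategy,
    )
    return mx


def filter_bipartite(db: DrugGeneBipartite, genes) -> DrugGeneBipartite:
    """Restrict drug-target edges to genes present in the multiplex; drop drugs left targetless."""
    genes = set(genes)
    kept = {(d, g) for d, g in db.edges if g in genes}
    dropped_edges = db.edges - kept
    for d, g in sorted(dropped_edges):
        logger.info("DROP_BIPARTITE_EDGE_ABSENT_GENE drug=%s gene=%s", d, g)
    surviving_drugs = {d for d, _ in kept}
    for d in sorted({d for d, _ in db.edges} - surviving_drugs):
        logger.info("DROP_DRUG_NO_TARGETS drug=%s", d)
    if not kept:
        logger.warning("EMPTY_BIPARTITE no drug-target edge survives the gene filter")
    return DrugGeneBipartite(frozenset(kept))


def build_mh_network(multiplex: MultiplexNetwork, db: DrugGeneBipartite) -> MHNetwork:
    """Attach the (already filtered) drug bipartite to the multiplex."""
    mh = MHNetwork(multiplex, db)
    logger.info(
        "MH_BUILT nodes=%d gene_nodes=%d drugs=%d drug_gene_edges=%d",
        mh.n_nodes, mh.n_gene_nodes, mh.n_drugs, mh.n_drug_gene_edges,
    )
    return mh


def write_mh_network(mh: MHNetwork, outdir) -> None:
    """Serialize the MH network as a TSV bundle plus a JSON manifest of counts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mx = mh.multiplex
    intra = []
    for name, A in zip(mx.layer_names, mx.adjacency):
        coo = sparse.triu(A, k=1).tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            intra.append((mx.genes[i], mx.genes[j], name, w))
    pd.DataFrame(intra, columns=["source", "target", "layer", "weight"]).to_csv(
        outdir / "intra_layer_edges.tsv", sep="\t", index=False
    )
    inter = [
        (ga, mx.layer_names[la], gb, mx.layer_names[lb])
        for (la, ga), (lb, gb) in sorted(mh.multiplex.inter_layer_edges)
    ]
    pd.DataFrame(inter, columns=["source", "source_layer", "target", "target_layer"]).to_csv(
        outdir / "inter_layer_edges.tsv", sep="\t", index=False
    )
    pd.DataFrame(sorted(mh.bipartite.edges), columns=["drug", "gene"]).to_csv(
        outdir / "drug_gene_edges.tsv", sep="\t", index=False
    )
    manifest = {
        "layers": mx.layer_names,
        "n_genes": mx.n_genes,
        "n_layers": mx.n_layers,
        "n_intra_edges": mx.n_intra_edges,
        "n_inter_edges": mx.n_inter_edges,
        "n_drugs": mh.n_drugs,
        "n_bipartite_edges": mh.bipartite.n_edges,
        "n_drug_gene_edges": mh.n_drug_gene_edges,
        "n_nodes": mh.n_nodes,
        "strategy": mx.strategy,
        "weighted_intra": mx.weighted_intra,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
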