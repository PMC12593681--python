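"""Readers, writers, and preprocessing for omics matrices, drug-target tables and gene sets.

All tabular formats are plain TSV with a header row.  Gene identifiers are
case-sensitive strings matched exactly across omics layers; no alias
resolution is attempted.  Every gene or drug dropped during preprocessing is
logged with a reason code so downstream network sizes are auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("omicsplex")

MODALITIES = ("quantitative", "beta", "cnv", "binary")


def _check_unique(ids, what: str) -> None:
    seen, dups = set(), []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class OmicsMatrix:
    """One modality's genes-by-samples numeric grid.

    ``values`` is a float array in which NaN marks a missing measurement.
    ``modality`` selects the downstream inference route: ``quantitative``
    (correlation tests), ``beta`` (methylation fractions in [0, 1]),
    ``cnv`` (signed integer copy-number calls) or ``binary`` (0/1 events).
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    layer_name: str
    modality: str

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        _check_unique(self.gene_ids, "gene IDs")
        _check_unique(self.sample_ids, "sample IDs")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        obs = self.values[~np.isnan(self.values)]
        if self.modality == "beta" and obs.size and (obs.min() < 0 or obs.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if self.modality == "cnv" and obs.size and not np.allclose(obs, np.round(obs)):
            raise ValueError("cnv values must be integers (sign encodes amplification/deletion)")
        if self.modality == "binary" and obs.size and not np.isin(obs, (0.0, 1.0)).all():
            raise ValueError("binary values must be 0 or 1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class DrugGeneBipartite:
    """Deduplicated drug -> target-gene edge set."""

    edges: frozenset  # of (drug_id, gene_id)

    @property
    def drugs(self) -> list:
        return sorted({d for d, _ in self.edges})

    @property
    def target_genes(self) -> list:
        return sorted({g for _, g in self.edges})

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def drug_degree(self, drug) -> int:
        return sum(1 for d, _ in self.edges if d == drug)

    def targets_of(self, drug) -> list:
        return sorted(g for d, g in self.edges if d == drug)

    def drugs_targeting(self, gene) -> list:
        return sorted(d for d, g in self.edges if g == gene)


@dataclass
class AnnotationSet:
    """Term -> gene-set mapping (GMT content) driving enrichment and evaluation labels."""

    terms: dict  # term -> frozenset of genes
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        self.terms = {t: frozenset(g) for t, g in self.terms.items()}

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def genes(self) -> set:
        out = set()
        for g in self.terms.values():
            out |= g
        return out

    def terms_of(self, gene) -> set:
        return {t for t, gs in self.terms.items() if gene in gs}


# ---------------------------------------------------------------------------
# Omics matrices
# ---------------------------------------------------------------------------

def read_omics_matrix(path, layer_name: str, modality: str) -> OmicsMatrix:
    """Read a genes-by-samples TSV (header = sample IDs, first column = gene IDs).

    Empty cells are recorded as missing.  Duplicate gene IDs and non-numeric
    cells raise with the offending identifier / position named.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    _check_unique(sample_ids, f"sample IDs in {path}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str, keep_default_na=False)
    gene_ids = [str(g) for g in df.index]
    _check_unique(gene_ids, f"gene IDs in {path}")
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for j in range(raw.shape[1]):
        col = pd.to_numeric(pd.Series(raw[:, j]).str.strip().replace("", np.nan), errors="coerce")
        bad = col.isna().to_numpy() & (pd.Series(raw[:, j]).str.strip() != "").to_numpy()
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric cell {raw[i, j]!r} at gene {gene_ids[i]!r}, "
                f"sample {sample_ids[j]!r} in {path}"
            )
        values[:, j] = col.to_numpy()
    return OmicsMatrix(gene_ids, sample_ids, values, layer_name, modality)


def write_omics_matrix(m: OmicsMatrix, path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="gene_id", na_rep="")


def preprocess_methylation(m: OmicsMatrix, offset: float = 0.5, impute: bool = True) -> OmicsMatrix:
    """Shift methylation values back onto the beta scale and impute missing entries.

    The offset is added to every entry (platform exports commonly store
    ``beta - 0.5``).  Each missing entry is replaced by the median of its
    gene's observed values; genes with no observed value are dropped and
    logged.  Post-offset values outside [0, 1] raise.
    """
    vals = m.values + offset
    obs = vals[~np.isnan(vals)]
    if obs.size and (obs.min() < -1e-12 or obs.max() > 1 + 1e-12):
        raise ValueError(
            f"post-offset methylation values outside [0, 1] "
            f"(range {obs.min():.4g}..{obs.max():.4g}); check the offset"
        )
    vals = np.clip(vals, 0.0, 1.0)
    all_missing = np.isnan(vals).all(axis=1)
    if all_missing.any():
        for g in np.asarray(m.gene_ids)[all_missing]:
            logger.info("DROP_GENE_ALL_MISSING layer=%s gene=%s", m.layer_name, g)
        vals = vals[~all_missing]
    gene_ids = [g for g, drop in zip(m.gene_ids, all_missing) if not drop]
    if impute and np.isnan(vals).any():
        med = np.nanmedian(vals, axis=1)
        idx = np.where(np.isnan(vals))
        vals[idx] = med[idx[0]]
    return OmicsMatrix(gene_ids, m.sample_ids, vals, m.layer_name, "beta")


def impute_median(m: OmicsMatrix) -> OmicsMatrix:
    """Per-gene median imputation for quantitative matrices (opt-in)."""
    vals = m.values.copy()
    all_missing = np.isnan(vals).all(axis=1)
    if all_missing.any():
        for g in np.asarray(m.gene_ids)[all_missing]:
            logger.info("DROP_GENE_ALL_MISSING layer=%s gene=%s", m.layer_name, g)
        vals = vals[~all_missing]
    gene_ids = [g for g, drop in zip(m.gene_ids, all_missing) if not drop]
    if np.isnan(vals).any():
        med = np.nanmedian(vals, axis=1)
        idx = np.where(np.isnan(vals))
        vals[idx] = med[idx[0]]
    return replace(m, gene_ids=gene_ids, values=vals)


# ---------------------------------------------------------------------------
# Drug-target table
# ---------------------------------------------------------------------------

def read_drug_gene_table(path) -> DrugGeneBipartite:
    """Read a two-column drug/target-gene TSV with a header row.

    Columns are assigned by header name when one contains ``drug`` and the
    other ``gene``/``target`` (case-insensitive); otherwise the first column
    is taken as the drug ID and the second as the gene ID.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"expected 2 columns in {path}, found {df.shape[1]}")
    if df.empty:
        raise ValueError(f"empty drug-gene table: {path}")
    cols = [c.lower() for c in df.columns]
    drug_col, gene_col = 0, 1
    for i, c in enumerate(cols):
        if "drug" in c:
            drug_col = i
        elif "gene" in c or "target" in c:
            gene_col = i
    if drug_col == gene_col:
        drug_col, gene_col = 0, 1
    edges = frozenset(
        (str(d).strip(), str(g).strip())
        for d, g in zip(df.iloc[:, drug_col], df.iloc[:, gene_col])
    )
    return DrugGeneBipartite(edges)


def write_drug_gene_table(db: DrugGeneBipartite, path) -> None:
    pd.DataFrame(sorted(db.edges), columns=["drug", "gene"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> AnnotationSet:
    """Read a standard GMT file: term, description, then tab-separated gene IDs."""
    terms, descriptions = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {lineno} in {path}: fewer than 3 fields")
            term, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                logger.warning("DROP_EMPTY_TERM term=%s line=%d", term, lineno)
                continue
            terms[term] = genes
            descriptions[term] = desc
    return AnnotationSet(terms, descriptions)


def write_gmt(ann: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(ann.terms):
            desc = ann.descriptions.get(term, "")
            fh.write("\t".join([term, desc] + sorted(ann.terms[term])) + "\n")
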