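"""Run configuration: statistical thresholds, diffusion parameters, embedding choices."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class RunConfig:
    """Parameters for the full inference -> assembly -> diffusion -> embedding run.

    Thresholds
    ----------
    min_abs_cor : minimum absolute correlation for a co-expression/co-abundance edge.
    max_fdr : BH-adjusted p-value ceiling for correlation edges.
    beta_threshold : methylation call cutoff on beta values (>= is methylated).
    bonferroni_alpha : Bonferroni-adjusted Fisher p ceiling for co-occurrence pairs.
    posthoc_alpha : per-cell goodness-of-fit alpha for the joint-presence excess check.

    Diffusion
    ---------
    r : restart probability in (0, 1]; larger r keeps the walk near the seed.
    tau : per-layer restart weights (None = uniform); must sum to 1.
    delta : inter-layer jump probability.
    lam : gene<->drug transition probability (applied only at nodes with drug links).
    aggregation : how a gene's per-layer proximities collapse (geometric|arithmetic|sum).
    """

    min_abs_cor: float = 0.5
    max_fdr: float = 0.05
    beta_threshold: float = 0.3
    bonferroni_alpha: float = 0.05
    posthoc_alpha: float = 0.05

    r: float = 0.7
    tau: list | None = None
    delta: float = 0.5
    lam: float = 0.5
    aggregation: str = "geometric"
    tol: float = 1e-10
    max_iter: int = 1000
    weighted: bool = False
    strategy: str = "node_coupling"

    embedding_method: str = "svd"
    embedding_d: int = 128
    clustering_method: str = "kmeans"
    clustering_params: dict = field(default_factory=dict)
    correlation_methods: dict = field(default_factory=dict)  # layer_name -> pearson|spearman
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.r <= 1):
            raise ValueError("r must be in (0, 1]")
        for name in ("delta", "lam"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("min_abs_cor", "max_fdr", "beta_threshold", "bonferroni_alpha", "posthoc_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.tau is not None:
            tau = [float(t) for t in self.tau]
            if any(t < 0 for t in tau):
                raise ValueError("tau entries must be non-negative")
            if abs(sum(tau) - 1.0) > 1e-9:
                raise ValueError("tau must sum to 1")
            self.tau = tau
        if self.aggregation not in ("geometric", "arithmetic", "sum"):
            raise ValueError("aggregation must be geometric|arithmetic|sum")
        if self.strategy not in ("node_coupling", "neighborhood_coupling"):
            raise ValueError("strategy must be node_coupling|neighborhood_coupling")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
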