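"""Cluster-correlated gene-expression simulator with known DE structure.

The generator emulates a meta-analysis of K = 5 case/control expression
studies, each with G = 2000 genes and 2N samples (first N controls, last N
cases).  Gene-gene correlation is induced in 40 clusters of 20 genes: for
each (cluster, study) pair a correlation matrix is drawn by standardizing an
inverse-Wishart sample

    Sigma' ~ W^-1(psi, 60),   psi = 0.5 I + 0.5 J  (20 x 20),

so cluster members share a prior correlation of about 0.5.  The remaining
1200 genes are i.i.d. N(0, sigma_k^2) with a per-study variance
sigma_k^2 ~ U(0.8, 1.2).

Differential expression: the first 1000 genes are split into five groups of
200; a gene in group j is differentially expressed in exactly j of the 5
studies (indicator matrix delta, rows summing to the group id), with shift
sizes mu_gk ~ U(0.5, 3) added to the case samples only.  Genes 1001-2000
carry no shift.  Truth labels under the three hypothesis frameworks:

    H1  non-zero effect in all studies       -> group 5 (200 genes)
    H2  non-zero effect in >= 1 study        -> groups 1-5 (1000 genes)
    H3  non-zero effect in >= r studies      -> groups r-5 (600 genes at r=3)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import invwishart

__all__ = [
    "SAMPLE_SIZE_SWEEP",
    "ExpressionSimConfig",
    "ExpressionSimTruth",
    "sample_cluster_correlation",
    "simulate_dataset",
    "truth_labels",
    "write_dataset",
]

# per-arm sizes N giving total per-study sizes 2N = 10,20,60,100,140,180,220
SAMPLE_SIZE_SWEEP = (5, 10, 30, 50, 70, 90, 110)


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Configuration of the expression-level simulator (defaults = benchmark)."""

    k_studies: int = 5
    n_genes: int = 2000
    n_per_arm: int = 50          # N; the benchmark scenario uses 2N = 100
    n_clusters: int = 40
    cluster_size: int = 20
    wishart_df: int = 60
    genes_per_group: int = 200
    mu_range: tuple[float, float] = (0.5, 3.0)
    sigma0_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters * self.cluster_size > self.n_genes:
            raise ValueError("clustered genes exceed n_genes")
        if self.wishart_df <= self.cluster_size - 1:
            raise ValueError("wishart_df must exceed cluster_size - 1")
        if self.k_studies * self.genes_per_group > self.n_genes:
            raise ValueError("DE groups exceed n_genes")
        if self.n_per_arm < 2:
            raise ValueError("need at least 2 samples per arm")


@dataclass
class ExpressionSimTruth:
    """Simulated studies plus the ground truth that generated them."""

    config: ExpressionSimConfig
    cluster_id: np.ndarray       # (G,) 0 = unclustered, 1..n_clusters
    group_id: np.ndarray         # (G,) k_g: number of studies in which DE
    delta: np.ndarray            # (G, K) binary DE indicators, rows sum to k_g
    mu: np.ndarray               # (G, K) shift sizes (0 where delta == 0)
    studies: list = field(repr=False)  # K arrays of shape (G, 2N)

    @property
    def n_per_arm(self) -> int:
        return self.config.n_per_arm

    def control_block(self, study: int) -> np.ndarray:
        return self.studies[study][:, : self.n_per_arm]

    def case_block(self, study: int) -> np.ndarray:
        return self.studies[study][:, self.n_per_arm:]


def sample_cluster_correlation(rng, cluster_size: int = 20, df: int = 60,
                               prior_corr: float = 0.5, max_tries: int = 5):
    """Draw one cluster correlation matrix.

    Samples Sigma' ~ W^-1(psi, df) with psi = (1-c) I + c J, then rescales to
    unit diagonal: D^-1/2 Sigma' D^-1/2.  The result is symmetric positive
    definite; in the (numerically rare) event Cholesky fails, the draw is
    repeated with a warning.
    """
    if df <= cluster_size - 1:
        raise ValueError("df must exceed cluster_size - 1")
    p = cluster_size
    psi = (1.0 - prior_corr) * np.eye(p) + prior_corr * np.ones((p, p))
    for _ in range(max_tries):
        sig = invwishart.rvs(df=df, scale=psi, random_state=rng)
        d = np.sqrt(np.diag(sig))
        corr = sig / np.outer(d, d)
        corr = 0.5 * (corr + corr.T)
        np.fill_diagonal(corr, 1.0)
        try:
            np.linalg.cholesky(corr)
            return corr
        except np.linalg.LinAlgError:
            warnings.warn("non-PD correlation draw; redrawing", RuntimeWarning)
    raise RuntimeError("could not draw a positive-definite correlation matrix")


def _assignments(cfg: ExpressionSimConfig, rng):
    G, K = cfg.n_genes, cfg.k_studies
    cluster_id = np.zeros(G, dtype=int)
    n_clustered = cfg.n_clusters * cfg.cluster_size
    cluster_id[:n_clustered] = np.repeat(np.arange(1, cfg.n_clusters + 1),
                                         cfg.cluster_size)
    group_id = np.zeros(G, dtype=int)
    for j in range(1, K + 1):
        lo = (j - 1) * cfg.genes_per_group
        group_id[lo: lo + cfg.genes_per_group] = j
    delta = np.zeros((G, K), dtype=np.int8)
    mu = np.zeros((G, K))
    lo_mu, hi_mu = cfg.mu_range
    for g in np.flatnonzero(group_id):
        idx = rng.choice(K, size=group_id[g], replace=False)
        delta[g, idx] = 1
        mu[g, idx] = rng.uniform(lo_mu, hi_mu, size=group_id[g])
    return cluster_id, group_id, delta, mu


def simulate_dataset(cfg: ExpressionSimConfig | None = None, **overrides) -> ExpressionSimTruth:
    """Simulate all K studies and the generating truth.

    Deterministic given ``cfg.seed``: the same seed yields bit-identical
    output.  Keyword overrides are applied to the default config.
    """
    if cfg is None:
        cfg = ExpressionSimConfig(**overrides)
    elif overrides:
        cfg = replace(cfg, **overrides)
    rng = np.random.default_rng(cfg.seed)
    G, K, N = cfg.n_genes, cfg.k_studies, cfg.n_per_arm
    n_samples = 2 * N
    cluster_id, group_id, delta, mu = _assignments(cfg, rng)

    n_clustered = cfg.n_clusters * cfg.cluster_size
    studies = []
    for k in range(K):
        X = np.empty((G, n_samples))
        for c in range(cfg.n_clusters):
            corr = sample_cluster_correlation(rng, cfg.cluster_size,
                                              cfg.wishart_df)
            L = np.linalg.cholesky(corr)
            rows = slice(c * cfg.cluster_size, (c + 1) * cfg.cluster_size)
            X[rows] = L @ rng.standard_normal((cfg.cluster_size, n_samples))
        sigma_k2 = rng.uniform(*cfg.sigma0_range)
        X[n_clustered:] = rng.normal(
            0.0, np.sqrt(sigma_k2), size=(G - n_clustered, n_samples)
        )
        # shift case samples only; controls untouched
        X[:, N:] += (mu[:, k] * delta[:, k])[:, None]
        studies.append(X)
    return ExpressionSimTruth(cfg, cluster_id, group_id, delta, mu, studies)


def truth_labels(truth: ExpressionSimTruth, hypothesis: str, r: int = 3) -> np.ndarray:
    """Binary truth vector under one of the three hypothesis frameworks.

    H1: DE in all K studies; H2: DE in at least one; H3: DE in at least r
    (r defaults to 3, i.e. a majority of K = 5).
    """
    K = truth.config.k_studies
    h = hypothesis.upper()
    if h == "H1":
        return truth.group_id == K
    if h == "H2":
        return truth.group_id >= 1
    if h == "H3":
        if not 1 <= r <= K:
            raise ValueError(f"r must be in [1, {K}], got {r}")
        return truth.group_id >= r
    raise ValueError("hypothesis must be one of 'H1', 'H2', 'H3'")


def write_dataset(truth: ExpressionSimTruth, out_dir):
    """Write per-study expression TSVs and the truth table (seed in header)."""
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    genes = [f"g{i+1}" for i in range(cfg.n_genes)]
    N = cfg.n_per_arm
    cols = [f"ctrl{j+1}" for j in range(N)] + [f"case{j+1}" for j in range(N)]
    header = f"# dsld2 sim-expr seed={cfg.seed} config={cfg}"
    for k, X in enumerate(truth.studies):
        path = out / f"study{k+1}.tsv"
        with open(path, "w") as fh:
            fh.write(header + "\n")
            pd.DataFrame(X, index=pd.Index(genes, name="gene_id"),
                         columns=cols).to_csv(fh, sep="\t")
    tr = pd.DataFrame({"gene_id": genes, "cluster": truth.cluster_id,
                       "k_g": truth.group_id})
    for k in range(cfg.k_studies):
        tr[f"delta_{k+1}"] = truth.delta[:, k]
    for k in range(cfg.k_studies):
        tr[f"mu_{k+1}"] = truth.mu[:, k]
    with open(out / "truth.tsv", "w") as fh:
        fh.write(header + "\n")
        tr.to_csv(fh, sep="\t", index=False)
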