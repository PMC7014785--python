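"""End-to-end benchmark: simulate expression studies, combine, evaluate.

Ties the simulator, effect-size computation, the seven combining methods
and the metric suite into a single reproducible run, and provides the
sample-size sweep used to study threshold behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effect_sizes import effects_from_arrays
from .estimators import METHODS, pool_batch, tau2_batch
from .evaluation import bh_adjust, metric_row
from .sim_expression import ExpressionSimConfig, simulate_dataset, truth_labels

__all__ = ["BenchmarkResult", "effects_from_truth", "run_benchmark",
           "sample_size_sweep"]


@dataclass
class BenchmarkResult:
    """Per-gene results and evaluation metrics of one benchmark run."""

    config: ExpressionSimConfig
    truth: object = field(repr=False)
    results: pd.DataFrame = field(repr=False)   # long: one row per gene x method
    metrics: pd.DataFrame = field(repr=False)   # one row per method x hypothesis

    def pvalues(self, method: str) -> np.ndarray:
        sub = self.results[self.results["method"] == method]
        return sub["p"].to_numpy()


def effects_from_truth(truth, measure: str = "SMD", correction: str = "hedges"):
    """Per-gene effect tables (Y, S2) of shape (G, K) from simulated studies."""
    N = truth.config.n_per_arm
    ys, s2s = [], []
    for X in truth.studies:
        y, s2 = effects_from_arrays(X[:, :N], X[:, N:], measure, correction)
        ys.append(y)
        s2s.append(s2)
    return np.column_stack(ys), np.column_stack(s2s)


def run_benchmark(seed: int = 0, n_per_arm: int = 50, methods=METHODS,
                  hypotheses=("H1",), r: int = 3, measure: str = "SMD",
                  correction: str = "hedges", alpha: float = 0.05,
                  fdr: float = 0.05, config: ExpressionSimConfig | None = None,
                  ) -> BenchmarkResult:
    """Simulate one dataset and evaluate every requested method.

    ``hypotheses`` selects the truth framework(s) to score against; the
    per-gene results are hypothesis-independent.
    """
    if config is None:
        config = ExpressionSimConfig(n_per_arm=n_per_arm, seed=seed)
    truth = simulate_dataset(config)
    Y, S2 = effects_from_truth(truth, measure, correction)
    G = Y.shape[0]
    gene_ids = np.array([f"g{i+1}" for i in range(G)])

    frames = []
    pvals: dict[str, np.ndarray] = {}
    for method in methods:
        tau2, _ = tau2_batch(Y, S2, method)
        out = pool_batch(Y, S2, tau2)
        q = bh_adjust(out["p"])
        frames.append(pd.DataFrame({
            "gene_id": gene_ids, "method": method, "tau2": out["tau2"],
            "mean": out["mean"], "var": out["variance"],
            "ci_low": out["ci_low"], "ci_high": out["ci_high"],
            "z": out["z"], "p": out["p"], "i2": out["i2"], "p_adj": q,
        }))
        pvals[method] = out["p"]
    results = pd.concat(frames, ignore_index=True)

    rows = []
    for hyp in hypotheses:
        labels = truth_labels(truth, hyp, r=r)
        for method in methods:
            sub = results[results["method"] == method]
            rows.append({
                "method": method, "hypothesis": hyp,
                "n_per_arm": config.n_per_arm, "seed": config.seed,
                **metric_row(sub["p"].to_numpy(), labels, alpha=alpha,
                             fdr=fdr, p_adj=sub["p_adj"].to_numpy()),
            })
    return BenchmarkResult(config, truth, results, pd.DataFrame(rows))


def sample_size_sweep(seeds, n_per_arm_list, methods=("DSLD2",),
                      hypotheses=("H1",), r: int = 3, measure: str = "SMD",
                      **kwargs) -> pd.DataFrame:
    """Benchmark metrics across per-arm sample sizes and seeds."""
    tables = []
    for n in n_per_arm_list:
        for seed in seeds:
            res = run_benchmark(seed=seed, n_per_arm=n, methods=methods,
                                hypotheses=hypotheses, r=r, measure=measure,
                                **kwargs)
            tables.append(res.metrics)
    return pd.concat(tables, ignore_index=True)
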