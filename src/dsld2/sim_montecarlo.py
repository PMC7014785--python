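"""Monte Carlo study of between-study variance estimator bias, RMSE and I^2.

Each iteration simulates one meta-analysis of k case/control studies with
normal observations: study sample sizes n_i ~ N(40, (40/3)^2) (rounded, at
least 2, equal arms), within-study variance sigma^2 = 10 in both arms,
control mean 0 and case mean mu_i ~ N(0, tau2).  Effect sizes are computed
by the chosen measure (MD or SMD) and every between-study variance
estimator is applied.  Across iterations the study reports

    bias      mean(tau2_hat) - tau2_true
    rmse      sqrt(mean((tau2_hat - tau2_true)^2))
    mean_i2   average Higgins I^2 at each iteration's estimate
    mc_se     Monte Carlo standard error of the bias

On the SMD scale the generating tau2 acts on raw means, so the true
between-study variance of the standardized effects is tau2 / sigma^2; MD
bias is scored against tau2 directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import estimators
from .estimators import _i_squared_batch, tau2_batch

__all__ = ["MC_METHODS", "MCConfig", "simulate_effects", "mc_iteration", "run_mc"]

# FEM has no between-study variance; the six REM estimators are compared.
MC_METHODS = ("DSL", "DSLR2", "PM", "RML", "SJ", "DSLD2")


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo design (defaults are the full study grid)."""

    k_list: tuple = (5, 10, 20, 40, 80)
    tau2_list: tuple = (0.0, 1.0)
    n_mean: float = 40.0
    n_sd: float = 40.0 / 3.0
    sigma2: float = 10.0
    n_iter: int = 1000
    measure: str = "SMD"
    seed: int = 0

    def __post_init__(self):
        if self.n_iter < 1 or self.sigma2 <= 0 or self.n_mean <= 0:
            raise ValueError("invalid Monte Carlo configuration")
        if self.measure not in ("SMD", "MD"):
            raise ValueError("measure must be 'SMD' or 'MD'")


def simulate_effects(rng, k: int, tau2: float, n_iter: int, measure: str,
                     n_mean: float = 40.0, n_sd: float = 40.0 / 3.0,
                     sigma2: float = 10.0):
    """Simulate ``n_iter`` meta-analyses; return (Y, S2) of shape (n_iter, k).

    Raw observations are drawn per study (masked to each study's n_i) and
    summarized to group means and ddof-1 variances before the effect-size
    computation, exactly as an analyst would process real data.
    """
    n = np.rint(rng.normal(n_mean, n_sd, size=(n_iter, k)))
    n = np.maximum(n, 2).astype(int)
    mu_case = rng.normal(0.0, np.sqrt(tau2), size=(n_iter, k)) if tau2 > 0 \
        else np.zeros((n_iter, k))
    sd = np.sqrt(sigma2)

    def _masked_stats(shift, ni):
        nmax = ni.max()
        x = rng.normal(0.0, sd, size=(n_iter, nmax)) + shift[:, None]
        mask = np.arange(nmax)[None, :] < ni[:, None]
        s1 = (x * mask).sum(axis=1)
        s2 = (x * x * mask).sum(axis=1)
        mean = s1 / ni
        var = (s2 - ni * mean**2) / (ni - 1)
        return mean, np.maximum(var, 0.0)

    Y = np.empty((n_iter, k))
    S2 = np.empty((n_iter, k))
    for i in range(k):
        ni = n[:, i]
        m0, v0 = _masked_stats(np.zeros(n_iter), ni)
        m1, v1 = _masked_stats(mu_case[:, i], ni)
        if measure == "MD":
            Y[:, i] = m1 - m0
            S2[:, i] = (v1 + v0) / ni
        else:  # SMD, Hedges-adjusted with equal arms
            dof = 2 * ni - 2
            sp2 = ((ni - 1) * v1 + (ni - 1) * v0) / dof
            d = (m1 - m0) / np.sqrt(sp2)
            d *= 1.0 - 3.0 / (4.0 * dof - 1.0)
            Y[:, i] = d
            S2[:, i] = 2.0 / ni + d**2 / (4.0 * ni)
    return Y, S2


def mc_iteration(rng, k: int, tau2: float, measure: str = "SMD",
                 **kwargs) -> dict[str, float]:
    """One Monte Carlo iteration: tau2_hat for every REM estimator."""
    Y, S2 = simulate_effects(rng, k, tau2, 1, measure, **kwargs)
    return {m: float(tau2_batch(Y, S2, m)[0][0]) for m in MC_METHODS}


def run_mc(cfg: MCConfig, methods=MC_METHODS, keep_draws: bool = False):
    """Run the full Monte Carlo grid; returns a long-format DataFrame.

    Columns: method, k, tau2, measure, tau2_true, bias, rmse, mean_i2,
    mc_se, n_iter.  With ``keep_draws=True`` additionally returns a dict of
    per-cell estimate arrays keyed by (method, k, tau2).
    """
    rows = []
    draws: dict = {}
    ss = np.random.SeedSequence(cfg.seed)
    for k in cfg.k_list:
        for tau2 in cfg.tau2_list:
            rng = np.random.default_rng(ss.spawn(1)[0])
            Y, S2 = simulate_effects(rng, k, tau2, cfg.n_iter, cfg.measure,
                                     cfg.n_mean, cfg.n_sd, cfg.sigma2)
            # the generating tau2 acts on raw means; on the SMD scale the
            # true between-study variance is tau2 / sigma2
            tau2_true = tau2 / cfg.sigma2 if cfg.measure == "SMD" else tau2
            for m in methods:
                est, _ = tau2_batch(Y, S2, m)
                err = est - tau2_true
                bias = float(err.mean())
                rows.append({
                    "method": m,
                    "k": k,
                    "tau2": tau2,
                    "measure": cfg.measure,
                    "tau2_true": tau2_true,
                    "bias": bias,
                    "rmse": float(np.sqrt((err**2).mean())),
                    "mean_i2": float(_i_squared_batch(est, S2).mean()),
                    "mc_se": float(est.std(ddof=1) / np.sqrt(cfg.n_iter)),
                    "n_iter": cfg.n_iter,
                })
                if keep_draws:
                    draws[(m, k, tau2)] = est
    table = pd.DataFrame(rows)
    return (table, draws) if keep_draws else table
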