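"""Combining methods for random-effects meta-analysis of per-gene effect sizes.

The random-effects model for gene g observes effect sizes

    y_ig = mu_g + xi_ig + eps_ig,   xi_ig ~ N(0, tau2_g),  eps_ig ~ N(0, sigma2_ig)

across k studies, where tau2_g is the between-study variance and sigma2_ig the
within-study (sampling) variance.  Seven combining methods are provided:

FEM     fixed-effects model (tau2 fixed at 0)
DSL     DerSimonian-Laird moments estimator of tau2
DSLR2   two-step: DSL first, then the between-study variability R^2
PM      Paule-Mandel: root of the generalized-Q estimating equation
RML     restricted maximum likelihood, Fisher-scoring iteration
SJ      Sidik-Jonkman two-step estimator
DSLD2   two-step: DSL first, then the moments estimator D^2 built from the
        difference between Cochran's Q and the generalized Q at random-effects
        weights; pooling then uses D^2 in the inverse-variance weights

Every estimator is implemented vectorized over a (genes x studies) table; the
scalar functions below operate on one gene and are thin wrappers.  All tau2
estimates are truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "METHODS",
    "TauEstimate",
    "PooledResult",
    "InsufficientStudiesError",
    "NonConvergenceError",
    "cochran_q",
    "tau2_dsl",
    "tau2_dslr2",
    "tau2_pm",
    "tau2_rml",
    "tau2_sj",
    "tau2_dsld2",
    "tau2_batch",
    "pool",
    "pool_batch",
    "run_method",
    "combine_table",
    "i_squared",
]

METHODS = ("FEM", "DSL", "DSLR2", "PM", "RML", "SJ", "DSLD2")

Z_CRIT = 1.96  # CI multiplier, fixed (not a t quantile)
P_FLOOR = 1e-300  # keeps -log10(p) finite


class InsufficientStudiesError(ValueError):
    """Raised when fewer than two studies are supplied."""


class NonConvergenceError(RuntimeError):
    """Raised when an iterative tau2 estimator fails to converge."""


@dataclass
class TauEstimate:
    """A between-study variance estimate with diagnostics.

    Attributes
    ----------
    method : str
        One of ``METHODS`` (excluding FEM, which fixes tau2 = 0).
    tau2 : float
        The estimate, always >= 0.
    Q : float
        Cochran's Q at fixed-effects weights.
    truncated : bool
        True when a negative raw value was clipped to zero (or, for SJ, when
        the first-step estimate hit its 0.01 floor).
    iterations : int
        Iterations used by iterative methods (0 for closed forms).
    converged : bool
        False only when an iterative method hit its iteration cap.
    """

    method: str
    tau2: float
    Q: float
    truncated: bool = False
    iterations: int = 0
    converged: bool = True


@dataclass
class PooledResult:
    """Pooled overall effect for one gene under inverse-variance weighting."""

    mean: float
    variance: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    i2: float
    weights: np.ndarray = field(repr=False)
    tau: TauEstimate | None = None


# ---------------------------------------------------------------------------
# input validation / batch plumbing
# ---------------------------------------------------------------------------

def _as_batch(y, s2):
    """Coerce inputs to (G, k) float arrays and validate."""
    Y = np.atleast_2d(np.asarray(y, dtype=float))
    S2 = np.atleast_2d(np.asarray(s2, dtype=float))
    if Y.shape != S2.shape:
        raise ValueError(f"y and s2 shapes differ: {Y.shape} vs {S2.shape}")
    if Y.shape[1] < 2:
        raise InsufficientStudiesError(
            f"need at least 2 studies, got k={Y.shape[1]}"
        )
    if not np.all(np.isfinite(Y)) or not np.all(np.isfinite(S2)):
        raise ValueError("non-finite effect size or variance")
    if np.any(S2 <= 0):
        raise ValueError("within-study variances must be strictly positive")
    return Y, S2


def _fem_parts(Y, S2):
    """Fixed-effects weights and summaries: (W, Sw, Sw2, M, Q, denom)."""
    W = 1.0 / S2
    Sw = W.sum(axis=1)
    Sw2 = (W * W).sum(axis=1)
    M = (W * Y).sum(axis=1) / Sw
    Q = (W * (Y - M[:, None]) ** 2).sum(axis=1)
    denom = Sw - Sw2 / Sw
    return W, Sw, Sw2, M, Q, denom


# ---------------------------------------------------------------------------
# batch estimators (the actual implementation)
# ---------------------------------------------------------------------------

def _dsl_batch(Y, S2):
    k = Y.shape[1]
    _, _, _, M, Q, denom = _fem_parts(Y, S2)
    if np.any(denom <= 0):
        raise NonConvergenceError("degenerate DSL denominator (all weight in one study)")
    raw = (Q - (k - 1)) / denom
    tau2 = np.maximum(0.0, raw)
    return tau2, {"Q": Q, "truncated": raw < 0, "M_fem": M, "denom": denom}


def _wstar_mean(Y, S2, tau2):
    """Random-effects weights and pooled mean at a given tau2 vector."""
    Wstar = 1.0 / (S2 + tau2[:, None])
    Mstar = (Wstar * Y).sum(axis=1) / Wstar.sum(axis=1)
    return Wstar, Mstar


def _dslr2_batch(Y, S2):
    tau_dsl, info = _dsl_batch(Y, S2)
    Q = info["Q"]
    Wstar, Mstar = _wstar_mean(Y, S2, tau_dsl)
    num = (Wstar * (Y - Mstar[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - num / Q
    zero_q = Q <= 0
    r2 = np.where(zero_q, 0.0, r2)
    raw = r2.copy()
    r2 = np.maximum(0.0, r2)
    return r2, {"Q": Q, "truncated": (raw < 0) | zero_q}


def _pm_F(Y, S2, t, k):
    Wstar = 1.0 / (S2 + t[:, None])
    Mstar = (Wstar * Y).sum(axis=1) / Wstar.sum(axis=1)
    return (Wstar * (Y - Mstar[:, None]) ** 2).sum(axis=1) - (k - 1)


def _pm_batch(Y, S2, tol=1e-12, max_expand=80, max_bisect=200):
    """Paule-Mandel by vectorized bracketed bisection.

    F(t) = sum (y - M*(t))^2 / (s2 + t) - (k - 1) is continuous and
    non-increasing in t; F(0) <= 0 means tau2 = 0 (truncated).
    """
    G, k = Y.shape
    _, _, _, _, Q, _ = _fem_parts(Y, S2)
    zero = np.zeros(G)
    f0 = _pm_F(Y, S2, zero, k)
    active = f0 > 0
    tau2 = np.zeros(G)
    converged = np.ones(G, dtype=bool)
    iters = 0
    if active.any():
        cap = 1e6 * S2.max(axis=1)
        lo = np.zeros(G)
        hi = np.where(active, np.maximum(S2.mean(axis=1), 1.0), 0.0)
        for _ in range(max_expand):
            iters += 1
            need = active & (_pm_F(Y, S2, hi, k) > 0)
            if not need.any():
                break
            hi = np.where(need, np.minimum(hi * 4.0, cap), hi)
            if np.any(need & (hi >= cap) & (_pm_F(Y, S2, cap, k) > 0)):
                bad = need & (hi >= cap) & (_pm_F(Y, S2, cap, k) > 0)
                converged[bad] = False
                active &= ~bad
        for _ in range(max_bisect):
            iters += 1
            mid = 0.5 * (lo + hi)
            fm = _pm_F(Y, S2, mid, k)
            go_up = fm > 0
            lo = np.where(active & go_up, mid, lo)
            hi = np.where(active & ~go_up, mid, hi)
            if np.max((hi - lo)[active], initial=0.0) < tol:
                break
        tau2 = np.where(active, 0.5 * (lo + hi), tau2)
    return tau2, {"Q": Q, "truncated": f0 <= 0, "converged": converged,
                  "iterations": iters}


def _rml_batch(Y, S2, tol=1e-10, max_iter=200):
    """REML by the standard Fisher-scoring fixed point, profiling mu.

    Update: tau2 <- sum w^2 ((y - mu)^2 - s2) / sum w^2 + 1 / sum w,
    with w = 1/(s2 + tau2) and mu the weighted mean; negatives clipped to 0.
    Initialized at the DSL estimate.
    """
    tau2, info = _dsl_batch(Y, S2)
    Q = info["Q"]
    tau2 = tau2.copy()
    raw = tau2
    it = 0
    delta = np.full(Y.shape[0], np.inf)
    for it in range(1, max_iter + 1):
        W = 1.0 / (S2 + tau2[:, None])
        Sw = W.sum(axis=1)
        mu = (W * Y).sum(axis=1) / Sw
        W2 = W * W
        Sw2 = W2.sum(axis=1)
        raw = (W2 * ((Y - mu[:, None]) ** 2 - S2)).sum(axis=1) / Sw2 + 1.0 / Sw
        new = np.maximum(0.0, raw)
        delta = np.abs(new - tau2)
        tau2 = new
        if delta.max() < tol:
            break
    return tau2, {"Q": Q, "truncated": raw < 0, "converged": delta < tol,
                  "iterations": it}


def _sj_batch(Y, S2):
    k = Y.shape[1]
    _, _, _, _, Q, _ = _fem_parts(Y, S2)
    yA = Y.mean(axis=1)
    crude = ((Y - yA[:, None]) ** 2).sum(axis=1) / (k - 1) - S2.mean(axis=1)
    tau0 = np.maximum(0.01, crude)
    Wstar = 1.0 / (1.0 + S2 / tau0[:, None])
    Mstar = (Wstar * Y).sum(axis=1) / Wstar.sum(axis=1)
    tau2 = (Wstar * (Y - Mstar[:, None]) ** 2).sum(axis=1) / (k - 1)
    return tau2, {"Q": Q, "truncated": crude < 0.01}


def _dsld2_batch(Y, S2):
    """The D^2 moments estimator, computed after a first-pass DSL fit.

    D^2 = (Q - S_MM) / (sum w - sum w^2 / sum w), with Q Cochran's statistic
    at fixed-effects weights and S_MM the generalized Q at random-effects
    weights and mean.  D^2 >= 0 by construction (Q majorizes S_MM); tiny
    negative values from roundoff are clipped.
    """
    tau_dsl, info = _dsl_batch(Y, S2)
    Q, denom = info["Q"], info["denom"]
    _, Mstar = _wstar_mean(Y, S2, tau_dsl)
    s_mm = (((Y - Mstar[:, None]) ** 2) / (S2 + tau_dsl[:, None])).sum(axis=1)
    raw = (Q - s_mm) / denom
    tau2 = np.maximum(0.0, raw)
    return tau2, {"Q": Q, "truncated": raw < 0, "S_MM": s_mm}


def d_squared(y, s2, tau2_plug: float) -> float:
    """D^2 evaluated at an arbitrary plug-in tau2 (used in S_MM and M*).

    The DSLD2 method plugs in the DSL estimate; exposing the plug-in value
    makes the monotonicity of D^2 in tau2 directly checkable.
    """
    Y, S2 = _as_batch(y, s2)
    if tau2_plug < 0:
        raise ValueError("tau2_plug must be >= 0")
    _, _, _, _, Q, denom = _fem_parts(Y, S2)
    t = np.full(Y.shape[0], float(tau2_plug))
    _, Mstar = _wstar_mean(Y, S2, t)
    s_mm = (((Y - Mstar[:, None]) ** 2) / (S2 + t[:, None])).sum(axis=1)
    return float(((Q - s_mm) / denom)[0])


_TAU2_BATCH = {
    "DSL": _dsl_batch,
    "DSLR2": _dslr2_batch,
    "PM": _pm_batch,
    "RML": _rml_batch,
    "SJ": _sj_batch,
    "DSLD2": _dsld2_batch,
}


def tau2_batch(Y, S2, method: str):
    """Between-study variance estimates for a (genes x studies) table.

    Returns ``(tau2, info)`` where ``tau2`` is a length-G array and ``info``
    a dict of per-gene diagnostic arrays (always containing ``Q``).
    """
    Y, S2 = _as_batch(Y, S2)
    if method == "FEM":
        _, _, _, _, Q, _ = _fem_parts(Y, S2)
        return np.zeros(Y.shape[0]), {"Q": Q, "truncated": np.zeros(Y.shape[0], bool)}
    try:
        fn = _TAU2_BATCH[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return fn(Y, S2)


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------

def cochran_q(y, s2) -> tuple[float, float]:
    """Cochran's heterogeneity statistic and the fixed-effects pooled mean.

    Q = sum w (y - M)^2 with w = 1/s2 and M the inverse-variance weighted
    mean; Q has expectation k-1 under homogeneity.
    """
    Y, S2 = _as_batch(y, s2)
    _, _, _, M, Q, _ = _fem_parts(Y, S2)
    return float(Q[0]), float(M[0])


def _scalar_tau(method, y, s2) -> TauEstimate:
    Y, S2 = _as_batch(y, s2)
    tau2, info = tau2_batch(Y, S2, method)
    conv = info.get("converged", np.ones(1, bool))
    if method == "PM" and not bool(np.atleast_1d(conv)[0]):
        raise NonConvergenceError("PM bracket expansion exceeded 1e6 * max(s2)")
    return TauEstimate(
        method=method,
        tau2=float(tau2[0]),
        Q=float(info["Q"][0]),
        truncated=bool(np.atleast_1d(info["truncated"])[0]),
        iterations=int(info.get("iterations", 0)),
        converged=bool(np.atleast_1d(conv)[0]),
    )


def tau2_dsl(y, s2) -> TauEstimate:
    """DerSimonian-Laird moments estimator: max(0, (Q - (k-1)) / c)."""
    return _scalar_tau("DSL", y, s2)


def tau2_dslr2(y, s2) -> TauEstimate:
    """Two-step R^2 between-study variability (DSL first pass), clipped to [0, 1]."""
    return _scalar_tau("DSLR2", y, s2)


def tau2_pm(y, s2) -> TauEstimate:
    """Paule-Mandel: unique root of sum w*(y - M*)^2 = k - 1."""
    return _scalar_tau("PM", y, s2)


def tau2_rml(y, s2) -> TauEstimate:
    """Restricted maximum likelihood (Fisher scoring from the DSL start)."""
    return _scalar_tau("RML", y, s2)


def tau2_sj(y, s2) -> TauEstimate:
    """Sidik-Jonkman two-step estimator with the 0.01 first-step floor."""
    return _scalar_tau("SJ", y, s2)


def tau2_dsld2(y, s2) -> TauEstimate:
    """The D^2 moments estimator (DSL first pass)."""
    return _scalar_tau("DSLD2", y, s2)


def i_squared(tau2: float, s2) -> float:
    """Higgins' I^2: fraction of total variability that is between-study.

    I^2 = tau2 / (tau2 + s_typ^2) with the moment-based typical within-study
    variance s_typ^2 = (k-1) sum(w) / ((sum w)^2 - sum w^2), w = 1/s2.
    """
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    s2 = np.asarray(s2, dtype=float)
    k = s2.size
    w = 1.0 / s2
    sw = w.sum()
    s_typ = (k - 1) * sw / (sw**2 - (w**2).sum())
    return float(tau2 / (tau2 + s_typ))


def _i_squared_batch(tau2, S2):
    k = S2.shape[1]
    W = 1.0 / S2
    Sw = W.sum(axis=1)
    s_typ = (k - 1) * Sw / (Sw**2 - (W**2).sum(axis=1))
    return tau2 / (tau2 + s_typ)


def pool_batch(Y, S2, tau2):
    """Inverse-variance pooling at given tau2 (length-G array or scalar).

    Returns a dict of per-gene arrays: mean, variance, ci_low, ci_high, z, p,
    i2.  tau2 = 0 reproduces fixed-effects pooling exactly.
    """
    Y, S2 = _as_batch(Y, S2)
    tau2 = np.broadcast_to(np.asarray(tau2, dtype=float), (Y.shape[0],)).copy()
    if np.any(tau2 < 0):
        raise ValueError("tau2 must be >= 0")
    Wstar = 1.0 / (S2 + tau2[:, None])
    Sw = Wstar.sum(axis=1)
    mean = (Wstar * Y).sum(axis=1) / Sw
    variance = 1.0 / Sw
    se = np.sqrt(variance)
    z = mean / se
    p = np.maximum(2.0 * norm.sf(np.abs(z)), P_FLOOR)
    return {
        "mean": mean,
        "variance": variance,
        "ci_low": mean - Z_CRIT * se,
        "ci_high": mean + Z_CRIT * se,
        "z": z,
        "p": p,
        "i2": _i_squared_batch(tau2, S2),
        "weights": Wstar,
        "tau2": tau2,
    }


def pool(y, s2, tau2: float, tau: TauEstimate | None = None) -> PooledResult:
    """Pool one gene's effect sizes at a fixed between-study variance."""
    out = pool_batch(y, s2, tau2)
    return PooledResult(
        mean=float(out["mean"][0]),
        variance=float(out["variance"][0]),
        ci_low=float(out["ci_low"][0]),
        ci_high=float(out["ci_high"][0]),
        z=float(out["z"][0]),
        p=float(out["p"][0]),
        i2=float(out["i2"][0]),
        weights=out["weights"][0],
        tau=tau,
    )


def run_method(method: str, y, s2) -> PooledResult:
    """Estimate tau2 by ``method`` (0 for FEM) and pool.  Deterministic."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if method == "FEM":
        Q, _ = cochran_q(y, s2)
        tau = TauEstimate(method="FEM", tau2=0.0, Q=Q)
    else:
        tau = _scalar_tau(method, y, s2)
    return pool(y, s2, tau.tau2, tau=tau)


def combine_table(Y, S2, method: str, gene_ids=None):
    """Run one combining method over a (genes x studies) effect table.

    Returns a pandas DataFrame with one row per gene: gene_id, method, k,
    tau2, mean, var, ci_low, ci_high, z, p, i2.
    """
    import pandas as pd

    Y, S2 = _as_batch(Y, S2)
    tau2, _ = tau2_batch(Y, S2, method)
    out = pool_batch(Y, S2, tau2)
    if gene_ids is None:
        gene_ids = [f"g{i+1}" for i in range(Y.shape[0])]
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "method": method,
            "k": Y.shape[1],
            "tau2": out["tau2"],
            "mean": out["mean"],
            "var": out["variance"],
            "ci_low": out["ci_low"],
            "ci_high": out["ci_high"],
            "z": out["z"],
            "p": out["p"],
            "i2": out["i2"],
        }
    )
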