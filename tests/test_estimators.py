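"""Between-study variance estimators and inverse-variance pooling.

Hand-computable k=3 instances, closed forms under equal within-study
variances, grid-search oracles for the iterative estimators, and a frozen
cross-check against R metafor 4.8 (rma with methods DL / PM / REML) on a
fixed k=6 instance.
"""

import numpy as np
import pytest
from scipy.stats import kstest

from dsld2.estimators import (
    METHODS,
    InsufficientStudiesError,
    cochran_q,
    combine_table,
    d_squared,
    i_squared,
    pool,
    run_method,
    tau2_batch,
    tau2_dsl,
    tau2_dsld2,
    tau2_dslr2,
    tau2_pm,
    tau2_rml,
    tau2_sj,
)
from conftest import random_instances

Y3, S3 = np.array([0.0, 2.0, 4.0]), np.ones(3)


@pytest.mark.parametrize(
    "y, s2, exp_q, exp_m",
    [
        ([1, 1, 1], [1, 1, 1], 0.0, 1.0),
        ([0, 2, 4], [1, 1, 1], 8.0, 2.0),
        ([0, 1], [1, 4], 0.2, 0.2),
    ],
)
def test_cochran_q_hand_examples(y, s2, exp_q, exp_m):
    q, m = cochran_q(y, s2)
    assert q == pytest.approx(exp_q)
    assert m == pytest.approx(exp_m)


class TestHandExamples:
    """All six estimators on the equal-variance y=(0,2,4) instance."""

    def test_dsl(self):
        est = tau2_dsl(Y3, S3)
        assert est.tau2 == pytest.approx(3.0)
        assert est.Q == pytest.approx(8.0)
        assert not est.truncated

    def test_dsl_boundary_no_truncation(self):
        est = tau2_dsl([0, 1, 2], [1, 1, 1])
        assert est.tau2 == 0.0
        assert not est.truncated  # Q = k-1 exactly

    def test_dsl_truncates_at_zero(self):
        est = tau2_dsl([1, 1, 1], [1, 2, 3])
        assert est.tau2 == 0.0
        assert est.truncated

    def test_pm(self):
        # equal variances: M* = 2 for all tau2, solve 8/(1+tau2) = 2
        est = tau2_pm(Y3, S3)
        assert est.tau2 == pytest.approx(3.0, abs=1e-8)
        assert est.converged

    def test_pm_zero_dispersion(self):
        est = tau2_pm([1, 1, 1], [1, 1, 1])
        assert est.tau2 == 0.0
        assert est.truncated

    def test_rml(self):
        # equal variances: REML tau2 = unbiased var(y) - sigma2 = 4 - 1
        est = tau2_rml(Y3, S3)
        assert est.tau2 == pytest.approx(3.0, abs=1e-7)
        assert est.converged

    def test_rml_constant_y(self):
        assert tau2_rml([2.5] * 4, [1, 1, 1, 1]).tau2 == 0.0

    def test_sj(self):
        est = tau2_sj(Y3, S3)
        assert est.tau2 == pytest.approx(3.0)

    def test_sj_floor_and_zero(self):
        est = tau2_sj([1.0, 1.0, 1.0], [1, 1, 1])
        assert est.truncated  # first step hit the 0.01 floor
        assert est.tau2 == pytest.approx(0.0)

    def test_dslr2(self):
        est = tau2_dslr2(Y3, S3)
        # DSL tau2 = 3 -> w* = 1/4, numerator 8/4 = 2, Q = 8
        assert est.tau2 == pytest.approx(0.75)

    def test_dslr2_zero_when_dsl_zero(self):
        assert tau2_dslr2([0, 1, 2], [1, 1, 1]).tau2 == 0.0

    def test_dsld2(self):
        est = tau2_dsld2(Y3, S3)
        # Q=8, tau2(DSL)=3, M*=2, S_MM=2, denom=2 -> D2 = 3
        assert est.tau2 == pytest.approx(3.0)

    def test_dsld2_zero_dispersion(self):
        assert tau2_dsld2([1.0, 1.0, 1.0], [1, 2, 0.5]).tau2 == pytest.approx(0.0)


def test_dsld2_stepwise_equals_helper():
    y, s2 = [0.0, 1.0, 5.0], [0.5, 1.0, 2.0]
    dsl = tau2_dsl(y, s2).tau2
    assert tau2_dsld2(y, s2).tau2 == pytest.approx(d_squared(y, s2, dsl), abs=1e-12)


class TestPooling:
    def test_fem_pool(self):
        r = pool(Y3, S3, 0.0)
        assert r.mean == pytest.approx(2.0)
        assert r.variance == pytest.approx(1 / 3)
        assert r.z == pytest.approx(2 * np.sqrt(3))
        assert r.ci_low == pytest.approx(2.0 - 1.96 * np.sqrt(1 / 3))
        assert r.ci_high == pytest.approx(2.0 + 1.96 * np.sqrt(1 / 3))

    def test_equal_weight_pool(self):
        r = pool(Y3, S3, 3.0)
        assert r.mean == pytest.approx(2.0)
        assert r.variance == pytest.approx(4 / 3)

    def test_large_tau2_limit_is_unweighted_mean(self, rng):
        y = rng.normal(size=5)
        s2 = rng.uniform(0.5, 3.0, size=5)
        r = pool(y, s2, 1e9)
        assert r.mean == pytest.approx(y.mean(), rel=1e-6)

    def test_run_method_dispatch(self):
        fem = run_method("FEM", Y3, S3)
        assert fem.mean == pytest.approx(2.0)
        assert fem.variance == pytest.approx(1 / 3)
        # equal variances: D2 = DSL tau2 -> identical pooled results
        a = run_method("DSLD2", Y3, S3)
        b = run_method("DSL", Y3, S3)
        assert a.mean == b.mean and a.p == b.p

    def test_null_two_study_case(self):
        for m in METHODS:
            r = run_method(m, [0.0, 0.0], [1.0, 1.0])
            assert r.mean == 0.0
            assert r.p == pytest.approx(1.0)

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown method"):
            run_method("EGGER", Y3, S3)

    def test_insufficient_studies(self):
        with pytest.raises(InsufficientStudiesError):
            cochran_q([1.0], [1.0])

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            tau2_dsl([0, 1], [1.0, 0.0])


class TestISquared:
    def test_zero(self):
        assert i_squared(0.0, [1, 2, 3]) == 0.0

    def test_equal_weights_half(self):
        assert i_squared(1.0, [1.0, 1.0, 1.0]) == pytest.approx(0.5)

    def test_monotone_in_tau2(self):
        s2 = [0.3, 1.0, 2.5]
        vals = [i_squared(t, s2) for t in (0.0, 0.5, 1.0, 5.0, 50.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1.0


class TestIterativeOracles:
    """PM and RML against brute-force tau2 grids on random instances."""

    def test_pm_residual_small(self, rng):
        k = 3
        for y, s2 in random_instances(rng, 20):
            est = tau2_pm(y, s2)
            k = len(y)
            w = 1.0 / (s2 + est.tau2)
            m = np.sum(w * y) / np.sum(w)
            resid = np.sum(w * (y - m) ** 2) - (k - 1)
            if est.tau2 > 0:
                assert abs(resid) < 1e-8
            else:
                assert resid <= 1e-8  # F(0) <= 0: truncated at zero

    def test_rml_attains_grid_maximum(self, rng):
        grid = np.arange(0.0, 10.0, 1e-3)
        for y, s2 in random_instances(rng, 10, k_max=6):
            est = tau2_rml(y, s2)
            ll = _restricted_loglik(np.asarray(y), np.asarray(s2), grid)
            t_grid = grid[np.argmax(ll)]
            assert est.tau2 == pytest.approx(t_grid, abs=2e-3)


def _restricted_loglik(y, s2, tau_grid):
    """The three-term restricted log-likelihood profiled over mu."""
    v = s2[None, :] + tau_grid[:, None]
    w = 1.0 / v
    mu = (w * y).sum(axis=1) / w.sum(axis=1)
    return (
        -0.5 * np.log(v).sum(axis=1)
        - 0.5 * ((y - mu[:, None]) ** 2 / v).sum(axis=1)
        - 0.5 * np.log(w.sum(axis=1))
    )


# frozen oracle: R metafor 4.8, rma(yi, vi, method=...) on this instance
_Y6 = [0.12, -0.45, 0.83, 1.20, 0.05, -0.31]
_V6 = [0.10, 0.25, 0.08, 0.30, 0.15, 0.12]


@pytest.mark.parametrize(
    "fn, expected",
    [
        (tau2_dsl, 0.2007102308),
        (tau2_pm, 0.2181043624),
        # REML agreement limited by metafor's own stopping rule
        (tau2_rml, 0.1932794871),
    ],
)
def test_matches_metafor_reference(fn, expected):
    assert fn(_Y6, _V6).tau2 == pytest.approx(expected, abs=1e-5)


def test_fem_matches_metafor_reference():
    r = run_method("FEM", _Y6, _V6)
    assert r.mean == pytest.approx(0.2570631970, abs=1e-9)
    assert np.sqrt(r.variance) == pytest.approx(0.1493480255, abs=1e-9)
    assert r.p == pytest.approx(0.085208008834, abs=1e-9)


def test_pvalues_calibrated_under_global_null(rng):
    """Null calibration when y_ig ~ N(0, s2): FEM p-values are ~U(0,1);
    DSL p-values are valid but conservative (tau2 truncation at zero widens
    intervals whenever the estimate is positive)."""
    from dsld2.estimators import pool_batch

    G, k = 4000, 5
    S2 = rng.uniform(0.5, 2.0, size=(G, k))
    Y = rng.normal(0.0, np.sqrt(S2))
    tau2, _ = tau2_batch(Y, S2, "FEM")
    p_fem = pool_batch(Y, S2, tau2)["p"]
    assert kstest(p_fem, "uniform").pvalue > 0.001
    tau2, _ = tau2_batch(Y, S2, "DSL")
    p_dsl = pool_batch(Y, S2, tau2)["p"]
    # three sigma of binomial(G, alpha) above nominal
    for alpha in (0.01, 0.05):
        bound = alpha + 3 * np.sqrt(alpha * (1 - alpha) / G)
        assert (p_dsl < alpha).mean() <= bound
    # conservative, not anti-conservative: stochastically above uniform
    assert (p_dsl < 0.05).mean() <= (p_fem < 0.05).mean() + 0.005


def test_combine_table_layout():
    tab = combine_table(np.array([[0.0, 2.0, 4.0]]), np.ones((1, 3)), "DSLD2",
                        gene_ids=["geneA"])
    row = tab.iloc[0]
    assert row["gene_id"] == "geneA"
    assert row["tau2"] == pytest.approx(3.0)
    assert row["mean"] == pytest.approx(2.0)
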