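# Methods

## Model

For gene *g* observed in *k* independent case/control studies the package
assumes the standard normal–normal random-effects model

    y_ig = μ_g + ξ_ig + ε_ig,    ξ_ig ~ N(0, τ²_g),    ε_ig ~ N(0, σ²_ig),

with the within-study variances σ²_ig treated as known (plugged in as
estimates, as is universal in this literature).  The pooled mean is the
inverse-variance weighted mean with weights ω*_ig = 1/(τ̂²_g + σ̂²_ig); its
variance is 1/Σω*.  Confidence intervals use the fixed multiplier 1.96 and
p-values come from the standard normal — no t-quantile or Knapp–Hartung
small-sample adjustment, matching the convention of the combining methods
implemented here.  p-values are floored at 1e-300 so −log₁₀(p) stays finite.

## Between-study variance estimators

All estimators truncate negative values to zero and report a truncation
flag.  With ω = 1/σ̂², M the fixed-effects mean and Q = Σω(y − M)²:

- **DSL**: max(0, (Q − (k−1)) / (Σω − Σω²/Σω)).  Closed form, biased but the
  field's default.
- **DSLR2**: after a DSL first pass, R² = 1 − Σω*(y − M*)² / Q, used
  directly as the second-step between-study variance in the pooling weights
  (mirroring DSLD2's final step).  R² lies in [0, 1]; when Q = 0 it is set
  to 0.  Note R² is a relative variability measure, so on the raw τ² scale
  it is badly biased whenever τ² is far from 1 — visible in the Monte Carlo
  study.
- **PM**: the root of F(τ²) = Σ(y − M*(τ²))²/(σ̂² + τ²) − (k − 1).  F is
  continuous and non-increasing; F(0) ≤ 0 yields 0.  The estimating
  equation is the standard generalized-Q form with the squared residual.
- **RML**: restricted maximum likelihood for the three-term restricted
  log-likelihood (with the −½ln Σ(σ̂²+τ²)⁻¹ penalty), maximized by the
  Fisher-scoring fixed point
  τ² ← Σw²((y−μ)² − σ̂²)/Σw² + 1/Σw with μ profiled as the weighted mean.
- **SJ**: two-step Sidik–Jonkman with first step
  τ₀² = max{0.01, (1/(k−1))Σ(y − ȳ)² − (1/k)Σσ̂²} and second step
  τ̂² = (1/(k−1))Σω*(y − M*)² at ω* = 1/(1 + σ̂²/τ₀²).  The 0.01 floor makes
  the estimate strictly positive whenever the y are not all equal, which is
  why SJ is the most conservative caller on null genes.
- **D² (DSLD2)**: D² = (Q − S_MM)/(Σω − Σω²/Σω), where
  S_MM = Σ(y − M*)²/(σ̂² + τ̂²_DSL) is the generalized Q evaluated at the
  DSL-based random-effects weights and mean.  Since M minimizes the
  ω-weighted sum of squares and σ̂² + τ̂² ≥ σ̂², Q ≥ S_MM, so D² ≥ 0; it is
  also non-decreasing in the plugged-in τ² (both properties are asserted by
  the test suite, the latter via the exposed `d_squared(y, s2, tau2_plug)`
  helper).  DSLD2 then pools with D² in the weights.  Under equal
  within-study variances D² coincides with the DSL estimate.

I² uses Higgins' form τ̂²/(τ̂² + s̃²) with the moment-based typical
within-study variance s̃² = (k−1)Σω/((Σω)² − Σω²), so that I² varies with
the estimator that produced τ̂².

### Numerical choices

- PM is solved by vectorized bracketed bisection: the upper bracket grows
  geometrically (capped at 10⁶·max σ̂², beyond which non-convergence is
  flagged — unreachable in practice since F → −(k−1) as τ² → ∞) and the
  interval is shrunk below 1e-12, giving residuals |F| < 1e-8.
- RML iterates from the DSL start until |Δτ²| < 1e-10 (cap 200 iterations;
  convergence is linear, so the tight step tolerance is needed for ~1e-8
  accuracy in the root).  Profiling μ rather than jointly scoring (μ, τ²)
  is a stability choice invisible at reported precision.
- All estimators are implemented once, vectorized over a (genes × studies)
  array; the scalar API wraps single rows.  DSL/PM/REML pooled results were
  cross-checked against R metafor 4.8 on a fixed instance (frozen values in
  the test suite) to ~1e-6 / metafor's own stopping precision.

## Effect sizes

Two measures per gene and study, computed from group means and ddof-1
standard deviations:

- **MD**: y = mean_case − mean_ctrl, s² = sd²_case/n_case + sd²_ctrl/n_ctrl.
- **SMD** (default): Cohen's d on the pooled sd with the Hedges small-sample
  correction J = 1 − 3/(4(n₁+n₂−2)−1), variance
  (n₁+n₂)/(n₁n₂) + y²/(2(n₁+n₂)).  Hedges-adjusted g is the default because
  it is the convention of effect-size meta-analysis of expression data; the
  uncorrected d is available via `correction="cohen"` (at the benchmark
  sample sizes the two are indistinguishable, J ≈ 0.992).

Genes with zero pooled variance are rejected (matrix ingestion drops them
with a warning) rather than patched with an ε variance, which would grant
them unbounded weight downstream.

## The expression-level simulator

`sim_expression` emulates a meta-analysis of K = 5 case/control studies,
each with G = 2000 genes and 2N samples (N per arm; default 2N = 100, sweep
2N ∈ {10, 20, 60, 100, 140, 180, 220}):

- **Correlation structure**: 40 clusters of 20 genes.  Per (cluster, study)
  pair a fresh Σ' ~ inverse-Wishart(ψ, 60) is drawn with scale matrix
  ψ = 0.5·I + 0.5·J (prior correlation ≈ 0.5) and standardized to unit
  diagonal; cluster members are then multivariate normal with that
  correlation.  The remaining 1200 genes are i.i.d. N(0, σ²_k) with one
  σ²_k ~ U(0.8, 1.2) per study.
- **DE structure**: genes 1–1000 form five groups of 200; a gene in group j
  is DE in exactly j of the 5 studies.  The affected studies are drawn
  uniformly among the C(5, j) subsets, fresh per gene; shift sizes
  μ_gk ~ U(0.5, 3) are added to case samples only.  Cluster membership is
  assigned contiguously (genes 1–800 → clusters 1–40), so group-5 genes and
  most nulls are unclustered; the generator does not prescribe any
  correlation between cluster and DE status.
- **Truth frameworks**: H1 = DE in all studies (200 genes), H2 = DE in ≥ 1
  study (1000), H3 = DE in ≥ r studies (600 at the default r = 3, a
  majority of 5).

The generator does **not** emulate platform/batch effects, missing values,
normalization artifacts, count-based noise, or library-size variation.
Passing benchmarks therefore demonstrate correctness of the estimators and
the relative behaviour of the combining methods under clean normal data
with realistic gene–gene correlation — not robustness to real microarray
or RNA-seq preprocessing.

### Scoring convention for the benchmark table

Empirical FDRs (FP/(FP+TP) among p < 0.05 and BH-FDR < 0.05 calls) and the
threshold metrics (precision, accuracy, FPR, sensitivity, MCC at p < 0.05)
are scored against the **majority-DE truth (H3, r = 3)**.  This is the only
labeling arithmetically consistent with the reference benchmark values this
package reproduces: the fixed-effects model's ≈969 BH calls with empirical
FDR ≈ 0.38 imply ≈600 true positives — the majority-DE count — whereas the
all-studies truth (200 positives) would force FDR ≥ 0.69 for any method
calling 600+ genes.  ROC and precision-recall curves are computed against
each hypothesis's own truth, ranking genes by −p.  Multiple testing uses
Benjamini–Hochberg throughout.

## The Monte Carlo study

`sim_montecarlo` isolates the τ² estimators from the expression pipeline:
each iteration draws k studies with n_i ~ N(40, (40/3)²) samples per arm
(rounded, floored at 2), within-study variance σ² = 10, control mean 0 and
case mean μ_i ~ N(0, τ²), computes effect sizes by the chosen measure, and
applies all six random-effects estimators.  Grid: k ∈ {5, 10, 20, 40, 80},
τ² ∈ {0, 1}, 1000 iterations.  Reported: bias, RMSE, mean I², and the Monte
Carlo standard error of the bias (so "close curves" statements are
testable).  On the SMD scale the generating τ² acts on raw means, so bias
and RMSE are scored against τ²/σ² = τ²/10; MD is scored against τ²
directly.

## Problem sizes in the shipped checks

The default test suite and the acceptance script use 20 seeds for the
benchmark scenario, 5 seeds × 4 sample sizes for the large-sample sweep,
and 1000 Monte Carlo iterations per cell at k ∈ {5, 40} — sizes at which
every run completes in seconds while keeping Monte Carlo standard errors
well below the effects being measured.

## Known limitations

- DSL (and every truncated-τ̂² method) is conservative under the global
  null: truncation at zero widens intervals whenever τ̂² > 0, so null
  p-values are stochastically above uniform.  The suite asserts calibration
  as a one-sided bound rather than exact uniformity.
- The Sidik–Jonkman estimator exists in several variants (different first
  steps, with and without the 0.01 floor).  The variant implemented here is
  strictly positive on any dispersed input and is therefore the *most*
  conservative caller; reference results produced with a different SJ
  variant can rank SJ's FDR above rather than below the other
  random-effects methods.
- PM differs from DSL/REML/D² by a small systematic offset (~4e-3 at
  τ² = 0.1 on the SMD scale, k = 40).  At 1000 iterations this exceeds two
  Monte Carlo standard errors even though it is invisible at the scale of
  the bias curves; "the curves coincide" holds at figure resolution, not at
  arbitrary statistical resolution.
- Empirical FDR at the raw p < 0.05 threshold depends strongly on how many
  borderline group-1/2 genes cross 0.05, which is sensitive to the exact
  effect-size and variance conventions of the generator; the BH-threshold
  FDRs and the DE counts are far more stable and are the quantities this
  package reproduces tightly.
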