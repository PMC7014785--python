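# dsld2

Random-effects meta-analysis of per-gene effect sizes with the two-step
**DSLD2** method, built on the moments estimator **D²** of the between-study
variance — plus six comparator combining methods, a cluster-correlated
gene-expression simulator with known differential-expression structure, a
Monte Carlo study of estimator bias, and a confusion/ROC/precision-recall
evaluation suite.

## Who this is for

Combining case/control expression studies of the same disease is a standard
way to stabilize differential-expression (DE) calls that individual
small-sample studies get wrong.  Under the random-effects model, the observed
effect size of gene *g* in study *i* is

```
y_ig = μ_g + ξ_ig + ε_ig,     ξ_ig ~ N(0, τ²_g),   ε_ig ~ N(0, σ²_ig),
```

where τ²_g is the **between-study variance** (heterogeneity) and σ²_ig the
within-study sampling variance.  The pooled mean uses inverse-variance
weights ω\*_ig = 1/(τ̂²_g + σ̂²_ig); everything therefore hinges on how τ²_g
is estimated.  This package implements seven choices:

| method | between-study variance |
| ------ | ---------------------- |
| FEM    | fixed at 0 (fixed-effects model) |
| DSL    | DerSimonian–Laird moments estimator: max(0, (Q − (k−1)) / (Σω − Σω²/Σω)) |
| DSLR2  | two-step: DSL first, then the between-study variability R² |
| PM     | Paule–Mandel: root of Σ ω\*(y − M\*)² = k − 1 |
| RML    | restricted maximum likelihood (Fisher scoring) |
| SJ     | Sidik–Jonkman two-step with a 0.01 first-step floor |
| DSLD2  | two-step: DSL first, then **D² = (Q − S_MM) / (Σω − Σω²/Σω)** |

Here Q is Cochran's statistic at fixed-effects weights and S_MM is the
generalized Q recomputed at random-effects weights and the random-effects
pooled mean; D² is non-negative by construction and non-decreasing in the
plugged-in τ².  Per gene, every method reports the pooled mean, its variance,
a 95% CI (±1.96·SE), the z statistic, a two-sided normal p-value, and
Higgins' I².

## Worked example

A one-gene effects table with k = 3 studies, `y = (0, 2, 4)`, all
within-study variances 1:

```
$ dsld2 meta effects.tsv --method DSLD2 --method FEM --out meta.tsv
gene_id  method  k  tau2  mean  var     ci_low   ci_high  z       p          i2
geneA    DSLD2   3  3.0   2.0   1.3333  -0.2632  4.2632   1.7321  0.083265   0.75
geneA    FEM     3  0.0   2.0   0.3333   0.8684  3.1316   3.4641  0.000532   0.0
```

The studies disagree strongly (Q = 8 with k − 1 = 2 expected), so DSLD2
estimates D² = 3.0, which flattens the weights and widens the interval: the
same pooled mean of 2.0 is significant under the fixed-effects model
(p = 0.0005) but not once between-study heterogeneity is priced in
(p = 0.083).  On this equal-variance instance DSL, PM, RML and SJ all give
τ̂² = 3.0 as well — the hand-checkable identity the test suite asserts.

The simulation benchmark (5 studies, 2000 genes, 100 samples per study, 40
correlated clusters of 20 genes, groups of 200 genes DE in exactly 1..5
studies):

```python
>>> import dsld2
>>> res = dsld2.run_benchmark(seed=1, hypotheses=("H1", "H3"))
>>> res.metrics[res.metrics.hypothesis == "H3"][
...     ["method", "de1", "de2", "fdr1", "fdr2", "auc"]]
method  de1  de2   fdr1   fdr2    auc
   FEM 1015  966 0.4089 0.3789 0.9958
   DSL  622  402 0.1125 0.0323 0.9847
 DSLR2  599  436 0.1235 0.0321 0.9798
    PM  597  380 0.1039 0.0342 0.9825
   RML  600  380 0.1050 0.0342 0.9825
    SJ  587  377 0.0886 0.0265 0.9847
 DSLD2  624  402 0.1138 0.0323 0.9847
```

`de1`/`de2` count genes called at p < 0.05 and at Benjamini–Hochberg
FDR < 0.05; `fdr1`/`fdr2` are the corresponding empirical false discovery
rates against the majority-DE truth (non-zero effects in ≥ 3 of 5 studies).
The fixed-effects model calls far more genes but nearly 38% of its
BH-surviving calls are false — it treats between-study disagreement as
precision — while every random-effects method keeps the empirical FDR near
the nominal 5%.  Ranking genes by DSLD2 p-value separates the all-studies-DE
genes almost perfectly (ROC-AUC 0.997 against the first-hypothesis truth).

The command-line equivalents are `dsld2 effects` (expression matrix → effect
sizes), `dsld2 sim-expr`, `dsld2 sim-mc`, and `dsld2 benchmark`; see
`dsld2 --help`.

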