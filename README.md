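# voomlite

Normal-theory differential expression analysis for RNA-seq read counts,
built around observation-level precision weights estimated from the
mean-variance trend of log counts-per-million.

## The problem

RNA-seq expression profiles are matrices of read counts: G genes (tens of
thousands) by n sequenced libraries (often as few as three per condition).
Counts are heteroscedastic — large counts vary more than small ones — and a
log transformation overcorrects, leaving small log-counts noisier than
large ones. Methods built on count distributions handle this but give up
the flexible, exact small-sample machinery available for normal models
(arbitrary design matrices, quantitative weights, moderated t/F tests,
gene set tests that respect inter-gene correlation).

voomlite takes the normal-theory route: model the mean-variance
relationship explicitly and absorb it into precision weights, then run the
standard weighted linear model + empirical Bayes pipeline on
log<sub>2</sub>-cpm values

y<sub>gi</sub> = log<sub>2</sub>( (r<sub>gi</sub> + 0.5) / (R<sub>i</sub> + 1) × 10⁶ ),

where r<sub>gi</sub> is the read count and R<sub>i</sub> the library size.

## The method

1. **First pass.** Fit an unweighted linear model E(y<sub>g</sub>) = Xβ<sub>g</sub>
   per gene; collect residual standard deviations s<sub>g</sub> and fitted
   values μ̂<sub>gi</sub>.
2. **Trend.** Fit a robust LOWESS curve to √s<sub>g</sub> against average
   log₂-count r̃<sub>g</sub> = ȳ<sub>g</sub> + log₂(geomean(R+1)) − log₂10⁶,
   and interpolate it into a piecewise-linear function lo(·).
3. **Weights.** Map each observation to its fitted log₂-count
   λ̂<sub>gi</sub> = μ̂<sub>gi</sub> + log₂(R<sub>i</sub>+1) − log₂10⁶ and set
   w<sub>gi</sub> = lo(λ̂<sub>gi</sub>)⁻⁴ — the inverse predicted variance.
   Because λ̂ depends on each library's depth, observations of one gene get
   different weights when sequencing depths differ.
4. **Inference.** Refit the models with the weights, squeeze the residual
   variances toward a prior with d₀ prior degrees of freedom estimated by
   moment matching on log s² (constant prior, or a spline trend in average
   log-cpm for the gene-level "trend" variant), and test coefficients or
   contrasts with moderated t/F statistics on d₀ + d<sub>g</sub> df,
   followed by Benjamini–Hochberg FDR control.

The package also provides TMM scale-normalization factors, quantile
normalization, weight-aware gene set tests (a self-contained rotation test
and a competitive test with the VIF = 1 + (m−1)ρ̄ correlation correction),
a negative-binomial simulator with truth labels, and a benchmark harness.

## Worked example

Simulate a two-group dataset (2,000 genes, 3 vs 3 libraries, 100 + 100
twofold-DE genes), then test the group effect:

```sh
voomlite simulate --scenario power --n-genes 2000 --seed 3 --out-prefix demo
voomlite fit demo.counts.tsv design.tsv --min-total 10 --coef 1 --out demo.toptable.tsv
```

where `design.tsv` holds an intercept and a group indicator per sample.
The `fit` command prints a run summary

```
{"d0": 93.65655905324637, "genes": 1996, "fdr_lt_0.05": 136, "fdr_lt_0.1": 162}
```

— d₀ is the estimated prior degrees of freedom (how much strength is
borrowed between genes; here each gene's 4-df variance is squeezed hard
toward the trend of the other 1,995 genes), and 136 genes pass a 5% FDR.
The top of `demo.toptable.tsv`:

```
gene      logFC   AveExpr  t      P.Value   FDR       B
gene897   1.636   8.521    6.33   7.44e-09  1.27e-05  10.01
gene180   1.496   12.607   6.21   1.27e-08  1.27e-05  9.51
```

`logFC` is the log₂ fold change (true value 1.0 for simulated DE genes,
estimated with shrinkage-free least squares), `AveExpr` the average
log₂-cpm, `t` the moderated t-statistic, and `B` the log posterior odds of
differential expression.

The same analysis is available programmatically:

```python
import voomlite as vl

cm = vl.read_counts("demo.counts.tsv")
cm = vl.filter_by_total(cm, 10)
X = vl.two_group_design(3, 3)
vr = vl.voom(cm, X)                                   # log-cpm + weights
fit = vl.fit_genewise(vr.y, X, weights=vr.weights)
eb = vl.ebayes(fit)
table = vl.top_table(fit, eb, coef=1)
```

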