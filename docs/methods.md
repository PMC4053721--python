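# Methods

## Model and working scale

All inference operates on log₂ counts-per-million,
y_gi = log₂((r_gi + 0.5)/(R_i + 1) × 10⁶). The 0.5 count offset keeps y
finite at zero counts and damps low-count variability; the +1 library
offset keeps the ratio strictly inside (0, 1). Analyses condition on the
library sizes R_i, which are frozen at read time: gene filtering never
recomputes them. When TMM factors f_i are computed, the effective sizes
R_i·f_i replace R_i inside the transform.

A first-order (delta-rule) expansion of the log transform around the
expected count λ links the count variance λ + φλ² (negative binomial,
φ = squared biological coefficient of variation) to the log scale:
var(ln-cpm) ≈ 1/λ + φ, i.e. the standard deviation of log-cpm is
approximately the count CV. On the log₂ scale the exact expansion divides
by ln 2; `approx_sd_log_cpm` exposes both conventions because the CV
identity is commonly quoted without the factor, while analytic checks on
log₂ data need it. (The empirical trend below is estimated from data, so
this convention does not touch the weights.) The expansion is taken around
log₂ λ; a version sometimes written as log₂(r) ≈ λ + (r−λ)/λ is
dimensionally loose and is not used.

## The mean-variance trend and observation weights

Per gene, E(y_g) = Xβ_g is fitted by ordinary least squares over the n × p
design matrix. Square roots of the residual standard deviations,
s_g^{1/2}, are smoothed against average log₂-count
r̃_g = ȳ_g + log₂(geomean(R+1)) − log₂10⁶ with LOWESS (tricube local
linear regression): span 0.5, 4 bisquare robustifying iterations, and the
classic δ = 1% interpolation shortcut. The square-root scale is used
because it makes the sd distribution roughly symmetric, which the
bisquare downweighting assumes. The smoothed values at the sorted r̃
become knots of a piecewise-linear interpolant lo(·).

Numerical choices for lo(·):

* **Extrapolation** beyond the knot range is constant (the boundary knot
  value). Linear extrapolation can cross zero or explode, either of which
  destroys the weights.
* **Floor**: lo is clipped below at 1% of its smallest positive knot so
  weights stay finite even if the smoother touches zero.
* **Duplicate knots** (ties in r̃) are collapsed by averaging their y
  values, since interpolation needs strictly increasing abscissae.
* Genes with zero residual df contribute nothing to the smoothing but are
  still assigned weights through lo.

Each observation's fitted log₂-count is
λ̂_gi = μ̂_gi + log₂(R_i + 1) − log₂10⁶ and its weight is
w_gi = lo(λ̂_gi)⁻⁴ (the trend is on the sqrt-sd scale, so the fourth power
gives an inverse variance). With equal depths and an intercept-only design
all observations of a gene share one weight and the procedure collapses to
gene-level variance modeling; with unequal depths, the per-observation
mapping is the entire point.

## Empirical Bayes moderation

Residual variances are modeled as chi-square scattered around a prior:
s̃_g² = (d₀·s₀_g² + d_g·s_g²)/(d₀ + d_g). Hyperparameters come from moment
matching on e_g = log s_g² − ψ(d_g/2) + log(d_g/2) (ψ = digamma): the mean
of e estimates log s₀², and the excess of its variance over the expected
sampling variance ψ′(d_g/2) identifies d₀ through a Newton inversion of
the trigamma function. If the excess is non-positive, d₀ = ∞ and the
prior is the plain mean of the variances (total squeezing). Heterogeneous
residual df are supported throughout.

Two priors are offered, mirroring the two gene-level strategies:

* **constant** (`trend=False`): scalar s₀², the default after voom
  weighting;
* **trended** (`trend=True`): s₀² is a natural cubic regression spline
  (4 df, truncated-power basis, knots at quantiles) in average log-cpm,
  fitted to the bias-corrected log variances — the "limma-trend" style
  pipeline for data analyzed without observation weights.

Moderated t = β̂/(s̃·u) is referred to t with d₀ + d_g df (normal when
d₀ = ∞); the joint F over k coefficients is the de-correlated quadratic
form β̂ᵀV⁻¹β̂/(k·s̃²) on (k, d₀ + d_g) df. Setting d₀ = 0 disables
moderation and reproduces the ordinary gene-wise t-test exactly — the
benchmark uses this as its unmoderated control, so method differences are
attributable to variance modeling alone. P-values are never exactly zero
(continuous reference distributions); BH q-values use stable tie handling.
The B statistic (log posterior odds) assumes a prior DE proportion of
0.01 and estimates the prior variance of true coefficients from the upper
tail of the moderated t distribution; it is reported for ranking and is
the least pinned-down quantity numerically (its value depends on that
tail fit).

## Gene set tests

The **rotation test** (self-contained) reduces each set gene, after
√weight scaling, to an orthonormal effect vector: the tested contrast
effect plus the d residual effects, using a design re-parameterized so
the contrast is the last coefficient. Under the null this vector is
spherically symmetric, so a random unit vector — one per rotation, shared
by all genes in the set to preserve inter-gene correlation — generates
exact null replicates of any set statistic. Statistics: mean of
normal-equivalent z-scores of the moderated t (directional) or mean
squared z (mixed). p = (b+1)/(B+1), granularity 1/(B+1), never zero; the
default B = 9999 makes the smallest attainable p equal 0.0001. By default
d₀ and s₀² are estimated from all genes in the supplied matrix; they can
be passed in from a prior whole-dataset fit. Note that on data where the
variance moment-matching returns d₀ = ∞ the rotated denominators become
constant, which is valid but weakens the test; supplying a finite d₀ from
a broader fit is then preferable.

The **competitive test** compares the mean normal-equivalent z-score of
the set against the remaining genes with a two-sample z-test whose set
variance is inflated by VIF = 1 + (m−1)·ρ̄, ρ̄ being the average pairwise
correlation of the set's weighted residuals (floored at −1/(m−1) so the
VIF stays non-negative). With ρ̄ = 0 it reduces to the standard
two-sample z-test; singleton sets get VIF = 1.

## Normalization

TMM factors follow the published trimmed-mean-of-M-values recipe: the
reference library is the one whose upper-quartile cpm is closest to the
mean upper quartile; gene-wise log₂ cpm ratios (M) are trimmed 30% per
tail, average log₂ abundances (A) 5% per tail, and the surviving M-values
averaged with inverse delta-method variance weights; factors are
re-centered to geometric mean 1. Pure depth differences therefore give
factors of exactly 1. Filtering happens before factor computation.
Quantile normalization maps every column to the mean of the column-wise
order statistics, ties receiving the mean of the targets their ranks
span; it is idempotent.

## The count simulator

The generator draws baseline expression proportions, scales them by
library size and fold change into expected counts
λ_gi = p_g · fc_gi · R_i, and samples NB counts as a gamma-Poisson
mixture (gamma shape 1/φ, scale λφ), which honors
var = λ + φλ² for any positive φ, including non-integer 1/φ. The
dispersion is a falling trend √ψ_gi = 0.2 + λ_gi^(−1/2) — a biological CV
asymptote of 0.2, intermediate between inbred-mouse and unrelated-human
variability — multiplied by gene-wise scatter δ_g, with 40/δ_g ~ χ²₄₀ by
default or a log-normal(0, 0.25) alternative with closely matched
log-scale spread (the inverse chi-square's log-sd is √ψ′(20) ≈ 0.226, the
log-normal's exactly 0.25). The trend is evaluated at the realized
expected count, fold change included, so DE genes in the upregulated
group sit slightly lower on the dispersion trend; with unequal depths the
same gene has different ψ in different libraries.

Baseline proportions are normalized log-normal draws with log-scale sd
2.0, giving the ~5 orders of magnitude of dynamic range seen in bulk
libraries. This is a parametric stand-in for an empirical distribution of
per-gene read proportions; user-supplied proportions are accepted
(`simulate(cfg, proportions=...)`). Consequences: absolute power numbers
depend modestly on this choice, but within-run comparisons between
pipelines — the quantities the benchmark asserts — do not hinge on it.
The simulator also does not model isoform structure, GC or length biases,
sample outliers, or correlated genes; passing benchmarks therefore speak
to the statistical engine under the stated NB model, not to robustness
against those artifacts.

Canonical scenarios: six libraries in two groups of three; equal depths of
11 million reads, or alternating 20M/2M (the same 66 million total reads,
unevenly spread); null (no DE) or power (100 genes twofold up in each
group, 200 truly DE among 10,000). Library sizes in the config are
expected depths; realized column sums fluctuate around them. Everything
is bit-reproducible from the config seed.

The spike-in style benchmark construction replicates each of the 23
non-DE control transcripts of the 92-transcript mixture design three
times, yielding 138 entries exactly half DE (23 transcripts fourfold up
in mix 1, 23 up 1.5-fold and 23 up twofold in mix 2).

## Benchmark harness and problem sizes

`run_benchmark` derives per-replicate seeds from a master seed via a seed
sequence, simulates, filters genes with fewer than ten reads total, runs
the requested pipelines (voom, limma-trend, limma-notrend, ordinary t)
and scores them against the truth labels of the retained genes: the
proportion of p-values under nominal cutoffs (type I error; strict
inequality, so a p exactly at the cutoff is not counted), true/false
positives of BH calls at q < 0.1 (empirical FDR defined as 0 when nothing
is called), and the cumulative false-discovery curve over the p-value
ranking (stable tie-break by gene index). The default of 25 replicate
simulations keeps a full scenario under a minute on one core while
putting the Monte-Carlo standard error of the type I proportion near
2×10⁻⁴; all per-simulation values are retained and standard errors
reported so tolerance bands are principled rather than ad hoc.

## Design decisions that were genuinely open

* LOWESS span 0.5 and 4 robustifying iterations: the smoother must be
  robust to hypervariable genes; the span is the common default for this
  smoother in this role, and the outlier-shift test pins the behavior.
* Filtering precedes TMM factor estimation in the pipeline helpers.
* The quadratic time-course design uses time centered and scaled to unit
  range for conditioning; a gene's peak stage is the observed stage
  maximizing the fitted trend (an interior vertex between two stages
  resolves to whichever observed stage is higher).
* The trend smoothing excludes no genes beyond those with zero residual
  df.
* `cpm` used for filtering comes from raw counts without the 0.5 offset;
  the offset belongs to the log transform only.
* Degenerate variance inputs: equal gene variances give d₀ = ∞ with the
  common variance as prior; all-zero residual sd is rejected as
  unanalyzable.

## Known limitations

* Missing values / per-observation NA patterns are not supported in the
  linear models (heterogeneous residual df are supported in the
  moderation step).
* No robust variant of the hyperparameter estimation against
  hypervariable genes; a single extreme gene can pull d₀ down (though not
  the LOWESS trend, which is robust).
* The competitive test estimates ρ̄ from residual correlations, which is
  noisy for very small sets; the rotation test is preferable below ~5
  genes.
* TMM factors are exactly invariant to pure depth changes but only
  approximately invariant to rescaling one library, because the
  delta-method gene weights depend on absolute counts.
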