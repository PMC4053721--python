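"""Mean-variance trend estimation and observation-level precision weights.

The central idea: after fitting gene-wise linear models to log2-cpm values,
the residual standard deviations still carry a strong trend with gene
abundance (large at low counts, flattening to the biological coefficient
of variation at high counts).  A robust LOWESS curve through the gene-wise
square-root residual standard deviations, as a function of average
log2-count, defines a piecewise-linear function ``lo``.  Each individual
observation then maps to a predicted standard deviation by evaluating
``lo`` at the observation's *fitted* log2-count -- which differs between
samples of unequal sequencing depth even when the fitted cpm is the same.
The precision weight of an observation is the inverse predicted variance

    w_gi = lo(lambda_hat_gi)^-4

(the trend is on the square-root-sd scale, hence the fourth power).  With
these weights, downstream normal-theory inference is free of the
mean-variance trend.

The gene-level alternative (``prior_trend``) drives the "trended prior"
empirical Bayes variant: instead of weighting observations, the gene-wise
variances are later squeezed toward a smooth function of average log-cpm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .counts import CountMatrix
from .linmod import DesignMatrix, GeneFit, fit_genewise
from .logcpm import LogCpmMatrix, to_log_cpm

_LOG2_1E6 = np.log2(1e6)


@dataclass
class MeanVarTrend:
    """Piecewise-linear map from average log2-count to predicted sqrt-sd.

    Constant extrapolation beyond the observed knot range keeps predicted
    standard deviations positive and bounded; a floor at 1% of the smallest
    positive knot value keeps weights finite even for degenerate fits.
    """

    knots_x: np.ndarray
    knots_y: np.ndarray

    def __post_init__(self):
        kx = np.asarray(self.knots_x, dtype=float)
        ky = np.asarray(self.knots_y, dtype=float)
        order = np.argsort(kx)
        kx, ky = kx[order], ky[order]
        # collapse duplicate x by averaging y (interpolation needs strict order)
        ux, inv = np.unique(kx, return_inverse=True)
        if len(ux) < len(kx):
            uy = np.zeros_like(ux)
            cnt = np.zeros_like(ux)
            np.add.at(uy, inv, ky)
            np.add.at(cnt, inv, 1)
            kx, ky = ux, uy / cnt
        pos = ky[ky > 0]
        floor = 0.01 * pos.min() if pos.size else 1e-6
        self.knots_x = kx
        self.knots_y = np.maximum(ky, floor)

    def lo(self, x):
        """Predicted square-root standard deviation at log2-count ``x``."""
        return np.interp(np.asarray(x, dtype=float), self.knots_x, self.knots_y)

    def __call__(self, x):
        return self.lo(x)


@dataclass
class VoomResult:
    y: LogCpmMatrix
    weights: np.ndarray          # (G, n), w_gi = lo(lambda_hat_gi)^-4
    trend: MeanVarTrend
    fitted_logcount: np.ndarray  # (G, n) lambda_hat on log2 scale
    first_fit: GeneFit = None    # unweighted fit used to build the trend


def avg_log_count(fit: GeneFit, lib_sizes) -> np.ndarray:
    """Average log2-count per gene: ybar_g + log2(geomean(R_i + 1)) - log2(1e6).

    The geometric (not arithmetic) mean of the offset library sizes converts
    the average log-cpm back to the count scale consistently with the log
    transform.
    """
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if np.any(lib_sizes <= 0):
        raise ValueError("library sizes must be positive")
    return fit.avg_logcpm + np.mean(np.log2(lib_sizes + 1.0)) - _LOG2_1E6


def fitted_log_count(fit: GeneFit, lib_sizes) -> np.ndarray:
    """Fitted log2-count per observation: mu_hat_gi + log2(R_i + 1) - log2(1e6)."""
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    return fit.mu + np.log2(lib_sizes + 1.0)[None, :] - _LOG2_1E6


def fit_trend(
    r_tilde, sigma, span: float = 0.5, iterations: int = 4
) -> MeanVarTrend:
    """Robust LOWESS of sqrt residual sd against average log2-count.

    Square-root standard deviations are used because their distribution is
    roughly symmetric; the bisquare robustifying iterations keep single
    hypervariable genes from deflecting the trend.  Genes with undefined
    sigma (zero residual df) are excluded from the smoothing but are still
    covered by the returned interpolant.
    """
    r_tilde = np.asarray(r_tilde, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    ok = np.isfinite(sigma) & np.isfinite(r_tilde)
    x, s = r_tilde[ok], sigma[ok]
    if len(x) < 10:
        raise ValueError("need at least 10 genes with positive residual df")
    if np.all(s == 0):
        raise ValueError("all residual standard deviations are zero")
    sqrt_sd = np.sqrt(s)
    delta = 0.01 * (x.max() - x.min())  # interpolation speedup, as in classic lowess
    fitted = sm.nonparametric.lowess(
        sqrt_sd, x, frac=span, it=iterations, delta=delta, return_sorted=True
    )
    return MeanVarTrend(knots_x=fitted[:, 0], knots_y=fitted[:, 1])


def voom(
    cm: CountMatrix,
    design: DesignMatrix,
    use_effective_sizes: bool = False,
    normalize: str = "none",
    span: float = 0.5,
    iterations: int = 4,
) -> VoomResult:
    """Estimate the mean-variance trend and return log-cpm plus weights.

    Pipeline: log2-cpm -> unweighted gene-wise fits -> LOWESS trend of
    sqrt residual sd on average log2-count -> evaluate the trend at each
    observation's fitted log2-count -> weights ``lo(.)^-4``.

    ``normalize='quantile'`` quantile-normalizes the log-cpm matrix between
    libraries before fitting; TMM normalization is requested by computing
    factors on the counts and passing ``use_effective_sizes=True``.
    """
    ym = to_log_cpm(cm, use_effective_sizes=use_effective_sizes)
    if normalize == "quantile":
        from .counts import quantile_normalize

        ym.y = quantile_normalize(ym.y)
    elif normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")
    fit = fit_genewise(ym, design)
    r_tilde = avg_log_count(fit, ym.lib_sizes_used)
    trend = fit_trend(r_tilde, fit.sigma, span=span, iterations=iterations)
    lam_hat = fitted_log_count(fit, ym.lib_sizes_used)
    weights = trend.lo(lam_hat) ** -4
    return VoomResult(
        y=ym, weights=weights, trend=trend, fitted_logcount=lam_hat, first_fit=fit
    )


def _natural_spline_basis(x, df: int = 4):
    """Natural cubic spline basis (truncated-power construction).

    Columns: x plus df-1 natural-constrained cubic terms; knots at
    quantiles of x with the outermost pair acting as boundary knots.
    Linearity beyond the boundary knots is implied by the construction.
    """
    x = np.asarray(x, dtype=float)
    n_knots = df + 1
    qs = np.linspace(0, 1, n_knots)
    knots = np.quantile(x, qs)
    knots = np.unique(knots)
    if len(knots) < 3:
        # nearly-degenerate covariate: fall back to linear
        return x[:, None]
    kK = knots[-1]
    kK1 = knots[-2]

    def d(k):
        return (np.clip(x - k, 0, None) ** 3 - np.clip(x - kK, 0, None) ** 3) / (
            kK - k
        )

    dK1 = d(kK1)
    cols = [x] + [d(k) - dK1 for k in knots[:-2]]
    return np.column_stack(cols)


def prior_trend(sigma2, covariate, df=None, spline_df: int = 4):
    """Trended prior variance: regression spline of log variance on abundance.

    Fits a natural cubic spline with ``spline_df`` degrees of freedom to the
    bias-corrected log variances (each log s_g^2 is offset by the mean of
    its sampling distribution under chi-square residual df, so the fitted
    curve estimates the log prior variance rather than the mean log sample
    variance).  Returns the per-gene prior variance exp(fitted).
    """
    from scipy.special import digamma

    sigma2 = np.asarray(sigma2, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    G = len(sigma2)
    if G < spline_df + 2:
        raise ValueError("too few genes to fit the variance trend spline")
    if df is None:
        e = np.log(sigma2)
    else:
        dfa = np.broadcast_to(np.asarray(df, dtype=float), sigma2.shape)
        e = np.log(sigma2) - digamma(dfa / 2.0) + np.log(dfa / 2.0)
    B = np.column_stack([np.ones(G), _natural_spline_basis(covariate, spline_df)])
    coef, *_ = np.linalg.lstsq(B, e, rcond=None)
    return np.exp(B @ coef)
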