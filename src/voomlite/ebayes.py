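"""Empirical Bayes variance moderation and moderated t/F inference.

Gene-wise residual variances s_g^2 with d_g residual degrees of freedom are
modeled as scaled chi-square draws around a prior variance s0^2 (a scalar,
or a smooth function of average log-cpm for the trended variant) with prior
degrees of freedom d0.  The posterior variance is the weighted average

    s~_g^2 = (d0 * s0_g^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t-statistic beta_hat / (s~ * u) follows a t distribution
with d0 + d_g degrees of freedom exactly under the normal model, which is
what gives small-sample type I error control.  The hyperparameters (d0,
s0^2) are estimated by moment matching on z_g = log(s_g^2): the mean and
excess variance of z relative to its chi-square sampling moments identify
s0^2 and d0 through digamma/trigamma equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .linmod import GeneFit
from .voom import _natural_spline_basis


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y):
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Monotone decreasing target; the iteration below converges from the
    asymptotic starting value 0.5 + 1/y in a handful of steps.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("trigamma inverse requires positive input")
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


@dataclass
class EBayesFit:
    d0: float                 # prior degrees of freedom (may be inf)
    s0sq: np.ndarray          # scalar-like or per-gene prior variance
    post_var: np.ndarray      # (G,) posterior variances
    df_total: np.ndarray      # (G,) d0 + d_g (capped at G * max df)
    t: np.ndarray = None      # (G, k)
    p: np.ndarray = None      # (G, k)
    lods: np.ndarray = None   # (G, k)
    F: np.ndarray = None      # (G,)
    F_p: np.ndarray = None    # (G,)


def estimate_prior(sigma, df, covariate=None, spline_df: int = 4):
    """Moment-matching estimate of (d0, s0^2) from gene-wise variances.

    ``sigma`` are residual standard deviations, ``df`` the residual degrees
    of freedom (scalar or per gene; genes with df = 0 are ignored).  When
    ``covariate`` (average log-cpm) is supplied the prior variance is a
    natural-spline trend in the covariate and a per-gene vector is
    returned, otherwise a scalar.
    """
    sigma = np.asarray(sigma, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), sigma.shape).copy()
    ok = np.isfinite(sigma) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need at least 2 genes with positive residual df")
    s2 = np.maximum(sigma[ok] ** 2, 1e-300)
    d = df[ok]
    z = np.log(s2)
    # center z by the chi-square sampling mean so e estimates log(s0^2)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)

    if covariate is None:
        emean = np.full(int(ok.sum()), e.mean())
        s0_log_all = np.full(sigma.shape, e.mean())
    else:
        cov = np.asarray(covariate, dtype=float)
        # one basis over all genes so df=0 genes still get a prior value
        B_all = np.column_stack(
            [np.ones(len(cov)), _natural_spline_basis(cov, spline_df)]
        )
        coef, *_ = np.linalg.lstsq(B_all[ok], e, rcond=None)
        emean = B_all[ok] @ coef
        s0_log_all = B_all @ coef

    n = int(ok.sum())
    evar = np.mean((e - emean) ** 2) * n / max(n - 1, 1)
    evar = evar - np.mean(_trigamma(d / 2.0))
    if evar > 0:
        d0 = 2.0 * float(_trigamma_inverse(evar))
        s0sq = np.exp(s0_log_all + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        # no excess variability between genes: the prior is the common
        # variance itself and squeezing is total
        d0 = np.inf
        if covariate is None:
            s0sq = np.full(sigma.shape, s2.mean())
        else:
            zB, *_ = np.linalg.lstsq(B_all[ok], z, rcond=None)
            s0sq = np.exp(B_all @ zB)
    if covariate is None:
        return d0, float(s0sq.flat[0])
    return d0, s0sq


def squeeze_var(sigma2, df, d0, s0sq):
    """Posterior variance: convex combination of gene and prior variances."""
    sigma2 = np.asarray(sigma2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), sigma2.shape)
    s0sq = np.broadcast_to(np.asarray(s0sq, dtype=float), sigma2.shape)
    if d0 < 0:
        raise ValueError("prior degrees of freedom must be non-negative")
    if np.isinf(d0):
        return s0sq.copy()
    return (d0 * s0sq + df * sigma2) / (d0 + df)


def ebayes(
    fit: GeneFit,
    trend: bool = False,
    d0_override: float = None,
    proportion: float = 0.01,
) -> EBayesFit:
    """Full moderated inference for every coefficient of a fit.

    ``trend=True`` squeezes toward a spline trend in average log-cpm (the
    gene-level alternative to observation weights); ``d0_override=0`` turns
    moderation off entirely, reproducing the ordinary gene-wise t-test.
    ``proportion`` is the assumed prior fraction of DE genes used only by
    the log-odds (B) statistic.
    """
    covariate = fit.avg_logcpm if trend else None
    if d0_override is not None:
        d0 = float(d0_override)
        if d0 == 0 and not trend:
            s0sq = np.nanmean(fit.sigma**2)  # unused when d0 = 0
        else:
            try:
                _, s0sq = estimate_prior(fit.sigma, fit.df_resid, covariate)
            except ValueError:
                s0sq = np.nanmean(fit.sigma**2)
    else:
        d0, s0sq = estimate_prior(fit.sigma, fit.df_resid, covariate)

    sigma2 = fit.sigma**2
    post_var = squeeze_var(sigma2, fit.df_resid, d0, s0sq)
    df_total = fit.df_resid + (0.0 if np.isinf(d0) else d0)
    if np.isinf(d0):
        df_total = np.full_like(fit.df_resid, np.inf)

    se = np.sqrt(post_var)[:, None] * fit.stdev_unscaled
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.beta / se
    p = _t_pvalue(t, df_total[:, None])
    eb = EBayesFit(
        d0=d0, s0sq=np.asarray(s0sq), post_var=post_var, df_total=df_total,
        t=t, p=p,
    )
    eb.lods = _lods(fit, eb, proportion)
    return eb


def _t_pvalue(t, df):
    df = np.broadcast_to(df, np.shape(t))
    p = np.empty_like(np.asarray(t, dtype=float))
    fin = np.isfinite(df)
    p[fin] = 2.0 * stats.t.sf(np.abs(t)[fin], df[fin])
    p[~fin] = 2.0 * stats.norm.sf(np.abs(t)[~fin])
    return p


def moderated_t(fit: GeneFit, eb: EBayesFit, coef: int = -1):
    """Moderated t and two-sided p for one coefficient."""
    return eb.t[:, coef], eb.p[:, coef]


def moderated_F(fit: GeneFit, eb: EBayesFit, coefs=None):
    """Joint moderated F-test that a set of coefficients is zero.

    F_g is the mean of squared de-correlated moderated t-values, i.e. the
    quadratic form beta' V^-1 beta / (k * s~^2) with V the unscaled
    coefficient covariance; the reference distribution is F(k, d0 + d_g).
    """
    G, pcoef = fit.beta.shape
    if coefs is None:
        coefs = list(range(pcoef))
    coefs = list(coefs)
    k = len(coefs)
    if k < 1:
        raise ValueError("need at least one coefficient")
    b = fit.beta[:, coefs]
    V = fit.cov_unscaled[np.ix_(range(G), coefs, coefs)]
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular coefficient covariance") from exc
    quad = np.einsum("gi,gij,gj->g", b, Vi, b)
    F = quad / (k * eb.post_var)
    df2 = eb.df_total
    p = np.where(
        np.isfinite(df2),
        stats.f.sf(F, k, np.where(np.isfinite(df2), df2, 1.0)),
        stats.chi2.sf(k * F, k),
    )
    return F, p


def bh_fdr(p):
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j>=i} m p_(j) / j, capped at 1; ties share the value of
    the largest rank among them (stable, order-preserving).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _lods(fit: GeneFit, eb: EBayesFit, proportion: float = 0.01):
    """Log posterior odds of differential expression (B-statistic).

    Uses a normal prior on true coefficients with variance v0 estimated
    from the upper tail of the moderated t-statistics, and the assumed
    prior proportion of DE genes.
    """
    G, k = eb.t.shape
    lods = np.empty((G, k))
    for j in range(k):
        v0 = _var_prior(
            eb.t[:, j], fit.stdev_unscaled[:, j], eb.df_total, proportion
        )
        r = (fit.stdev_unscaled[:, j] ** 2 + v0) / fit.stdev_unscaled[:, j] ** 2
        t2 = eb.t[:, j] ** 2
        dft = eb.df_total
        fin = np.isfinite(dft)
        dft_safe = np.where(fin, dft, 1.0)
        with np.errstate(over="ignore"):
            kernel = np.where(
                fin,
                (1.0 + dft_safe) / 2.0 * np.log((t2 + dft_safe) / (t2 / r + dft_safe)),
                t2 * (1.0 - 1.0 / r) / 2.0,
            )
        lods[:, j] = np.log(proportion / (1.0 - proportion)) - 0.5 * np.log(r) + kernel
    return lods


def _var_prior(t, stdev_unscaled, df_total, proportion):
    """Estimate the prior variance of true coefficients from top |t| values."""
    G = len(t)
    ntarget = int(np.ceil(proportion / 2.0 * G))
    if ntarget < 1:
        return 1.0
    at = np.abs(t)
    o = np.argsort(-at)[:ntarget]
    tt = at[o]
    v1 = stdev_unscaled[o] ** 2
    dfo = np.where(np.isfinite(df_total[o]), df_total[o], 1e6)
    prop = max(ntarget / G, proportion)
    r = np.arange(1, ntarget + 1) - 0.5
    p0 = 2.0 * stats.t.sf(tt, dfo)
    ptarget = ((r / G) - (1.0 - prop) * p0) / prop
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if pos.any():
        qtarget = stats.t.isf(ptarget[pos] / 2.0, dfo[pos])
        v0[pos] = v1[pos] * np.maximum((tt[pos] / qtarget) ** 2 - 1.0, 0.0)
    return float(np.mean(v0)) if ntarget else 1.0


def top_table(
    fit: GeneFit, eb: EBayesFit, coef: int = -1, sort: str = "p", n: int = None
) -> pd.DataFrame:
    """Ranked differential expression table.

    Columns: gene, logFC (the coefficient, log2 fold change), AveExpr
    (average log2-cpm), t (moderated t), P value, FDR (BH-adjusted) and B
    (log posterior odds).
    """
    coef_idx = coef if coef >= 0 else eb.t.shape[1] + coef
    p = eb.p[:, coef_idx]
    tab = pd.DataFrame(
        {
            "gene": (
                fit.gene_ids
                if fit.gene_ids is not None
                else np.arange(len(p)).astype(str)
            ),
            "logFC": fit.beta[:, coef_idx],
            "AveExpr": fit.avg_logcpm,
            "t": eb.t[:, coef_idx],
            "P.Value": p,
            "FDR": bh_fdr(p),
            "B": eb.lods[:, coef_idx],
        }
    )
    key = {"p": "P.Value", "B": "B", "logFC": "logFC"}[sort]
    ascending = key == "P.Value"
    if key == "logFC":
        tab = tab.reindex(tab["logFC"].abs().sort_values(ascending=False).index)
    else:
        tab = tab.sort_values(key, ascending=ascending, kind="mergesort")
    tab = tab.reset_index(drop=True)
    return tab.head(n) if n is not None else tab
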