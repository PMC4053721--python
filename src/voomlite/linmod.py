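"""Gene-wise (weighted) least-squares linear models.

Every gene g gets its own regression E(y_g) = X beta_g over a shared
n x p design matrix X, optionally with observation weights w_gi.  The fits
are vectorized across genes: a single QR factorization when weights are
absent, batched normal equations otherwise (p is small, G is large).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DesignMatrix:
    X: np.ndarray           # (n, p), full column rank
    names: list[str]

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n, p = self.X.shape
        if np.linalg.matrix_rank(self.X) < p:
            dep = _dependent_columns(self.X, self.names)
            raise ValueError(f"design matrix is rank deficient; dependent columns: {dep}")

    @property
    def n(self):
        return self.X.shape[0]

    @property
    def p(self):
        return self.X.shape[1]


def _dependent_columns(X, names):
    r = np.linalg.matrix_rank(X)
    keep, cols = [], []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            cols.append(names[j] if names else j)
    return cols if cols else list(range(r, X.shape[1]))


def design_from_groups(groups) -> DesignMatrix:
    """Intercept + indicator coding: coefficient j>0 is the log2 fold change
    of group j relative to the first group."""
    groups = pd.Series(list(groups))
    levels = list(pd.unique(groups))
    X = np.ones((len(groups), len(levels)))
    for j, lev in enumerate(levels[1:], start=1):
        X[:, j] = (groups == lev).to_numpy(dtype=float)
    names = ["(Intercept)"] + [str(l) for l in levels[1:]]
    return DesignMatrix(X, names)


def read_design(path) -> DesignMatrix:
    """Tab-delimited design: samples in rows (first column = sample names),
    covariates in header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DesignMatrix(df.to_numpy(dtype=float), list(df.columns))


def quadratic_time_design(times) -> DesignMatrix:
    """Design {1, t, t^2} with t centered and scaled to unit range.

    Used for time-course studies without replication, where a smooth
    quadratic trend in time stands in for replication; the stage at which
    a fitted concave trend peaks assigns each gene to a stage.
    """
    times = np.asarray(times, dtype=float)
    if len(np.unique(times)) < 3:
        raise ValueError("need at least 3 distinct time points for a quadratic trend")
    t = (times - times.mean()) / (times.max() - times.min())
    X = np.column_stack([np.ones_like(t), t, t * t])
    return DesignMatrix(X, ["(Intercept)", "t", "t2"])


def peak_stage(fit: "GeneFit", times) -> np.ndarray:
    """Observed stage at which each gene's fitted trend is largest."""
    idx = np.argmax(fit.mu, axis=1)
    return np.asarray(times)[idx]


@dataclass
class GeneFit:
    """Per-gene regression output.

    ``stdev_unscaled[g, j]`` is sqrt of the j-th diagonal entry of
    (X' W_g X)^-1: multiplying by the residual sd gives the standard error
    of coefficient j.  ``cov_unscaled`` keeps the full p x p inverse for
    contrasts and joint F-tests.
    """

    beta: np.ndarray            # (G, p)
    mu: np.ndarray              # (G, n) fitted values
    sigma: np.ndarray           # (G,) residual sd
    df_resid: np.ndarray        # (G,)
    avg_logcpm: np.ndarray      # (G,) unweighted row means of y
    stdev_unscaled: np.ndarray  # (G, p)
    cov_unscaled: np.ndarray    # (G, p, p)
    coef_names: list = None
    gene_ids: np.ndarray = None


def fit_genewise(y, X: DesignMatrix, weights=None, gene_ids=None) -> GeneFit:
    """Fit E(y_g) = X beta_g per gene by (weighted) least squares.

    ``y`` may be a LogCpmMatrix or a (G, n) array.  Weights, if given, must
    be strictly positive and finite, one per observation.
    """
    from .logcpm import LogCpmMatrix

    if isinstance(y, LogCpmMatrix):
        if gene_ids is None:
            gene_ids = y.gene_ids
        y = y.y
    y = np.atleast_2d(np.asarray(y, dtype=float))
    G, n = y.shape
    Xm = X.X
    p = X.p
    if n != X.n:
        raise ValueError("y and design have different numbers of samples")
    df_resid = np.full(G, n - p)
    avg_logcpm = y.mean(axis=1)

    if weights is None:
        Q, R = np.linalg.qr(Xm)
        beta = np.linalg.solve(R, Q.T @ y.T).T
        cov1 = np.linalg.inv(R.T @ R)
        cov = np.broadcast_to(cov1, (G, p, p)).copy()
        mu = beta @ Xm.T
        rss = ((y - mu) ** 2).sum(axis=1)
    else:
        w = np.atleast_2d(np.asarray(weights, dtype=float))
        if w.shape != y.shape:
            raise ValueError("weights must match y in shape")
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("weights must be strictly positive and finite")
        # batched normal equations; p is small so this is stable enough
        XtWX = np.einsum("ni,gn,nj->gij", Xm, w, Xm)
        XtWy = np.einsum("ni,gn->gi", Xm, w * y)
        cov = np.linalg.inv(XtWX)
        beta = np.einsum("gij,gj->gi", cov, XtWy)
        mu = beta @ Xm.T
        rss = (w * (y - mu) ** 2).sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        sigma = np.sqrt(rss / np.maximum(df_resid, 1))
    sigma[df_resid == 0] = np.nan
    sd_unscaled = np.sqrt(np.diagonal(cov, axis1=1, axis2=2))
    return GeneFit(
        beta=beta,
        mu=mu,
        sigma=sigma,
        df_resid=df_resid.astype(float),
        avg_logcpm=avg_logcpm,
        stdev_unscaled=sd_unscaled,
        cov_unscaled=cov,
        coef_names=list(X.names),
        gene_ids=gene_ids,
    )


def apply_contrasts(fit: GeneFit, C: np.ndarray, names=None) -> GeneFit:
    """Re-parameterize a fit to k contrast coefficients beta' = C' beta.

    ``C`` is p x k.  The unscaled covariance transforms as C' V C; residual
    sd and df are untouched.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.ndim != 2 or C.shape[0] != fit.beta.shape[1]:
        raise ValueError(
            f"contrast matrix must have {fit.beta.shape[1]} rows, got {C.shape}"
        )
    if not np.all(np.isfinite(C)):
        raise ValueError("contrast matrix must be finite")
    beta = fit.beta @ C
    cov = np.einsum("ik,gij,jl->gkl", C, fit.cov_unscaled, C)
    sd = np.sqrt(np.diagonal(cov, axis1=1, axis2=2))
    return GeneFit(
        beta=beta,
        mu=fit.mu,
        sigma=fit.sigma,
        df_resid=fit.df_resid,
        avg_logcpm=fit.avg_logcpm,
        stdev_unscaled=sd,
        cov_unscaled=cov,
        coef_names=list(names) if names is not None else [f"C{j}" for j in range(C.shape[1])],
        gene_ids=fit.gene_ids,
    )
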