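"""Weight-aware gene set tests.

Two complementary questions about a set of genes:

* self-contained (rotation test): are the genes in the set differentially
  expressed at all, ignoring genes outside the set?  The null distribution
  is generated by random rotations of the residual-space component of the
  data, which preserves inter-gene correlation exactly and is valid for
  any sample size with residual df >= 1.
* competitive: are the genes in the set *more* differentially expressed
  than the rest of the genome?  A two-sample comparison of gene-level
  z-scores, with the set's variance inflated by VIF = 1 + (m - 1) * rho_bar
  to account for the mean inter-gene residual correlation rho_bar -- the
  correction that keeps correlated sets from producing tiny spurious
  p-values.

Both consume the observation-level precision weights, so they apply
directly to the output of the mean-variance modeling pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ebayes import estimate_prior, squeeze_var
from .linmod import DesignMatrix


@dataclass
class GeneSet:
    name: str
    members: list

    def __post_init__(self):
        if len(self.members) == 0:
            raise ValueError(f"gene set {self.name!r} has no members")
        seen, uniq = set(), []
        for m in self.members:
            if m in seen:
                warnings.warn(f"duplicate member {m!r} in set {self.name!r}; deduplicated")
            else:
                seen.add(m)
                uniq.append(m)
        self.members = uniq


@dataclass
class GeneSetResult:
    name: str
    n_genes_used: int
    direction: str          # up | down | mixed
    p_value: float
    statistic: float
    vif: float = None       # competitive test only
    rotations_used: int = None  # rotation test only
    p_up: float = None
    p_down: float = None


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: name <tab> description <tab> member genes."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected name, description and at "
                    f"least one member (tab-delimited)"
                )
            members = [m for m in parts[2:] if m.strip()]
            if not members:
                raise ValueError(f"{path}:{lineno}: set {parts[0]!r} has no members")
            sets.append(GeneSet(name=parts[0], members=members))
    return sets


def _contrast_last_design(X: np.ndarray, contrast: np.ndarray):
    """Re-parameterize so the tested contrast is the last coefficient.

    Returns the transformed design X* with the property that the last
    element of the new coefficient vector equals c' beta.
    """
    p = X.shape[1]
    c = np.asarray(contrast, dtype=float).reshape(p)
    # build invertible C with c as its last column
    basis = np.eye(p)
    cols = [c]
    for j in range(p):
        trial = np.column_stack(cols + [basis[:, j]])
        if np.linalg.matrix_rank(trial) > len(cols):
            cols.append(basis[:, j])
        if len(cols) == p:
            break
    C = np.column_stack(cols[1:] + [c])  # contrast last
    return X @ np.linalg.inv(C).T


def rotation_set_test(
    y,
    weights,
    X,
    contrast,
    gene_set: GeneSet,
    B: int = 9999,
    stat: str = "mean",
    d0: float = None,
    s0sq: float = None,
    rng=None,
) -> GeneSetResult:
    """Self-contained rotation test of a gene set for one contrast.

    For each member gene the (weighted) data are reduced to an orthonormal
    effect vector z_g of length d+1: the contrast effect plus the d residual
    effects.  Under the null these are spherically symmetric, so random
    rotations -- shared across genes to preserve correlations -- generate
    the exact null distribution of any set statistic.  The reported p is
    (b + 1)/(B + 1), never zero and with granularity 1/(B + 1).

    Moderation hyperparameters (d0, s0sq) may be passed from a whole-matrix
    fit; by default they are estimated from the supplied genes.
    """
    from .logcpm import LogCpmMatrix

    if isinstance(y, LogCpmMatrix):
        gene_ids, ymat = y.gene_ids, y.y
    else:
        ymat = np.asarray(y, dtype=float)
        gene_ids = np.arange(ymat.shape[0]).astype(str)
    if isinstance(X, DesignMatrix):
        X = X.X
    if B < 99:
        raise ValueError("need at least 99 rotations")
    rng = np.random.default_rng(rng)

    idx = [i for i, g in enumerate(gene_ids) if g in set(gene_set.members)]
    if not idx:
        raise ValueError(f"no genes of set {gene_set.name!r} found in the matrix")
    m = len(idx)
    n, p = X.shape
    d = n - p
    if d < 1:
        raise ValueError("rotation test needs residual df >= 1")

    Xstar = _contrast_last_design(X, contrast)
    if weights is None:
        weights = np.ones_like(ymat)
    w = np.asarray(weights, dtype=float)

    # per-gene effects: contrast effect + residual effects (length d+1)
    Z = np.empty((m, d + 1))
    for k, g in enumerate(idx):
        sw = np.sqrt(w[g])
        Q, _ = np.linalg.qr(Xstar * sw[:, None], mode="complete")
        u = Q.T @ (ymat[g] * sw)
        Z[k, 0] = u[p - 1]       # contrast effect
        Z[k, 1:] = u[p:]         # residual effects

    if d0 is None or s0sq is None:
        # moderate with hyperparameters estimated from every gene supplied,
        # not just the set, matching a whole-matrix empirical Bayes fit
        from .linmod import DesignMatrix as _DM, fit_genewise

        full_fit = fit_genewise(ymat, _DM(X, [f"c{j}" for j in range(p)]),
                                weights=w)
        try:
            d0_est, s0_est = estimate_prior(full_fit.sigma, full_fit.df_resid)
        except ValueError:
            d0_est, s0_est = 0.0, float(np.nanmean(full_fit.sigma**2))
        d0 = d0_est if d0 is None else d0
        s0sq = s0_est if s0sq is None else s0sq
    df_total = d0 + d if np.isfinite(d0) else np.inf

    def set_stats(b_eff, s2):
        s2_mod = squeeze_var(s2, float(d), d0, np.asarray(s0sq))
        t = b_eff / np.sqrt(s2_mod)
        if np.isfinite(df_total):
            z = stats.norm.isf(stats.t.sf(t, df_total))
        else:
            z = t
        z = np.clip(z, -38.0, 38.0)
        return z.mean(), (z**2).mean()

    norm2 = (Z**2).sum(axis=1)
    obs_mean, obs_msq = set_stats(Z[:, 0], (norm2 - Z[:, 0] ** 2) / d)

    # random rotations: first row of a random orthogonal matrix, shared genes
    R = rng.standard_normal((B, d + 1))
    R /= np.linalg.norm(R, axis=1, keepdims=True)
    count_up = count_down = count_msq = 0
    rot_eff = R @ Z.T                      # (B, m)
    rot_s2 = (norm2[None, :] - rot_eff**2) / d
    for b in range(B):
        mn, msq = set_stats(rot_eff[b], rot_s2[b])
        count_up += mn >= obs_mean
        count_down += mn <= obs_mean
        count_msq += msq >= obs_msq

    p_up = (count_up + 1) / (B + 1)
    p_down = (count_down + 1) / (B + 1)
    p_mixed = (count_msq + 1) / (B + 1)
    if stat == "mean":
        if p_up <= p_down:
            direction, p_value, statistic = "up", p_up, obs_mean
        else:
            direction, p_value, statistic = "down", p_down, obs_mean
    elif stat == "msq":
        direction, p_value, statistic = "mixed", p_mixed, obs_msq
    else:
        raise ValueError(f"unknown statistic {stat!r}")
    return GeneSetResult(
        name=gene_set.name,
        n_genes_used=m,
        direction=direction,
        p_value=float(p_value),
        statistic=float(statistic),
        rotations_used=B,
        p_up=float(p_up),
        p_down=float(p_down),
    )


def competitive_set_test(
    t_stats,
    set_mask,
    residuals=None,
    weights=None,
    df_total=None,
    name: str = "set",
) -> GeneSetResult:
    """Competitive test with an inter-gene correlation correction.

    Gene-level moderated t-statistics are mapped to normal-equivalent
    z-scores, and the mean z of the set is compared with the mean z of all
    other genes by a two-sample z-test whose set variance is inflated by
    VIF = 1 + (m - 1) * rho_bar, rho_bar being the mean pairwise
    correlation of the set's (weighted) residuals.
    """
    t_stats = np.asarray(t_stats, dtype=float)
    mask = np.asarray(set_mask, dtype=bool)
    G = len(t_stats)
    m = int(mask.sum())
    if m == 0:
        raise ValueError("gene set matches no genes")
    if G - m < 2:
        raise ValueError("too few genes outside the set")

    if df_total is None:
        z = t_stats.copy()
    else:
        dft = np.broadcast_to(np.asarray(df_total, dtype=float), t_stats.shape)
        z = np.where(
            np.isfinite(dft),
            stats.norm.isf(np.clip(stats.t.sf(t_stats, dft), 1e-300, 1.0)),
            t_stats,
        )
        z = np.clip(z, -38.0, 38.0)

    if m == 1 or residuals is None:
        rho = 0.0
    else:
        res = np.asarray(residuals, dtype=float)[mask]
        if weights is not None:
            res = res * np.sqrt(np.asarray(weights, dtype=float)[mask])
        cc = np.corrcoef(res)
        iu = np.triu_indices(m, k=1)
        rho = float(np.nanmean(cc[iu]))
        rho = max(rho, -1.0 / (m - 1))  # keep VIF non-negative
    vif = 1.0 + (m - 1) * rho

    mean_set = z[mask].mean()
    mean_rest = z[~mask].mean()
    # pooled spread of the z-scores
    s2 = np.var(z, ddof=1)
    se = np.sqrt(s2 * (vif / m + 1.0 / (G - m)))
    zstat = (mean_set - mean_rest) / se
    p_two = 2.0 * stats.norm.sf(abs(zstat))
    direction = "up" if zstat >= 0 else "down"
    return GeneSetResult(
        name=name,
        n_genes_used=m,
        direction=direction,
        p_value=float(p_two),
        statistic=float(zstat),
        vif=float(vif),
        p_up=float(stats.norm.sf(zstat)),
        p_down=float(stats.norm.cdf(zstat)),
    )
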