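"""Count matrix container, I/O, filtering and scale normalization.

A bulk or single-cell RNA-seq experiment summarized at the gene level is a
G x n matrix of non-negative integer read counts, one row per gene and one
column per sequenced library.  The library size ``R_i`` (total mapped reads
of sample ``i``) is the primary scale factor; the trimmed mean of M-values
(TMM) method supplies an additional compositional normalization factor per
library, so that the *effective* library size is ``R_i * f_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.stats


class CountValidationError(ValueError):
    """Raised when a count matrix violates the integer/non-negative contract."""


@dataclass
class CountMatrix:
    """Genes x samples read counts with per-sample library sizes.

    Parameters
    ----------
    gene_ids : sequence of unique gene identifiers (length G).
    sample_ids : sequence of unique sample names (length n).
    counts : (G, n) array of non-negative integers.
    lib_sizes : optional (n,) positive array; defaults to column sums of
        ``counts``.  Library sizes are frozen when the object is built;
        gene filtering never recomputes them.
    norm_factors : optional (n,) positive array of compositional
        normalization factors (default all 1).
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    counts: np.ndarray
    lib_sizes: np.ndarray = None
    norm_factors: np.ndarray = None

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.counts = np.asarray(self.counts)
        G, n = self.counts.shape
        if len(self.gene_ids) != G or len(self.sample_ids) != n:
            raise CountValidationError(
                f"label lengths ({len(self.gene_ids)}, {len(self.sample_ids)}) "
                f"do not match counts shape {self.counts.shape}"
            )
        dup = pd.Index(self.gene_ids).duplicated()
        if dup.any():
            dups = sorted(set(self.gene_ids[dup]))
            raise CountValidationError(f"duplicate gene IDs: {dups}")
        if pd.Index(self.sample_ids).duplicated().any():
            raise CountValidationError("duplicate sample IDs")
        _validate_counts(self.counts, self.gene_ids, self.sample_ids)
        self.counts = self.counts.astype(np.int64)
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
            if self.lib_sizes.shape != (n,):
                raise CountValidationError("lib_sizes length mismatch")
        if np.any(self.lib_sizes <= 0):
            raise CountValidationError("library sizes must be positive")
        if self.norm_factors is None:
            self.norm_factors = np.ones(n)
        else:
            self.norm_factors = np.asarray(self.norm_factors, dtype=float)
            if self.norm_factors.shape != (n,) or np.any(self.norm_factors <= 0):
                raise CountValidationError("norm_factors must be n positive reals")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def effective_lib_sizes(self) -> np.ndarray:
        return self.lib_sizes * self.norm_factors

    def cpm(self, use_effective_sizes: bool = False) -> np.ndarray:
        """Counts per million from raw counts (no offset; used for filtering)."""
        R = self.effective_lib_sizes() if use_effective_sizes else self.lib_sizes
        return self.counts / R * 1e6

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        """Row subset; library sizes and factors are kept as-is."""
        return replace(
            self,
            gene_ids=self.gene_ids[mask],
            counts=self.counts[mask],
            lib_sizes=self.lib_sizes.copy(),
            norm_factors=self.norm_factors.copy(),
        )


def _validate_counts(counts, gene_ids, sample_ids):
    if counts.size == 0:
        raise CountValidationError("empty count matrix")
    arr = np.asarray(counts, dtype=float)
    bad = ~np.isfinite(arr) | (arr < 0) | (arr != np.floor(arr))
    if bad.any():
        g, i = np.argwhere(bad)[0]
        raise CountValidationError(
            f"count for gene {gene_ids[g]!r}, sample {sample_ids[i]!r} is "
            f"{arr[g, i]!r}: counts must be non-negative integers"
        )


def read_counts(path, format: str = "tsv") -> CountMatrix:
    """Read a count matrix from disk.

    ``tsv``: tab-delimited with a header row of sample names and gene IDs in
    the first column.  ``mtx``: MatrixMarket sparse matrix with sidecar label
    files ``<path>.rows`` (gene IDs) and ``<path>.cols`` (sample names), one
    label per line.
    """
    path = str(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except pd.errors.EmptyDataError:
            raise CountValidationError(f"{path}: empty file") from None
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise CountValidationError(f"{path}: no genes or no samples")
        return CountMatrix(
            gene_ids=df.index.to_numpy(dtype=object),
            sample_ids=df.columns.to_numpy(dtype=object),
            counts=df.to_numpy(),
        )
    if format == "mtx":
        mat = scipy.io.mmread(path).toarray()
        with open(path + ".rows") as fh:
            genes = [ln.strip() for ln in fh if ln.strip()]
        with open(path + ".cols") as fh:
            samples = [ln.strip() for ln in fh if ln.strip()]
        return CountMatrix(gene_ids=genes, sample_ids=samples, counts=mat)
    raise ValueError(f"unknown format {format!r}")


def write_counts(cm: CountMatrix, path) -> None:
    pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.sample_ids).to_csv(
        path, sep="\t"
    )


def filter_by_total(cm: CountMatrix, min_total: int) -> CountMatrix:
    """Keep genes with at least ``min_total`` reads summed across all samples.

    A threshold of 10 discards genes with fewer than ten reads total, the
    usual pre-filter before variance modeling.  Library sizes are unchanged.
    """
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    mask = cm.counts.sum(axis=1) >= min_total
    if not mask.any():
        raise ValueError(
            f"filter_by_total removed every gene; lower min_total (= {min_total})"
        )
    return cm.subset_genes(mask)


def filter_by_cpm(
    cm: CountMatrix, cpm_threshold: float, min_samples: int
) -> CountMatrix:
    """Keep genes with cpm >= ``cpm_threshold`` in at least ``min_samples`` samples.

    The cpm here is computed from raw counts with no offset; the 0.5 offset
    belongs to the log transform only.
    """
    if min_samples > cm.n_samples:
        raise ValueError("min_samples exceeds number of samples")
    mask = (cm.cpm() >= cpm_threshold).sum(axis=1) >= min_samples
    if not mask.any():
        raise ValueError("filter_by_cpm removed every gene; lower the threshold")
    return cm.subset_genes(mask)


def tmm_factors(cm: CountMatrix, ref_sample: int | None = None) -> np.ndarray:
    """Trimmed mean of M-values scale-normalization factors.

    For each library against a reference library, gene-wise log2 ratios of
    cpm (M-values) are trimmed by 30% at each tail, average log2 abundances
    (A-values) by 5% at each tail, and the surviving M-values averaged with
    inverse-asymptotic-variance weights.  Factors are re-centered to have
    geometric mean 1, so the product over samples is 1.
    """
    counts = cm.counts.astype(float)
    lib = cm.lib_sizes
    n = cm.n_samples
    if ref_sample is None:
        # reference: library whose upper-quartile cpm is closest to the mean
        q75 = np.array(
            [np.quantile(counts[:, i] / lib[i], 0.75) for i in range(n)]
        )
        ref_sample = int(np.argmin(np.abs(q75 - q75.mean())))
    f = np.ones(n)
    for i in range(n):
        if i == ref_sample:
            continue
        f[i] = _tmm_pair(counts[:, i], lib[i], counts[:, ref_sample], lib[ref_sample])
    # geometric-mean centering
    f = f / np.exp(np.mean(np.log(f)))
    return f


def _tmm_pair(
    obs, n_obs, ref, n_ref, logratio_trim=0.3, sum_trim=0.05, a_cutoff=-1e10
):
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValueError("sample shares no expressed genes with the reference")
    obs, ref = obs[pos], ref[pos]
    p_obs, p_ref = obs / n_obs, ref / n_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    keep = np.isfinite(M) & np.isfinite(A) & (A > a_cutoff)
    M, A = M[keep], A[keep]
    obs, ref = obs[keep], ref[keep]
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    # asymptotic (delta-method) variance of each M-value
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    nkeep = len(M)
    lo_l = np.floor(nkeep * logratio_trim) + 1
    hi_l = nkeep + 1 - lo_l
    lo_s = np.floor(nkeep * sum_trim) + 1
    hi_s = nkeep + 1 - lo_s
    rank_m = scipy.stats.rankdata(M)
    rank_a = scipy.stats.rankdata(A)
    kept = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not kept.any():
        return 1.0
    tmm = np.sum(M[kept] / v[kept]) / np.sum(1.0 / v[kept])
    return float(2.0 ** tmm)


def quantile_normalize(y: np.ndarray) -> np.ndarray:
    """Force every column of ``y`` to the mean empirical distribution.

    The target distribution is the mean of column-wise order statistics;
    tied values within a column receive the mean of the target values their
    ranks span.  Idempotent.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("quantile_normalize requires complete data")
    G, n = y.shape
    target = np.sort(y, axis=0).mean(axis=1)
    out = np.empty_like(y)
    grid = np.arange(1, G + 1, dtype=float)
    for j in range(n):
        ranks = scipy.stats.rankdata(y[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, target)
    return out
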