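"""Log counts-per-million and the delta-rule variance approximation.

The working expression scale throughout the package is

    y_gi = log2( (r_gi + 0.5) / (R_i + 1) * 1e6 )

The count offset of 0.5 keeps the log finite at zero counts and damps the
variability of low counts; the library-size offset of 1 guarantees
(r + 0.5)/(R + 1) lies strictly inside (0, 1).

For a count r with mean lambda and quadratic variance lambda + phi*lambda^2
(the negative-binomial form, phi = squared biological coefficient of
variation), a first-order Taylor expansion gives

    var(log y) ~ var(r)/lambda^2 = 1/lambda + phi

on the natural-log scale, i.e. the standard deviation of log-cpm is
approximately the coefficient of variation of the counts.  On the log2
scale the exact delta rule divides the sd by ln 2; both conventions are
exposed because the CV identity is often quoted without the factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .counts import CountMatrix

LN2 = np.log(2.0)


@dataclass
class LogCpmMatrix:
    """Log2 counts-per-million with the library sizes used to compute them."""

    y: np.ndarray                 # (G, n) log2-cpm
    lib_sizes_used: np.ndarray    # (n,) effective or raw library sizes
    gene_ids: np.ndarray = None
    sample_ids: np.ndarray = None
    offset_count: float = 0.5
    offset_lib: float = 1.0


def to_log_cpm(cm: CountMatrix, use_effective_sizes: bool = False) -> LogCpmMatrix:
    """Transform a count matrix to log2 counts per million.

    With ``use_effective_sizes`` the raw library sizes are multiplied by the
    compositional normalization factors first.
    """
    R = cm.effective_lib_sizes() if use_effective_sizes else cm.lib_sizes
    y = np.log2((cm.counts + 0.5) / (R + 1.0) * 1e6)
    return LogCpmMatrix(
        y=y,
        lib_sizes_used=np.asarray(R, dtype=float),
        gene_ids=cm.gene_ids,
        sample_ids=cm.sample_ids,
    )


def cv2_of_counts(lam, phi):
    """Squared coefficient of variation of a count: 1/lambda + phi.

    The 1/lambda term is the Poisson (technical) part and vanishes for large
    counts; phi is the biological part that the CV asymptotes to.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lambda must be positive")
    return 1.0 / lam + np.asarray(phi, dtype=float)


def approx_sd_log_cpm(lam, phi, log_base2: bool = False):
    """Delta-rule standard deviation of log-cpm: sqrt(1/lambda + phi).

    On the natural-log scale this equals the count CV; set ``log_base2`` to
    get the sd of log2-cpm (divides by ln 2).
    """
    sd = np.sqrt(cv2_of_counts(lam, phi))
    return sd / LN2 if log_base2 else sd


def subtract_log2_length(y: np.ndarray, length_kb) -> np.ndarray:
    """Convert log2-cpm to log2-rpkm by subtracting log2 gene length in kb.

    Precision weights are identical on either scale, so downstream inference
    is unchanged; this helper only shifts gene-wise intercepts.
    """
    length_kb = np.asarray(length_kb, dtype=float)
    if np.any(length_kb <= 0):
        raise ValueError("gene lengths must be positive")
    return y - np.log2(length_kb)[:, None]
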