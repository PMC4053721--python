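"""Negative-binomial RNA-seq count simulator with truth labels.

The generator emulates a two-group comparison with realistic bulk RNA-seq
characteristics:

* baseline expression proportions p_g (relative share of sequenced reads
  per gene) with a heavy right tail spanning several orders of magnitude;
* expected counts lambda_gi = p_g * foldchange_gi * R_i for library sizes
  R_i, with two canonical depth scenarios -- six libraries of 11 million
  reads, or alternating 20 million / 2 million (same total, unevenly
  distributed);
* a dispersion trend falling with expected count,
  sqrt(psi_gi) = 0.2 + lambda_gi^(-1/2), asymptoting to a biological CV of
  0.2 for large counts, intermediate between laboratory-mouse and
  unrelated-human variability;
* gene-wise scatter around the trend, delta_g with 40/delta_g ~ chi2(40)
  (or a matched log-normal), giving observation dispersions
  phi_gi = psi_gi * delta_g;
* NB sampling realized as a gamma-Poisson mixture, which honors the
  mean/variance contract lambda + phi*lambda^2 for any positive phi.

In the power scenario 100 randomly chosen genes are twofold upregulated in
each group (200 truly DE genes among 10,000).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .counts import CountMatrix

EQUAL_LIB_SIZES = tuple([11e6] * 6)
UNEQUAL_LIB_SIZES = (20e6, 2e6, 20e6, 2e6, 20e6, 2e6)


@dataclass
class NBSimConfig:
    """Configuration of one simulated two-group dataset.

    Defaults reproduce the canonical benchmark: 10,000 genes, two groups of
    three libraries, equal depths of 11 million reads, 100 + 100 twofold-DE
    genes, dispersion trend asymptote sqrt(psi) -> 0.2, inverse chi-square
    gene scatter with 40 df.  Set ``n_de_per_group=0`` for the null
    scenario.
    """

    n_genes: int = 10_000
    group_sizes: tuple = (3, 3)
    lib_sizes: tuple = EQUAL_LIB_SIZES
    n_de_per_group: int = 100
    fold_change: float = 2.0
    disp_asymptote_sqrt: float = 0.2
    disp_df: float = 40.0
    disp_family: str = "inv_chisq"   # or "lognormal"
    disp_lognormal_sd: float = 0.25
    baseline_log_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if len(self.lib_sizes) != sum(self.group_sizes):
            raise ValueError("lib_sizes length must equal total sample count")
        if any(s <= 0 for s in self.lib_sizes):
            raise ValueError("library sizes must be positive")
        if 2 * self.n_de_per_group > self.n_genes:
            raise ValueError("more DE genes requested than genes simulated")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")


@dataclass
class TruthLabels:
    """Per-gene DE status: 0 = null, 1 = up in group 1, 2 = up in group 2."""

    status: np.ndarray
    true_log2fc: np.ndarray

    @property
    def is_de(self) -> np.ndarray:
        return self.status != 0

    def subset(self, mask) -> "TruthLabels":
        return TruthLabels(self.status[mask], self.true_log2fc[mask])


def baseline_proportions(n_genes: int, seed=None, log_sd: float = 2.0) -> np.ndarray:
    """Heavy-tailed relative expression proportions, summing to 1.

    Normalized log-normal draws with log-scale sd 2.0 (base e) give roughly
    five orders of magnitude between the most and least expressed genes,
    matching the dynamic range of typical bulk libraries.  Pass an explicit
    array to ``simulate`` via ``proportions=`` to use empirical values.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=log_sd, size=n_genes)
    return raw / raw.sum()


def dispersion_trend(lam, asymptote_sqrt: float = 0.2):
    """Trend dispersion psi = (0.2 + lambda^(-1/2))^2 at expected count lambda."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("expected counts must be positive")
    return (asymptote_sqrt + lam ** -0.5) ** 2


def gene_dispersion_scatter(
    n_genes: int,
    family: str = "inv_chisq",
    seed=None,
    df: float = 40.0,
    lognormal_sd: float = 0.25,
) -> np.ndarray:
    """Gene-wise multiplicative scatter delta_g around the dispersion trend.

    ``inv_chisq``: df/delta ~ chi2(df), mean df/(df-2).  ``lognormal``:
    exp(N(0, sd)) with median exactly 1; sd 0.25 matches the log-scale
    spread of the 40-df inverse chi-square.
    """
    rng = np.random.default_rng(seed)
    if family == "inv_chisq":
        return df / rng.chisquare(df, size=n_genes)
    if family == "lognormal":
        return np.exp(rng.normal(0.0, lognormal_sd, size=n_genes))
    raise ValueError(f"unknown dispersion family {family!r}")


def simulate(cfg: NBSimConfig, proportions=None, dispersion=None):
    """Draw one dataset; returns (CountMatrix, TruthLabels).

    Bit-reproducible for a fixed config (all randomness flows from
    ``cfg.seed``).  Fold changes multiply expected counts without
    renormalizing the baseline proportions, and the dispersion trend is
    evaluated at the realized expected count (fold change included).
    ``dispersion`` overrides the trend-plus-scatter dispersions with a
    fixed phi (scalar or (G, n) array); zero gives pure Poisson counts.
    """
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    n1, n2 = cfg.group_sizes
    n = n1 + n2
    R = np.asarray(cfg.lib_sizes, dtype=float)

    if proportions is None:
        p = baseline_proportions(G, seed=rng, log_sd=cfg.baseline_log_sd)
    else:
        p = np.asarray(proportions, dtype=float)
        p = p / p.sum()

    status = np.zeros(G, dtype=int)
    if cfg.n_de_per_group > 0:
        de = rng.choice(G, size=2 * cfg.n_de_per_group, replace=False)
        status[de[: cfg.n_de_per_group]] = 1
        status[de[cfg.n_de_per_group:]] = 2
    lfc = np.log2(cfg.fold_change)
    true_log2fc = np.where(status == 0, 0.0, lfc)

    fc = np.ones((G, n))
    fc[status == 1, :n1] = cfg.fold_change
    fc[status == 2, n1:] = cfg.fold_change

    lam = p[:, None] * fc * R[None, :]
    lam = np.maximum(lam, 1e-12)
    if dispersion is None:
        psi = dispersion_trend(lam, cfg.disp_asymptote_sqrt)
        delta = gene_dispersion_scatter(
            G, cfg.disp_family, seed=rng, df=cfg.disp_df,
            lognormal_sd=cfg.disp_lognormal_sd,
        )
        phi = psi * delta[:, None]
    else:
        phi = np.broadcast_to(np.asarray(dispersion, dtype=float), lam.shape)

    # gamma-Poisson: shape 1/phi, scale lam*phi => mean lam, var lam + phi lam^2
    pos = phi > 0
    lam_mixed = lam.copy()
    if pos.any():
        lam_mixed[pos] = rng.gamma(1.0 / phi[pos], (lam * phi)[pos])
    counts = rng.poisson(lam_mixed)

    cm = CountMatrix(
        gene_ids=np.array([f"gene{g+1}" for g in range(G)], dtype=object),
        sample_ids=np.array(
            [f"grp1_{i+1}" for i in range(n1)] + [f"grp2_{i+1}" for i in range(n2)],
            dtype=object,
        ),
        counts=counts,
    )
    return cm, TruthLabels(status=status, true_log2fc=true_log2fc)


@dataclass
class SpikeinTruth:
    transcript_ids: np.ndarray
    is_de: np.ndarray
    fold_change_mix1_vs_mix2: np.ndarray


def make_spikein_benchmark(
    n_transcripts: int = 92,
    n_nonde: int = 23,
    replicate_factor: int = 3,
) -> SpikeinTruth:
    """Truth table for the replicated spike-in FDR benchmark.

    92 control transcripts, of which 23 are non-DE and the remaining 69
    split evenly three ways: fourfold up in Mix 1, 1.5-fold up in Mix 2,
    twofold up in Mix 2.  Each non-DE transcript is replicated
    ``replicate_factor`` times so that with the default factor of 3 the
    benchmark has (92 - 23) + 23*3 = 138 entries, exactly half DE.
    """
    n_de = n_transcripts - n_nonde
    if n_de % 3 != 0:
        raise ValueError("DE transcripts must split into three equal fold-change groups")
    k = n_de // 3
    ids, de, fc = [], [], []
    for j in range(k):
        ids.append(f"up4_mix1_{j+1}"); de.append(True); fc.append(4.0)
    for j in range(k):
        ids.append(f"up1.5_mix2_{j+1}"); de.append(True); fc.append(1 / 1.5)
    for j in range(k):
        ids.append(f"up2_mix2_{j+1}"); de.append(True); fc.append(0.5)
    for j in range(n_nonde):
        for r in range(replicate_factor):
            ids.append(f"nonde_{j+1}_rep{r+1}"); de.append(False); fc.append(1.0)
    return SpikeinTruth(
        transcript_ids=np.array(ids, dtype=object),
        is_de=np.array(de),
        fold_change_mix1_vs_mix2=np.array(fc),
    )


def null_config(lib_sizes=EQUAL_LIB_SIZES, seed: int = 0, **kw) -> NBSimConfig:
    return NBSimConfig(n_de_per_group=0, lib_sizes=tuple(lib_sizes), seed=seed, **kw)


def power_config(lib_sizes=EQUAL_LIB_SIZES, seed: int = 0, **kw) -> NBSimConfig:
    return NBSimConfig(n_de_per_group=100, lib_sizes=tuple(lib_sizes), seed=seed, **kw)
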