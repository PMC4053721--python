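"""Benchmark protocols: type I error, power/FDR and false-discovery curves.

The harness runs the four internal pipelines -- observation-weighted
(voom), gene-level trended prior (limma-trend), constant prior
(limma-notrend) and the unmoderated ordinary t-test -- on replicate
simulated datasets and summarizes error control and ranking quality.
The ordinary t-test is literally the same engine with prior df forced to
zero and unit weights, so differences between methods are attributable to
the variance modeling alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .counts import CountMatrix, filter_by_total
from .ebayes import bh_fdr, ebayes
from .linmod import DesignMatrix, fit_genewise
from .logcpm import to_log_cpm
from .simulate import NBSimConfig, TruthLabels, simulate
from .voom import voom

METHODS = ("voom", "limma_trend", "limma_notrend", "ordinary_t")


def two_group_design(n1: int, n2: int) -> DesignMatrix:
    X = np.ones((n1 + n2, 2))
    X[:, 1] = [0.0] * n1 + [1.0] * n2
    return DesignMatrix(X, ["(Intercept)", "group2"])


def run_pipeline(cm: CountMatrix, design: DesignMatrix, method: str, coef: int = 1):
    """Run one differential expression pipeline; returns (p, t) per gene."""
    if method == "voom":
        vr = voom(cm, design)
        fit = fit_genewise(vr.y, design, weights=vr.weights)
        eb = ebayes(fit, trend=False)
    elif method == "limma_trend":
        y = to_log_cpm(cm)
        fit = fit_genewise(y, design)
        eb = ebayes(fit, trend=True)
    elif method == "limma_notrend":
        y = to_log_cpm(cm)
        fit = fit_genewise(y, design)
        eb = ebayes(fit, trend=False)
    elif method == "ordinary_t":
        y = to_log_cpm(cm)
        fit = fit_genewise(y, design)
        eb = ebayes(fit, d0_override=0.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return eb.p[:, coef], eb.t[:, coef]


def type1_error(p, cutoff: float) -> float:
    """Proportion of p-values strictly below the cutoff."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    return float(np.mean(p < cutoff))


def power_fdr(p, truth: TruthLabels, fdr_cutoff: float = 0.1):
    """BH calls at q < cutoff, split into true/false positives.

    Returns (TP, FP, empirical_fdr) with the empirical FDR defined as 0
    when nothing is called.
    """
    p = np.asarray(p, dtype=float)
    if len(p) != len(truth.status):
        raise ValueError("p-values and truth labels have different lengths")
    q = bh_fdr(p)
    called = q < fdr_cutoff
    tp = int(np.sum(called & truth.is_de))
    fp = int(np.sum(called & ~truth.is_de))
    efdr = fp / max(1, tp + fp)
    return tp, fp, efdr


def fd_curve(rank_stat, truth: TruthLabels, max_selected: int = None) -> np.ndarray:
    """Cumulative false discoveries among the top-k genes, k = 1..max_selected.

    Genes are ranked by ``rank_stat`` ascending (p-values); ties broken by
    gene index (stable sort).
    """
    rank_stat = np.asarray(rank_stat, dtype=float)
    order = np.argsort(rank_stat, kind="mergesort")
    is_false = ~truth.is_de[order]
    curve = np.cumsum(is_false)
    if max_selected is not None:
        curve = curve[:max_selected]
    return curve


@dataclass
class EvalResult:
    method: str
    scenario: str
    n_sims: int
    typeI_at_cutoffs: dict = field(default_factory=dict)      # cutoff -> mean prop
    typeI_se: dict = field(default_factory=dict)              # cutoff -> MC se of mean
    power: float = None               # mean TP at the FDR threshold
    empirical_fdr: float = None       # mean FP/(TP+FP)
    empirical_fdr_se: float = None
    fd_curve: np.ndarray = None       # mean false discoveries vs k
    per_sim: dict = field(default_factory=dict)


def run_benchmark(
    cfg: NBSimConfig,
    methods=METHODS,
    n_sims: int = 25,
    seed: int = 0,
    cutoffs=(0.01, 0.05),
    fdr_cutoff: float = 0.1,
    min_total: int = 10,
    fd_curve_k: int = 400,
) -> dict[str, EvalResult]:
    """Replicate the simulation protocol over ``n_sims`` datasets.

    Each replicate draws a fresh dataset from a seed derived
    deterministically from the master seed, filters genes with fewer than
    ``min_total`` reads total, runs every requested pipeline and scores it
    against the truth labels of the retained genes.  Per-simulation values
    are kept so Monte-Carlo standard errors of all summaries are available.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    n1, n2 = cfg.group_sizes
    design = two_group_design(n1, n2)
    ss = np.random.SeedSequence(seed)
    sim_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_sims)]

    acc = {
        m: {"typeI": {c: [] for c in cutoffs}, "tp": [], "fp": [], "efdr": [], "fd": []}
        for m in methods
    }
    for s in range(n_sims):
        cfg_s = NBSimConfig(**{**cfg.__dict__, "seed": sim_seeds[s]})
        cm, truth = simulate(cfg_s)
        keep = cm.counts.sum(axis=1) >= min_total
        cm_f = filter_by_total(cm, min_total)
        truth_f = truth.subset(keep)
        for m in methods:
            p, _ = run_pipeline(cm_f, design, m)
            for c in cutoffs:
                acc[m]["typeI"][c].append(type1_error(p, c))
            tp, fp, efdr = power_fdr(p, truth_f, fdr_cutoff)
            acc[m]["tp"].append(tp)
            acc[m]["fp"].append(fp)
            acc[m]["efdr"].append(efdr)
            acc[m]["fd"].append(fd_curve(p, truth_f, fd_curve_k))

    scen = f"{'unequal' if len(set(cfg.lib_sizes)) > 1 else 'equal'}-" + (
        "null" if cfg.n_de_per_group == 0 else "power"
    )
    out = {}
    for m in methods:
        a = acc[m]
        def mc_se(v):
            v = np.asarray(v, dtype=float)
            return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        fd = np.vstack([c[: min(map(len, a["fd"]))] for c in a["fd"]]).mean(axis=0)
        out[m] = EvalResult(
            method=m,
            scenario=scen,
            n_sims=n_sims,
            typeI_at_cutoffs={c: float(np.mean(a["typeI"][c])) for c in cutoffs},
            typeI_se={c: mc_se(a["typeI"][c]) for c in cutoffs},
            power=float(np.mean(a["tp"])),
            empirical_fdr=float(np.mean(a["efdr"])),
            empirical_fdr_se=mc_se(a["efdr"]),
            fd_curve=fd,
            per_sim={
                "typeI": {c: np.array(a["typeI"][c]) for c in cutoffs},
                "tp": np.array(a["tp"]),
                "fp": np.array(a["fp"]),
                "efdr": np.array(a["efdr"]),
            },
        )
    return out
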