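import numpy as np
import pytest

import voomlite as vl


@pytest.fixture
def tiny_counts():
    """2x2 toy matrix with known column sums (4, 6)."""
    return vl.CountMatrix(
        gene_ids=["g1", "g2"],
        sample_ids=["s1", "s2"],
        counts=np.array([[1, 2], [3, 4]]),
    )


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated dataset shared by read-only tests."""
    cfg = vl.NBSimConfig(n_genes=1200, n_de_per_group=30, seed=314)
    cm, truth = vl.simulate(cfg)
    keep = cm.counts.sum(axis=1) >= 10
    return vl.filter_by_total(cm, 10), truth.subset(keep)


@pytest.fixture(scope="session")
def design33():
    return vl.two_group_design(3, 3)


@pytest.fixture(scope="session")
def small_voom(small_sim, design33):
    cm, _ = small_sim
    vr = vl.voom(cm, design33)
    fit = vl.fit_genewise(vr.y, design33, weights=vr.weights)
    eb = vl.ebayes(fit)
    return vr, fit, eb
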