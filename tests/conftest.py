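import numpy as np
import pandas as pd
import pytest

from allelix.classify import SampleDesign
from allelix.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study design (4 WT + 3 KO, ~340 genes), seed 1."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_design(default_dataset):
    return SampleDesign(default_dataset.design_groups())


@pytest.fixture()
def small_allelic_counts():
    """Two genes x two samples with a mix of deep and shallow SNPs."""
    rows = [
        # sample, snp, maternal, paternal
        ("s1", "gA_1", 5, 5),     # 50%
        ("s1", "gA_2", 7, 3),     # 30%
        ("s1", "gB_1", 9, 1),     # 10% but coverage 10
        ("s1", "gB_2", 5, 0),     # below 10X
        ("s2", "gA_1", 90, 10),   # 10%
        ("s2", "gA_2", 0, 0),     # zero coverage
        ("s2", "gB_1", 3, 1),     # below 10X
        ("s2", "gB_2", 2, 2),     # below 10X
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "snp_id", "maternal_count", "paternal_count"]
    )


@pytest.fixture()
def small_snp_map():
    return pd.DataFrame(
        {
            "snp_id": ["gA_1", "gA_2", "gB_1", "gB_2"],
            "gene_id": ["geneA", "geneA", "geneB", "geneB"],
        }
    )


def welch_p_oracle(a, b):
    """Textbook Welch t-test: statistic, Welch-Satterthwaite df, two-sided p."""
    from scipy import stats

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (b.mean() - a.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2 * stats.t.sf(abs(t), df)


def bh_oracle(pvals):
    """Brute-force step-up: q_(i) = min_{j >= i} p_(j) * m / j."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q
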