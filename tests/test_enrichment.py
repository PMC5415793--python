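import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from allelix import enrichment as en
from allelix.types import GeneModel


class TestQuintilePartition:
    def test_even_split(self):
        pct = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        out = en.quintile_partition(pct, k=5)
        assert out.groupby("quintile").size().tolist() == [2, 2, 2, 2, 2]

    def test_338_genes_split_68_68_68_67_67(self):
        rng = np.random.default_rng(0)
        pct = pd.Series(rng.uniform(0, 30, 338),
                        index=[f"g{i:03d}" for i in range(338)])
        out = en.quintile_partition(pct, k=5)
        assert out.groupby("quintile").size().tolist() == [68, 68, 68, 67, 67]

    def test_lowest_percents_in_quintile_one(self):
        pct = pd.Series([5.0, 1.0, 9.0, 3.0, 7.0],
                        index=list("abcde"))
        out = en.quintile_partition(pct, k=5).set_index("gene_id")
        assert out.loc["b", "quintile"] == 1
        assert out.loc["c", "quintile"] == 5

    def test_permutation_invariance_and_tie_break(self):
        pct = pd.Series([2.0, 2.0, 1.0, 3.0, 4.0, 5.0],
                        index=["z", "a", "m", "q", "r", "s"])
        out1 = en.quintile_partition(pct, k=3)
        out2 = en.quintile_partition(pct.sample(frac=1, random_state=1), k=3)
        pd.testing.assert_frame_equal(out1, out2)
        # tie at 2.0 broken lexicographically: "a" ranks before "z"
        ranked = out1.set_index("gene_id")["rank"]
        assert ranked["a"] < ranked["z"]

    def test_too_few_genes_errors(self):
        with pytest.raises(ValueError):
            en.quintile_partition(pd.Series([1.0, 2.0], index=["a", "b"]), k=5)

    @settings(derandomize=True, max_examples=50)
    @given(n=st.integers(5, 400), k=st.integers(2, 8))
    def test_sizes_sum_to_n_and_differ_by_at_most_one(self, n, k):
        if n < k:
            return
        pct = pd.Series(np.linspace(0, 50, n), index=[f"g{i:04d}" for i in range(n)])
        out = en.quintile_partition(pct, k=k)
        sizes = out.groupby("quintile").size()
        assert sizes.sum() == n
        assert sizes.max() - sizes.min() <= 1
        assert out["gene_id"].is_unique


class TestFisher:
    def _balanced_table(self):
        # 5 quintiles of 10 genes; all 10 derepressed genes in quintile 4
        return np.array([[0, 0, 0, 10, 0], [10, 10, 10, 0, 10]])

    def test_concentrated_table_is_significant(self):
        p = en.fisher_exact_2xk(self._balanced_table(), method="exact")
        assert p < 0.01

    def test_exact_enumeration_matches_mc_within_error(self):
        tables = [
            self._balanced_table(),
            np.array([[1, 2, 0, 3, 1], [5, 4, 6, 3, 5]]),
            np.array([[2, 2, 2], [8, 8, 8]]),
        ]
        for t in tables:
            p_exact = en.fisher_exact_2xk(t, method="exact")
            p_mc = en.fisher_exact_2xk(t, method="mc", n_draws=100_000, seed=0)
            se = math.sqrt(p_exact * (1 - p_exact) / 100_000)
            assert abs(p_mc - p_exact) <= 3 * se + 2e-5

    def test_proportional_spread_gives_p_one(self):
        t = np.array([[2, 2, 2, 2, 2], [8, 8, 8, 8, 8]])
        assert en.fisher_exact_2xk(t, method="exact") == pytest.approx(1.0)
        assert en.fisher_exact_2xk(t, method="mc", seed=0) > 0.99

    def test_2x2_matches_scipy(self):
        t = np.array([[8, 2], [1, 5]])
        assert en.fisher_exact_2xk(t) == pytest.approx(stats.fisher_exact(t)[1])

    def test_exact_probabilities_sum_to_one_over_network(self):
        # enumeration visits every table with the observed margins exactly once
        t = np.array([[1, 2, 1], [3, 2, 3]])
        row = t.sum(axis=1)
        col = t.sum(axis=0)
        total = 0.0
        for a in itertools.product(*(range(c + 1) for c in col)):
            if sum(a) != row[0]:
                continue
            cand = np.array([a, col - np.array(a)])
            total += math.exp(en._log_table_prob(cand))
        assert total == pytest.approx(1.0, rel=1e-9)

    def test_zero_gene_quintile_rejected(self):
        with pytest.raises(ValueError):
            en.fisher_exact_2xk(np.array([[1, 2, 0], [3, 4, 0]]))


class TestQuintileEnrichment:
    def test_counts_and_2x2_collapse(self):
        pct = pd.Series(np.arange(20.0), index=[f"g{i:02d}" for i in range(20)])
        quint = en.quintile_partition(pct, k=5)
        flags = pd.Series(False, index=pct.index)
        flags.loc[["g12", "g13", "g14", "g15"]] = True  # quintiles 4-ish
        counts, p_full = en.quintile_enrichment(quint, flags, method="exact")
        assert counts["n_genes"].tolist() == [4, 4, 4, 4, 4]
        assert counts["n_derepressed"].sum() == 4
        _, p_22 = en.quintile_enrichment(
            quint, flags, method="exact", quintile_vs_rest=4
        )
        assert 0 <= p_22 <= 1

    def test_missing_flag_errors(self):
        pct = pd.Series(np.arange(5.0), index=list("abcde"))
        quint = en.quintile_partition(pct, k=5)
        with pytest.raises(ValueError, match="missing"):
            en.quintile_enrichment(quint, pd.Series({"a": True}))


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        # fully separated 3 vs 3: the most extreme of C(6,3)=20 orderings in
        # either direction -> two-sided p = 2/20
        u, p = en.mann_whitney([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)

    def test_exact_matches_rank_permutation_oracle(self):
        a = [3.1, 9.2, 1.4]
        b = [2.0, 7.7, 5.5, 8.1]
        u_obs, p = en.mann_whitney(a, b)
        # oracle: enumerate every assignment of pooled ranks to group a
        pooled = np.array(a + b)
        ranks = stats.rankdata(pooled)
        na = len(a)
        center = na * len(b) / 2
        u_all = []
        for combo in itertools.combinations(range(len(pooled)), na):
            r = ranks[list(combo)].sum()
            u_all.append(r - na * (na + 1) / 2)
        u_all = np.array(u_all)
        p_oracle = np.mean(np.abs(u_all - center) >= abs(u_obs - center) - 1e-12)
        assert p == pytest.approx(p_oracle)

    def test_identical_groups_give_p_one(self):
        _, p = en.mann_whitney([4.0, 4.0, 4.0], [4.0, 4.0])
        assert p == 1.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.8, 1, 12)
        _, p1 = en.mann_whitney(a, b)
        _, p2 = en.mann_whitney(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2)

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.lists(st.integers(0, 30), min_size=1, max_size=8),
        b=st.lists(st.integers(0, 30), min_size=1, max_size=8),
    )
    def test_u_statistics_sum_to_product(self, a, b):
        ua, _ = en.mann_whitney(a, b)
        ub, _ = en.mann_whitney(b, a)
        assert ua + ub == pytest.approx(len(a) * len(b))


class TestCorrelation:
    def test_identical_vectors(self):
        v = pd.Series([1.0, 5.0, 3.0], index=list("abc"))
        r, n = en.wt_ko_correlation(v, v)
        assert r == pytest.approx(1.0)
        assert n == 3

    def test_negative_affine(self):
        v = pd.Series([1.0, 5.0, 3.0], index=list("abc"))
        r, _ = en.wt_ko_correlation(v, -2 * v + 7)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_flagged_undefined(self):
        a = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        b = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        r, n = en.wt_ko_correlation(a, b)
        assert math.isnan(r) and n == 3

    def test_pairs_on_common_genes_only(self):
        a = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        b = pd.Series([1.0, 2.0, 9.0], index=list("abd"))
        _, n = en.wt_ko_correlation(a, b)
        assert n == 2


class TestStrata:
    def _boundaries(self):
        return en.StratumBoundaries(
            [("S1", 0, 1000), ("S3", 2000, 3000), ("S5", 3000, 4000)]
        )

    def test_assignment_by_human_start(self):
        b = self._boundaries()
        g = GeneModel("g", "chrX", "+", 0, 100, human_start=2500)
        assert en.assign_strata([g], b)["g"] == "S3"

    def test_half_open_boundary(self):
        b = self._boundaries()
        assert b.assign(3000) == "S5"   # start inclusive
        assert b.assign(1999) is None   # gap
        assert b.assign(1000) is None   # end exclusive

    def test_unmapped_gene_gets_none(self):
        g = GeneModel("g", "chrX", "+", 0, 100, human_start=None)
        assert en.assign_strata([g], self._boundaries())["g"] is None

    def test_overlapping_boundaries_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            en.StratumBoundaries([("A", 0, 100), ("B", 50, 200)])
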