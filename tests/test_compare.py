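from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ighrep.compare import (
    bh_adjust,
    compare_group_summaries,
    differential_usage,
    pca_usage,
    pearson_pairwise_complete,
    wilcoxon_rank_sum,
)


def enumerate_ranksum_p(x, y):
    """Exact two-sided rank-sum p by full enumeration of rank assignments."""
    ranks = sps.rankdata(np.concatenate([x, y]))
    n1, n = len(x), len(x) + len(y)
    mu = n1 * (n + 1) / 2
    obs = abs(ranks[:n1].sum() - mu)
    hits = total = 0
    for comb in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(comb)].sum() - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


def bh_step_up_brute(p):
    """Literal step-up definition: adj_(i) = min_{j >= i} m p_(j) / rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    best = np.inf
    for i in range(m - 1, -1, -1):
        best = min(best, m * p[order[i]] / (i + 1))
        adj[order[i]] = min(best, 1.0)
    return adj


class TestWilcoxon:
    def test_fully_separated_triples(self):
        stat, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=6), rng.normal(size=5)
        s1 = wilcoxon_rank_sum(x, y)
        s2 = wilcoxon_rank_sum(rng.permutation(x), rng.permutation(y))
        assert s1 == s2

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n1, n2 = rng.integers(2, 7, 2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            _, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(enumerate_ranksum_p(x, y))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_evenly_spaced_collapse(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            assert bh_adjust(p) == pytest.approx(bh_step_up_brute(p))

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(3)
        p = rng.random(25)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDifferentialUsage:
    def _usage(self, rng, n_a, n_b, shift=0.0):
        genes = [f"G{i}" for i in range(6)]
        rows = {}
        for i in range(n_a + n_b):
            u = rng.dirichlet(np.ones(6)) * 100
            if shift and i < n_a:
                u[0] += shift
            rows[f"s{i}"] = u / u.sum() * 100
        usage = pd.DataFrame(rows, index=genes).T
        labels = pd.Series(["A"] * n_a + ["B"] * n_b, index=usage.index)
        return usage, labels

    def test_single_cohort_rejected(self):
        usage, labels = self._usage(np.random.default_rng(4), 4, 0)
        with pytest.raises(ValueError):
            differential_usage(usage, pd.Series("A", index=usage.index))

    def test_one_sample_cohort_rejected(self):
        usage, labels = self._usage(np.random.default_rng(5), 1, 4)
        with pytest.raises(ValueError):
            differential_usage(usage, labels)

    def test_zero_usage_genes_excluded_from_family(self):
        usage, labels = self._usage(np.random.default_rng(6), 4, 4)
        usage["dead_gene"] = 0.0
        res = differential_usage(usage, labels)
        assert "dead_gene" not in set(res.table["gene"])
        assert len(res.table) == 6

    def test_strong_planted_shift_detected(self):
        usage, labels = self._usage(np.random.default_rng(7), 8, 8, shift=150.0)
        res = differential_usage(usage, labels)
        row = res.table.set_index("gene").loc["G0"]
        assert row["p_adj"] <= 0.05

    def test_null_type_one_error_calibrated(self):
        # raw significance rate over many identical-distribution cohorts
        rng = np.random.default_rng(8)
        hits = total = 0
        for _ in range(100):
            usage, labels = self._usage(rng, 6, 6)
            res = differential_usage(usage, labels)
            hits += int((res.table["p"] <= 0.05).sum())
            total += len(res.table)
        assert 0.01 <= hits / total <= 0.08


class TestPcaUsage:
    def _usage(self, rng, n=10, k=6):
        return pd.DataFrame(
            rng.dirichlet(np.ones(k), size=n) * 100,
            index=[f"s{i}" for i in range(n)],
            columns=[f"G{i}" for i in range(k)],
        )

    def test_variance_percentages_sum_to_hundred(self):
        res = pca_usage(self._usage(np.random.default_rng(9)))
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-6)

    def test_rank_one_data_loads_on_pc1(self):
        base = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        x = pd.DataFrame(
            [2**(c * base) - 1 for c in (1.0, 1.5, 2.0, 2.5)],
            index=list("abcd"), columns=[f"G{i}" for i in range(6)],
        )
        res = pca_usage(x)
        assert res.percent_variance[0] == pytest.approx(100.0, abs=1e-8)

    def test_reconstruction(self):
        usage = self._usage(np.random.default_rng(10))
        res = pca_usage(usage)
        x = np.log2(usage.to_numpy() + 1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T + x.mean(0)
        assert np.allclose(recon, x, atol=1e-8)

    def test_sign_convention_deterministic(self):
        usage = self._usage(np.random.default_rng(11))
        res = pca_usage(usage)
        for comp in res.loadings.columns:
            col = res.loadings[comp]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] >= 0

    def test_constant_matrix_gives_zero_variance(self):
        x = pd.DataFrame(np.full((4, 5), 7.0), columns=[f"G{i}" for i in range(5)])
        res = pca_usage(x)
        assert res.percent_variance.sum() == 0.0
        assert np.allclose(res.scores.to_numpy(), 0.0)


class TestPearsonPairwiseComplete:
    def test_self_correlation_is_one(self):
        t = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 1, 4, 3]})
        res = pearson_pairwise_complete(t)
        assert res.r.loc["a", "a"] == 1.0

    def test_perfect_anticorrelation_significant(self):
        x = np.arange(5.0)
        t = pd.DataFrame({"x": x, "y": -x})
        res = pearson_pairwise_complete(t)
        assert res.r.loc["x", "y"] == pytest.approx(-1.0)
        assert res.p.loc["x", "y"] < 0.05
        assert res.masked_r.loc["x", "y"] == pytest.approx(-1.0)

    def test_hand_computed_three_complete_pairs(self):
        t = pd.DataFrame(
            {"x": [1, 2, 3, 4, np.nan], "y": [np.nan, 2, 4, 6, 8]}, dtype=float
        )
        res = pearson_pairwise_complete(t)
        assert res.n.loc["x", "y"] == 3
        assert res.r.loc["x", "y"] == pytest.approx(1.0)

    def test_matches_naive_recomputation_with_missingness(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(20, 5))
        x[rng.random(x.shape) < 0.25] = np.nan
        t = pd.DataFrame(x, columns=list("abcde"))
        res = pearson_pairwise_complete(t)
        for i, ci in enumerate(t.columns):
            for j, cj in enumerate(t.columns):
                if i >= j:
                    continue
                both = t[ci].notna() & t[cj].notna()
                m = int(both.sum())
                if m < 3:
                    assert np.isnan(res.r.loc[ci, cj])
                    continue
                xi, xj = t.loc[both, ci], t.loc[both, cj]
                r = np.corrcoef(xi, xj)[0, 1]
                tt = r * np.sqrt((m - 2) / (1 - r**2))
                p = 2 * sps.t.sf(abs(tt), m - 2)
                assert res.r.loc[ci, cj] == pytest.approx(r)
                assert res.p.loc[ci, cj] == pytest.approx(p)

    def test_zero_variance_is_undefined_not_an_error(self):
        t = pd.DataFrame({"a": [1.0, 1, 1, 1], "b": [1.0, 2, 3, 4]})
        res = pearson_pairwise_complete(t)
        assert np.isnan(res.r.loc["a", "b"])


class TestGroupSummaries:
    def test_identical_cohorts_not_significant(self):
        m = pd.DataFrame({"n_clones": [10.0, 20, 30, 10, 20, 30]},
                         index=[f"s{i}" for i in range(6)])
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=m.index)
        res = compare_group_summaries(m, labels)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_missing_metric_excludes_sample(self):
        m = pd.DataFrame(
            {"d": [1.0, 2, np.nan, 5, 6, 7]}, index=[f"s{i}" for i in range(6)]
        )
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=m.index)
        res = compare_group_summaries(m, labels)
        assert res.loc[0, "mean_A"] == pytest.approx(1.5)

    def test_metric_absent_for_a_cohort_rejected(self):
        m = pd.DataFrame(
            {"d": [np.nan, np.nan, 1.0, 2.0]}, index=[f"s{i}" for i in range(4)]
        )
        labels = pd.Series(["A", "A", "B", "B"], index=m.index)
        with pytest.raises(ValueError):
            compare_group_summaries(m, labels)
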