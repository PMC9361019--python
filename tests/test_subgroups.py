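"""Median split, differential expression, consensus clustering and the
subgroup-response association, checked against hand computations and
exhaustive multiple-testing oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from hccstem import (
    association_test,
    compare_expression_wilcoxon,
    consensus_cluster,
    differential_expression,
    split_by_median,
)
from tests.conftest import make_blob_matrix


def _bh_oracle(pvals):
    """Brute-force Benjamini-Hochberg step-up from the definition."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


def _hommel_oracle(pvals):
    """Closed-testing adjusted p-values: for each hypothesis i, the
    adjusted p is the max over all subsets S containing i of the local
    Simes test p-value on S.  Exact for small m."""
    p = np.asarray(pvals, float)
    m = len(p)
    adj = np.zeros(m)
    for subset_bits in range(1, 2**m):
        S = [i for i in range(m) if subset_bits >> i & 1]
        ps = np.sort(p[S])
        k = len(S)
        simes = min(k * ps[j] / (j + 1) for j in range(k))
        for i in S:
            adj[i] = max(adj[i], simes)
    return np.minimum(adj, 1.0)


class TestMedianSplit:
    def test_hand_example(self):
        s = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5], index=list("abcde"))
        lab = split_by_median(s)
        assert list(lab) == ["low", "low", "low", "high", "high"]

    def test_tie_goes_low(self):
        s = pd.Series([0.1, 0.55, 0.56, 0.9])
        lab = split_by_median(s)
        # median is 0.555; exactly-median membership only arises with odd n
        s2 = pd.Series([0.1, 0.55, 0.9])
        assert split_by_median(s2)[1] == "low"
        assert lab[2] == "high"

    def test_value_just_above_cutoff_is_high(self):
        s = pd.Series([0.2, 0.55, 0.56, 0.6, 0.1])
        assert split_by_median(s)[2] == "high"

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            split_by_median(pd.Series([0.3, 0.3, 0.3]))


class TestDifferentialExpression:
    def _labels(self, n_a, n_b):
        return pd.Series(
            ["high"] * n_a + ["low"] * n_b,
            index=[f"s{i}" for i in range(n_a + n_b)],
        )

    def test_planted_shift_is_deg(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            rng.normal(0, 0.1, size=(5, 40)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(40)],
        )
        X.iloc[0, :20] += 3.0
        de = differential_expression(X, self._labels(20, 20))
        assert bool(de.iloc[0]["is_deg"])
        assert de.iloc[0]["log2fc"] == pytest.approx(3.0, abs=0.15)
        assert not de.iloc[1:]["is_deg"].any()

    def test_null_labels_give_no_degs(self):
        n_with_degs = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(
                rng.normal(size=(50, 30)),
                index=[f"g{i}" for i in range(50)],
                columns=[f"s{i}" for i in range(30)],
            )
            de = differential_expression(X, self._labels(15, 15))
            n_with_degs += de["is_deg"].any()
        assert n_with_degs <= 5

    def test_bh_matches_bruteforce(self):
        X = pd.DataFrame(np.zeros((4, 4)))  # adjustment checked directly
        from statsmodels.stats.multitest import multipletests

        fixed = [0.01, 0.02, 0.03, 0.04]
        np.testing.assert_allclose(
            multipletests(fixed, method="fdr_bh")[1], [0.04, 0.04, 0.04, 0.04]
        )
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.uniform(size=5)
            np.testing.assert_allclose(
                multipletests(p, method="fdr_bh")[1], _bh_oracle(p), atol=1e-12
            )

    def test_deg_count_monotone_in_thresholds(self, sim_small, cohort_scores):
        X = sim_small["X_cohort"]
        labels = split_by_median(cohort_scores.mrnasi_series())
        counts = [
            differential_expression(X, labels, lfc_threshold=l, p_threshold=a)["is_deg"].sum()
            for l, a in [(0.5, 0.05), (1.0, 0.05), (1.0, 0.01), (1.5, 0.01)]
        ]
        assert counts == sorted(counts, reverse=True)

    def test_small_group_rejected(self):
        X = pd.DataFrame(np.ones((3, 3)), columns=["a", "b", "c"])
        labels = pd.Series(["high", "low", "low"], index=["a", "b", "c"])
        with pytest.raises(ValueError):
            differential_expression(X, labels)


class TestConsensusClustering:
    def test_planted_two_blob_recovery(self, blob_matrix):
        cons = consensus_cluster(blob_matrix, reps=250, rng_seed=1)
        n_per = blob_matrix.shape[1] // 2
        truth = [0] * n_per + [1] * n_per
        assert cons.chosen_k == 2
        assert adjusted_rand_score(truth, cons.labels) == 1.0
        M = cons.consensus_matrices[2]
        assert M[:n_per, :n_per].min() >= 0.95
        assert M[n_per:, n_per:].min() >= 0.95
        assert M[:n_per, n_per:].max() <= 0.05

    def test_small_blob_consensus_crisp(self):
        """10+10 samples at 10-sd separation: consensus at k=2 is
        block-perfect and the k=2 labels recover the partition."""
        X = make_blob_matrix(n_per_blob=10, n_genes=100, separation=10.0, seed=3)
        cons = consensus_cluster(X, reps=250, rng_seed=1)
        M = cons.consensus_matrices[2]
        assert min(M[:10, :10].min(), M[10:, 10:].min()) >= 0.95
        assert M[:10, 10:].max() <= 0.05
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        lab2 = fcluster(
            linkage(squareform(1 - M, checks=False), method="average"), 2, criterion="maxclust"
        )
        assert adjusted_rand_score([0] * 10 + [1] * 10, lab2) == 1.0

    def test_duplicate_samples_fully_coassigned(self):
        X = make_blob_matrix(n_per_blob=5, n_genes=50, separation=6.0, seed=2)
        X2 = pd.concat([X, X.add_suffix("_dup", axis=1)], axis=1)
        cons = consensus_cluster(X2, reps=100, rng_seed=0)
        n = X.shape[1]
        M = cons.consensus_matrices[2]
        for i in range(n):
            assert M[i, i + n] == pytest.approx(1.0)

    def test_deterministic(self, blob_matrix):
        c1 = consensus_cluster(blob_matrix, reps=50, rng_seed=9)
        c2 = consensus_cluster(blob_matrix, reps=50, rng_seed=9)
        assert c1.chosen_k == c2.chosen_k
        assert c1.labels.equals(c2.labels)
        np.testing.assert_array_equal(c1.consensus_matrices[3], c2.consensus_matrices[3])

    def test_consensus_converges_with_reps(self, blob_matrix):
        c1 = consensus_cluster(blob_matrix, reps=500, rng_seed=1)
        c2 = consensus_cluster(blob_matrix, reps=1000, rng_seed=2)
        diff = np.abs(c1.consensus_matrices[2] - c2.consensus_matrices[2]).max()
        assert diff < 0.05

    def test_bad_k_range_rejected(self, blob_matrix):
        with pytest.raises(ValueError):
            consensus_cluster(blob_matrix, k_range=range(2, 60), reps=5)


class TestAssociation:
    def test_balanced_subgroup_null(self):
        lab = pd.Series(["high"] * 20 + ["low"] * 20)
        resp = pd.Series(
            ["responder", "non_responder"] * 10 + ["responder", "non_responder"] * 10
        )
        res = association_test(lab, resp)
        assert res.per_subgroup_chi2["high"] == pytest.approx(0.0)
        assert res.per_subgroup_p["high"] == pytest.approx(1.0)

    def test_reproduces_printed_proportion_tests(self):
        """Table reconstructed from the published marginals (21/46 with
        8%/89% subgroup response rates): per-subgroup goodness-of-fit
        p-values 7.76e-9 and 5.79e-4."""
        lab = pd.Series(["high"] * 48 + ["low"] * 19)
        resp = pd.Series(
            ["responder"] * 4 + ["non_responder"] * 44
            + ["responder"] * 17 + ["non_responder"] * 2
        )
        res = association_test(lab, resp)
        assert f"{res.per_subgroup_p['high']:.2e}" == "7.76e-09"
        assert f"{res.per_subgroup_p['low']:.2e}" == "5.79e-04"
        assert res.per_subgroup_chi2["high"] == pytest.approx((44 - 4) ** 2 / 48)

    def test_empty_subgroup_rejected(self):
        lab = pd.Series(["high", "high"])
        resp = pd.Series(["responder", "responder"])
        with pytest.raises(ValueError):
            association_test(lab, resp)


class TestWilcoxonHommel:
    def _data(self, shift=0.0, n=30, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(3, 2 * n)),
            index=["g1", "g2", "g3"],
            columns=[f"s{i}" for i in range(2 * n)],
        )
        X.iloc[0, :n] += shift
        resp = pd.Series(
            ["non_responder"] * n + ["responder"] * n, index=X.columns
        )
        return X, resp

    def test_identical_groups_maximal_p(self):
        X, resp = self._data()
        X.loc["g1"] = np.tile([1.0, 2.0, 3.0], 20)
        res = compare_expression_wilcoxon(X, ["g1"], resp)
        assert res.loc["g1", "p"] > 0.9

    def test_hommel_matches_closed_testing(self):
        from statsmodels.stats.multitest import multipletests

        np.testing.assert_allclose(
            multipletests([0.01, 0.02, 0.03], method="hommel")[1],
            _hommel_oracle([0.01, 0.02, 0.03]),
            atol=1e-12,
        )
        rng = np.random.default_rng(4)
        for m in (3, 4, 5):
            for _ in range(10):
                p = rng.uniform(size=m)
                np.testing.assert_allclose(
                    multipletests(p, method="hommel")[1], _hommel_oracle(p), atol=1e-12
                )

    def test_shifted_gene_significant_after_adjustment(self):
        X, resp = self._data(shift=2.0)
        res = compare_expression_wilcoxon(X, ["g1", "g2", "g3"], resp)
        assert res.loc["g1", "adj_p"] < 0.01
        assert res.loc["g2", "adj_p"] > 0.05

    def test_constant_gene_warns(self):
        X, resp = self._data()
        X.loc["g1"] = 1.0
        with pytest.warns(UserWarning):
            res = compare_expression_wilcoxon(X, ["g1"], resp)
        assert res.loc["g1", "p"] == 1.0
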