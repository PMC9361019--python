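"""PCA signature fitting/projection against an eigendecomposition
oracle, ROC/AUC arithmetic against brute-force pair counting, and the
cutoff rule."""

import numpy as np
import pandas as pd
import pytest

from hccstem import classify_response, fit_signature, roc_curve, score_signature
from hccstem.signature import DEFAULT_CUTOFF, SignaturePanel


def _panel_frame(n_samples=40, seed=0, shift=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(8, 1, size=(4, n_samples))
    if shift is not None:
        X[:, : n_samples // 2] += shift
    return pd.DataFrame(
        X, index=["RXRB", "NR1H3", "CYP8B1", "SCD"],
        columns=[f"s{i}" for i in range(n_samples)],
    )


class TestFitSignature:
    def test_rank_one_two_gene_panel(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=30)
        X = pd.DataFrame([g, 2 * g + 5], index=["a", "b"],
                         columns=[f"s{i}" for i in range(30)])
        panel = fit_signature(X)
        np.testing.assert_allclose(np.abs(panel.loadings[0]), [1 / np.sqrt(2)] * 2, atol=1e-10)
        share = panel.explained_variance[0] / panel.explained_variance.sum()
        assert share == pytest.approx(1.0, abs=1e-10)

    def test_loadings_match_covariance_eigensolve(self):
        X = _panel_frame(seed=3)
        panel = fit_signature(X)
        Z = ((X.T - X.mean(axis=1)) / X.std(axis=1, ddof=1)).to_numpy()
        evals, evecs = np.linalg.eigh(Z.T @ Z / (Z.shape[0] - 1))
        order = np.argsort(evals)[::-1]
        for a in range(2):
            v = evecs[:, order[a]]
            j = np.argmax(np.abs(v))
            if v[j] < 0:
                v = -v
            np.testing.assert_allclose(panel.loadings[a], v, atol=1e-8)
            assert panel.explained_variance[a] == pytest.approx(evals[order[a]], abs=1e-8)

    def test_refit_deterministic(self):
        X = _panel_frame(seed=4)
        p1, p2 = fit_signature(X), fit_signature(X)
        np.testing.assert_array_equal(p1.loadings, p2.loadings)

    def test_zero_variance_gene_rejected(self):
        X = _panel_frame()
        X.loc["RXRB"] = 2.0
        with pytest.raises(ValueError, match="RXRB"):
            fit_signature(X)

    def test_panel_roundtrip(self, tmp_path):
        panel = fit_signature(_panel_frame(seed=5))
        panel.save(tmp_path / "p.json")
        back = SignaturePanel.load(tmp_path / "p.json")
        np.testing.assert_allclose(back.loadings, panel.loadings, atol=1e-15)
        assert back.gene_ids == panel.gene_ids


class TestScoreSignature:
    def test_centroid_sample_scores_zero(self):
        X = _panel_frame(seed=6)
        panel = fit_signature(X)
        centroid = pd.DataFrame(
            X.mean(axis=1).to_numpy()[:, None], index=X.index, columns=["c"]
        )
        sc = score_signature(panel, centroid)
        assert sc.dim1[0] == pytest.approx(0.0, abs=1e-10)
        assert sc.dim2[0] == pytest.approx(0.0, abs=1e-10)
        assert sc.pparscore[0] == pytest.approx(0.0, abs=1e-10)

    def test_fitting_cohort_dims_mean_zero(self):
        X = _panel_frame(seed=7)
        sc = score_signature(fit_signature(X), X)
        assert abs(sc.dim1.mean()) < 1e-10
        assert abs(sc.dim2.mean()) < 1e-10

    def test_pparscore_is_sum_of_dims(self):
        X = _panel_frame(seed=8)
        sc = score_signature(fit_signature(X), X)
        np.testing.assert_allclose(sc.pparscore, sc.dim1 + sc.dim2, atol=0)

    def test_missing_panel_gene_rejected(self):
        X = _panel_frame(seed=9)
        panel = fit_signature(X)
        with pytest.raises(KeyError, match="SCD"):
            score_signature(panel, X.drop(index="SCD"))

    def test_planted_shift_separates_responses(self, sim_small):
        """Non-responders carry the chain-root shift: the PPARscore
        separates simulated response groups."""
        X = sim_small["X_cohort"]
        truth = sim_small["truth"]
        panel = fit_signature(X.loc[truth.panel_genes])
        sc = score_signature(panel, X)
        y = (truth.true_response.reindex(sc.sample_ids) == "non_responder").astype(int)
        roc = roc_curve(sc.pparscore, y.to_numpy())
        assert roc.auc > 0.8

    def test_sign_convention_stable_under_resampling(self, sim_small):
        X = sim_small["X_cohort"]
        truth = sim_small["truth"]
        Xp = X.loc[truth.panel_genes]
        ref = fit_signature(Xp)
        rng = np.random.default_rng(0)
        agree = 0
        n_boot = 40
        for _ in range(n_boot):
            cols = rng.choice(Xp.shape[1], size=Xp.shape[1], replace=True)
            boot = Xp.iloc[:, cols]
            boot.columns = [f"b{i}" for i in range(len(cols))]
            pb = fit_signature(boot)
            agree += np.sign(pb.loadings[0] @ ref.loadings[0]) > 0
        assert agree / n_boot >= 0.95


class TestROC:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.0])
        labels = np.array([1, 1, 1, 0, 0, 0])
        roc = roc_curve(scores, labels)
        assert roc.auc == 1.0
        assert 0.2 <= roc.optimal_cutoff < 0.7
        assert roc.sensitivity_at_cutoff == 1.0
        assert roc.specificity_at_cutoff == 1.0

    def test_brute_force_pair_fixture(self):
        """positives {0.9, 0.8, 0.4}, negatives {0.7, 0.3, 0.2}: 8 of 9
        pairs are concordant, AUC = 8/9."""
        scores = np.array([0.9, 0.8, 0.4, 0.7, 0.3, 0.2])
        labels = np.array([1, 1, 1, 0, 0, 0])
        assert roc_curve(scores, labels).auc == pytest.approx(8 / 9, rel=1e-12)

    def test_matches_sklearn_on_random_fixtures(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        for _ in range(10):
            scores = np.round(rng.normal(size=60), 1)  # induce ties
            labels = rng.integers(0, 2, size=60)
            if labels.min() == labels.max():
                continue
            assert roc_curve(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores), rel=1e-12
            )

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(2)
        inside = 0
        for _ in range(40):
            scores = rng.normal(size=200)
            labels = rng.integers(0, 2, size=200)
            auc = roc_curve(scores, labels).auc
            inside += 0.4 < auc < 0.6
        assert inside / 40 >= 0.95

    def test_complement_symmetry(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        assert roc_curve(scores, labels).auc + roc_curve(-scores, labels).auc == pytest.approx(1.0)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, size=80)
        a1 = roc_curve(scores, labels).auc
        a2 = roc_curve(np.exp(scores), labels).auc
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_optimal_cutoff_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            scores = np.round(rng.normal(size=40), 1)
            labels = rng.integers(0, 2, size=40)
            if labels.min() == labels.max():
                continue
            roc = roc_curve(scores, labels)
            pos, neg = scores[labels == 1], scores[labels == 0]
            best = None
            for t in np.concatenate([[scores.min() - 1], np.unique(scores)]):
                sens, spec = (pos > t).mean(), (neg <= t).mean()
                d2 = (1 - sens) ** 2 + (1 - spec) ** 2
                key = (d2, -sens, t)
                if best is None or key < best[0]:
                    best = (key, t, d2)
            assert roc.optimal_cutoff == best[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_roc_curve_monotone(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        roc = roc_curve(scores, labels)
        assert (np.diff(roc.tpr) <= 1e-12).all()  # thresholds ascending
        assert (np.diff(roc.fpr) <= 1e-12).all()


class TestClassify:
    def test_boundary_score_is_responder(self):
        s = pd.Series([DEFAULT_CUTOFF], index=["x"])
        assert classify_response(s).iloc[0] == "responder"

    def test_default_cutoff_constant(self):
        assert DEFAULT_CUTOFF == -0.56

    def test_all_below_cutoff(self):
        s = pd.Series([-5.0, -1.0, -0.6])
        assert (classify_response(s) == "responder").all()

    def test_above_cutoff_predicted_resistant(self):
        s = pd.Series([-0.5, 0.0, 3.0])
        assert (classify_response(s) == "non_responder").all()
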