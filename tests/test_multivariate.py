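import numpy as np
import pytest

import symbioscreen as ss
from symbioscreen.errors import ComputationError, InputError
from symbioscreen.multivariate import PlsdaModel


def _reference_nipals(X, y, n_components):
    """Independent textbook NIPALS PLS1 (no shared code with the package):
    X, y already centered/scaled.  Returns the regression vector."""
    Xd, yd = X.copy(), y.copy()
    W, P, Q = [], [], []
    for _ in range(n_components):
        w = Xd.T @ yd
        w = w / np.sqrt((w**2).sum())
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        q = (yd @ t) / (t @ t)
        Xd = Xd - np.outer(t, p)
        yd = yd - q * t
        W.append(w), P.append(p), Q.append(q)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    return W @ np.linalg.inv(P.T @ W) @ Q


class TestPca:
    def test_duplicated_feature_adds_no_variance(self):
        rng = np.random.default_rng(0)
        X = 10 ** rng.normal(5, 0.3, (6, 3))
        X = np.hstack([X, X[:, :1]])  # perfect collinearity
        res = ss.pca(X, n_components=4, scale=False)
        # rank is 3 after centering; the 4th axis carries ~0 variance
        assert res.explained_variance_fraction[3] == pytest.approx(0.0, abs=1e-12)

    def test_equivalent_to_covariance_eigendecomposition(self):
        rng = np.random.default_rng(1)
        X = 10 ** rng.normal(5, 0.2, (5, 4))
        res = ss.pca(X, n_components=4, scale=False)
        Xc = np.log10(X) - np.log10(X).mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        np.testing.assert_allclose(
            res.explained_variance_fraction,
            evals[:4] / evals.sum(), atol=1e-10,
        )
        # scores orthogonal, reconstruction exact with all components
        S = res.scores.to_numpy()
        off = S.T @ S - np.diag(np.diag(S.T @ S))
        assert np.abs(off).max() < 1e-8
        recon = S @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, Xc, atol=1e-8)

    def test_separated_groups_separate_on_pc1(self):
        cfg = ss.SimFeatureConfig(n_features_per_mode=30, baseline_log_sd=0.05,
                                  missing_rate=0.0, seed=2)
        planted = [ss.PlantedCandidate(j, ("B108",), 10, 10) for j in range(5)]
        table, _ = ss.simulate_feature_table(cfg, planted)
        sub = table.subset_groups(["B108", "LB"])
        res = ss.pca(sub, n_components=2)
        pc1 = res.scores["PC1"]
        g = sub.samples["group"]
        gap = abs(pc1[g == "B108"].mean() - pc1[g == "LB"].mean())
        spread = max(pc1[g == "B108"].std(), pc1[g == "LB"].std())
        assert gap > spread

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        X = 10 ** rng.normal(5, 0.3, (6, 4))
        a = ss.pca(X, 2)
        b = ss.pca(X, 2)
        assert a.loadings.equals(b.loadings)
        for col in a.loadings:
            j = a.loadings[col].abs().idxmax()
            assert a.loadings.loc[j, col] > 0

    def test_too_many_components_rejected(self):
        with pytest.raises(InputError):
            ss.pca(np.ones((3, 2)) + np.eye(3, 2), n_components=4)


class TestPlsda:
    def test_single_class_rejected(self):
        X = 10 ** np.random.default_rng(0).normal(5, 0.3, (6, 4))
        with pytest.raises(InputError, match="two classes"):
            ss.plsda_fit(X, ["a"] * 6)

    def test_perfect_predictor_gets_max_weight(self, two_group_matrix):
        X, y, labels = two_group_matrix
        model = ss.plsda_fit(X, labels, n_components=1)
        assert np.argmax(np.abs(model.weights[:, 0])) == 3

    def test_matches_textbook_nipals(self):
        rng = np.random.default_rng(4)
        X = 10 ** rng.normal(5, 0.3, (6, 5))
        labels = ["a", "a", "a", "b", "b", "b"]
        y = np.array([0.0] * 3 + [1.0] * 3)
        model = ss.plsda_fit(X, labels, n_components=2)
        Xl = np.log10(X)
        Xc = (Xl - Xl.mean(axis=0)) / Xl.std(axis=0, ddof=1)
        beta = _reference_nipals(Xc, y - y.mean(), 2)
        pred_ref = y.mean() + Xc @ beta
        np.testing.assert_allclose(model.predict(X), pred_ref, atol=1e-8)

    def test_full_rank_limit_equals_ols(self):
        """With as many components as the rank, PLS1 predictions converge to
        ordinary least squares on the same scaled design."""
        rng = np.random.default_rng(5)
        X = 10 ** rng.normal(5, 0.3, (8, 4))
        labels = ["a"] * 4 + ["b"] * 4
        y = np.array([0.0] * 4 + [1.0] * 4)
        model = ss.plsda_fit(X, labels, n_components=4)
        Xl = np.log10(X)
        Xc = (Xl - Xl.mean(axis=0)) / Xl.std(axis=0, ddof=1)
        beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(model.predict(X), y.mean() + Xc @ beta, atol=1e-6)

    def test_matches_sklearn_predictions(self, two_group_matrix):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y, labels = two_group_matrix
        model = ss.plsda_fit(X, labels, n_components=2)
        sk = sklearn.PLSRegression(n_components=2, scale=True).fit(np.log10(X), y)
        np.testing.assert_allclose(
            model.predict(X), sk.predict(np.log10(X)).ravel(), atol=1e-8
        )


class TestVip:
    def test_equal_weights_give_unit_vip(self):
        model = PlsdaModel(
            classes=("a", "b"), n_components=1,
            weights=np.full((4, 1), 0.5), x_scores=np.ones((6, 1)),
            x_loadings=np.full((4, 1), 0.5), y_loadings=np.array([1.0]),
            y_explained_ss=np.array([2.0]), x_mean=np.zeros(4),
            x_scale=np.ones(4), y_mean=0.5, feature_ids=list("wxyz"),
        )
        np.testing.assert_allclose(ss.vip_scores(model), 1.0)

    def test_hand_computed_three_feature_case(self):
        model = PlsdaModel(
            classes=("a", "b"), n_components=1,
            weights=np.array([[0.8], [0.6], [0.0]]), x_scores=np.ones((6, 1)),
            x_loadings=np.array([[0.8], [0.6], [0.0]]),
            y_loadings=np.array([1.0]), y_explained_ss=np.array([3.0]),
            x_mean=np.zeros(3), x_scale=np.ones(3), y_mean=0.5,
            feature_ids=list("uvw"),
        )
        vip = ss.vip_scores(model)
        np.testing.assert_allclose(
            vip.to_numpy(),
            [np.sqrt(3 * 0.64), np.sqrt(3 * 0.36), 0.0], atol=1e-10,
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_mean_square_identity(self, seed):
        rng = np.random.default_rng(seed)
        X = 10 ** rng.normal(5, 0.3, (10, 7))
        labels = ["a"] * 5 + ["b"] * 5
        vip = ss.vip_scores(ss.plsda_fit(X, labels, n_components=2))
        assert (vip**2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_model_rejected(self):
        model = PlsdaModel(
            classes=("a", "b"), n_components=1, weights=np.ones((2, 1)),
            x_scores=np.ones((4, 1)), x_loadings=np.ones((2, 1)),
            y_loadings=np.array([0.0]), y_explained_ss=np.array([0.0]),
            x_mean=np.zeros(2), x_scale=np.ones(2), y_mean=0.5,
            feature_ids=list("ab"),
        )
        with pytest.raises(ComputationError):
            ss.vip_scores(model)


class TestPermutation:
    def test_small_n_perm_rejected(self, two_group_matrix):
        X, _, labels = two_group_matrix
        with pytest.raises(InputError):
            ss.permutation_test(X, labels, n_perm=5)

    def test_strong_signal_passes(self):
        rng = np.random.default_rng(0)
        X = 10 ** rng.normal(5, 0.3, (12, 6))
        y = np.array([0.0] * 6 + [1.0] * 6)
        X[:, 3] = 10 ** (5 + y)  # noiseless perfect predictor
        res = ss.permutation_test(X, ["a"] * 6 + ["b"] * 6, n_perm=100, seed=0)
        assert res.passed
        assert res.q2_orig > max(res.q2_perm)
        assert res.q2_intercept < 0

    def test_pure_noise_rarely_passes(self):
        labels = ["a"] * 6 + ["b"] * 6
        rng = np.random.default_rng(1)
        passes = 0
        n_sets = 40
        for i in range(n_sets):
            X = 10 ** rng.normal(5, 0.3, (12, 15))
            passes += ss.permutation_test(X, labels, n_perm=20, seed=i).passed
        assert passes / n_sets <= 0.10
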