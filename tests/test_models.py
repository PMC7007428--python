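import numpy as np
import pytest

from specgrade import (
    fit_pca_lda,
    fit_pls_da,
    pls_cv_threshold,
    predict_pca_lda,
    predict_pls_da,
    select_components,
    venetian_blinds,
)
from specgrade.models import AxisMismatchError, fit_pca, model_from_dict, model_to_dict


def two_blobs(n=40, d=5, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n, d))
    X[n:, 0] += sep
    y = np.array(["G1"] * n + ["G2"] * n, dtype=object)
    return X, y


class TestPca:
    def test_rank_one_matrix_single_pc_explains_everything(self):
        u = np.arange(1.0, 7.0)[:, None]
        v = np.array([[2.0, -1.0, 0.5]])
        _, _, _, evr = fit_pca(u @ v, 1)
        assert evr[0] == pytest.approx(100.0)

    def test_scores_orthogonal_and_reconstruction_exact(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 7))
        mean, loadings, eigs, _ = fit_pca(X, 7)
        scores = (X - mean) @ loadings
        gram = scores.T @ scores
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-10)
        np.testing.assert_allclose(scores @ loadings.T + mean, X, atol=1e-10)

    def test_k_beyond_rank_rejected(self):
        X = np.outer(np.arange(5.0), np.arange(3.0))
        with pytest.raises(ValueError, match="rank"):
            fit_pca(X, 3)


class TestPcaLda:
    def test_separated_blobs_training_accuracy_100(self):
        X, y = two_blobs(sep=8.0)
        m = fit_pca_lda(X, y, 2)
        pred, _ = predict_pca_lda(m, X)
        assert (pred == y).all()

    def test_class_mean_spectrum_assigned_to_its_class(self):
        X, y = two_blobs()
        m = fit_pca_lda(X, y, 3)
        for c in ("G1", "G2"):
            mu = X[y == c].mean(axis=0, keepdims=True)
            pred, _ = predict_pca_lda(m, mu)
            assert pred[0] == c

    def test_matches_closed_form_lda_oracle(self):
        """Full-rank PCA-LDA with equal priors equals the textbook linear
        discriminant w = S^-1 (m2 - m1) applied mid-way between the means."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        X[15:] += [1.0, -0.5, 0.3, 0.0]
        y = np.array(["G1"] * 15 + ["G2"] * 15, dtype=object)
        m = fit_pca_lda(X, y, 4, priors="equal")
        pred, _ = predict_pca_lda(m, X)

        m1, m2 = X[:15].mean(axis=0), X[15:].mean(axis=0)
        S = (np.cov(X[:15].T) * 14 + np.cov(X[15:].T) * 14) / 28
        w = np.linalg.solve(S, m2 - m1)
        proj = X @ w - (m1 + m2) @ w / 2
        oracle = np.where(proj > 0, "G2", "G1")
        assert (pred == oracle).all()

    def test_matches_sklearn_lda(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 6))
        X[30:] += 0.8
        y = np.array(["G1"] * 30 + ["G2"] * 20, dtype=object)
        ours = fit_pca_lda(X, y, 6, priors="equal")
        pred, _ = predict_pca_lda(ours, X)
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
        assert (pred == sk.predict(X)).all()

    def test_proportional_priors_shift_boundary_toward_minority(self):
        rng = np.random.default_rng(4)
        X = np.r_[rng.normal(size=(60, 3)), rng.normal(size=(12, 3)) + 1.2]
        y = np.array(["G1"] * 60 + ["G2"] * 12, dtype=object)
        prop = fit_pca_lda(X, y, 3, priors="proportional")
        eq = fit_pca_lda(X, y, 3, priors="equal")
        pred_p, _ = predict_pca_lda(prop, X)
        pred_e, _ = predict_pca_lda(eq, X)
        assert (pred_p == "G2").sum() <= (pred_e == "G2").sum()

    def test_score_sign_convention_and_axis_mismatch(self):
        X, y = two_blobs()
        m = fit_pca_lda(X, y, 2)
        _, score = predict_pca_lda(m, X)
        assert score[y == "G2"].mean() > score[y == "G1"].mean()
        with pytest.raises(AxisMismatchError):
            predict_pca_lda(m, X[:, :3])

    def test_discriminant_orthogonal_to_retained_pc_is_chance(self):
        """When the class difference lives outside the retained PC, accuracy
        collapses to chance."""
        rng = np.random.default_rng(5)
        n = 200
        big = rng.normal(scale=10.0, size=(2 * n, 1))  # PC1 carries no class info
        small = np.r_[rng.normal(size=(n, 1)), rng.normal(size=(n, 1)) + 1.0]
        X = np.hstack([big, small])
        y = np.array(["G1"] * n + ["G2"] * n, dtype=object)
        m = fit_pca_lda(X, y, 1)
        pred, _ = predict_pca_lda(m, X)
        assert 0.4 < float(np.mean(pred == y)) < 0.6


class TestPlsDa:
    def test_first_weight_parallel_to_xty(self):
        X, y = two_blobs(seed=6)
        m = fit_pls_da(X, y, 1)
        yc = np.where(y == "G2", 1.0, -1.0)
        v = (X - X.mean(axis=0)).T @ (yc - yc.mean())
        cos = v @ m.weights[:, 0] / np.linalg.norm(v)
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_full_rank_pls_equals_least_squares(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(25, 4))
        y = np.array(["G1"] * 12 + ["G2"] * 13, dtype=object)
        m = fit_pls_da(X, y, 4)
        _, resp = predict_pls_da(m, X)
        yc = np.where(y == "G2", 1.0, -1.0)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, yc - yc.mean(), rcond=None)
        np.testing.assert_allclose(resp, Xc @ beta + yc.mean(), atol=1e-8)

    def test_label_swap_negates_regression_vector(self):
        X, y = two_blobs(seed=8)
        a = fit_pls_da(X, y, 3, positive_class="G2")
        b = fit_pls_da(X, y, 3, positive_class="G1")
        np.testing.assert_allclose(
            a.regression_vector, -b.regression_vector, atol=1e-10
        )
        pa, _ = predict_pls_da(a, X)
        pb, _ = predict_pls_da(b, X)
        assert (pa == pb).mean() > 0.95  # only exact-threshold ties may differ

    def test_matches_sklearn_pls_regression(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 10))
        y = np.array(["G1"] * 15 + ["G2"] * 15, dtype=object)
        yc = np.where(y == "G2", 1.0, -1.0)
        for k in (1, 3, 5):
            ours = fit_pls_da(X, y, k)
            sk = PLSRegression(n_components=k, scale=False).fit(X, yc)
            _, resp = predict_pls_da(ours, X)
            np.testing.assert_allclose(
                resp, sk.predict(X).ravel(), atol=1e-8
            )

    def test_positive_centroid_predicts_positive(self):
        X, y = two_blobs(seed=10)
        m = fit_pls_da(X, y, 2)
        _, resp = predict_pls_da(m, X[y == "G2"].mean(axis=0, keepdims=True))
        assert resp[0] > m.threshold

    def test_response_monotone_in_regression_direction(self):
        X, y = two_blobs(seed=11)
        m = fit_pls_da(X, y, 2)
        _, r0 = predict_pls_da(m, X[:1])
        _, r1 = predict_pls_da(m, X[:1] + 0.1 * m.regression_vector)
        assert r1[0] > r0[0]

    def test_training_response_rss_non_increasing_in_k(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 15))
        X[20:, :3] += 0.7
        y = np.array(["G1"] * 20 + ["G2"] * 20, dtype=object)
        yc = np.where(y == "G2", 1.0, -1.0)
        rss = []
        for k in range(1, 9):
            m = fit_pls_da(X, y, k, threshold=0.0)
            _, resp = predict_pls_da(m, X)
            rss.append(float(np.sum((resp - yc) ** 2)))
        assert all(b <= a + 1e-10 for a, b in zip(rss, rss[1:]))

    def test_column_permutation_equivariance(self):
        X, y = two_blobs(seed=13)
        perm = np.random.default_rng(0).permutation(X.shape[1])
        a = fit_pls_da(X, y, 3)
        b = fit_pls_da(X[:, perm], y, 3)
        np.testing.assert_allclose(
            a.regression_vector[perm], b.regression_vector, atol=1e-10
        )

    def test_serialisation_round_trip(self):
        X, y = two_blobs(seed=14)
        for fit, predict in (
            (lambda: fit_pls_da(X, y, 2), predict_pls_da),
            (lambda: fit_pca_lda(X, y, 2), predict_pca_lda),
        ):
            m = fit()
            back = model_from_dict(model_to_dict(m))
            p1, s1 = predict(m, X)
            p2, s2 = predict(back, X)
            assert (p1 == p2).all()
            np.testing.assert_allclose(s1, s2)


class TestSelectComponents:
    def test_low_dimensional_structure_chooses_small_k(self):
        rng = np.random.default_rng(15)
        n = 120
        X = rng.normal(size=(2 * n, 20)) * 0.3
        X[n:, :2] += 1.0
        y = np.array(["G1"] * n + ["G2"] * n, dtype=object)
        folds = venetian_blinds(2 * n, 10)
        rep = select_components(X, y, folds, k_max=8, model_kind="plsda")
        assert rep.n_components_chosen <= 4
        assert rep.cv_accuracy_by_k["cv_accuracy"].max() > 0.9

    def test_pure_noise_labels_near_chance_for_all_k(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(200, 10))
        y = np.array(["G1", "G2"] * 100, dtype=object)
        folds = venetian_blinds(200, 10)
        rep = select_components(X, y, folds, k_max=4, model_kind="pcalda")
        assert (rep.cv_accuracy_by_k["cv_accuracy"] < 0.65).all()

    def test_k_max_one_returns_one(self):
        X, y = two_blobs(seed=17)
        folds = venetian_blinds(len(y), 5)
        rep = select_components(X, y, folds, k_max=1, model_kind="plsda")
        assert rep.n_components_chosen == 1
        assert rep.training_residuals is not None


class TestCvThreshold:
    def test_balanced_data_threshold_near_fitted_midpoint(self):
        X, y = two_blobs(n=50, sep=3.0, seed=18)
        folds = venetian_blinds(len(y), 10)
        thr = pls_cv_threshold(X, y, 2, folds)
        m = fit_pls_da(X, y, 2)
        assert abs(thr - m.threshold) < 0.3
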