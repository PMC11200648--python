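import numpy as np
import pytest

from gdmnir import (
    lda_threshold,
    load_model,
    pls1_fit,
    pls1_predict,
    plslda_classify,
    save_model,
)


def simpls_predict(X, y, A, X_new):
    """Independent SIMPLS (de Jong 1993) predictions, single response."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - xm, y - ym
    s = Xc.T @ yc
    n, p = Xc.shape
    R = np.zeros((p, A))
    V = np.zeros((p, A))
    q = np.zeros(A)
    for a in range(A):
        r = s.copy()
        t = Xc @ r
        t_norm = np.linalg.norm(t - t.mean())
        t = (t - t.mean()) / t_norm
        r = r / t_norm
        pa = Xc.T @ t
        q[a] = yc @ t
        v = pa.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pa)
        v /= np.linalg.norm(v)
        s = s - v * (v @ s)
        R[:, a], V[:, a] = r, v
    b = R @ q
    return (np.asarray(X_new, float) - xm) @ b + ym


@pytest.fixture()
def toy(rng):
    X = rng.standard_normal((20, 5))
    beta = np.array([1.0, -2.0, 0.5, 0.0, 0.0])
    y = (X @ beta + 0.3 * rng.standard_normal(20) > 0).astype(float)
    return X, y


class TestPLS1Fit:
    def test_first_weight_is_normalized_covariance(self, toy):
        X, y = toy
        m = pls1_fit(X, y, 1)
        w_expect = (X - X.mean(0)).T @ (y - y.mean())
        w_expect /= np.linalg.norm(w_expect)
        np.testing.assert_allclose(m.W[:, 0], w_expect, atol=1e-12)

    def test_full_rank_equals_least_squares(self, toy):
        X, y = toy
        m = pls1_fit(X, y, 5)
        Xc = X - X.mean(0)
        yc = y - y.mean()
        y_ols = Xc @ np.linalg.lstsq(Xc, yc, rcond=None)[0] + y.mean()
        np.testing.assert_allclose(pls1_predict(m, X), y_ols, atol=1e-8)

    def test_constant_y_gives_zero_coefficients(self, rng):
        X = rng.standard_normal((10, 4))
        m = pls1_fit(X, np.full(10, 0.5), 3)
        np.testing.assert_allclose(m.b, 0.0, atol=1e-12)

    def test_model_invariants(self, toy):
        X, y = toy
        m = pls1_fit(X, y, 4)
        Xc = X - m.x_mean
        # T = X R
        np.testing.assert_allclose(m.T, Xc @ m.R, atol=1e-8)
        # b = R q
        np.testing.assert_allclose(m.b, m.R @ m.q, atol=1e-10)
        # score orthogonality
        G = m.T.T @ m.T
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)

    def test_rank_exceeded_reduces_with_warning(self, rng):
        X = rng.standard_normal((6, 3))
        y = np.array([0, 1, 0, 1, 0, 1], float)
        with pytest.warns(UserWarning, match="rank"):
            m = pls1_fit(X, y, 5)
        assert m.n_components <= 3

    def test_residual_monotone_in_components(self, toy):
        X, y = toy
        m = pls1_fit(X, y, 5)
        fitted = m.fitted_path()
        rss = ((y[:, None] - fitted) ** 2).sum(axis=0)
        assert np.all(np.diff(rss) <= 1e-10)

    def test_matches_independent_simpls(self, rng):
        X = rng.standard_normal((15, 8))
        y = (rng.random(15) > 0.5).astype(float)
        y[:2] = [0, 1]
        X_new = rng.standard_normal((4, 8))
        for A in (1, 2, 3):
            m = pls1_fit(X, y, A)
            np.testing.assert_allclose(
                pls1_predict(m, X_new), simpls_predict(X, y, A, X_new), atol=1e-8
            )


class TestPLS1Predict:
    def test_training_prediction_reproduces_fitted(self, toy):
        X, y = toy
        m = pls1_fit(X, y, 3)
        np.testing.assert_allclose(pls1_predict(m, X), m.fitted_path()[:, 2], atol=1e-10)

    def test_score_route_equals_coefficient_route(self, toy):
        X, y = toy
        m = pls1_fit(X, y, 3)
        scores = (X - m.x_mean) @ m.R
        via_scores = scores @ m.q + m.y_mean
        via_coef = pls1_predict(m, X)
        np.testing.assert_allclose(via_scores, via_coef, atol=1e-10)

    def test_column_mismatch_rejected(self, toy):
        X, y = toy
        m = pls1_fit(X, y, 2)
        with pytest.raises(ValueError, match="mismatch"):
            pls1_predict(m, X[:, :3])


class TestLDAThreshold:
    def test_symmetric_midpoint(self):
        y_hat = np.array([0.0, 0.2, 0.8, 1.0])
        y = np.array([0, 0, 1, 1])
        t = lda_threshold(y_hat, y)
        assert t.threshold == pytest.approx(0.5)
        assert t.orientation == "gdm_above"

    def test_equal_priors_ignore_variance(self, rng):
        y = np.r_[np.zeros(30), np.ones(10)].astype(int)
        y_hat = np.r_[rng.normal(0.1, 0.3, 30), rng.normal(0.9, 0.05, 10)]
        t = lda_threshold(y_hat, y, priors="equal")
        m0, m1 = y_hat[y == 0].mean(), y_hat[y == 1].mean()
        assert t.threshold == pytest.approx((m0 + m1) / 2)

    def test_proportional_priors_match_grid_search_oracle(self, rng):
        # brute-force argmax of the two Gaussian posteriors on a fine grid
        y = np.r_[np.zeros(40), np.ones(8)].astype(int)
        y_hat = np.r_[rng.normal(0.15, 0.2, 40), rng.normal(0.8, 0.2, 8)]
        t = lda_threshold(y_hat, y, priors="proportional")
        m0, m1 = y_hat[y == 0].mean(), y_hat[y == 1].mean()
        grid = np.linspace(min(y_hat) - 1, max(y_hat) + 1, 200_001)
        # posterior log-ratio of the pooled-variance Gaussians
        def log_post(cls_mean, prior):
            return -((grid - cls_mean) ** 2) / (2 * t.pooled_var) + np.log(prior)

        diff = log_post(m1, t.pi1) - log_post(m0, t.pi0)
        crossing = grid[np.argmin(np.abs(diff))]
        assert t.threshold == pytest.approx(crossing, abs=1e-4)

    def test_degenerate_means_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            lda_threshold(np.array([0.5, 0.5]), np.array([0, 1]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            lda_threshold(np.array([0.1, 0.2]), np.array([0, 0]))


class TestClassification:
    def test_above_threshold_is_gdm(self):
        y_hat = np.array([0.0, 0.1, 0.9, 1.0])
        y = np.array([0, 0, 1, 1])
        m = pls1_fit(y_hat[:, None], y.astype(float), 1)
        t = lda_threshold(pls1_predict(m, y_hat[:, None]), y)
        labels = plslda_classify(m, t, y_hat[:, None])
        np.testing.assert_array_equal(labels, y)

    def test_exact_tie_goes_to_ngt(self):
        from gdmnir.plslda import LDAThreshold, classify_scores

        t = LDAThreshold(0.5, "gdm_above", 0.2, 0.8, 0.01, 0.5, 0.5)
        assert classify_scores(np.array([0.5, 0.5]), t).tolist() == [0, 0]

    def test_separable_training_data_recovered(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(3, 0.1, (6, 3))])
        y = np.r_[np.zeros(10), np.ones(6)].astype(int)
        m = pls1_fit(X, y.astype(float), 2)
        t = lda_threshold(pls1_predict(m, X), y)
        np.testing.assert_array_equal(plslda_classify(m, t, X), y)

    def test_text_export_round_trip(self, toy, tmp_path, rng):
        X, y = toy
        m = pls1_fit(X, y, 3)
        t = lda_threshold(pls1_predict(m, X), y.astype(int))
        save_model(tmp_path / "model.json", m, t)
        m2, t2 = load_model(tmp_path / "model.json")
        X_new = rng.standard_normal((5, X.shape[1]))
        np.testing.assert_array_equal(pls1_predict(m, X_new), pls1_predict(m2, X_new))
        assert t2 == t

    def test_labels_invariant_under_affine_transform(self, rng):
        from gdmnir.plslda import LDAThreshold, classify_scores

        scores = rng.standard_normal(20)
        t = LDAThreshold(0.3, "gdm_above", 0.0, 1.0, 0.1, 0.5, 0.5)
        base = classify_scores(scores, t)
        a, b = 2.7, -1.2
        t2 = LDAThreshold(a * 0.3 + b, "gdm_above", 0.0, 1.0, 0.1, 0.5, 0.5)
        np.testing.assert_array_equal(classify_scores(a * scores + b, t2), base)
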