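"""Single-SNP, elastic-net and KNN predictor contracts."""

import numpy as np
import pytest

from cisxpred import models as m
from cisxpred.evaluation import r_squared


def brute_force_knn(X_train, y_train, X_test, k, weights):
    """Independent nearest-neighbor oracle: full sort on (distance, index)."""
    preds = []
    for row in np.asarray(X_test, dtype=float):
        d = [
            sum(w * abs(a - b) for w, a, b in zip(weights, row, tr))
            for tr in np.asarray(X_train, dtype=float)
        ]
        order = sorted(range(len(d)), key=lambda i: (d[i], i))
        preds.append(np.mean([y_train[i] for i in order[:k]]))
    return np.array(preds)


class TestSingleSnp:
    def test_noiseless_linear_recovery(self, rng):
        X = rng.integers(0, 3, size=(30, 5)).astype(float)
        model = m.fit_single_best_snp(X, 2.0 * X[:, 1])
        assert model.snp_index == 1
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)
        assert model.train_r2 == pytest.approx(1.0)

    def test_tie_break_lowest_index(self):
        x = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        X = np.column_stack([x, x])  # identical columns tie in |r|
        y = x + 0.5
        model = m.fit_single_best_snp(X, y)
        assert model.snp_index == 0

    def test_negative_correlation_usable(self):
        x = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
        y = -3.0 * x + 1.0
        model = m.fit_single_best_snp(np.column_stack([x]), y)
        assert model.slope == pytest.approx(-3.0)
        assert model.train_r2 == pytest.approx(1.0)

    def test_shift_invariance_up_to_intercept(self, rng):
        X = rng.integers(0, 3, size=(40, 6)).astype(float)
        y = X[:, 2] + rng.normal(scale=0.3, size=40)
        a = m.fit_single_best_snp(X, y)
        b = m.fit_single_best_snp(X, y + 100.0)
        assert a.snp_index == b.snp_index
        assert a.slope == pytest.approx(b.slope)
        assert b.intercept - a.intercept == pytest.approx(100.0)

    def test_all_constant_errors(self):
        with pytest.raises(ValueError, match="no informative SNP"):
            m.fit_single_best_snp(np.ones((10, 3)), np.arange(10.0))

    def test_null_test_r2_near_zero(self, rng):
        vals = []
        for _ in range(50):
            X = rng.integers(0, 3, size=(300, 10)).astype(float)
            y = rng.normal(size=300)
            model = m.fit_single_best_snp(X[:200], y[:200])
            vals.append(r_squared(y[200:], m.predict_single_snp(model, X[200:])))
        assert abs(np.mean(vals)) < 0.05


class TestElasticNet:
    def test_planted_sign_recovery(self, rng):
        hits = 0
        for _ in range(10):
            X = rng.integers(0, 3, size=(300, 20)).astype(float)
            beta = np.zeros(20)
            beta[[2, 7, 11]] = [1.5, -2.0, 1.0]
            y = X @ beta
            model = m.fit_elastic_net(X, y, seed=0)
            top = np.argsort(-np.abs(model.snp_weights))[:3]
            if set(top) == {2, 7, 11} and all(
                np.sign(model.snp_weights[j]) == np.sign(beta[j]) for j in top
            ):
                hits += 1
        assert hits >= 9

    def test_grid_max_lambda_gives_zero_weights(self, rng):
        X = rng.integers(0, 3, size=(50, 8)).astype(float)
        y = X[:, 0] + rng.normal(size=50)
        lam_max = m.lambda_grid(X, y)[0]
        model = m.fit_elastic_net(X, y, lambdas=np.array([lam_max * 1.01]))
        np.testing.assert_allclose(model.snp_weights, 0.0, atol=1e-12)
        np.testing.assert_allclose(
            m.predict_linear(model, X), np.full(50, y.mean()), atol=1e-10
        )

    def test_internal_cv_score_not_optimistic(self, rng):
        """Mean internal-validation R2 is below the in-sample R2 on average."""
        gaps = []
        for _ in range(10):
            X = rng.integers(0, 3, size=(80, 15)).astype(float)
            y = X[:, 3] - X[:, 9] + rng.normal(size=80)
            model = m.fit_elastic_net(X, y, seed=1)
            in_sample = r_squared(y, m.predict_linear(model, X))
            gaps.append(in_sample - model.train_r2_cv)
        assert np.mean(gaps) > 0

    def test_degenerate_y_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            m.fit_elastic_net(np.eye(6), np.ones(6))


class TestKnnDistance:
    def test_unit_weights(self):
        D = m.knn_distance_matrix([[0, 2, 1]], [[1, 0, 1]], [1, 1, 1])
        assert D[0, 0] == 3.0

    def test_weighted(self):
        D = m.knn_distance_matrix([[0, 2, 1]], [[1, 0, 1]], [2, 0, 1])
        assert D[0, 0] == 2.0

    def test_identical_rows_zero_and_symmetry(self, rng):
        X = rng.integers(0, 3, size=(12, 6)).astype(float)
        D = m.knn_distance_matrix(X, X, np.ones(6))
        assert np.diag(D).sum() == 0.0
        np.testing.assert_array_equal(D, D.T)

    def test_integer_valued_for_unit_weights(self, rng):
        X = rng.integers(0, 3, size=(10, 9)).astype(float)
        D = m.knn_distance_matrix(X, X)
        np.testing.assert_array_equal(D, np.round(D))

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            m.knn_distance_matrix([[0.0]], [[1.0]], [-1.0])


class TestKnnFit:
    def test_selected_k_matches_exhaustive_search(self, rng):
        X = np.vstack([
            rng.integers(0, 2, size=(10, 8)),
            rng.integers(1, 3, size=(10, 8)),
        ]).astype(float)
        y = np.r_[rng.normal(0, 0.1, 10), rng.normal(3, 0.1, 10)]
        model = m.fit_simple_knn(X, y)
        D = m.knn_distance_matrix(X, X)
        best = max(
            range(1, 20),
            key=lambda k: m.loo_r2_by_k(D, y, np.array([k]))[0],
        )
        assert model.k == best
        assert model.train_r2 == pytest.approx(
            m.loo_r2_by_k(D, y, np.array([best]))[0]
        )

    def test_k_equals_n_minus_one_predicts_leave_one_out_mean(self, rng):
        X = rng.integers(0, 3, size=(8, 4)).astype(float)
        y = rng.normal(size=8)
        D = m.knn_distance_matrix(X, X)
        r2 = m.loo_r2_by_k(D, y, np.array([7]))
        expect = np.array([(y.sum() - y[i]) / 7 for i in range(8)])
        ss = ((y - y.mean()) ** 2).sum()
        assert r2[0] == pytest.approx(1 - ((y - expect) ** 2).sum() / ss)

    def test_predict_k1_identical_genotype(self, rng):
        X = rng.integers(0, 3, size=(10, 5)).astype(float)
        y = rng.normal(size=10)
        model = m.fit_simple_knn(X, y, k_grid=[1])
        pred = m.predict_knn(model, X[[4]])
        assert pred[0] == y[4]

    def test_predict_k_equals_n_train_is_global_mean(self, rng):
        X = rng.integers(0, 3, size=(6, 4)).astype(float)
        y = rng.normal(size=6)
        model = m.fit_simple_knn(X, y, k_grid=[3])
        model.k = 6  # prediction allows k up to N_train
        pred = m.predict_knn(model, rng.integers(0, 3, size=(3, 4)).astype(float))
        np.testing.assert_allclose(pred, y.mean())

    def test_k_above_n_train_errors(self, rng):
        X = rng.integers(0, 3, size=(5, 3)).astype(float)
        model = m.fit_simple_knn(X, rng.normal(size=5), k_grid=[2])
        model.k = 6
        with pytest.raises(ValueError, match="exceeds"):
            m.predict_knn(model, X)

    def test_matches_brute_force_oracle(self, rng):
        """Exact agreement with a full-sort nearest-neighbor implementation."""
        for _ in range(25):
            n, d = int(rng.integers(5, 26)), int(rng.integers(2, 15))
            X_tr = rng.integers(0, 3, size=(n, d)).astype(float)
            X_te = rng.integers(0, 3, size=(8, d)).astype(float)
            y = rng.normal(size=n)
            k = int(rng.integers(1, n + 1))
            w = rng.integers(0, 4, size=d).astype(float)
            if not w.any():
                w[0] = 1.0
            model = m.KnnModel(k=k, snp_weights=w, train_X=X_tr, train_y=y,
                               train_r2=np.nan)
            np.testing.assert_array_equal(
                m.predict_knn(model, X_te), brute_force_knn(X_tr, y, X_te, k, w)
            )


class TestCombine:
    def test_elementwise_mean(self):
        np.testing.assert_array_equal(
            m.combine_predictions([1.0, 3.0], [3.0, 1.0]), [2.0, 2.0]
        )

    def test_idempotent_on_agreement(self, rng):
        p = rng.normal(size=7)
        np.testing.assert_array_equal(m.combine_predictions(p, p), p)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            m.combine_predictions([1.0], [1.0, 2.0])
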