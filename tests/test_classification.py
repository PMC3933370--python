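import numpy as np
import pytest
from scipy.optimize import minimize

from lungsound.classification import (
    ELMModel,
    FeatureScaler,
    elm_predict,
    elm_train,
    encode_labels,
    load_model,
    save_model,
    svm_predict,
    svm_train,
)


def _blobs(rng, n_per=10, sep=2.5, dim=2):
    X = np.vstack(
        [rng.normal(0, 1, (n_per, dim)), rng.normal(sep, 1, (n_per, dim))]
    )
    d = np.r_[-np.ones(n_per), np.ones(n_per)]
    return X, d


class TestELM:
    def test_square_system_zero_training_error(self):
        rng = np.random.default_rng(0)
        X = rng.random((10, 2))
        d = np.r_[-np.ones(5), np.ones(5)]
        model = elm_train(X, d, n_hidden=10, rng_seed=3)
        _, scores = elm_predict(model, X)
        assert np.linalg.norm(scores - d) <= 1e-6
        labels, _ = elm_predict(model, X)
        np.testing.assert_array_equal(labels, d)

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        X, d = _blobs(rng)
        m1 = elm_train(X, d, rng_seed=5)
        m2 = elm_train(X, d, rng_seed=5)
        np.testing.assert_array_equal(m1.centers, m2.centers)
        np.testing.assert_array_equal(m1.output_weights, m2.output_weights)
        m3 = elm_train(X, d, rng_seed=6)
        assert not np.array_equal(m1.centers, m3.centers)

    def test_training_order_invariance(self):
        rng = np.random.default_rng(2)
        X, d = _blobs(rng)
        perm = rng.permutation(len(d))
        m1 = elm_train(X, d, rng_seed=0)
        m2 = elm_train(X[perm], d[perm], rng_seed=0)
        np.testing.assert_allclose(m1.centers, m2.centers)
        probe = rng.normal(1.0, 1.0, (5, 2))
        np.testing.assert_allclose(
            elm_predict(m1, probe)[1], elm_predict(m2, probe)[1], atol=1e-8
        )

    def test_xor_capacity(self):
        base = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        targets = np.array([-1.0, 1.0, 1.0, -1.0])
        rng = np.random.default_rng(42)
        X = np.repeat(base, 40, axis=0) + rng.normal(0, 0.05, (160, 2))
        d = np.repeat(targets, 40)
        successes = 0
        for seed in range(10):
            model = elm_train(X, d, n_hidden=10, rng_seed=seed)
            labels, _ = elm_predict(model, X)
            if np.mean(labels == d) >= 0.95:
                successes += 1
        assert successes >= 8

    def test_output_weights_solve_least_squares(self):
        # beta must achieve the oracle residual and have minimum norm
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X, d = _blobs(rng, n_per=8)
            model = elm_train(X, d, n_hidden=10, rng_seed=seed)
            M = model.hidden(X)
            beta_oracle, *_ = np.linalg.lstsq(M, d, rcond=None)
            r_model = np.linalg.norm(M @ model.output_weights - d)
            r_oracle = np.linalg.norm(M @ beta_oracle - d)
            assert r_model <= r_oracle + 1e-8
            assert np.linalg.norm(model.output_weights) <= (
                np.linalg.norm(beta_oracle) + 1e-6
            )

    def test_predict_matches_manual_forward_pass(self):
        rng = np.random.default_rng(3)
        X, d = _blobs(rng)
        model = elm_train(X, d, rng_seed=1)
        probe = rng.normal(size=(7, 2))
        sq = ((probe[:, None, :] - model.centers[None]) ** 2).sum(-1)
        oracle = np.exp(-model.widths[None, :] * sq) @ model.output_weights
        _, scores = elm_predict(model, probe)
        assert np.max(np.abs(scores - oracle)) <= 1e-10

    def test_score_continuity(self):
        rng = np.random.default_rng(4)
        X, d = _blobs(rng)
        model = elm_train(X, d, rng_seed=0)
        p = np.array([[1.0, 1.0]])
        s0 = elm_predict(model, p)[1][0]
        s1 = elm_predict(model, p + 1e-9)[1][0]
        assert abs(s1 - s0) <= 1e-6

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="single class"):
            elm_train(np.random.rand(6, 2), np.ones(6))

    def test_dimension_mismatch_errors(self):
        rng = np.random.default_rng(5)
        X, d = _blobs(rng)
        model = elm_train(X, d, rng_seed=0)
        with pytest.raises(ValueError, match="dimension"):
            elm_predict(model, np.zeros((3, 5)))


class TestSVM:
    def test_two_point_problem(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        d = np.array([-1.0, 1.0])
        model = svm_train(X, d, C=10.0, gamma=1.0)
        assert model.support_vectors.shape[0] == 2
        labels, _ = svm_predict(model, X)
        np.testing.assert_array_equal(labels, d)

    def test_separable_blobs_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X, d = _blobs(rng, n_per=15, sep=6.0)
        model = svm_train(X, d, C=1e3)
        labels, _ = svm_predict(model, X)
        assert np.mean(labels == d) == 1.0

    def test_dual_constraints_hold(self):
        rng = np.random.default_rng(1)
        X, d = _blobs(rng, sep=1.5)
        C = 2.0
        model = svm_train(X, d, C=C)
        alpha = np.abs(model.dual_coefs)
        assert np.all(alpha >= -1e-8)
        assert np.all(alpha <= C + 1e-8)
        assert abs(np.sum(model.dual_coefs)) <= 1e-6

    def test_dual_objective_matches_qp_oracle(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X, d = _blobs(rng, n_per=10, sep=2.5)
            C, gamma = 1.0, 1.0 / (2 * X.var())
            model = svm_train(X, d, C=C, gamma=gamma)
            sq = ((X[:, None, :] - X[None]) ** 2).sum(-1)
            Q = np.exp(-gamma * sq) * np.outer(d, d)
            alpha = np.zeros(len(d))
            for coef, sv in zip(model.dual_coefs, model.support_vectors):
                alpha[np.argmin(((X - sv) ** 2).sum(1))] = abs(coef)
            obj_model = alpha.sum() - 0.5 * alpha @ Q @ alpha
            res = minimize(
                lambda a: -(a.sum() - 0.5 * a @ Q @ a),
                np.full(len(d), 0.5),
                jac=lambda a: -(np.ones_like(a) - Q @ a),
                bounds=[(0.0, C)] * len(d),
                constraints=[{"type": "eq", "fun": lambda a: a @ d, "jac": lambda a: d}],
                method="SLSQP",
                options={"maxiter": 1000, "ftol": 1e-14},
            )
            assert obj_model == pytest.approx(-res.fun, abs=1e-6)

    def test_kkt_margins(self):
        rng = np.random.default_rng(2)
        X, d = _blobs(rng, n_per=15, sep=4.0)
        C = 10.0
        model = svm_train(X, d, C=C)
        _, margins = svm_predict(model, X)
        alpha = np.zeros(len(d))
        for coef, sv in zip(model.dual_coefs, model.support_vectors):
            alpha[np.argmin(((X - sv) ** 2).sum(1))] = abs(coef)
        on_margin = (alpha > 1e-6) & (alpha < C - 1e-6)
        assert np.all(np.abs(np.abs(margins[on_margin]) - 1.0) <= 1e-4)
        non_sv = alpha <= 1e-6
        assert np.all(np.abs(margins[non_sv]) >= 1.0 - 1e-4)

    def test_predict_matches_kernel_sum_oracle(self):
        rng = np.random.default_rng(3)
        X, d = _blobs(rng)
        model = svm_train(X, d)
        probe = rng.normal(1.0, 2.0, size=(9, 2))
        oracle = np.array(
            [
                sum(
                    coef * np.exp(-model.gamma * np.sum((p - sv) ** 2))
                    for coef, sv in zip(model.dual_coefs, model.support_vectors)
                )
                + model.bias
                for p in probe
            ]
        )
        _, margins = svm_predict(model, probe)
        assert np.max(np.abs(margins - oracle)) <= 1e-10

    def test_slack_nonnegative_and_zero_when_separable(self):
        rng = np.random.default_rng(4)
        X, d = _blobs(rng, sep=8.0)
        model = svm_train(X, d, C=1e3)
        assert np.all(model.slack >= 0)
        assert np.max(model.slack) <= 1e-3


class TestSupport:
    def test_encode_labels(self):
        np.testing.assert_array_equal(
            encode_labels(["abnormal", "normal"]), [1.0, -1.0]
        )
        with pytest.raises(ValueError):
            encode_labels(["weird"])

    def test_scaler_fit_transform(self, rng):
        X = rng.normal(3.0, 2.0, size=(50, 3))
        sc = FeatureScaler.fit(X)
        Z = sc.transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)

    def test_model_json_round_trip(self, tmp_path, rng):
        X, d = _blobs(rng)
        for model in (elm_train(X, d, rng_seed=0), svm_train(X, d)):
            path = tmp_path / "m.json"
            save_model(model, path)
            back = load_model(path)
            probe = rng.normal(size=(4, 2))
            if isinstance(back, ELMModel):
                np.testing.assert_array_equal(
                    elm_predict(model, probe)[1], elm_predict(back, probe)[1]
                )
            else:
                np.testing.assert_array_equal(
                    svm_predict(model, probe)[1], svm_predict(back, probe)[1]
                )
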