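"""Prediction-model fitting: splits, bivariate regression, constant
centroid correction and the shallow network."""

import numpy as np
import pytest

from reccp import (
    MODALITIES,
    NetConfig,
    SingularDesignError,
    fit_bivariate_regression,
    fit_constant_model,
    fit_shallow_net,
    load_model,
    predict_linear,
    predict_net,
    published_models,
    save_model,
    split_dataset,
)


class TestSplit:
    def test_study_sizes(self):
        s = split_dataset(509, seed=1)
        assert (len(s.train), len(s.validation), len(s.test)) == (305, 102, 102)

    def test_small_n(self):
        s = split_dataset(10, seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == (6, 2, 2)

    def test_partition_and_determinism(self):
        a = split_dataset(509, seed=5)
        b = split_dataset(509, seed=5)
        c = split_dataset(509, seed=6)
        assert np.array_equal(a.train, b.train)
        assert not np.array_equal(a.train, c.train)
        union = np.concatenate([a.train, a.validation, a.test])
        assert sorted(union) == list(range(509))

    def test_too_small(self):
        with pytest.raises(ValueError):
            split_dataset(4, seed=0)


class TestBivariateRegression:
    def test_identity_data(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 2))
        m = fit_bivariate_regression(X, X)
        assert np.allclose(m.A, np.eye(2), atol=1e-10)
        assert np.allclose(m.b, 0.0, atol=1e-10)

    def test_residual_centroid_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 2))
        Y = X @ np.array([[0.5, 0.1], [0.0, 0.4]]).T + [-0.3, 0.05] + rng.normal(
            0, 0.3, size=(120, 2)
        )
        m = fit_bivariate_regression(X, Y)
        resid = Y - m.predict(X)
        assert np.allclose(resid.mean(axis=0), 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        """OLS solution equals the directly solved normal equations."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 2))
        Y = rng.normal(size=(80, 2))
        m = fit_bivariate_regression(X, Y)
        D = np.column_stack([X, np.ones(80)])
        beta = np.linalg.solve(D.T @ D, D.T @ Y)
        assert np.allclose(m.A, beta[:2].T, atol=1e-8)
        assert np.allclose(m.b, beta[2], atol=1e-8)

    def test_loglik_closed_form(self):
        """logL matches the bivariate normal density summed at the ML fit."""
        from scipy.stats import multivariate_normal

        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 2))
        Y = X * 0.5 + rng.normal(0, 0.2, size=(60, 2))
        m = fit_bivariate_regression(X, Y)
        resid = Y - m.predict(X)
        sigma = resid.T @ resid / len(resid)
        expected = multivariate_normal(mean=[0, 0], cov=sigma).logpdf(resid).sum()
        assert m.logL == pytest.approx(expected, rel=1e-10)

    def test_parameter_recovery(self):
        """Recovers the generating (A0, b0) within 3 analytic standard errors."""
        rng = np.random.default_rng(4)
        A0 = np.array([[0.54, 0.07], [-0.01, 0.38]])
        b0 = np.array([-0.30, -0.04])
        sigma = 0.3
        X = rng.normal(0, 0.8, size=(2000, 2))
        Y = X @ A0.T + b0 + rng.normal(0, sigma, size=(2000, 2))
        m = fit_bivariate_regression(X, Y)
        D = np.column_stack([X, np.ones(2000)])
        se = sigma * np.sqrt(np.diag(np.linalg.inv(D.T @ D)))  # per-column SEs
        for j in range(2):  # output component
            assert abs(m.A[j, 0] - A0[j, 0]) < 3 * se[0]
            assert abs(m.A[j, 1] - A0[j, 1]) < 3 * se[1]
            assert abs(m.b[j] - b0[j]) < 3 * se[2]

    def test_collinear_rejected(self):
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(SingularDesignError):
            fit_bivariate_regression(X, X)

    def test_predict_shapes(self):
        m = published_models()["IOLMK"]
        single = predict_linear(m, np.array([0.5, -0.2]))
        batch = predict_linear(m, np.array([[0.5, -0.2], [0.0, 0.0]]))
        assert single.shape == (2,)
        assert np.allclose(batch[0], single)


class TestPublishedModels:
    def test_intercepts_and_matrix(self):
        pub = published_models()
        assert np.allclose(pub["IOLMK"].predict(np.zeros(2)), [-0.304, -0.043])
        sens = pub["IOLMK"].predict(np.array([1.0, 0.0])) - pub["IOLMK"].predict(np.zeros(2))
        assert np.allclose(sens, [0.543, -0.01])
        assert pub["IOLMK"].A[0, 0] == 0.543
        assert np.allclose(pub["CorTTP"].b, [-0.236, -0.024])

    def test_all_modalities_present_with_shrinking_diagonals(self):
        pub = published_models()
        assert set(pub) == set(MODALITIES)
        for m in pub.values():
            assert m.A[0, 0] < 1.0 and m.A[1, 1] < 1.0  # astigmatism shrinkage
            assert np.isfinite(m.logL)


class TestConstantModel:
    def test_cohort_centroid_offset(self):
        """Offset from the published IOLMK and recCP centroids is the
        printed (-0.32, 0.01) dpt correction after rounding."""
        X = np.array([[0.0046, -0.0598]])
        Y = np.array([[-0.3149, -0.0498]])
        m = fit_constant_model(X, Y)
        assert np.allclose(m.offset, [-0.3195, 0.0100], atol=1e-10)
        assert tuple(np.round(m.offset, 2)) == (-0.32, 0.01)

    def test_identity_when_equal(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        assert np.allclose(fit_constant_model(X, X).offset, 0.0)

    def test_leaves_spread_unchanged(self):
        from reccp import error_ellipse_95

        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 2))
        Y = X @ np.diag([0.5, 0.4]) + rng.normal(0, 0.3, size=(200, 2)) + [-0.3, 0.1]
        m = fit_constant_model(X, Y)
        raw = error_ellipse_95(Y - X).area
        corrected = error_ellipse_95(Y - m.predict(X)).area
        assert corrected == pytest.approx(raw, abs=1e-10)


class TestShallowNet:
    def _linear_data(self, n=400, sigma=0.2, seed=0):
        rng = np.random.default_rng(seed)
        A = np.array([[0.54, 0.07], [-0.01, 0.38]])
        X = rng.normal(0, 0.8, size=(n, 2))
        Y = X @ A.T + [-0.3, -0.04] + rng.normal(0, sigma, size=(n, 2))
        return X, Y

    def test_linear_ground_truth_matches_ols(self):
        """On truly linear data the net's test MSE is within 10% of OLS."""
        X, Y = self._linear_data(n=600, seed=1)
        Xt, Yt = self._linear_data(n=400, seed=2)
        net = fit_shallow_net(X[:400], Y[:400], X[400:], Y[400:], NetConfig(seed=3))
        lin = fit_bivariate_regression(X[:400], Y[:400])
        mse_net = float(np.mean(np.sum((predict_net(net, Xt) - Yt) ** 2, axis=1)))
        mse_lin = float(np.mean(np.sum((lin.predict(Xt) - Yt) ** 2, axis=1)))
        assert mse_net <= 1.10 * mse_lin

    def test_nonlinear_beats_linear_on_training(self):
        """With a saturating ground truth the net fits strictly better."""
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1.0, size=(500, 2))
        Y = np.tanh(1.5 * X) + rng.normal(0, 0.05, size=(500, 2))
        net = fit_shallow_net(X[:350], Y[:350], X[350:], Y[350:], NetConfig(seed=7))
        lin = fit_bivariate_regression(X[:350], Y[:350])
        mse_net = float(np.mean(np.sum((predict_net(net, X[:350]) - Y[:350]) ** 2, axis=1)))
        mse_lin = float(np.mean(np.sum((lin.predict(X[:350]) - Y[:350]) ** 2, axis=1)))
        assert mse_net < mse_lin

    def test_zero_epoch_training(self):
        X, Y = self._linear_data(n=40)
        net = fit_shallow_net(X[:30], Y[:30], X[30:], Y[30:], NetConfig(max_epochs=0, seed=0))
        assert np.isfinite(predict_net(net, X)).all()
        assert net.epochs_run == 0

    def test_deterministic_given_seed(self):
        X, Y = self._linear_data(n=60)
        cfg = NetConfig(seed=11, max_epochs=50)
        a = fit_shallow_net(X[:40], Y[:40], X[40:], Y[40:], cfg)
        b = fit_shallow_net(X[:40], Y[:40], X[40:], Y[40:], cfg)
        assert np.array_equal(predict_net(a, X), predict_net(b, X))

    def test_batch_equals_single(self):
        X, Y = self._linear_data(n=60)
        net = fit_shallow_net(X[:40], Y[:40], X[40:], Y[40:], NetConfig(max_epochs=100, seed=0))
        batch = predict_net(net, X[:5])
        for i in range(5):
            assert np.allclose(predict_net(net, X[i]), batch[i])

    def test_architecture(self):
        X, Y = self._linear_data(n=40)
        net = fit_shallow_net(X[:30], Y[:30], X[30:], Y[30:], NetConfig(max_epochs=1, seed=0))
        shapes = [w.shape for w in net.weights]
        assert shapes == [(2, 12), (12, 12), (12, 2)]


class TestSerialization:
    def test_round_trip_all_kinds(self, tmp_path):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 2))
        Y = X * 0.5 + rng.normal(0, 0.1, size=(50, 2))
        models = {
            "lin": fit_bivariate_regression(X, Y),
            "const": fit_constant_model(X, Y),
            "net": fit_shallow_net(X[:35], Y[:35], X[35:], Y[35:], NetConfig(max_epochs=50, seed=1)),
        }
        probe = np.array([0.3, -0.4])
        for name, model in models.items():
            path = tmp_path / f"{name}.json"
            save_model(model, path)
            loaded = load_model(path)
            assert np.allclose(loaded.predict(probe), model.predict(probe), atol=1e-12)

    def test_unknown_kind(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"kind": "mystery"}')
        with pytest.raises(ValueError, match="unknown model kind"):
            load_model(p)
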