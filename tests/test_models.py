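import numpy as np
import pytest
from scipy import sparse
from sklearn.svm import SVC

from fpkit.models import (
    MLP,
    TrainConfig,
    count_parameters,
    fit_platt,
    load_model,
    platt_probability,
    predict_probabilities,
    primal_to_dual,
    prior_platt_params,
    save_model,
    train_deep_kernel,
    train_nystrom_svm,
    train_spectrum_dnn,
)
from fpkit.nystrom import NystromProjection


@pytest.fixture
def separable_2d(rng):
    X = np.vstack(
        [rng.normal([2.0, 2.0], 0.3, (25, 2)), rng.normal([-2.0, -2.0], 0.3, (25, 2))]
    )
    Y = np.array([1.0] * 25 + [0.0] * 25).reshape(-1, 1)
    return X, Y


class TestCountParameters:
    def test_deep_kernel_size(self):
        assert count_parameters([28000, 2500, 8000, 5220]) == 131_760_000

    def test_linear_svm_size(self):
        assert count_parameters([28000, 5220]) == 146_160_000

    def test_spectrum_dnn_size(self):
        assert count_parameters([102093, 2500, 8000, 5220]) == 316_992_500

    def test_bias_inclusion(self):
        assert count_parameters([3, 2], include_bias=True) == 8

    def test_additive_over_splits(self):
        assert count_parameters([7, 5, 3]) == count_parameters(
            [7, 5]
        ) + count_parameters([5, 3])

    def test_invalid_dims(self):
        with pytest.raises(ValueError):
            count_parameters([5])
        with pytest.raises(ValueError):
            count_parameters([5, 0])


class TestNystromSVM:
    def test_separable_training_accuracy(self, separable_2d):
        X, Y = separable_2d
        cfg = TrainConfig(
            epochs=200, learning_rate=1e-2, batch_size=10, seed=0, svm_C=10.0
        )
        model = train_nystrom_svm(X, Y, cfg=cfg)
        pred = model.mlp.decision_values(X) > 0
        assert (pred.astype(float) == Y).mean() == 1.0

    def test_matches_qp_oracle_sign_pattern(self, separable_2d):
        X, Y = separable_2d
        cfg = TrainConfig(
            epochs=200, learning_rate=1e-2, batch_size=10, seed=0, svm_C=10.0
        )
        model = train_nystrom_svm(X, Y, cfg=cfg)
        sgd_signs = np.sign(model.mlp.decision_values(X)).ravel()
        oracle = SVC(kernel="linear", C=10.0).fit(X, Y.ravel())
        qp_signs = np.sign(oracle.decision_function(X))
        np.testing.assert_array_equal(sgd_signs, qp_signs)

    def test_zero_epochs_zero_weights(self, separable_2d):
        X, Y = separable_2d
        model = train_nystrom_svm(X, Y, cfg=TrainConfig(epochs=0))
        assert (model.mlp.weights[-1] == 0).all()
        assert (model.mlp.biases[-1] == 0).all()

    def test_seed_determinism(self, separable_2d):
        X, Y = separable_2d
        cfg = TrainConfig(epochs=20, batch_size=8, seed=3)
        m1 = train_nystrom_svm(X, Y, cfg=cfg)
        m2 = train_nystrom_svm(X, Y, cfg=cfg)
        np.testing.assert_array_equal(m1.mlp.weights[-1], m2.mlp.weights[-1])

    def test_single_class_label_flagged_constant(self, separable_2d):
        X, Y = separable_2d
        Y2 = np.hstack([Y, np.ones_like(Y)])
        model = train_nystrom_svm(X, Y2, cfg=TrainConfig(epochs=5))
        assert model.constant_labels == ["label_1"]
        probs = predict_probabilities(model, X)
        assert np.allclose(probs[:, 1], probs[0, 1])

    def test_sample_weights_shift_boundary(self, rng):
        # one mislabeled point with huge weight must dominate the fit
        X = np.array([[1.0], [2.0], [3.0], [-1.0], [-2.0], [-3.0]])
        Y = np.array([[1], [1], [1], [0], [0], [0]], dtype=float)
        w_up = np.array([1, 1, 1, 100.0, 1, 1])
        cfg = TrainConfig(epochs=300, learning_rate=1e-2, batch_size=6, seed=0)
        m = train_nystrom_svm(X, Y, weights=w_up, cfg=cfg)
        m0 = train_nystrom_svm(X, Y, cfg=cfg)
        # upweighting a negative point pushes its decision value down
        d_up = m.mlp.decision_values(X[3:4])[0, 0]
        d_base = m0.mlp.decision_values(X[3:4])[0, 0]
        assert d_up < d_base


class TestPrimalToDual:
    def _projection(self, rng, m=12, r=6):
        A = rng.normal(size=(m, m))
        K = A @ A.T
        from fpkit.kernels import KernelMatrix
        from fpkit.nystrom import fit_projection

        return fit_projection(
            KernelMatrix([f"c{i}" for i in range(m)], [f"c{i}" for i in range(m)], K),
            max_rank=r,
        )

    def test_zero_weights_zero_coefficients(self, rng, separable_2d):
        proj = self._projection(rng)
        X = rng.normal(size=(10, proj.rank))
        Y = (rng.random((10, 3)) < 0.5).astype(float)
        Y[0] = [1, 1, 1]
        Y[1] = [0, 0, 0]
        model = train_nystrom_svm(X, Y, cfg=TrainConfig(epochs=0))
        dual = primal_to_dual(model, proj)
        assert (dual.support_coefficients == 0).all()

    def test_dual_matches_primal_on_random_inputs(self, rng):
        proj = self._projection(rng)
        n, L = 30, 4
        K_rows = rng.normal(size=(n, len(proj.landmark_ids)))
        X = K_rows @ proj.gamma
        Y = (rng.random((n, L)) < 0.5).astype(float)
        Y[0], Y[1] = 1.0, 0.0
        model = train_nystrom_svm(
            X, Y, cfg=TrainConfig(epochs=30, batch_size=8, seed=1)
        )
        dual = primal_to_dual(model, proj)
        K_test = rng.normal(size=(20, len(proj.landmark_ids)))
        primal = model.mlp.decision_values(K_test @ proj.gamma)
        via_dual = dual.decision_values(K_test)
        np.testing.assert_allclose(via_dual, primal, atol=1e-6)

    def test_identity_projection_gives_centered_weights(self, rng):
        m = 5
        proj = NystromProjection(
            landmark_ids=[f"c{i}" for i in range(m)],
            gamma=np.eye(m),
            eigenvalues=np.ones(m),
            eig_floor=1e-10,
        )
        X = rng.normal(size=(20, m))
        Y = (rng.random((20, 2)) < 0.5).astype(float)
        Y[0], Y[1] = 1.0, 0.0
        model = train_nystrom_svm(X, Y, cfg=TrainConfig(epochs=10, seed=0))
        dual = primal_to_dual(model, proj)
        W = model.mlp.weights[-1]
        np.testing.assert_allclose(
            dual.support_coefficients, W - W.mean(axis=0, keepdims=True), atol=1e-12
        )
        assert np.allclose(dual.support_coefficients.sum(axis=0), 0.0, atol=1e-10)

    def test_kind_mismatch_errors(self, rng):
        proj = self._projection(rng)
        X = rng.normal(size=(10, proj.rank))
        Y = (rng.random((10, 2)) < 0.5).astype(float)
        Y[0], Y[1] = 1.0, 0.0
        model = train_deep_kernel(
            X, Y, cfg=TrainConfig(hidden_sizes=[4], epochs=1, batch_size=5)
        )
        with pytest.raises(ValueError, match="SVM"):
            primal_to_dual(model, proj)


class TestPlatt:
    def test_symmetric_separation_gives_zero_B(self):
        d = np.array([1.0] * 50 + [-1.0] * 50)
        y = np.array([1] * 50 + [0] * 50)
        A, B = fit_platt(d, y)
        assert abs(B) < 1e-3
        assert A < 0

    def test_monotone_in_decision_value(self):
        d = np.linspace(-3, 3, 50)
        y = (d + np.sin(d) > 0).astype(int)
        A, B = fit_platt(d, y)
        p = platt_probability(np.linspace(-5, 5, 100), A, B)
        assert (np.diff(p) > 0).all()

    def test_label_inversion_flips_A(self, rng):
        d = rng.normal(size=200)
        y = (d + rng.normal(scale=0.5, size=200) > 0).astype(int)
        A1, _ = fit_platt(d, y)
        A2, _ = fit_platt(d, 1 - y)
        assert np.sign(A1) == -np.sign(A2)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_platt(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_prior_params_constant_probability(self):
        A, B = prior_platt_params(0.25)
        p = platt_probability(np.array([-10.0, 0.0, 10.0]), A, B)
        np.testing.assert_allclose(p, 0.25, atol=1e-12)


class TestDeepKernel:
    def _toy(self, rng, n=40, d=6, L=3):
        X = rng.normal(size=(n, d))
        W = rng.normal(size=(d, L))
        Y = (X @ W > 0).astype(float)
        return X, Y

    def test_zero_epochs_outputs_half(self, rng):
        X, Y = self._toy(rng)
        model = train_deep_kernel(
            X, Y, cfg=TrainConfig(hidden_sizes=[8], epochs=0)
        )
        probs = predict_probabilities(model, X)
        np.testing.assert_allclose(probs, 0.5)

    def test_loss_decreases_after_first_epoch(self, rng):
        X, Y = self._toy(rng)
        cfg = TrainConfig(hidden_sizes=[16], epochs=1, batch_size=10, seed=2,
                          dropout_rate=0.0)
        mlp_init = MLP([X.shape[1], 16, Y.shape[1]], seed=cfg.seed)
        loss0 = mlp_init.dataset_loss(X, Y, np.ones(len(X)))
        model = train_deep_kernel(X, Y, cfg=cfg)
        loss1 = model.mlp.dataset_loss(X, Y, np.ones(len(X)))
        assert loss1 < loss0

    def test_seed_determinism(self, rng):
        X, Y = self._toy(rng)
        cfg = TrainConfig(hidden_sizes=[8, 8], epochs=3, batch_size=8, seed=5)
        p1 = predict_probabilities(train_deep_kernel(X, Y, cfg=cfg), X)
        p2 = predict_probabilities(train_deep_kernel(X, Y, cfg=cfg), X)
        np.testing.assert_array_equal(p1, p2)

    def test_empty_hidden_degrades_to_linear(self, rng, caplog):
        X, Y = self._toy(rng)
        with caplog.at_level("WARNING"):
            model = train_deep_kernel(
                X, Y, cfg=TrainConfig(hidden_sizes=[], epochs=1)
            )
        assert model.layer_dims == [X.shape[1], Y.shape[1]]
        assert "linear" in caplog.text

    def test_single_sgd_step_matches_hand_gradient(self):
        # 2-unit toy network, no dropout, no l2, one batch, one epoch of SGD.
        X = np.array([[1.0, -2.0], [0.5, 1.0], [-1.0, 0.0]])
        Y = np.array([[1.0], [0.0], [1.0]])
        lr = 0.1
        mlp = MLP([2, 2, 1], seed=42, dropout_rate=0.0, l2_output=0.0)
        W1, b1 = mlp.weights[0].copy(), mlp.biases[0].copy()
        W2, b2 = mlp.weights[1].copy(), mlp.biases[1].copy()

        # hand-computed forward/backward for weighted-mean sigmoid CE
        H_pre = X @ W1 + b1
        H = np.maximum(H_pre, 0.0)
        Z = H @ W2 + b2
        P = 1.0 / (1.0 + np.exp(-Z))
        dZ = (P - Y) / len(X)
        gW2 = H.T @ dZ
        gb2 = dZ.sum(axis=0)
        dH = (dZ @ W2.T) * (H > 0)
        gW1 = X.T @ dH
        gb1 = dH.sum(axis=0)

        mlp.fit(X, Y, epochs=1, batch_size=3, learning_rate=lr, optimizer="sgd",
                seed=0)
        np.testing.assert_allclose(mlp.weights[0], W1 - lr * gW1, atol=1e-6)
        np.testing.assert_allclose(mlp.biases[0], b1 - lr * gb1, atol=1e-6)
        np.testing.assert_allclose(mlp.weights[1], W2 - lr * gW2, atol=1e-6)
        np.testing.assert_allclose(mlp.biases[1], b2 - lr * gb2, atol=1e-6)

    def test_gradients_match_finite_differences(self, rng):
        X = rng.normal(size=(6, 3))
        Y = (rng.random((6, 2)) < 0.5).astype(float)
        sw = rng.uniform(0.5, 2.0, size=6)
        mlp = MLP([3, 4, 2], seed=1, dropout_rate=0.0, l2_output=1e-3)
        _, gW, gb = mlp.loss_and_grads(X, Y, sw)
        eps = 1e-6
        for layer in range(2):
            W = mlp.weights[layer]
            idx = (0, 0)
            orig = W[idx]
            W[idx] = orig + eps
            up, _, _ = mlp.loss_and_grads(X, Y, sw)
            W[idx] = orig - eps
            down, _, _ = mlp.loss_and_grads(X, Y, sw)
            W[idx] = orig
            fd = (up - down) / (2 * eps)
            assert gW[layer][idx] == pytest.approx(fd, abs=1e-5)


class TestSpectrumDNN:
    def test_sparse_input_accepted(self, rng):
        X = sparse.random(30, 50, density=0.1, random_state=7, format="csr")
        Y = (rng.random((30, 2)) < 0.5).astype(float)
        model = train_spectrum_dnn(
            X, Y, cfg=TrainConfig(hidden_sizes=[8], epochs=2, batch_size=10)
        )
        probs = predict_probabilities(model, X)
        assert probs.shape == (30, 2)

    def test_all_zero_spectra_constant_predictions(self, rng):
        X = np.zeros((20, 10))
        Y = (rng.random((20, 3)) < 0.5).astype(float)
        model = train_spectrum_dnn(
            X, Y, cfg=TrainConfig(hidden_sizes=[4], epochs=3, batch_size=5)
        )
        probs = predict_probabilities(model, X)
        assert np.allclose(probs, probs[0])

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(20, 10))
        Y = (rng.random((20, 2)) < 0.5).astype(float)
        cfg = TrainConfig(hidden_sizes=[6], epochs=2, batch_size=7, seed=11)
        p1 = predict_probabilities(train_spectrum_dnn(X, Y, cfg=cfg), X)
        p2 = predict_probabilities(train_spectrum_dnn(X, Y, cfg=cfg), X)
        np.testing.assert_array_equal(p1, p2)


class TestPredictProbabilities:
    def test_outputs_in_unit_interval(self, rng):
        X = rng.normal(size=(15, 4))
        Y = (rng.random((15, 3)) < 0.5).astype(float)
        Y[0], Y[1] = 1.0, 0.0
        for trainer in (train_deep_kernel, train_nystrom_svm):
            cfg = TrainConfig(hidden_sizes=[4], epochs=2, batch_size=5)
            probs = predict_probabilities(trainer(X, Y, cfg=cfg), X)
            assert ((probs >= 0) & (probs <= 1)).all()

    def test_svm_probability_monotone_in_decision(self, rng):
        X = rng.normal(size=(30, 2))
        Y = (X[:, :1] > 0).astype(float)
        model = train_nystrom_svm(
            X, Y, cfg=TrainConfig(epochs=50, learning_rate=1e-2, batch_size=10)
        )
        d = model.mlp.decision_values(X)[:, 0]
        p = predict_probabilities(model, X)[:, 0]
        order = np.argsort(d)
        assert (np.diff(p[order]) >= -1e-12).all()

    def test_inference_deterministic_despite_dropout(self, rng):
        X = rng.normal(size=(10, 5))
        Y = (rng.random((10, 2)) < 0.5).astype(float)
        model = train_deep_kernel(
            X, Y, cfg=TrainConfig(hidden_sizes=[8], dropout_rate=0.5, epochs=2,
                                  batch_size=5)
        )
        np.testing.assert_array_equal(
            predict_probabilities(model, X), predict_probabilities(model, X)
        )


class TestSerialization:
    def test_roundtrip_svm(self, rng, tmp_path):
        X = rng.normal(size=(20, 3))
        Y = (rng.random((20, 2)) < 0.5).astype(float)
        Y[0], Y[1] = 1.0, 0.0
        model = train_nystrom_svm(X, Y, cfg=TrainConfig(epochs=5))
        path = tmp_path / "model.h5"
        save_model(model, path)
        back = load_model(path)
        assert back.kind == "nystrom_svm"
        np.testing.assert_array_equal(
            predict_probabilities(back, X), predict_probabilities(model, X)
        )

    def test_roundtrip_deep_kernel(self, rng, tmp_path):
        X = rng.normal(size=(15, 4))
        Y = (rng.random((15, 3)) < 0.5).astype(float)
        model = train_deep_kernel(
            X, Y, cfg=TrainConfig(hidden_sizes=[6, 5], epochs=2, batch_size=5)
        )
        path = tmp_path / "dk.h5"
        save_model(model, path)
        back = load_model(path)
        assert back.layer_dims == model.layer_dims
        np.testing.assert_allclose(
            predict_probabilities(back, X), predict_probabilities(model, X)
        )
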