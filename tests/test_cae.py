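"""Autoencoder classifier: encoder/decoder algebra, gradient
correctness, SGD behavior and the softmax head."""

import numpy as np
import pytest

from mihawk import cae


def _params(W, b, W_hat, b_hat, Wc=None, bc=None):
    m, d = W.shape
    k = 2 if Wc is None else Wc.shape[0]
    return cae.CAEParams(W=W, b=b, W_hat=W_hat, b_hat=b_hat,
                         Wc=np.zeros((k, m)) if Wc is None else Wc,
                         bc=np.zeros(k) if bc is None else bc)


class TestPrimitives:
    @pytest.mark.parametrize("x,expect", [(-1.0, 0.0), (2.0, 2.0), (0.0, 0.0)])
    def test_relu(self, x, expect):
        assert cae.relu(x) == expect

    def test_encode_zero_parameters_give_zero_code(self):
        p = _params(np.zeros((3, 4)), np.zeros(3), np.zeros((4, 3)),
                    np.zeros(4))
        np.testing.assert_allclose(cae.encode(np.ones(4), p), 0.0)

    def test_encode_single_unit_kernel(self):
        p = _params(np.array([[1.0]]), np.zeros(1), np.array([[1.0]]),
                    np.zeros(1))
        assert cae.encode(np.array([0.5]), p) == pytest.approx(0.5)

    def test_encode_nonnegative_for_random_draws(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = _params(rng.standard_normal((4, 6)), rng.standard_normal(4),
                        rng.standard_normal((6, 4)), rng.standard_normal(6))
            assert np.all(cae.encode(rng.standard_normal(6), p) >= 0.0)

    def test_decode_zero_code_zero_bias(self):
        p = _params(np.zeros((3, 4)), np.zeros(3), np.ones((4, 3)),
                    np.zeros(4))
        np.testing.assert_allclose(cae.decode(np.zeros(3), p), 0.0)

    def test_orthogonal_encoder_transpose_decoder_roundtrip(self):
        # rotation matrix is unitary; positive codes stay unclipped
        theta = 0.3
        Q = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        p = _params(Q, np.zeros(2), Q.T, np.zeros(2))
        x = np.array([2.0, 1.0])          # chosen so Qx > 0 elementwise
        assert np.all(Q @ x > 0)
        np.testing.assert_allclose(cae.decode(cae.encode(x, p), p), x,
                                   atol=1e-12)

    def test_decode_shape_matches_patch(self):
        rng = np.random.default_rng(1)
        p = _params(rng.standard_normal((5, 7)), rng.standard_normal(5),
                    rng.standard_normal((7, 5)), rng.standard_normal(7))
        assert cae.decode(cae.encode(rng.standard_normal(7), p), p).shape == (7,)


class TestReconstructionCost:
    def test_perfect_reconstruction_costs_zero(self):
        Q = np.eye(3)
        p = _params(Q, np.zeros(3), Q, np.zeros(3))
        patches = np.abs(np.random.default_rng(0).standard_normal((5, 3)))
        assert cae.reconstruction_cost(patches, p) == pytest.approx(0.0)

    def test_single_patch_squared_norm(self):
        p = _params(np.zeros((2, 2)), np.zeros(2), np.zeros((2, 2)),
                    np.zeros(2))
        assert cae.reconstruction_cost(np.array([[1.0, 0.0]]), p) == 1.0

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        p = _params(rng.standard_normal((3, 4)), rng.standard_normal(3),
                    rng.standard_normal((4, 3)), rng.standard_normal(4))
        patches = rng.standard_normal((6, 4))
        assert cae.reconstruction_cost(patches, p) == pytest.approx(
            cae.reconstruction_cost(patches[::-1], p))

    def test_empty_patchset_rejected(self):
        p = _params(np.zeros((2, 2)), np.zeros(2), np.zeros((2, 2)),
                    np.zeros(2))
        with pytest.raises(ValueError):
            cae.reconstruction_cost(np.empty((0, 2)), p)


class TestGradients:
    def test_analytic_matches_central_differences(self):
        rng = np.random.default_rng(5)
        cfg = cae.CAEConfig(n_kernels=1, patch_len=3, num_classes=2)
        params = cae.CAEParams.init(cfg, rng)
        # non-zero random values everywhere so no ReLU kink sits at 0
        for arr in params.arrays().values():
            arr += 0.1 * rng.standard_normal(arr.shape) + 0.05
        X = rng.standard_normal((4, 2, 3))     # 4 samples, 2 patches
        y = np.zeros((4, 2))
        y[np.arange(4), rng.integers(0, 2, 4)] = 1.0

        def loss():
            j, ce, _ = cae._forward_backward(params, X, y, cfg.lambda_ce)
            return j + cfg.lambda_ce * ce

        _, _, grads = cae._forward_backward(params, X, y, cfg.lambda_ce)
        eps = 1e-6
        for name, arr in params.arrays().items():
            num = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = arr[i]
                arr[i] = orig + eps
                hi = loss()
                arr[i] = orig - eps
                lo = loss()
                arr[i] = orig
                num[i] = (hi - lo) / (2 * eps)
            scale = np.maximum(np.abs(num), 1e-8)
            rel = np.max(np.abs(grads[name] - num) / scale)
            assert rel < 1e-4, f"{name}: rel err {rel}"


class TestTraining:
    @staticmethod
    def _toy(seed, n=20, L=8):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, L))
        y = np.where(X[:, 0] > 0, "a", "b")
        return X, y

    def test_zero_learning_rate_leaves_parameters(self):
        X, y = self._toy(0)
        cfg = cae.CAEConfig(lr=0.0, epochs=3, seed=1)
        clf = cae.CAEClassifier(cfg).fit(X, y)
        fresh = cae.CAEParams.init(cfg, np.random.default_rng(1))
        for name, arr in clf.params.arrays().items():
            np.testing.assert_array_equal(arr, fresh.arrays()[name])

    def test_fixed_seed_reproducible_trace(self):
        X, y = self._toy(1)
        cfg = cae.CAEConfig(epochs=4, seed=3)
        t1 = cae.CAEClassifier(cfg).fit(X, y).loss_trace
        t2 = cae.CAEClassifier(cfg).fit(X, y).loss_trace
        assert t1 == t2

    def test_sgd_reduces_reconstruction_loss(self):
        # 100-patch synthetic set; unsupervised reconstruction only
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((25, 16))       # 25 x 4 patches of len 4
            cfg = cae.CAEConfig(n_kernels=8, patch_len=4, lr=0.01,
                                epochs=10, seed=seed, lambda_ce=0.0)
            clf = cae.CAEClassifier(cfg).fit(X, ["a"] * 25)
            trace = clf.loss_trace
            wins += trace[-1]["j_cae"] < trace[0]["j_cae"]
        assert wins >= 19

    def test_divergence_raises_with_diagnostics(self):
        X, y = self._toy(2)
        cfg = cae.CAEConfig(lr=50.0, epochs=5, seed=0)
        with pytest.raises(RuntimeError, match="diverged"):
            cae.CAEClassifier(cfg).fit(X, y)


class TestClassification:
    def test_untrained_head_rejected(self):
        with pytest.raises(cae.UntrainedModelError):
            cae.CAEClassifier().predict(np.ones((1, 8)))

    def test_uniform_scores_for_zero_logits(self):
        cfg = cae.CAEConfig(n_kernels=4, patch_len=4, num_classes=2)
        clf = cae.CAEClassifier(cfg)
        clf.params = cae.CAEParams.init(cfg, np.random.default_rng(0))
        clf.params.Wc[:] = 0.0
        clf.params.bc[:] = 0.0
        clf.classes_ = ["a", "b"]
        np.testing.assert_allclose(clf.predict_proba(np.ones((3, 4))),
                                   0.5)

    def test_score_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((10, 8))
        y = np.where(X[:, 0] > 0, "a", "b")
        clf = cae.CAEClassifier(cae.CAEConfig(epochs=3, seed=0)).fit(X, y)
        rows = clf.predict_proba(rng.standard_normal((7, 8))).sum(axis=1)
        np.testing.assert_allclose(rows, 1.0, atol=1e-6)

    def test_separable_toy_reaches_perfect_accuracy(self):
        rng = np.random.default_rng(6)
        n = 40
        X = np.zeros((n, 4))
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        X[:n // 2, 0] = 2.0 + 0.1 * rng.standard_normal(n // 2)
        X[n // 2:, 1] = 2.0 + 0.1 * rng.standard_normal(n // 2)
        cfg = cae.CAEConfig(n_kernels=8, patch_len=4, lr=0.1, epochs=30,
                            seed=0)
        clf = cae.CAEClassifier(cfg).fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0
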