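"""Gradient checks for the autodiff core and oracles for the special layers."""

import numpy as np
import pytest

from ehrsynth.nn import (
    Adam,
    BatchNorm1d,
    Dense,
    MinibatchDiscrimination,
    SpectralNormDense,
    Tensor,
    concat,
    minibatch_features,
    spectral_normalize,
)
from ehrsynth.nn.autograd import minibatch_similarity


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    for idx in np.ndindex(x.shape):
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g


@pytest.mark.parametrize(
    "name,op,ref",
    [
        ("matmul_sum", lambda t: (t @ Tensor(np.arange(12.0).reshape(4, 3))).sum(),
         lambda x: (x @ np.arange(12.0).reshape(4, 3)).sum()),
        ("tanh", lambda t: t.tanh().sum(), lambda x: np.tanh(x).sum()),
        ("sigmoid", lambda t: t.sigmoid().sum(),
         lambda x: (1 / (1 + np.exp(-x))).sum()),
        ("leaky", lambda t: t.leaky_relu(0.2).sum(),
         lambda x: np.where(x > 0, x, 0.2 * x).sum()),
        ("softmax", lambda t: (t.softmax(axis=1) ** 2).sum(),
         lambda x: ((np.exp(x - x.max(1, keepdims=True))
                     / np.exp(x - x.max(1, keepdims=True)).sum(1, keepdims=True))
                    ** 2).sum()),
        ("mean_axis", lambda t: (t.mean(axis=0) ** 2).sum(),
         lambda x: (x.mean(axis=0) ** 2).sum()),
        ("div_broadcast", lambda t: (t / Tensor(np.array([2.0, 3.0, 4.0, 5.0]))).sum(),
         lambda x: (x / np.array([2.0, 3.0, 4.0, 5.0])).sum()),
        ("exp_log", lambda t: ((t * t).exp() + (t * t + 1).log()).sum(),
         lambda x: (np.exp(x * x) + np.log(x * x + 1)).sum()),
    ],
)
def test_gradients_match_finite_differences(name, op, ref, rng):
    x = rng.normal(size=(5, 4)) * 0.7
    t = Tensor(x.copy(), requires_grad=True)
    op(t).backward()
    np.testing.assert_allclose(t.grad, numeric_grad(ref, x), rtol=1e-5, atol=1e-6)


def test_concat_and_slice_gradients(rng):
    a = Tensor(rng.normal(size=(3, 2)), requires_grad=True)
    b = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
    out = concat([a, b], axis=1)
    (out[:, 1:4] ** 2).sum().backward()
    expected_a = np.zeros_like(a.data)
    expected_a[:, 1] = 2 * a.data[:, 1]
    np.testing.assert_allclose(a.grad, expected_a)
    expected_b = np.zeros_like(b.data)
    expected_b[:, :2] = 2 * b.data[:, :2]
    np.testing.assert_allclose(b.grad, expected_b)


def test_constant_inputs_do_not_block_gradients(rng):
    # regression: concat of parameters with constant blocks must keep alignment
    p = Tensor(rng.normal(size=(3, 2)), requires_grad=True)
    const = Tensor(np.ones((3, 5)))
    out = concat([const, p, const], axis=1)
    out.sum().backward()
    np.testing.assert_allclose(p.grad, np.ones_like(p.data))


class TestMinibatchDiscrimination:
    def test_single_row_similarity_is_zero(self, rng):
        kernel = rng.normal(size=(4, 3, 2))
        out = minibatch_features(rng.normal(size=(1, 4)), kernel)
        np.testing.assert_allclose(out[0, 4:], 0.0, atol=1e-12)

    def test_identical_rows_similarity_equals_n_minus_one(self, rng):
        kernel = rng.normal(size=(4, 3, 2))
        batch = np.tile(rng.normal(size=(1, 4)), (4, 1))
        out = minibatch_features(batch, kernel)
        np.testing.assert_allclose(out[:, 4:], 3.0, atol=1e-9)

    def test_output_width_is_d_plus_B(self, rng):
        out = minibatch_features(rng.normal(size=(6, 5)), rng.normal(size=(5, 7, 3)))
        assert out.shape == (6, 5 + 7)

    def test_matches_double_loop_oracle(self, rng):
        batch = rng.normal(size=(5, 4))
        kernel = rng.normal(size=(4, 3, 2))
        out = minibatch_features(batch, kernel)
        n, B = 5, 3
        oracle = np.zeros((n, B))
        M = np.einsum("nd,dbc->nbc", batch, kernel)
        for i in range(n):
            for b in range(B):
                oracle[i, b] = sum(
                    np.exp(-np.abs(M[i, b] - M[j, b]).sum())
                    for j in range(n)
                    if j != i
                )
        np.testing.assert_allclose(out[:, 4:], oracle, atol=1e-9)

    def test_layer_gradient_matches_finite_differences(self, rng):
        M = rng.normal(size=(5, 3, 2))
        w = rng.normal(size=(5, 3))
        t = Tensor(M.copy(), requires_grad=True)
        (minibatch_similarity(t) * Tensor(w)).sum().backward()

        def f(Md):
            diff = np.abs(Md[:, None] - Md[None, :]).sum(-1)
            return ((np.exp(-diff).sum(1) - 1.0) * w).sum()

        np.testing.assert_allclose(t.grad, numeric_grad(f, M), rtol=1e-5, atol=1e-7)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            minibatch_features(rng.normal(size=(3, 4)), rng.normal(size=(5, 2, 2)))


class TestSpectralNormalize:
    def test_identity_is_fixed_point(self):
        W_hat, _ = spectral_normalize(np.eye(3), steps=10)
        np.testing.assert_allclose(W_hat, np.eye(3), atol=1e-6)

    def test_scaled_identity_normalizes_back(self):
        W_hat, _ = spectral_normalize(2 * np.eye(3), steps=10)
        np.testing.assert_allclose(W_hat, np.eye(3), atol=1e-6)

    def test_rank_deficient_diagonal(self):
        W_hat, _ = spectral_normalize(np.diag([3.0, 0.0]), steps=10)
        np.testing.assert_allclose(W_hat, np.diag([1.0, 0.0]), atol=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            spectral_normalize(np.zeros((3, 3)))

    @pytest.mark.parametrize("shape", [(4, 3), (3, 6), (5, 5)])
    def test_converged_norm_matches_svd_oracle(self, shape, rng):
        W = rng.normal(size=shape)
        u = None
        for _ in range(10):  # >= 5 iterations in total, persistent state
            W_hat, u = spectral_normalize(W, u, steps=5)
        sigma = np.linalg.svd(W_hat, compute_uv=False)[0]
        assert abs(sigma - 1.0) <= 1e-3


class TestLayers:
    def test_dense_gradcheck(self, rng):
        layer = Dense(4, 3, rng)
        x = rng.normal(size=(5, 4))
        (layer(Tensor(x)) ** 2).sum().backward()
        W0 = layer.W.data.copy()

        def f(W):
            return (((x @ W) + layer.b.data) ** 2).sum()

        np.testing.assert_allclose(layer.W.grad, numeric_grad(f, W0), rtol=1e-5,
                                   atol=1e-7)

    def test_batchnorm_train_standardizes_and_eval_uses_running_stats(self, rng):
        bn = BatchNorm1d(3, momentum=1.0)
        x = rng.normal(loc=5, scale=2, size=(64, 3))
        y = bn(Tensor(x))
        np.testing.assert_allclose(y.data.mean(axis=0), 0, atol=1e-7)
        np.testing.assert_allclose(y.data.std(axis=0), 1, atol=1e-3)
        bn.eval()
        y2 = bn(Tensor(x[:1]))
        expect = (x[:1] - x.mean(0)) / np.sqrt(x.var(0) + bn.eps)
        np.testing.assert_allclose(y2.data, expect, atol=1e-3)

    def test_spectral_dense_layer_norm_converges_to_one(self, rng):
        layer = SpectralNormDense(6, 4, rng, train_steps=1, eval_steps=5)
        x = rng.normal(size=(8, 6))
        for _ in range(40):  # persistent u converges across forwards
            layer(Tensor(x))
        sigma = np.linalg.svd(layer.normalized_weight().data, compute_uv=False)[0]
        assert sigma <= 1 + 1e-3

    def test_adam_reduces_a_quadratic(self, rng):
        p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = Adam([p], lr=0.1)
        for _ in range(200):
            opt.zero_grad()
            (p**2).sum().backward()
            opt.step()
        assert np.abs(p.data).max() < 0.1

    def test_minibatch_layer_appends_kernels(self, rng):
        layer = MinibatchDiscrimination(4, 6, 3, rng)
        out = layer(Tensor(rng.normal(size=(5, 4))))
        assert out.data.shape == (5, 10)
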