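"""Loss primitives, the autodiff engine and the per-view network."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from mhsgtr._autograd import Adam, Tensor, concat, softmax
from mhsgtr.selfexpress import (EncoderState, LossWeights,
                                encode_decode, high_order_alignment_loss,
                                l21_norm, reconstruction_loss,
                                self_expression_loss)

finite_matrices = arrays(np.float64, (4, 3),
                         elements=st.floats(-100, 100, allow_nan=False))


class TestLossPrimitives:
    def test_l21_norm_values(self):
        assert l21_norm(np.zeros((3, 3))) == 0.0
        assert l21_norm(np.eye(2)) == 2.0
        assert l21_norm(np.array([[3.0, 4.0], [0.0, 0.0]])) == 5.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(finite_matrices, finite_matrices, st.floats(0.1, 10))
    def test_l21_triangle_inequality_and_homogeneity(self, A, B, c):
        assert l21_norm(A + B) <= l21_norm(A) + l21_norm(B) + 1e-8
        assert l21_norm(c * A) == pytest.approx(c * l21_norm(A), rel=1e-10)

    def test_reconstruction_loss_values_and_homogeneity(self, rng):
        X = rng.normal(size=(4, 5))
        assert reconstruction_loss(X, X, 4) == 0.0
        ones = np.ones((2, 3))
        assert reconstruction_loss(ones, np.zeros((2, 3)), 2) == 1.5
        R = rng.normal(size=(4, 5))
        assert reconstruction_loss(X + 3 * R, X, 4) == pytest.approx(
            9 * reconstruction_loss(X + R, X, 4))

    def test_self_expression_loss_degenerate_cases(self, rng):
        Z = rng.normal(size=(5, 3))
        assert self_expression_loss(Z, np.zeros((5, 5)), 1.0, 1.0) == \
            pytest.approx((Z ** 2).sum())
        C = rng.normal(size=(5, 5))
        assert self_expression_loss(np.zeros((5, 3)), C, 1.0, 2.0) == \
            pytest.approx(2.0 * (C ** 2).sum())
        # C = I makes the fit term vanish, leaving lambda2 * N — the trivial
        # solution the zero-diagonal constraint exists to forbid
        assert self_expression_loss(Z, np.eye(5), 1.0, 1.0) == pytest.approx(5.0)

    def test_alignment_loss_symmetric_and_value(self, rng):
        A = rng.normal(size=(4, 4))
        assert high_order_alignment_loss(A, A, 2.0) == 0.0
        B = A + 1.0
        assert high_order_alignment_loss(A, B, 2.0) == pytest.approx(32.0)
        assert high_order_alignment_loss(A, B, 1.5) == pytest.approx(
            high_order_alignment_loss(B, A, 1.5))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=-0.1)


def central_difference(f, x, h=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + h
        fp = f()
        x[idx] = orig - h
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * h)
    return g


def check_grad(build_loss, param: Tensor, rtol=1e-4):
    param.zero_grad()
    build_loss().backward()
    analytic = param.grad.copy()
    numeric = central_difference(lambda: build_loss().item(), param.data)
    scale = np.maximum(np.abs(numeric), 1e-6)
    assert np.max(np.abs(analytic - numeric) / scale) < rtol


class TestGradients:
    """Analytic gradients of every hand-coded loss vs central differences."""

    def test_reconstruction_and_l21_gradients(self, rng):
        X = Tensor(rng.normal(size=(5, 4)))
        W = Tensor(rng.normal(size=(4, 3)), requires_grad=True)

        def rec():
            return ((X @ W @ Tensor(rng2) - X @ Tensor(rng3)) ** 2).sum() \
                * (1 / 10.0)

        rng2 = np.random.default_rng(0).normal(size=(3, 4))
        rng3 = np.random.default_rng(1).normal(size=(4, 4))
        check_grad(rec, W)

        def l21():
            return ((W ** 2).sum(axis=1) + 1e-300).sqrt().sum() * 0.3

        check_grad(l21, W)

    def test_self_expression_and_alignment_gradients(self, rng):
        Z = Tensor(rng.normal(size=(6, 3)))
        C = Tensor(rng.normal(size=(6, 6)) * 0.3, requires_grad=True)
        A = Tensor(rng.uniform(size=(6, 6)))
        mask = Tensor(1.0 - np.eye(6))

        def se():
            Cm = C * mask
            return ((Z - Cm @ Z) ** 2).sum() * 0.7 + (Cm ** 2).sum() * 0.2

        check_grad(se, C)

        def align():
            return ((A - C * mask) ** 2).sum() * 1.3

        check_grad(align, C)

    def test_attention_softmax_and_kl_chain_gradients(self, rng):
        n, V = 4, 2
        graphs = [Tensor(np.abs(rng.normal(size=(n, n)))) for _ in range(V)]
        W = Tensor(rng.normal(size=(n * V, V)), requires_grad=True)
        C = Tensor(rng.normal(size=(n, n)) * 0.5, requires_grad=True)
        mask = Tensor(1.0 - np.eye(n))
        P = np.abs(rng.normal(size=(n, n))) + 0.1
        P /= P.sum(axis=1, keepdims=True)

        def kl_loss():
            sym = (C.abs() + C.abs().T) * 0.5
            M = softmax((concat([sym * g for g in graphs], axis=1)
                         @ W).leaky_relu(0.01), axis=1)
            CF = None
            for v, g in enumerate(graphs):
                col = M @ Tensor(np.eye(V)[:, v:v + 1])
                CF = col * g if CF is None else CF + col * g
            off = CF * mask
            rows = off.sum(axis=1, keepdims=True) + 1e-12
            S = (off + off.T) / (2.0 * rows) * mask + Tensor(np.eye(n))
            Sn = S / S.sum(axis=1, keepdims=True)
            # KL(P || Sn) with P constant: sum P log P - sum P log Sn
            return Tensor((P * np.log(P)).sum()) - (Tensor(P) * Sn.log()).sum()

        # gradient w.r.t. both the attention matrix and the affinity source
        check_grad(kl_loss, W, rtol=5e-4)
        check_grad(kl_loss, C, rtol=5e-4)


class TestNetwork:
    def test_forward_is_deterministic_and_shaped(self, rng):
        st_ = EncoderState(6, 10, (8, 4), rng=np.random.default_rng(0))
        X = rng.normal(size=(6, 10))
        Z1, X1, CZ1 = encode_decode(X, st_)
        Z2, X2, CZ2 = encode_decode(X, st_)
        np.testing.assert_array_equal(Z1, Z2)
        np.testing.assert_array_equal(X1, X2)
        assert Z1.shape == (6, 4) and X1.shape == (6, 10)
        with pytest.raises(ValueError):
            encode_decode(rng.normal(size=(6, 9)), st_)

    def test_pretrain_path_reconstructs_from_latent(self, rng):
        st_ = EncoderState(5, 8, (6, 3), rng=np.random.default_rng(1))
        X = rng.normal(size=(5, 8))
        _, Xrec, _ = encode_decode(X, st_, use_self_expression=False)
        Z = st_.encode(Tensor(X))
        np.testing.assert_allclose(Xrec, st_.decode(Z).data)

    def test_symmetrized_graph_is_nonnegative_symmetric_zero_diag(self, rng):
        st_ = EncoderState(7, 5, (4, 2), rng=np.random.default_rng(2))
        st_.C.data[...] = rng.normal(size=(7, 7))
        G = st_.symmetrized_graph()
        assert G.min() >= 0
        np.testing.assert_allclose(G, G.T)
        np.testing.assert_array_equal(np.diag(G), 0.0)

    def test_adam_descends_simple_quadratic(self):
        x = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = Adam([x], lr=0.1)
        for _ in range(200):
            loss = (x ** 2).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert np.abs(x.data).max() < 0.05
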