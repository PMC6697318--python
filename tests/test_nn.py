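"""Numeric building blocks checked against independent oracles.

Forward passes are compared with scipy/skimage reference implementations and
explicit loops; backward passes are compared with float64 central differences.
"""

import numpy as np
import pytest
from scipy.signal import correlate2d

from octoseg import nn


def _to_float64(layer):
    """Promote a layer's parameters to float64 for tight gradient checks."""
    if hasattr(layer, "W"):
        layer.W = layer.W.astype(np.float64)
        layer.b = layer.b.astype(np.float64)
        layer.dW = np.zeros_like(layer.W)
        layer.db = np.zeros_like(layer.b)
    return layer


def _gradcheck(loss_fn, params_and_grads, eps=1e-6, rtol=1e-6):
    """Compare analytic gradients against central differences, elementwise."""
    rng = np.random.default_rng(99)
    for p, g in params_and_grads:
        flat = rng.choice(p.size, size=min(p.size, 8), replace=False)
        for fi in flat:
            idx = np.unravel_index(fi, p.shape)
            old = p[idx]
            p[idx] = old + eps
            lp = loss_fn()
            p[idx] = old - eps
            lm = loss_fn()
            p[idx] = old
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(g[idx], rel=rtol, abs=1e-9), (
                f"param shape {p.shape} index {idx}"
            )


class TestConv2D:
    def test_forward_matches_scipy_correlate2d(self):
        rng = np.random.default_rng(0)
        conv = nn.Conv2D(1, 1, 3, rng)
        x = rng.standard_normal((1, 7, 9, 1)).astype(np.float32)
        y = conv.forward(x, train=False)
        ref = correlate2d(
            x[0, :, :, 0].astype(np.float64),
            conv.W[:, :, 0, 0].astype(np.float64),
            mode="same",
        ) + float(conv.b[0])
        np.testing.assert_allclose(y[0, :, :, 0], ref, rtol=1e-5, atol=1e-5)

    def test_multichannel_forward_matches_explicit_loop(self):
        rng = np.random.default_rng(1)
        conv = nn.Conv2D(3, 2, 3, rng)
        x = rng.standard_normal((2, 5, 6, 3)).astype(np.float32)
        y = conv.forward(x, train=False)
        ref = np.zeros((2, 5, 6, 2))
        for ci in range(3):
            for co in range(2):
                for n in range(2):
                    ref[n, :, :, co] += correlate2d(
                        x[n, :, :, ci].astype(np.float64),
                        conv.W[:, :, ci, co].astype(np.float64),
                        mode="same",
                    )
        ref += conv.b.astype(np.float64)
        np.testing.assert_allclose(y, ref, rtol=1e-4, atol=1e-5)

    def test_one_by_one_conv_is_channel_matmul(self):
        rng = np.random.default_rng(2)
        conv = nn.Conv2D(4, 3, 1, rng)
        x = rng.standard_normal((1, 4, 4, 4)).astype(np.float32)
        y = conv.forward(x, train=False)
        ref = x.astype(np.float64) @ conv.W[0, 0].astype(np.float64) + conv.b
        np.testing.assert_allclose(y, ref, rtol=1e-5, atol=1e-6)

    def test_gradients_match_central_differences(self):
        rng = np.random.default_rng(3)
        conv = _to_float64(nn.Conv2D(2, 3, 3, rng))
        x = np.random.default_rng(4).standard_normal((2, 5, 5, 2))
        t = np.random.default_rng(5).standard_normal((2, 5, 5, 3))

        def loss():
            return float((conv.forward(x, train=False) * t).sum())

        conv.forward(x, train=True)
        dx = conv.backward(t.copy())
        _gradcheck(loss, conv.params())
        # input gradient against central differences on a few pixels
        eps = 1e-6
        for idx in [(0, 0, 0, 0), (1, 2, 3, 1), (0, 4, 4, 1)]:
            xp = x.copy()
            xp[idx] += eps
            lp = float((conv.forward(xp, train=False) * t).sum())
            xp[idx] -= 2 * eps
            lm = float((conv.forward(xp, train=False) * t).sum())
            assert (lp - lm) / (2 * eps) == pytest.approx(dx[idx], rel=1e-6)


class TestReLU:
    def test_forward_and_subgradient(self):
        relu = nn.ReLU()
        x = np.array([[-1.0, 0.0, 2.0]])[None, ..., None]
        y = relu.forward(x)
        np.testing.assert_array_equal(y.ravel(), [0.0, 0.0, 2.0])
        dx = relu.backward(np.ones_like(x))
        # subgradient at 0 is taken as 0
        np.testing.assert_array_equal(dx.ravel(), [0.0, 0.0, 1.0])


class TestMaxPool2:
    def test_forward_matches_block_reduce(self):
        from skimage.measure import block_reduce

        rng = np.random.default_rng(6)
        pool = nn.MaxPool2()
        x = rng.standard_normal((2, 6, 8, 3)).astype(np.float32)
        y = pool.forward(x, train=False)
        for n in range(2):
            for c in range(3):
                ref = block_reduce(x[n, :, :, c], (2, 2), np.max)
                np.testing.assert_array_equal(y[n, :, :, c], ref)

    def test_backward_routes_gradient_to_argmax(self):
        pool = nn.MaxPool2()
        x = np.zeros((1, 2, 2, 1), dtype=np.float32)
        x[0, 1, 0, 0] = 5.0  # unique maximum of the single 2x2 window
        pool.forward(x, train=True)
        dy = np.full((1, 1, 1, 1), 7.0, dtype=np.float32)
        dx = pool.backward(dy)
        expected = np.zeros_like(x)
        expected[0, 1, 0, 0] = 7.0
        np.testing.assert_array_equal(dx, expected)


class TestUpConv2:
    def test_forward_matches_explicit_loop(self):
        rng = np.random.default_rng(7)
        up = nn.UpConv2(2, 3, rng)
        x = rng.standard_normal((1, 3, 4, 2)).astype(np.float32)
        y = up.forward(x, train=False)
        assert y.shape == (1, 6, 8, 3)
        ref = np.zeros((1, 6, 8, 3))
        for i in range(3):
            for j in range(4):
                for di in range(2):
                    for dj in range(2):
                        ref[0, 2 * i + di, 2 * j + dj, :] = (
                            x[0, i, j, :].astype(np.float64)
                            @ up.W[:, :, di, dj].astype(np.float64)
                        )
        ref += up.b.astype(np.float64)
        np.testing.assert_allclose(y, ref, rtol=1e-5, atol=1e-6)

    def test_gradients_match_central_differences(self):
        rng = np.random.default_rng(8)
        up = _to_float64(nn.UpConv2(2, 2, rng))
        x = np.random.default_rng(9).standard_normal((2, 3, 3, 2))
        t = np.random.default_rng(10).standard_normal((2, 6, 6, 2))

        def loss():
            return float((up.forward(x, train=False) * t).sum())

        up.forward(x, train=True)
        dx = up.backward(t.copy())
        _gradcheck(loss, up.params())
        eps = 1e-6
        idx = (1, 2, 1, 0)
        xp = x.copy()
        xp[idx] += eps
        lp = float((up.forward(xp, train=False) * t).sum())
        xp[idx] -= 2 * eps
        lm = float((up.forward(xp, train=False) * t).sum())
        assert (lp - lm) / (2 * eps) == pytest.approx(dx[idx], rel=1e-6)


class TestConcat:
    def test_forward_backward_split(self):
        cat = nn.Concat()
        a = np.ones((1, 2, 2, 3), dtype=np.float32)
        b = np.full((1, 2, 2, 2), 2.0, dtype=np.float32)
        y = cat.forward(a, b)
        assert y.shape == (1, 2, 2, 5)
        da, db = cat.backward(y)
        np.testing.assert_array_equal(da, a)
        np.testing.assert_array_equal(db, b)


class TestSoftmaxCrossEntropy:
    def test_loss_matches_scipy_log_softmax(self):
        from scipy.special import log_softmax

        rng = np.random.default_rng(11)
        logits = rng.standard_normal((2, 3, 3, 4))
        targets = rng.integers(0, 4, (2, 3, 3))
        loss, _ = nn.softmax_cross_entropy(logits, targets)
        ls = log_softmax(logits, axis=-1)
        ref = -np.take_along_axis(ls, targets[..., None], axis=-1).mean()
        assert loss == pytest.approx(float(ref), rel=1e-10)

    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(12)
        logits = rng.standard_normal((1, 2, 2, 4))
        targets = rng.integers(0, 4, (1, 2, 2))
        _, grad = nn.softmax_cross_entropy(logits, targets)
        eps = 1e-6
        for idx in [(0, 0, 0, 0), (0, 1, 1, 3), (0, 0, 1, 2)]:
            lp_logits = logits.copy()
            lp_logits[idx] += eps
            lp, _ = nn.softmax_cross_entropy(lp_logits, targets)
            lp_logits[idx] -= 2 * eps
            lm, _ = nn.softmax_cross_entropy(lp_logits, targets)
            assert (lp - lm) / (2 * eps) == pytest.approx(
                float(grad[idx]), rel=1e-4, abs=1e-9
            )

    def test_softmax_rows_sum_to_one(self):
        rng = np.random.default_rng(13)
        p = nn.softmax(rng.standard_normal((2, 3, 3, 4)) * 50, axis=-1)
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, rtol=1e-12)
        assert (p >= 0).all()


class TestAdam:
    def test_first_step_moves_by_learning_rate(self):
        # with bias correction the first Adam step is -lr * sign(g)
        p = np.zeros(3, dtype=np.float64)
        g = np.array([0.3, -2.0, 0.0])
        opt = nn.Adam([(p, g)], lr=0.1)
        opt.step()
        np.testing.assert_allclose(p[:2], [-0.1, 0.1], rtol=1e-6)
        assert p[2] == 0.0

    def test_two_steps_match_reference_recursion(self):
        rng = np.random.default_rng(14)
        p = rng.standard_normal(4)
        p_ref = p.copy()
        grads = [rng.standard_normal(4), rng.standard_normal(4)]
        gbuf = grads[0].copy()
        opt = nn.Adam([(p, gbuf)], lr=0.01)
        m = np.zeros(4)
        v = np.zeros(4)
        for t, g in enumerate(grads, start=1):
            gbuf[...] = g
            opt.step()
            m = 0.9 * m + 0.1 * g
            v = 0.999 * v + 0.001 * g * g
            p_ref -= 0.01 * (m / (1 - 0.9**t)) / (
                np.sqrt(v / (1 - 0.999**t)) + 1e-8
            )
        np.testing.assert_allclose(p, p_ref, rtol=1e-10)
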