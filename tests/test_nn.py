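"""The autodiff core: every primitive's gradient against finite differences,
and the convolution forward pass against an independent dense oracle."""

import numpy as np
import pytest

from canet import nn
from canet.nn import Tensor, concat
from canet.nn import functional as F

from conftest import numeric_grad


def _check_grad(build, arrays, atol=2e-3, rtol=2e-2):
    """`build(tensors) -> scalar Tensor`; checks d(out)/d(each array)."""
    tensors = [Tensor(a, requires_grad=True) for a in arrays]
    out = build(tensors)
    out.backward()
    for t, a in zip(tensors, arrays):
        num = numeric_grad(lambda: build([Tensor(x) for x in arrays]).item(), a)
        np.testing.assert_allclose(t.grad, num, atol=atol, rtol=rtol)


def _smooth(rng, *shape):
    # keep values away from ReLU/max kinks for clean finite differences
    return (rng.uniform(0.2, 1.5, shape) * rng.choice([-1, 1], shape)).astype(np.float32)


class TestElementwiseGrads:
    def test_arithmetic_chain(self, rng):
        a = _smooth(rng, 2, 3)
        b = _smooth(rng, 2, 3)
        _check_grad(lambda ts: ((ts[0] * ts[1] + ts[0] / ts[1] - ts[1]) ** 2).sum(),
                    [a, b])

    def test_broadcasting(self, rng):
        a = _smooth(rng, 2, 3, 4)
        b = _smooth(rng, 1, 3, 1)
        _check_grad(lambda ts: (ts[0] * ts[1] + ts[1]).sum(), [a, b])

    @pytest.mark.parametrize("op", ["relu", "sigmoid", "exp"])
    def test_unary(self, rng, op):
        a = _smooth(rng, 3, 4)
        _check_grad(lambda ts: getattr(ts[0], op)().sum(), [a])

    def test_log(self, rng):
        a = rng.uniform(0.5, 2.0, (3, 4)).astype(np.float32)
        _check_grad(lambda ts: ts[0].log().sum(), [a])

    def test_matmul_batched(self, rng):
        a = _smooth(rng, 2, 3, 4)
        b = _smooth(rng, 4, 5)
        _check_grad(lambda ts: (ts[0] @ ts[1]).sum(), [a, b])

    def test_reductions_and_shapes(self, rng):
        # well-separated values: ties at a max would confuse finite differences
        a = rng.permutation(np.linspace(-1.2, 1.2, 24)).reshape(2, 3, 4).astype(np.float32)
        _check_grad(lambda ts: (ts[0].mean(axis=(0, 2)) ** 2).sum(), [a])
        _check_grad(lambda ts: ts[0].max(axis=-1).sum(), [a])
        _check_grad(lambda ts: ts[0].reshape(6, 4).transpose(1, 0).sum(axis=1).max(axis=0),
                    [a])

    def test_concat_and_slice(self, rng):
        a = _smooth(rng, 1, 2, 3)
        b = _smooth(rng, 1, 4, 3)
        _check_grad(lambda ts: (concat(ts, axis=1)[:, 1:5] ** 2).sum(), [a, b])


class TestConv2d:
    @pytest.mark.parametrize("k,stride,dilation", [
        (1, 1, 1), (3, 1, 1), (3, 2, 1), (3, 1, 3), (5, 1, 2), (2, 2, 1),
    ])
    def test_forward_matches_dense_oracle(self, rng, k, stride, dilation):
        """im2col conv vs an explicit quadruple-loop cross-correlation."""
        B, Cin, Cout, H, W = 2, 3, 4, 8, 9
        pad = (k - 1) // 2 * dilation
        x = rng.normal(size=(B, Cin, H, W)).astype(np.float32)
        w = rng.normal(size=(Cout, Cin, k, k)).astype(np.float32)
        got = F.conv2d(Tensor(x), Tensor(w), stride=stride, padding=pad,
                       dilation=dilation).data

        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        ke = (k - 1) * dilation + 1
        Ho = (H + 2 * pad - ke) // stride + 1
        Wo = (W + 2 * pad - ke) // stride + 1
        ref = np.zeros((B, Cout, Ho, Wo))
        for b in range(B):
            for o in range(Cout):
                for i in range(Ho):
                    for j in range(Wo):
                        patch = xp[b, :,
                                   i * stride:i * stride + ke:dilation,
                                   j * stride:j * stride + ke:dilation]
                        ref[b, o, i, j] = (patch * w[o]).sum()
        np.testing.assert_allclose(got, ref, atol=1e-4)

    @pytest.mark.parametrize("k,stride,dilation,pad", [
        (3, 1, 1, 1), (3, 2, 1, 1), (3, 1, 2, 2), (1, 1, 1, 0),
    ])
    def test_gradients(self, rng, k, stride, dilation, pad):
        x = _smooth(rng, 1, 2, 6, 6)
        w = _smooth(rng, 3, 2, k, k) * 0.3
        b = _smooth(rng, 3) * 0.1
        _check_grad(
            lambda ts: (F.conv2d(ts[0], ts[1], ts[2], stride, pad, dilation) ** 2).sum(),
            [x, w, b],
        )

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="channels"):
            F.conv2d(Tensor(np.zeros((1, 2, 4, 4))), Tensor(np.zeros((1, 3, 3, 3))),
                     padding=1)


class TestPoolAndResize:
    def test_max_pool_grad(self, rng):
        x = _smooth(rng, 1, 2, 6, 6)
        _check_grad(lambda ts: (F.max_pool2d(ts[0], 3, 2, padding=1) ** 2).sum(), [x])

    def test_max_pool_forward(self):
        x = np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4)
        out = F.max_pool2d(Tensor(x), 2, 2).data
        np.testing.assert_array_equal(out[0, 0], [[5, 7], [13, 15]])

    @pytest.mark.parametrize("mode", ["bilinear", "nearest"])
    @pytest.mark.parametrize("scale", [2, 4])
    def test_resize_grad(self, rng, mode, scale):
        x = _smooth(rng, 1, 2, 3, 3)
        _check_grad(lambda ts: (F.resize2d(ts[0], scale, mode) ** 2).sum(), [x])

    def test_bilinear_matches_interp_oracle(self, rng):
        """Separable matrix resize vs per-axis np.interp at half-pixel centres."""
        x = rng.normal(size=(1, 1, 5, 7)).astype(np.float32)
        scale = 2
        got = F.resize2d(Tensor(x), scale).data[0, 0]
        H, W = 5, 7
        src_r = np.clip((np.arange(H * scale) + 0.5) / scale - 0.5, 0, H - 1)
        src_c = np.clip((np.arange(W * scale) + 0.5) / scale - 0.5, 0, W - 1)
        tmp = np.stack([np.interp(src_c, np.arange(W), row) for row in x[0, 0]])
        ref = np.stack([np.interp(src_r, np.arange(H), col) for col in tmp.T]).T
        np.testing.assert_allclose(got, ref, atol=1e-5)

    def test_resize_preserves_constant(self):
        x = Tensor(np.full((1, 1, 4, 4), 3.25, dtype=np.float32))
        np.testing.assert_allclose(F.resize2d(x, 2).data, 3.25, atol=1e-6)


class TestModules:
    def test_batchnorm_train_normalises_and_backprops(self, rng):
        bn = nn.BatchNorm2d(3)
        x = rng.normal(2.0, 3.0, size=(4, 3, 5, 5)).astype(np.float32)
        out = bn(Tensor(x, requires_grad=True))
        assert abs(out.data.mean()) < 1e-4
        np.testing.assert_allclose(out.data.std(), 1.0, atol=1e-2)
        a = _smooth(rng, 2, 3, 4, 4)
        _check_grad(lambda ts: (bn(ts[0]) ** 2).sum(), [a])

    def test_batchnorm_eval_uses_running_stats(self, rng):
        bn = nn.BatchNorm2d(2)
        for _ in range(30):
            bn(Tensor(rng.normal(1.0, 2.0, size=(8, 2, 4, 4)).astype(np.float32)))
        bn.eval()
        x = rng.normal(1.0, 2.0, size=(4, 2, 4, 4)).astype(np.float32)
        out = bn(Tensor(x))
        assert abs(out.data.mean()) < 0.3  # normalised by accumulated stats

    def test_layernorm_grad(self, rng):
        ln = nn.LayerNorm(6)
        a = _smooth(rng, 2, 3, 6)
        _check_grad(lambda ts: (ln(ts[0]) ** 2).sum(), [a])

    def test_state_dict_roundtrip(self, rng):
        m1 = nn.Sequential(nn.ConvBlock(2, 4), nn.ConvBlock(4, 4))
        nn.manual_seed(99)
        m2 = nn.Sequential(nn.ConvBlock(2, 4), nn.ConvBlock(4, 4))
        x = Tensor(rng.normal(size=(1, 2, 6, 6)).astype(np.float32))
        assert not np.allclose(m1(x).data, m2(x).data)
        m2.load_state_dict(m1.state_dict())
        m1.eval(), m2.eval()
        np.testing.assert_array_equal(m1(x).data, m2(x).data)

    def test_identity_conv(self, rng):
        conv = nn.identity_conv_(nn.Conv2d(3, 3, 3))
        x = rng.normal(size=(1, 3, 5, 5)).astype(np.float32)
        np.testing.assert_allclose(conv(Tensor(x)).data, x, atol=1e-6)


class TestAdam:
    def test_first_step_matches_closed_form(self):
        # with constant gradient g, the bias-corrected first step is -lr * sign-ish
        p = nn.Parameter(np.array([1.0, -2.0]))
        opt = nn.Adam([p], lr=0.1)
        p.grad = np.array([0.5, -0.25], dtype=np.float32)
        opt.step()
        # m-hat = g, v-hat = g^2  ->  update = lr * g / (|g| + eps) = lr * sign(g)
        np.testing.assert_allclose(p.data, [1.0 - 0.1, -2.0 + 0.1], atol=1e-5)

    def test_converges_on_quadratic(self):
        p = nn.Parameter(np.array([5.0]))
        opt = nn.Adam([p], lr=0.3)
        for _ in range(200):
            opt.zero_grad()
            loss = (p * p).sum()
            loss.backward()
            opt.step()
        assert abs(p.data[0]) < 1e-2


class TestBCEWithLogits:
    def test_matches_clipped_naive(self, rng):
        z = rng.uniform(-4.5, 4.5, size=(2, 1, 4, 4)).astype(np.float32)
        y = (rng.random((2, 1, 4, 4)) > 0.5).astype(np.float32)
        p = np.clip(1 / (1 + np.exp(-z)), 0.01, 0.99)
        naive = -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean()
        got = F.bce_with_logits(Tensor(z), y).item()
        assert abs(got - naive) < 1e-6

    def test_stable_at_extreme_logits(self):
        z = Tensor(np.array([[100.0, -100.0]]), requires_grad=True)
        y = np.array([[1.0, 0.0]], dtype=np.float32)
        loss = F.bce_with_logits(z, y)
        assert np.isfinite(loss.item()) and loss.item() < 1e-6
        loss.backward()
        assert np.all(np.isfinite(z.grad))

    def test_gradient(self, rng):
        z = _smooth(rng, 2, 3)
        y = (rng.random((2, 3)) > 0.5).astype(np.float32)
        _check_grad(lambda ts: F.bce_with_logits(ts[0], y), [z])
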