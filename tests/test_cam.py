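"""Cascaded aggregation: shape/wiring contracts and exact equation oracles.

The oracle tests build the module with batch-norm off and all convolutions
set to the identity (or to a channel sum where widths reduce), so the cascade
collapses to direct array arithmetic on tiny nonnegative feature maps.
"""

import numpy as np
import pytest

from canet import CAM, CamConfig, ConfigurationError, cam_forward
from canet import nn
from canet.nn import Tensor


def _up(x: np.ndarray, scale: int) -> np.ndarray:
    """Independent bilinear upsampling oracle (per-axis np.interp)."""
    h, w = x.shape
    src_r = np.clip((np.arange(h * scale) + 0.5) / scale - 0.5, 0, h - 1)
    src_c = np.clip((np.arange(w * scale) + 0.5) / scale - 0.5, 0, w - 1)
    tmp = np.stack([np.interp(src_c, np.arange(w), row) for row in x])
    return np.stack([np.interp(src_r, np.arange(h), col) for col in tmp.T]).T


def _passthrough(conv: nn.Conv2d) -> None:
    """Identity for square convs; channel-sum when the width reduces to one."""
    w = np.zeros_like(conv.weight.data)
    c = conv.kernel // 2
    for o in range(conv.out_ch):
        if conv.in_ch == conv.out_ch:
            w[o, o, c, c] = 1.0
        else:
            w[o, :, c, c] = 1.0
    conv.weight.data = w
    if conv.bias is not None:
        conv.bias.data[:] = 0.0


def _unit_cam(source: str = "f3_agg") -> CAM:
    cam = CAM((1, 1, 1), CamConfig(mid_channels=1, batch_norm=False,
                                   second_path_source=source))
    for m in cam.modules():
        if isinstance(m, nn.Conv2d):
            _passthrough(m)
    return cam


def _toy_pyramid(rng):
    f2 = rng.uniform(0.1, 1.0, (1, 1, 8, 8)).astype(np.float32)
    f3 = rng.uniform(0.1, 1.0, (1, 1, 4, 4)).astype(np.float32)
    f4 = rng.uniform(0.1, 1.0, (1, 1, 2, 2)).astype(np.float32)
    return f2, f3, f4


class TestConvBlockContract:
    def test_same_padding_any_odd_kernel(self, rng):
        for k in (1, 3, 5):
            blk = nn.ConvBlock(4, 8, k)
            out = blk(Tensor(rng.normal(size=(1, 4, 16, 16)).astype(np.float32)))
            assert out.shape == (1, 8, 16, 16)

    def test_zero_input_gives_uniform_map(self):
        blk = nn.ConvBlock(2, 3, 3)
        out = blk(Tensor(np.zeros((1, 2, 8, 8), dtype=np.float32))).data
        for ch in out[0]:
            assert np.ptp(ch) < 1e-6

    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigurationError, match="odd"):
            nn.ConvBlock(2, 3, 4)


class TestShapeContracts:
    def test_intermediate_strides_and_fcam(self, rng):
        # pyramid of a 256x256 image with tiny-family channels
        f2 = Tensor(rng.normal(size=(2, 32, 32, 32)).astype(np.float32))
        f3 = Tensor(rng.normal(size=(2, 64, 16, 16)).astype(np.float32))
        f4 = Tensor(rng.normal(size=(2, 96, 8, 8)).astype(np.float32))
        cfg = CamConfig(mid_channels=16)
        fcam, inter = cam_forward(f2, f3, f4, cfg)
        assert inter.f3_prime.shape == (2, 16, 16, 16)
        assert inter.f3_agg.shape == (2, 32, 16, 16)      # concat doubles width
        assert inter.f2_prime.shape == (2, 16, 32, 32)
        assert inter.f2_agg.shape == (2, 32, 32, 32)
        assert fcam.shape == (2, 16, 32, 32)              # stride 8 for 256 input

    def test_invalid_source_selector(self):
        with pytest.raises(ConfigurationError, match="second_path_source"):
            CAM((8, 8, 8), CamConfig(second_path_source="f9"))

    def test_batch_equivariance_of_aggregation(self, rng):
        cam = CAM((1, 1, 1), CamConfig(mid_channels=2, batch_norm=False)).eval()
        f3p = rng.normal(size=(2, 2, 4, 4)).astype(np.float32)
        f4 = rng.normal(size=(2, 1, 2, 2)).astype(np.float32)
        out = cam.aggregate_first_path(Tensor(f3p), Tensor(f4)).data
        swapped = cam.aggregate_first_path(Tensor(f3p[::-1].copy()),
                                           Tensor(f4[::-1].copy())).data
        np.testing.assert_allclose(out[::-1], swapped, atol=1e-6)


class TestMultiplicativeGuidance:
    def test_zero_f4_annihilates_first_product(self, rng):
        cam = _unit_cam()
        f2, f3, _ = _toy_pyramid(rng)
        zero4 = Tensor(np.zeros((1, 1, 2, 2), dtype=np.float32))
        f3p = cam.guided_refine_f3(Tensor(f3), zero4)
        np.testing.assert_array_equal(f3p.data, 0.0)
        f2p = cam.guided_refine_f2(Tensor(f2), Tensor(f3), zero4)
        np.testing.assert_array_equal(f2p.data, 0.0)

    def test_zero_f3_annihilates_nested_product(self, rng):
        cam = _unit_cam()
        f2, _, f4 = _toy_pyramid(rng)
        zero3 = Tensor(np.zeros((1, 1, 4, 4), dtype=np.float32))
        f2p = cam.guided_refine_f2(Tensor(f2), zero3, Tensor(f4))
        np.testing.assert_array_equal(f2p.data, 0.0)


class TestEquationOracles:
    def test_guided_refine_is_upsample_times_feature(self, rng):
        cam = _unit_cam()
        _, f3, f4 = _toy_pyramid(rng)
        got = cam.guided_refine_f3(Tensor(f3), Tensor(f4)).data[0, 0]
        np.testing.assert_allclose(got, _up(f4[0, 0], 2) * f3[0, 0], atol=1e-5)

    def test_nested_guidance_oracle(self, rng):
        cam = _unit_cam()
        f2, f3, f4 = _toy_pyramid(rng)
        got = cam.guided_refine_f2(Tensor(f2), Tensor(f3), Tensor(f4)).data[0, 0]
        ref = _up(f4[0, 0], 4) * (_up(f3[0, 0], 2) * f2[0, 0])
        np.testing.assert_allclose(got, ref, atol=1e-5)

    def test_whole_cascade_matches_direct_arithmetic(self, rng):
        """Unit-weight cascade == 15 lines of array arithmetic."""
        cam = _unit_cam()
        f2, f3, f4 = _toy_pyramid(rng)
        fcam, inter = cam(Tensor(f2), Tensor(f3), Tensor(f4))

        u4 = _up(f4[0, 0], 2)                       # f4 aligned to f3's grid
        f3p = u4 * f3[0, 0]
        f3a = np.stack([u4, f3p])                   # first-path aggregation
        f2p = _up(f4[0, 0], 4) * (_up(f3[0, 0], 2) * f2[0, 0])
        s = _up(f3a[0], 2) + _up(f3a[1], 2)         # channel-sum conv of Up(f3'')
        f2a = np.stack([s, f2p])
        ref_fcam = f2a.sum(axis=0)                  # two channel-sum transforms
        np.testing.assert_allclose(inter.f3_prime.data[0, 0], f3p, atol=1e-5)
        np.testing.assert_allclose(inter.f3_agg.data[0], f3a, atol=1e-5)
        np.testing.assert_allclose(inter.f2_agg.data[0], f2a, atol=1e-4)
        np.testing.assert_allclose(fcam.data[0, 0], ref_fcam, atol=1e-4)


class TestWiring:
    def test_default_consumes_first_path_output(self, rng):
        cam = CAM((4, 4, 4), CamConfig(mid_channels=4))
        f2 = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        f3 = Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32))
        f4 = Tensor(rng.normal(size=(1, 4, 2, 2)).astype(np.float32))
        fcam, inter = cam(f2, f3, f4)
        (fcam ** 2).sum().backward()
        for name in ("f3_prime", "f3_agg", "f2_prime", "f2_agg"):
            g = getattr(inter, name).grad
            assert g is not None and np.abs(g).max() > 0, name

    def test_literal_reading_leaves_first_path_aggregate_unused(self, rng):
        cam = CAM((4, 4, 4), CamConfig(mid_channels=4,
                                       second_path_source="f3_prime"))
        f2 = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        f3 = Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32))
        f4 = Tensor(rng.normal(size=(1, 4, 2, 2)).astype(np.float32))
        fcam, inter = cam(f2, f3, f4)
        (fcam ** 2).sum().backward()
        assert inter.f3_agg.grad is None          # computed but not consumed
        assert inter.f3_prime.grad is not None

    def test_determinism(self, rng):
        cam = CAM((4, 4, 4), CamConfig(mid_channels=4)).eval()
        args = [Tensor(rng.normal(size=s).astype(np.float32))
                for s in ((1, 4, 8, 8), (1, 4, 4, 4), (1, 4, 2, 2))]
        a, _ = cam(*args)
        b, _ = cam(*args)
        np.testing.assert_array_equal(a.data, b.data)
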