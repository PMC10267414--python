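"""Architecture contracts: attention algebra, shapes, parameters, gradients."""

import numpy as np
import pytest
from scipy.ndimage import correlate

from octseg import autodiff as ad
from octseg import nn
from octseg.autodiff import Tensor
from octseg.network import (CBAM, CBAMProject, ChannelAttention, DECBAM,
                            MultiScaleSegNet, NetworkConfig, SpatialAttention,
                            TINY_CONFIG, count_parameters, load_checkpoint,
                            save_checkpoint)

from conftest import MICRO_NET


def zero_params(module):
    for p in module.parameters():
        p.data[...] = 0.0


class TestChannelAttention:
    def test_zero_weights_give_half(self, rng):
        cam = ChannelAttention(8, np.random.default_rng(0), reduction=2)
        zero_params(cam)
        mc = cam(Tensor(rng.normal(size=(2, 8, 5, 5))))
        np.testing.assert_allclose(mc.data, 0.5)
        assert mc.shape == (2, 8, 1, 1)

    def test_constant_channels_double_the_mlp_path(self, rng):
        # constant per channel: avg pool == max pool, so Mc = sigma(2 MLP(avg))
        cam = ChannelAttention(4, np.random.default_rng(3), reduction=2)
        x = np.broadcast_to(rng.normal(size=(1, 4, 1, 1)), (1, 4, 6, 6)).copy()
        mc = cam(Tensor(x))
        avg = x.mean(axis=(2, 3))
        mlp = cam._mlp(Tensor(avg)).data
        np.testing.assert_allclose(mc.data[..., 0, 0], 1 / (1 + np.exp(-2 * mlp)),
                                   rtol=1e-12)

    def test_matches_pooling_affine_oracle(self, rng):
        cam = ChannelAttention(4, np.random.default_rng(5), reduction=2)
        x = rng.normal(size=(3, 4, 5, 5))
        mc = cam(Tensor(x)).data[..., 0, 0]
        w1, b1 = cam.fc1.weight.data, cam.fc1.bias.data
        w2, b2 = cam.fc2.weight.data, cam.fc2.bias.data

        def mlp(v):
            return np.maximum(v @ w1 + b1, 0) @ w2 + b2

        oracle = 1 / (1 + np.exp(-(mlp(x.mean(axis=(2, 3)))
                                   + mlp(x.max(axis=(2, 3))))))
        np.testing.assert_allclose(mc, oracle, atol=1e-6)


class TestSpatialAttention:
    def test_zero_weights_give_half(self, rng):
        sam = SpatialAttention(np.random.default_rng(0))
        zero_params(sam)
        ms = sam(Tensor(rng.normal(size=(2, 5, 9, 9))))
        np.testing.assert_allclose(ms.data, 0.5)
        assert ms.shape == (2, 1, 9, 9)

    def test_single_channel_pools_are_the_input(self, rng):
        sam = SpatialAttention(np.random.default_rng(1))
        x = rng.normal(size=(1, 1, 6, 6))
        ms = sam(Tensor(x)).data
        # with C = 1 both pooled maps equal the input itself
        w = sam.conv.weight.data          # (1, 2, 7, 7)
        stacked = np.concatenate([x, x], axis=1)[0]
        ref = correlate(stacked[0], w[0, 0], mode="constant") \
            + correlate(stacked[1], w[0, 1], mode="constant") \
            + sam.conv.bias.data[0]
        np.testing.assert_allclose(ms[0, 0], 1 / (1 + np.exp(-ref)), atol=1e-6)

    def test_matches_direct_correlation_oracle(self, rng):
        sam = SpatialAttention(np.random.default_rng(2))
        x = rng.normal(size=(1, 3, 9, 9))
        ms = sam(Tensor(x)).data[0, 0]
        avg, mx = x[0].mean(axis=0), x[0].max(axis=0)
        w = sam.conv.weight.data
        ref = correlate(avg, w[0, 0], mode="constant") \
            + correlate(mx, w[0, 1], mode="constant") + sam.conv.bias.data[0]
        np.testing.assert_allclose(ms, 1 / (1 + np.exp(-ref)), atol=1e-6)


class TestCBAM:
    def test_zero_input_maps_to_zero(self, rng):
        block = CBAM(6, np.random.default_rng(0), reduction=2)
        out = block(Tensor(np.zeros((1, 6, 4, 4))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_zero_weights_scale_by_quarter(self, rng):
        block = CBAM(6, np.random.default_rng(0), reduction=2)
        zero_params(block)
        x = rng.normal(size=(2, 6, 5, 5))
        np.testing.assert_allclose(block(Tensor(x)).data, 0.25 * x, rtol=1e-12)

    def test_equals_sequential_composition(self, rng):
        block = CBAM(4, np.random.default_rng(4), reduction=2)
        x = Tensor(rng.normal(size=(2, 4, 6, 6)))
        out = block(x)
        f1 = ad.mul(block.cam(x), x)
        ref = ad.mul(block.sam(f1), f1)
        np.testing.assert_allclose(out.data, ref.data, rtol=1e-12)

    def test_attention_maps_in_open_unit_interval(self, rng):
        block = CBAM(8, np.random.default_rng(7), reduction=4)
        for _ in range(5):
            x = Tensor(rng.normal(size=(1, 8, 6, 6)))
            mc = block.cam(x).data
            ms = block.sam(x).data
            assert (mc > 0).all() and (mc < 1).all()
            assert (ms > 0).all() and (ms < 1).all()


class TestDECBAM:
    def test_halves_channels_preserves_spatial(self):
        block = DECBAM(8, np.random.default_rng(0), reduction=2)
        out = block(Tensor(np.random.default_rng(1).normal(size=(1, 8, 16, 16))))
        assert out.shape == (1, 4, 16, 16)

    def test_odd_channel_count_rejected(self):
        with pytest.raises(ValueError):
            DECBAM(7, np.random.default_rng(0))

    def test_has_more_parameters_than_plain_projection(self):
        rng = np.random.default_rng(0)
        de = DECBAM(16, rng, reduction=4)
        plain = CBAMProject(16, np.random.default_rng(0), reduction=4)
        assert de.n_parameters() > plain.n_parameters()

    def test_zero_input_with_zero_shifts_stays_zero(self):
        block = DECBAM(8, np.random.default_rng(0), reduction=2)
        for mod in (block.ds1, block.ds2):
            mod.norm.beta.data[...] = 0.0
            mod.dw.bias.data[...] = 0.0
            mod.pw.bias.data[...] = 0.0
        out = block(Tensor(np.zeros((1, 8, 6, 6))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)


class TestEncoderDecoder:
    def test_pyramid_shapes_at_reference_size(self):
        model = MultiScaleSegNet(TINY_CONFIG)
        with ad.no_grad():
            pyr = model.encode(Tensor(np.zeros((1, 1, 64, 96))))
        c1, c2, c3, c4 = TINY_CONFIG.stage_widths
        assert pyr.shapes() == ((1, c1, 64, 96), (1, c2, 32, 48),
                                (1, c3, 16, 24), (1, c4, 8, 12))

    def test_minimal_divisible_input(self):
        model = MultiScaleSegNet(MICRO_NET)
        with ad.no_grad():
            pyr = model.encode(Tensor(np.zeros((1, 1, 8, 8))))
        assert [s[2] for s in pyr.shapes()] == [8, 4, 2, 1]

    def test_indivisible_input_advises_crop(self):
        model = MultiScaleSegNet(MICRO_NET)
        with pytest.raises(ValueError, match="crop_or_pad"):
            model.encode(Tensor(np.zeros((1, 1, 30, 40))))

    def test_logits_shape_matches_input(self):
        model = MultiScaleSegNet(MICRO_NET)
        with ad.no_grad():
            logits = model.forward(np.zeros((2, 1, 16, 24)))
        assert logits.shape == (2, 9, 16, 24)

    def test_decoder_concat_channel_bookkeeping(self):
        cfg = TINY_CONFIG
        d1, d2, d3 = cfg.decoder_in_channels()
        c1, c2, c3, c4 = cfg.stage_widths
        assert d1 == c3 + c4
        assert d2 == c2 + d1 // 2
        assert d3 == c1 + d2 // 2
        model = MultiScaleSegNet(cfg)
        cap = {}
        with ad.no_grad():
            model.forward(np.zeros((1, 1, 16, 16)), capture=cap)
        assert cap["de_cbam1"].shape[1] == d1 // 2
        assert cap["de_cbam2"].shape[1] == d2 // 2
        assert cap["de_cbam3"].shape[1] == d3 // 2

    def test_odd_concat_width_is_a_build_time_error(self):
        with pytest.raises(ValueError, match="odd"):
            NetworkConfig(stage_widths=(4, 5, 8, 8)).validate()

    def test_forward_deterministic_under_fixed_seed(self, rng):
        x = rng.random((1, 1, 16, 16))
        a = MultiScaleSegNet(MICRO_NET).predict_logits(x)
        b = MultiScaleSegNet(MICRO_NET).predict_logits(x)
        np.testing.assert_array_equal(a, b)

    def test_softmax_normalised_per_pixel(self, rng):
        model = MultiScaleSegNet(MICRO_NET)
        proba = model.predict_proba(rng.random((1, 1, 16, 16)))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_predict_returns_valid_mask(self, rng):
        model = MultiScaleSegNet(MICRO_NET)
        mask = model.predict(rng.random((16, 24)))
        assert mask.shape == (16, 24)
        assert mask.min() >= 0 and mask.max() < 9

    def test_transposed_upsampling_variant_runs(self, rng):
        cfg = NetworkConfig(stage_widths=(4, 4, 8, 8), stage_depths=(1, 1, 1, 1),
                            upsample_mode="transposed")
        model = MultiScaleSegNet(cfg)
        with ad.no_grad():
            assert model.forward(rng.random((1, 1, 16, 16))).shape == (1, 9, 16, 16)


class TestParameters:
    def test_count_matches_independent_arithmetic(self):
        cfg = NetworkConfig(stage_widths=(4, 4, 8, 8), stage_depths=(1, 1, 1, 1),
                            depthwise_kernel=3, expansion_ratio=2,
                            cam_reduction=2, n_classes=3)

        def convnext_block(c):
            return (c * 9 + c) + 2 * c + (c * 2 * c + 2 * c) \
                + (2 * c * c + c) + c          # dw, LN, pw1, pw2, scale

        def cam(c):
            r = min(2, max(1, c // 2))
            h = max(1, c // r)
            return (c * h + h) + (h * c + c)

        def sam():
            return 2 * 49 + 1

        def ds(cin, cout):
            return (cin * 9 + cin) + (cin * cout + cout) + 2 * cout

        def de_cbam(c):
            return cam(c) + sam() + ds(c, c // 2) + ds(c // 2, c // 2)

        c1, c2, c3, c4 = cfg.stage_widths
        total = (1 * 16 * c1 + c1) + 2 * c1              # stem + stem LN
        total += convnext_block(c1)
        for cin, cout in ((c1, c2), (c2, c3), (c3, c4)):
            total += 2 * cin + (cin * 4 * cout + cout)   # LN + 2x2 down conv
            total += convnext_block(cout)
        d1, d2, d3 = cfg.decoder_in_channels()
        total += de_cbam(d1) + de_cbam(d2) + de_cbam(d3)
        g = d3 // 2
        total += (g * 9 * g + g) + 2 * g                  # output 3x3 conv + LN
        total += g * cfg.n_classes + cfg.n_classes        # head
        assert count_parameters(cfg) == total

    def test_doubling_widths_grows_between_2x_and_4x(self):
        base = NetworkConfig(stage_widths=(8, 16, 32, 64),
                             stage_depths=(1, 1, 1, 1))
        big = NetworkConfig(stage_widths=(16, 32, 64, 128),
                            stage_depths=(1, 1, 1, 1))
        ratio = count_parameters(big) / count_parameters(base)
        assert 2.0 < ratio <= 4.0

    def test_attention_variant_changes_only_attention_blocks(self):
        de = NetworkConfig(stage_widths=(8, 16, 32, 64), stage_depths=(1, 1, 1, 1),
                           attention_variant="de_cbam")
        plain = NetworkConfig(stage_widths=(8, 16, 32, 64),
                              stage_depths=(1, 1, 1, 1),
                              attention_variant="cbam")
        m_de = MultiScaleSegNet(de)
        m_plain = MultiScaleSegNet(plain)
        assert m_de.n_parameters() > m_plain.n_parameters()
        # encoder parameter names/shapes identical across variants
        enc_de = {k: v.shape for k, v in m_de.state_dict().items()
                  if not k.startswith(("dec", "up"))}
        enc_plain = {k: v.shape for k, v in m_plain.state_dict().items()
                     if not k.startswith(("dec", "up"))}
        assert enc_de == enc_plain


def test_gradient_reaches_every_parameter_group(rng):
    model = MultiScaleSegNet(MICRO_NET)
    x = rng.random((2, 1, 16, 16))
    y = rng.integers(0, 9, size=(2, 16, 16))
    loss = ad.softmax_cross_entropy(model.forward(x), y)
    loss.backward()
    by_group: dict = {}
    for name, p in model.named_parameters():
        group = name.split(".")[0]
        norm = 0.0 if p.grad is None else float(np.abs(p.grad).sum())
        by_group[group] = by_group.get(group, 0.0) + norm
    assert all(v > 0 for v in by_group.values()), by_group


def test_checkpoint_round_trip(tmp_path, rng):
    model = MultiScaleSegNet(MICRO_NET)
    x = rng.random((1, 1, 16, 16))
    before = model.predict_logits(x)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(model, path)
    restored = load_checkpoint(path)
    assert restored.config == model.config
    np.testing.assert_array_equal(restored.predict_logits(x), before)
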