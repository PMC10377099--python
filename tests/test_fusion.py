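"""Softmax weight maps, per-layer fusion, max reconstruction, full pipeline."""

import numpy as np
import pytest

from fusionet import backbone as bb
from fusionet import fusion as ff


def softmax_loop_oracle(acts):
    """Scalar-loop softmax across sources, one pixel at a time."""
    import math

    z = len(acts)
    h, w = acts[0].shape
    out = [np.empty((h, w)) for _ in range(z)]
    for i in range(h):
        for j in range(w):
            es = [math.exp(a[i, j]) for a in acts]
            tot = sum(es)
            for k in range(z):
                out[k][i, j] = es[k] / tot
    return out


def small_cfg(blocks=(1,), **kw):
    return ff.FusionConfig(
        backbone=bb.BackboneSpec(variant="vgg11", tap_blocks=blocks), **kw
    )


class TestWeightMaps:
    def test_identical_activities_give_half_half(self):
        a = np.random.default_rng(0).random((6, 6))
        w1, w2 = ff.weight_maps([a, a.copy()])
        np.testing.assert_array_equal(w1, np.full((6, 6), 0.5))
        np.testing.assert_array_equal(w2, np.full((6, 6), 0.5))

    def test_log2_offset_gives_one_third_two_thirds(self, rng):
        a = rng.random((5, 5))
        w1, w2 = ff.weight_maps([a, a + np.log(2.0)])
        np.testing.assert_allclose(w1, 1 / 3)
        np.testing.assert_allclose(w2, 2 / 3)

    def test_three_sources_match_scalar_loop_oracle(self, rng):
        acts = [rng.random((8, 8)) * 3 for _ in range(3)]
        ws = ff.weight_maps(acts)
        expected = softmax_loop_oracle(acts)
        for w, e in zip(ws, expected):
            np.testing.assert_allclose(w, e, atol=1e-12)
        np.testing.assert_allclose(sum(ws), 1.0, atol=1e-6)

    def test_shape_mismatch_and_single_source_rejected(self):
        with pytest.raises(ValueError):
            ff.weight_maps([np.zeros((4, 4)), np.zeros((4, 5))])
        with pytest.raises(ValueError):
            ff.weight_maps([np.zeros((4, 4))])


class TestFuseLayer:
    def test_identical_sources_identity_transconv(self, rng):
        img = rng.random((6, 6))
        w = np.full((6, 6), 0.5)
        out = ff.fuse_layer([img, img], [w, w], small_cfg())
        np.testing.assert_array_equal(out, img)

    def test_uniform_weights_give_convex_combination(self):
        a, b = np.full((4, 4), 0.2), np.full((4, 4), 0.8)
        w = np.full((4, 4), 0.5)
        out = ff.fuse_layer([a, b], [w, w], small_cfg())
        np.testing.assert_allclose(out, 0.5)

    def test_loop_oracle_both_operators(self, rng):
        from test_backbone import scatter_add_transposed_conv

        srcs = [rng.random((8, 8)), rng.random((8, 8))]
        raw = [rng.random((8, 8)) for _ in srcs]
        ws = [raw[0] / (raw[0] + raw[1]), raw[1] / (raw[0] + raw[1])]
        kernel_spec = bb.TransConvSpec(init="smoothing")
        enhanced = [
            scatter_add_transposed_conv(s, bb.transconv_kernel(kernel_spec), 1, 1)
            for s in srcs
        ]
        for operator in ("apply", "hadamard"):
            cfg = small_cfg(transconv=kernel_spec, eq7_operator=operator)
            out = ff.fuse_layer(srcs, ws, cfg)
            expected = np.zeros((8, 8))
            for i in range(8):
                for j in range(8):
                    for s, w, e in zip(srcs, ws, enhanced):
                        term = w[i, j] * e[i, j]
                        if operator == "hadamard":
                            term *= s[i, j]
                        expected[i, j] += term
            np.testing.assert_allclose(out, np.clip(expected, 0, 1), atol=1e-9)

    def test_block_resolution_weights_are_upsampled(self, rng):
        srcs = [rng.random((8, 8)), rng.random((8, 8))]
        ws = [np.full((4, 4), 0.5), np.full((4, 4), 0.5)]
        out = ff.fuse_layer(srcs, ws, small_cfg())
        np.testing.assert_allclose(out, 0.5 * (srcs[0] + srcs[1]), atol=1e-9)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ff.fuse_layer([rng.random((4, 4))], [], small_cfg())


class TestFuseMax:
    def test_single_layer_identity(self, rng):
        img = rng.random((5, 5))
        np.testing.assert_array_equal(ff.fuse_max([img]), img)

    def test_constant_layers_take_maximum(self):
        out = ff.fuse_max([np.full((4, 4), 0.3), np.full((4, 4), 0.7)])
        np.testing.assert_allclose(out, 0.7)

    def test_matches_loop_oracle(self, rng):
        imgs = [rng.random((6, 6)) for _ in range(3)]
        expected = np.empty((6, 6))
        for i in range(6):
            for j in range(6):
                expected[i, j] = max(img[i, j] for img in imgs)
        np.testing.assert_allclose(ff.fuse_max(imgs), expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ff.fuse_max([])


class TestFusePair:
    def test_self_fusion_is_exact_identity(self, rng):
        img = rng.random((16, 16))
        out = ff.fuse_pair(img, img, small_cfg())
        np.testing.assert_array_equal(out, img)

    def test_source_order_symmetry(self, phantom64_gray):
        s, f = phantom64_gray
        cfg = small_cfg()
        np.testing.assert_array_equal(ff.fuse_pair(s, f, cfg), ff.fuse_pair(f, s, cfg))

    def test_convex_hull_bound_identity_transconv(self, phantom64_gray):
        s, f = phantom64_gray
        fused = ff.fuse_pair(s, f, small_cfg(blocks=(1,)))
        lo, hi = np.minimum(s, f), np.maximum(s, f)
        assert np.all(fused >= lo - 1e-9) and np.all(fused <= hi + 1e-9)

    def test_adding_layers_never_decreases_pixels(self, phantom64_gray):
        s, f = phantom64_gray
        one = ff.fuse_pair(s, f, small_cfg(blocks=(1,)))
        two = ff.fuse_pair(s, f, small_cfg(blocks=(1, 3)))
        assert np.all(two >= one - 1e-12)

    def test_three_source_fusion_supported(self, rng):
        srcs = [rng.random((16, 16)) for _ in range(3)]
        out = ff.fuse_sources(srcs, small_cfg())
        assert out.shape == (16, 16)
        lo = np.minimum.reduce(srcs)
        hi = np.maximum.reduce(srcs)
        assert np.all(out >= lo - 1e-9) and np.all(out <= hi + 1e-9)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ff.fuse_pair(rng.random((8, 8)), rng.random((8, 9)), small_cfg())

    def test_config_roundtrip(self):
        cfg = small_cfg(blocks=(1, 4), eq7_operator="hadamard")
        assert ff.FusionConfig.from_dict(cfg.to_dict()) == cfg
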