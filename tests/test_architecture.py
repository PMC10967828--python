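"""Oracle and structure tests for the hybrid attention U-Net building blocks."""

import numpy as np
import pytest

from octseg import (
    EdgeKernels,
    ModelConfig,
    build_ablation_variant,
    build_model,
    canny_edge_response,
    residual_skip,
    spatial_attention,
)
from octseg.architecture import (
    SOBEL_LONGITUDINAL,
    SOBEL_TRANSVERSE,
    EdgeAttentionBlock,
    SpatialAttentionBlock,
)
from octseg.exceptions import ArgumentError, ConfigurationError
from octseg.nn.core import Tensor, _sigmoid

RNG = np.random.default_rng(77)


def brute_force_conv_same(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Dense true 2D convolution, edge-replicated padding, nested loops."""
    h, w = image.shape
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    out = np.zeros_like(image, dtype=float)
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for i in range(kh):
                for j in range(kw):
                    rr = min(max(r - (i - ph), 0), h - 1)
                    cc = min(max(c - (j - pw), 0), w - 1)
                    acc += image[rr, cc] * kernel[i, j]
            out[r, c] = acc
    return out


class TestCannyEdgeResponse:
    def test_constant_map_gives_zero_response(self):
        x = np.full((1, 8, 8), 5.0)
        np.testing.assert_allclose(canny_edge_response(x), 0.0, atol=1e-12)

    def test_matches_brute_force_convolution_on_random_maps(self):
        kernels = EdgeKernels()
        for _ in range(100):
            x = RNG.normal(size=(1, 8, 8))
            got = canny_edge_response(x, kernels)[0]
            want = (brute_force_conv_same(x[0], kernels.transverse)
                    + brute_force_conv_same(x[0], kernels.longitudinal))
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_vertical_step_response_localised_to_step(self):
        x = np.zeros((1, 8, 8))
        x[0, :, 4:] = 1.0
        resp = canny_edge_response(x)[0]
        # interior rows: response only on the two columns astride the step
        inner = resp[1:-1]
        assert np.abs(inner[:, [3, 4]]).min() > 0
        np.testing.assert_allclose(inner[:, [0, 1, 6, 7]], 0.0, atol=1e-12)

    def test_unit_impulse_reproduces_kernel_sum(self):
        # delta-input convolution identity: conv(delta, K) == K centred at
        # the impulse (true-convolution semantics, no flip in the output)
        x = np.zeros((1, 9, 9))
        x[0, 4, 4] = 1.0
        resp = canny_edge_response(x)[0]
        ksum = SOBEL_TRANSVERSE + SOBEL_LONGITUDINAL
        np.testing.assert_allclose(resp[3:6, 3:6], ksum, atol=1e-12)
        outside = resp.copy()
        outside[3:6, 3:6] = 0.0
        np.testing.assert_allclose(outside, 0.0, atol=1e-12)

    def test_horizontal_flip_equivariance(self):
        # the transverse kernel is antisymmetric in the lateral direction, so
        # flip(response(x)) == response(flip(x)) up to that kernel's mirror sign
        x = RNG.normal(size=(2, 8, 8))
        lon = canny_edge_response(x, EdgeKernels(np.zeros((3, 3)), SOBEL_LONGITUDINAL))
        np.testing.assert_allclose(
            lon[:, :, ::-1],
            canny_edge_response(x[:, :, ::-1],
                                EdgeKernels(np.zeros((3, 3)), SOBEL_LONGITUDINAL)),
            atol=1e-12)
        tra = canny_edge_response(x, EdgeKernels(SOBEL_TRANSVERSE, np.zeros((3, 3))))
        np.testing.assert_allclose(
            -tra[:, :, ::-1],
            canny_edge_response(x[:, :, ::-1],
                                EdgeKernels(SOBEL_TRANSVERSE, np.zeros((3, 3)))),
            atol=1e-12)

    def test_nonzero_sum_kernel_rejected(self):
        with pytest.raises(ConfigurationError):
            canny_edge_response(np.zeros((1, 8, 8)),
                                EdgeKernels(np.ones((3, 3)), SOBEL_LONGITUDINAL))

    def test_kernel_larger_than_map_rejected(self):
        with pytest.raises(ArgumentError):
            canny_edge_response(np.zeros((1, 2, 2)))


class TestResidualSkip:
    def test_unique_max_zeroed(self):
        x = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        pooled, residual = residual_skip(x, 2)
        np.testing.assert_array_equal(pooled, [[[4.0]]])
        np.testing.assert_array_equal(residual, [[[1.0, 2.0], [3.0, 0.0]]])

    def test_tie_breaks_to_first_row_major_position(self):
        x = np.full((1, 2, 2), 7.0)
        _, residual = residual_skip(x, 2)
        np.testing.assert_array_equal(residual, [[[0.0, 7.0], [7.0, 7.0]]])

    def test_scatter_reconstruction_identity_on_random_maps(self):
        for _ in range(1000):
            x = RNG.normal(size=(1, 8, 8))
            pooled, residual = residual_skip(x, 2)
            recon = residual.copy()
            for bi in range(4):
                for bj in range(4):
                    block = recon[0, 2 * bi:2 * bi + 2, 2 * bj:2 * bj + 2]
                    flat = x[0, 2 * bi:2 * bi + 2, 2 * bj:2 * bj + 2].ravel()
                    i, j = divmod(int(flat.argmax()), 2)
                    assert block[i, j] == 0.0
                    block[i, j] = pooled[0, bi, bj]
            np.testing.assert_array_equal(recon, x)

    def test_indivisible_dims_rejected(self):
        with pytest.raises(ArgumentError):
            residual_skip(np.zeros((1, 5, 4)), 2)


class TestSpatialAttention:
    def test_zero_input_gives_half_attention_and_zero_output(self):
        out, att = spatial_attention(np.zeros((3, 4, 4)))
        np.testing.assert_allclose(att, 0.5)
        np.testing.assert_allclose(out, 0.0)

    def test_attention_strictly_inside_unit_interval(self):
        _, att = spatial_attention(RNG.normal(size=(4, 6, 6)) * 10)
        assert np.all(att > 0) and np.all(att < 1)

    def test_single_channel_reduces_to_x_times_sigmoid_x(self):
        x = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        out, att = spatial_attention(x)
        np.testing.assert_allclose(att, _sigmoid(x[0]))
        np.testing.assert_allclose(out, x * _sigmoid(x))


class TestEdgeAttentionBlock:
    def _block(self, skip_ch=4, gate_ch=4):
        rng = np.random.default_rng(3)
        return EdgeAttentionBlock(skip_ch, gate_ch, rng, dtype=np.float64)

    def test_alpha_one_returns_enhanced_features(self):
        block = self._block()
        block.psi.weight.data[:] = 0.0
        block.psi.bias.data[:] = 60.0          # sigmoid saturates to 1
        skip = Tensor(RNG.normal(size=(1, 4, 8, 8)))
        gate = Tensor(RNG.normal(size=(1, 4, 8, 8)))
        out = block(skip, gate)
        enhanced = skip.data + canny_edge_response(skip.data)
        np.testing.assert_allclose(out.data, enhanced, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(block.last_alpha, 1.0)

    def test_alpha_zero_returns_zeros(self):
        block = self._block()
        block.psi.weight.data[:] = 0.0
        block.psi.bias.data[:] = -60.0
        out = block(Tensor(RNG.normal(size=(1, 4, 8, 8))),
                    Tensor(RNG.normal(size=(1, 4, 8, 8))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_matches_straight_line_composition_oracle(self):
        block = self._block()
        skip = RNG.normal(size=(1, 4, 8, 8))
        gate = RNG.normal(size=(1, 4, 8, 8))
        out = block(Tensor(skip), Tensor(gate)).data

        # independent straight-line forward pass: edge response -> fuse ->
        # additive gate -> sigmoid -> multiply
        enhanced = skip + canny_edge_response(skip)
        ws, bs = block.w_skip.weight.data, block.w_skip.bias.data
        wg, bg = block.w_gate.weight.data, block.w_gate.bias.data
        wp, bp = block.psi.weight.data, block.psi.bias.data
        pre = (enhanced[0].reshape(4, -1).T @ ws[:, :, 0, 0].T + bs
               + gate[0].reshape(4, -1).T @ wg[:, :, 0, 0].T + bg)
        hid = np.maximum(pre, 0.0)
        alpha = _sigmoid(hid @ wp[:, :, 0, 0].T + bp).T.reshape(1, 1, 8, 8)
        np.testing.assert_allclose(out, enhanced * alpha, rtol=1e-8, atol=1e-10)
        assert block.last_alpha.min() >= 0.0 and block.last_alpha.max() <= 1.0

    def test_gate_upsampled_to_skip_resolution(self):
        block = self._block(skip_ch=4, gate_ch=6)
        out = block(Tensor(RNG.normal(size=(1, 4, 8, 8))),
                    Tensor(RNG.normal(size=(1, 6, 4, 4))), upsample_gate=True)
        assert out.data.shape == (1, 4, 8, 8)

    def test_incompatible_spatial_dims_rejected(self):
        block = self._block()
        with pytest.raises(ArgumentError):
            block(Tensor(np.zeros((1, 4, 8, 8))), Tensor(np.zeros((1, 4, 4, 4))))


class TestModelStructure:
    def test_default_layout_counts(self, tiny_model):
        counts = tiny_model.count_blocks()
        assert counts["encoder_stages"] == 5
        assert counts["decoder_stages"] == 5
        assert counts["base_stages"] == 1
        assert counts["edge_attention"] == 2
        assert counts["spatial_attention"] == 3

    @pytest.mark.parametrize("code,n_ea,n_sa", [
        ("A", 2, 3), ("B", 2, 3), ("C", 5, 0), ("D", 0, 5),
    ])
    def test_ablation_variant_block_counts(self, code, n_ea, n_sa):
        cfg = ModelConfig(depth=5, base_channels=2, input_shape=(64, 32))
        model = build_ablation_variant(code, cfg)
        counts = model.count_blocks()
        assert counts["edge_attention"] == n_ea
        assert counts["spatial_attention"] == n_sa
        if code in ("C", "D"):
            kinds = set(model.skip_layout.values())
            assert kinds == {"EA" if code == "C" else "SA"}

    def test_unknown_ablation_code_rejected(self):
        with pytest.raises(ArgumentError):
            build_ablation_variant("X")

    def test_indivisible_input_shape_rejected(self):
        with pytest.raises(ConfigurationError):
            build_model(ModelConfig(depth=5, input_shape=(100, 60)))

    def test_forward_softmax_on_probability_simplex(self, tiny_model):
        probs = tiny_model.predict_proba(RNG.random((2, 64, 32)).astype(np.float32))
        assert probs.shape == (2, 5, 64, 32)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_attention_coefficients_within_unit_interval(self, tiny_model):
        tiny_model.predict_proba(RNG.random((2, 64, 32)).astype(np.float32))
        maps = tiny_model.attention_maps()
        assert len(maps) == 5
        for arr in maps.values():
            assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_inference_deterministic_given_fixed_weights(self, tiny_model):
        x = RNG.random((1, 64, 32)).astype(np.float32)
        np.testing.assert_array_equal(tiny_model.predict_proba(x),
                                      tiny_model.predict_proba(x))

    def test_save_load_roundtrip(self, tiny_model, tmp_path):
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        clone = build_model(ModelConfig(depth=5, base_channels=2,
                                        input_shape=(64, 32), seed=9))
        clone.load(path)
        x = RNG.random((1, 64, 32)).astype(np.float32)
        np.testing.assert_array_equal(tiny_model.predict_proba(x),
                                      clone.predict_proba(x))

    def test_summary_reports_layout(self, tiny_model):
        summary = tiny_model.summary()
        assert [s["skip_attention"] for s in summary["stages"]] == \
            ["EA", "EA", "SA", "SA", "SA"]
        assert summary["n_parameters"] == tiny_model.n_parameters()
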