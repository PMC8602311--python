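"""Architectures: shape contracts, depth collapse, spectral norm, and the
autodiff engine they are built on."""

import numpy as np
import pytest

from rcmstain import nn
from rcmstain.nn import Tensor, ops
from rcmstain.networks import (Generator, GeneratorConfig, Discriminator,
                               DiscriminatorConfig, build_vshe_network,
                               architecture_summary, save_checkpoint,
                               load_checkpoint)


@pytest.fixture(scope="module")
def tiny_generator():
    return Generator(GeneratorConfig(base_channels=4, seed=0))


class TestGenerator:
    def test_seven_slice_input_maps_to_single_image(self, tiny_generator,
                                                    rng):
        out = tiny_generator(rng.random((7, 64, 64)))
        assert out.shape == (1, 64, 64)

    def test_depth_collapses_seven_five_three_one(self, tiny_generator):
        assert tiny_generator.depth_trace() == [7, 5, 3, 1]

    def test_wrong_slice_count_rejected(self, tiny_generator, rng):
        with pytest.raises(ValueError, match="7 input slices"):
            tiny_generator(rng.random((5, 64, 64)))

    def test_indivisible_spatial_size_prescribes_padding(self, tiny_generator,
                                                         rng):
        with pytest.raises(ValueError, match="divisible"):
            tiny_generator(rng.random((7, 60, 60)))

    def test_even_input_depth_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            Generator(GeneratorConfig(input_depth=6))

    def test_attention_toggle_preserves_shapes(self, rng):
        x = rng.random((7, 64, 64))
        for gates in (True, False):
            g = Generator(GeneratorConfig(base_channels=4,
                                          attention_gates=gates, seed=1))
            assert g(x).shape == (1, 64, 64)

    def test_output_in_unit_interval(self, tiny_generator, rng):
        out = tiny_generator(rng.random((7, 64, 64))).data
        assert out.min() > 0.0 and out.max() < 1.0

    def test_deterministic_under_fixed_weights(self, tiny_generator, rng):
        x = rng.random((7, 64, 64))
        a = tiny_generator.infer(x)
        b = tiny_generator.infer(x)
        assert np.array_equal(a, b)

    def test_translation_covariant_at_stride_multiples(self, rng):
        # shallow configuration keeps the receptive field inside the
        # comparison margin; shift by the full downsampling stride
        g = Generator(GeneratorConfig(input_depth=1, n_levels=2,
                                      base_channels=4, seed=2))
        img = rng.random((96, 96))
        g.train()
        g(img)                    # populate batch-norm running statistics
        g.eval()
        shift = 4                 # 2^2
        out = g.infer(img)
        out_shifted = g.infer(np.roll(img, shift, axis=1))
        m = 40
        np.testing.assert_allclose(
            out_shifted[m:-m, m + shift:-m],
            out[m:-m, m:-m - shift], atol=1e-6)

    def test_checkpoint_round_trip(self, tiny_generator, rng, tmp_path):
        x = rng.random((7, 64, 64))
        ref = tiny_generator.infer(x)
        path = tmp_path / "gen.npz"
        save_checkpoint(tiny_generator, path)
        clone = Generator(GeneratorConfig(base_channels=4, seed=99))
        load_checkpoint(clone, path)
        assert np.allclose(clone.infer(x), ref)

    def test_architecture_summary_counts_parameters(self, tiny_generator):
        summary = architecture_summary(tiny_generator)
        assert summary["n_parameters"] > 0
        assert all(len(s) >= 1 for s in summary["tensors"].values())


class TestDiscriminator:
    def test_score_in_open_unit_interval(self, rng):
        d = Discriminator(DiscriminatorConfig(base_channels=4, fc_width=32))
        s = d(rng.random((64, 64))).item()
        assert 0.0 < s < 1.0

    def test_not_constant_across_inputs(self, rng):
        d = Discriminator(DiscriminatorConfig(base_channels=4, fc_width=32))
        s1 = d(rng.random((64, 64))).item()
        s2 = d(np.zeros((64, 64))).item()
        assert s1 != pytest.approx(s2, abs=1e-9)

    def test_too_small_input_rejected(self, rng):
        d = Discriminator(DiscriminatorConfig(base_channels=4, fc_width=32))
        with pytest.raises(ValueError, match="too small"):
            d(rng.random((16, 16)))

    def test_spectral_norm_bounds_weight_spectrum(self, rng):
        d = Discriminator(DiscriminatorConfig(base_channels=4, fc_width=32,
                                              spectral_norm=True))
        for mod in d.modules():
            if isinstance(mod, nn.Conv2d) and mod.spectral_norm:
                for _ in range(1000):  # converge the power iteration
                    w = mod._normalized_weight().data
                sigma = np.linalg.svd(
                    w.reshape(w.shape[0], -1), compute_uv=False)[0]
                assert sigma <= 1.0 + 1e-3


class TestVsheNetwork:
    def test_two_channel_input_three_channel_output(self, rng):
        net = build_vshe_network(base_channels=4, n_levels=2)
        out = net(rng.random((2, 64, 64)))
        assert out.shape == (1, 3, 64, 64)

    def test_output_bounded_in_unit_interval(self, rng):
        net = build_vshe_network(base_channels=4, n_levels=2)
        out = net(rng.random((2, 64, 64))).data
        assert out.min() > 0.0 and out.max() < 1.0

    def test_wrong_channel_count_rejected(self, rng):
        net = build_vshe_network(base_channels=4, n_levels=2)
        with pytest.raises(ValueError, match="channels"):
            net(rng.random((4, 3, 64, 64)))


class TestAutodiffEngine:
    def test_gradients_match_finite_differences_through_unet(self, rng):
        cfg = GeneratorConfig(input_depth=1, n_levels=1, base_channels=2,
                              seed=3)
        x = Tensor(rng.random((1, 1, 4, 4)), requires_grad=True)
        model = Generator(cfg)
        loss = (model(x) ** 2).sum()
        loss.backward()
        eps = 1e-6
        num = np.zeros_like(x.data)
        for idx in np.ndindex(x.data.shape):
            xp, xm = x.data.copy(), x.data.copy()
            xp[idx] += eps
            xm[idx] -= eps
            lp = (Generator(cfg)(Tensor(xp)) ** 2).sum().item()
            lm = (Generator(cfg)(Tensor(xm)) ** 2).sum().item()
            num[idx] = (lp - lm) / (2 * eps)
        rel = np.abs(num - x.grad).max() / (np.abs(num).max() + 1e-12)
        assert rel < 1e-6

    def test_flow_warp_gradient_matches_finite_differences(self, rng):
        img = rng.random((1, 1, 8, 8))
        flow = Tensor(rng.normal(0, 0.5, size=(1, 2, 8, 8)),
                      requires_grad=True)
        out = ops.flow_warp(img, flow)
        (out ** 2).sum().backward()
        eps = 1e-6
        inner = np.s_[:, :, 2:-2, 2:-2]
        num = np.zeros_like(flow.data)
        for idx in np.ndindex(flow.data.shape):
            fp, fm = flow.data.copy(), flow.data.copy()
            fp[idx] += eps
            fm[idx] -= eps
            lp = float((ops.flow_warp(img, Tensor(fp)).data ** 2).sum())
            lm = float((ops.flow_warp(img, Tensor(fm)).data ** 2).sum())
            num[idx] = (lp - lm) / (2 * eps)
        assert np.abs((num - flow.grad)[inner]).max() < 1e-5
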