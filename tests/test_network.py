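"""Network building blocks and the assembled generator."""

import numpy as np
import pytest

from mrisr.attention import pcfb
from mrisr.autodiff import Tensor
from mrisr.losses import composite_loss
from mrisr.network import (
    Conv2d,
    LayerNorm,
    ModelConfig,
    PReLU,
    build_model,
    count_parameters,
    load_checkpoint,
    pixel_shuffle,
    save_checkpoint,
)


def tiny_config(**kw) -> ModelConfig:
    base = dict(scale_factor=2, n_chunks=2, n_res_blocks=2, n_features=8)
    base.update(kw)
    return ModelConfig(**base)


class TestPReLU:
    def test_piecewise_definition(self):
        act = PReLU(1, init=0.25)
        x = np.array([2.0, -2.0, 0.0]).reshape(1, 1, 1, 3)
        np.testing.assert_allclose(act(x), [[[[2.0, -0.5, 0.0]]]])

    def test_unit_slope_is_identity(self, rng):
        act = PReLU(3, init=1.0)
        x = rng.normal(size=(2, 3, 4, 4))
        np.testing.assert_array_equal(act(x), x)

    def test_slope_is_per_channel(self, rng):
        act = PReLU(2, init=0.5)
        act.slope.data = np.array([0.0, 1.0])
        x = -np.ones((1, 2, 2, 2))
        out = act(x)
        np.testing.assert_allclose(out[0, 0], 0.0)
        np.testing.assert_allclose(out[0, 1], -1.0)


class TestLayerNorm:
    def test_standardized_input_is_fixed_point(self, rng):
        x = rng.normal(size=(2, 4, 6, 6))
        x = (x - x.mean(axis=(1, 2, 3), keepdims=True)) / x.std(axis=(1, 2, 3), keepdims=True)
        ln = LayerNorm(4, eps=1e-10)
        np.testing.assert_allclose(ln(x), x, atol=1e-4)

    def test_two_value_sample(self):
        ln = LayerNorm(1, eps=1e-12)
        x = np.array([1.0, 3.0]).reshape(1, 1, 1, 2)
        np.testing.assert_allclose(ln(x).ravel(), [-1.0, 1.0], atol=1e-5)

    def test_zero_gamma_gives_beta(self, rng):
        ln = LayerNorm(2)
        ln.gamma.data = np.zeros(2)
        ln.beta.data = np.array([0.3, -0.7])
        out = ln(rng.normal(size=(1, 2, 3, 3)))
        np.testing.assert_allclose(out[0, 0], 0.3)
        np.testing.assert_allclose(out[0, 1], -0.7)

    def test_output_standardized_per_sample(self, rng):
        ln = LayerNorm(4, eps=1e-12)
        out = ln(rng.normal(size=(3, 4, 5, 5)) * 5 + 2)
        np.testing.assert_allclose(out.mean(axis=(1, 2, 3)), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.var(axis=(1, 2, 3)), 1.0, atol=1e-6)


class TestPixelShuffle:
    def test_identity_at_r1(self, feature_map):
        np.testing.assert_array_equal(pixel_shuffle(feature_map, 1), feature_map)

    def test_four_channel_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 4, 1, 1)
        np.testing.assert_array_equal(
            pixel_shuffle(x, 2)[0, 0], np.array([[1.0, 2.0], [3.0, 4.0]])
        )

    def test_matches_index_loop_oracle(self, rng):
        x = rng.normal(size=(2, 8, 3, 4))
        r = 2
        got = pixel_shuffle(x, r)
        want = np.zeros((2, 2, 6, 8))
        for b in range(2):
            for c in range(2):
                for h in range(3):
                    for w in range(4):
                        for i in range(r):
                            for j in range(r):
                                want[b, c, h * r + i, w * r + j] = x[b, c * r * r + i * r + j, h, w]
        np.testing.assert_array_equal(got, want)

    def test_preserves_pixel_multiset(self, rng):
        x = rng.normal(size=(1, 9, 2, 2))
        np.testing.assert_allclose(
            np.sort(pixel_shuffle(x, 3).ravel()), np.sort(x.ravel())
        )

    def test_indivisible_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            pixel_shuffle(rng.normal(size=(1, 6, 2, 2)), 2)


class TestBuildModel:
    def test_same_seed_bit_identical(self):
        cfg = tiny_config()
        a = build_model(cfg, seed=9)
        b = build_model(cfg, seed=9)
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_published_chunking_config_builds(self):
        build_model(ModelConfig(n_features=64, n_chunks=2, n_res_blocks=2), seed=0)

    def test_indivisible_chunking_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(n_features=64, n_chunks=3).validate()

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError, match="scale_factor"):
            ModelConfig(scale_factor=5).validate()


class TestForward:
    @pytest.mark.parametrize("r,h,w", [(2, 24, 24), (1, 16, 16), (3, 8, 10)])
    def test_output_scale_contract(self, rng, r, h, w):
        model = build_model(tiny_config(scale_factor=r), seed=0)
        out = model.forward(rng.random((2, 1, h, w)))
        assert out.shape == (2, 1, h * r, w * r)

    def test_scale_four_uses_two_stages(self, rng):
        model = build_model(tiny_config(scale_factor=4), seed=0)
        assert model.forward(rng.random((1, 1, 6, 6))).shape == (1, 1, 24, 24)

    def test_repeated_calls_identical(self, rng):
        model = build_model(tiny_config(), seed=1)
        x = rng.random((1, 1, 12, 12))
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_nonfinite_input_rejected(self):
        model = build_model(tiny_config(), seed=0)
        bad = np.full((1, 1, 8, 8), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            model.forward(bad)

    def test_zeroed_residual_branches_act_as_identity(self, rng):
        """With both branch convs and the LN shift zeroed, every residual
        block must pass its input through unchanged."""
        model = build_model(tiny_config(), seed=3)
        x = rng.normal(size=(1, 8, 6, 6))
        for block in model.blocks:
            block.conv1.weight.data[:] = 0.0
            block.conv1.bias.data[:] = 0.0
            block.conv2.weight.data[:] = 0.0
            block.conv2.bias.data[:] = 0.0
            block.norm.beta.data[:] = 0.0
            np.testing.assert_array_equal(block(x), x)

    def test_tensor_mode_matches_ndarray_mode(self, rng):
        model = build_model(tiny_config(), seed=2)
        x = rng.random((2, 1, 10, 10))
        np.testing.assert_allclose(
            model.forward(Tensor(x)).data, model.forward(x), atol=1e-12
        )


class TestParameterCount:
    def test_single_conv_enumeration(self):
        conv = Conv2d(1, 1, 3, 1, np.random.default_rng(0))
        assert count_parameters(conv) == 10  # 9 kernel weights + 1 bias

    def test_pcfb_is_parameter_neutral(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = int(rng.choice([1, 2, 4]))
            cfg = dict(
                scale_factor=int(rng.choice([1, 2, 3, 4])),
                n_res_blocks=int(rng.integers(1, 4)),
                n_features=int(rng.choice([8, 16])),
                n_chunks=n,
                pcfb_every_block=bool(rng.integers(0, 2)),
            )
            with_pcfb = build_model(ModelConfig(use_pcfb=True, **cfg), seed=0)
            without = build_model(ModelConfig(use_pcfb=False, **cfg), seed=0)
            assert count_parameters(with_pcfb) == count_parameters(without)

    def test_count_invariant_to_seed(self):
        cfg = tiny_config()
        assert count_parameters(build_model(cfg, 0)) == count_parameters(build_model(cfg, 99))


class TestCheckpoint:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        model = build_model(tiny_config(), seed=5)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        assert loaded.config == model.config
        for (na, pa), (nb, pb) in zip(model.named_parameters(), loaded.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)
        x = rng.random((1, 1, 8, 8))
        np.testing.assert_array_equal(model.forward(x), loaded.forward(x))


def test_composite_loss_gradient_matches_finite_difference(rng):
    """Autodiff gradient of the full training objective against a central
    finite difference on a sampled weight, on a tiny model."""
    model = build_model(tiny_config(n_res_blocks=1, n_features=4, n_chunks=2), seed=4)
    lr = rng.random((2, 1, 6, 6))
    hr = rng.random((2, 1, 12, 12))

    def loss_value():
        total, _ = composite_loss(model.forward(lr), hr)
        return float(total)

    total, _ = composite_loss(model.forward(Tensor(lr)), hr)
    model.zero_grad()
    total.backward()

    checked = 0
    rng2 = np.random.default_rng(0)
    for name, p in model.named_parameters():
        if "block0.conv2.weight" in name or "out_conv.weight" in name:
            flat_idx = int(rng2.integers(p.data.size))
            idx = np.unravel_index(flat_idx, p.data.shape)
            orig = p.data[idx]
            eps = 1e-5
            p.data[idx] = orig + eps
            up = loss_value()
            p.data[idx] = orig - eps
            dn = loss_value()
            p.data[idx] = orig
            numeric = (up - dn) / (2 * eps)
            auto = p.grad[idx]
            assert abs(auto - numeric) <= 1e-3 * max(1.0, abs(numeric))
            checked += 1
    assert checked == 2
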