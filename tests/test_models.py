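"""Architecture contracts: shape preservation, residual identity, discriminator
output range, parameter counting, gradient flow."""

import numpy as np
import pytest

from fundusgan import nd
from fundusgan.errors import ConfigurationError, InvalidParameterError
from fundusgan.models import (
    DiscriminatorSpec,
    GeneratorSpec,
    PatchDiscriminator,
    build_discriminator,
    build_generator,
    count_parameters,
    residual_block_forward,
    zero_parameters,
)
from fundusgan.nd import Tensor

FAMILIES = ["unet", "resnet6", "resnet9", "resunet"]


def _tiny_spec(family, in_ch=3, width=4, depth=2):
    return GeneratorSpec(family=family, in_channels=in_ch, base_width=width,
                         depth=depth, n_res_blocks=1)


class TestGeneratorShapes:
    @pytest.mark.parametrize("family", FAMILIES)
    @pytest.mark.parametrize("size", [64, 128])
    def test_output_matches_input_resolution(self, family, size):
        gen = build_generator(_tiny_spec(family), rng=0)
        x = Tensor(np.zeros((1, 3, size, size), np.float32))
        out = gen(x)
        assert out.shape == (1, 3, size, size)
        assert (out.data >= -1.0).all() and (out.data <= 1.0).all()

    def test_single_channel_conditioning(self):
        gen = build_generator(_tiny_spec("unet", in_ch=1), rng=0)
        out = gen(Tensor(np.zeros((2, 1, 32, 32), np.float32)))
        assert out.shape == (2, 3, 32, 32)

    def test_indivisible_input_raises_named_constraint(self):
        gen = build_generator(_tiny_spec("unet", depth=3), rng=0)
        with pytest.raises(ConfigurationError, match="divisible"):
            gen(Tensor(np.zeros((1, 3, 36, 36), np.float32)))

    def test_invalid_specs_rejected(self):
        with pytest.raises(InvalidParameterError):
            GeneratorSpec(family="vgg")
        with pytest.raises(InvalidParameterError):
            GeneratorSpec(family="resunet", n_res_blocks=4)
        with pytest.raises(InvalidParameterError):
            GeneratorSpec(in_channels=2)


class TestResidualBlocks:
    def test_zeroed_branch_is_exact_identity(self, rng):
        block = nd.ResidualBlock(4, rng)
        for p in block.parameters():
            p.data[...] = 0.0
        x = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        out = block(Tensor(x))
        np.testing.assert_array_equal(out.data, x)

    def test_forward_zero_input_returns_branch_output(self):
        b = np.float32(1.5)
        out = residual_block_forward(np.zeros((2, 2), np.float32),
                                     lambda t: Tensor(np.full((2, 2), b)))
        np.testing.assert_array_equal(out.data, np.full((2, 2), b))

    def test_forward_matches_elementwise_sum(self, rng):
        x = rng.normal(size=(3, 5)).astype(np.float32)
        w = rng.normal(size=(3, 5)).astype(np.float32)
        out = residual_block_forward(x, lambda t: nd.mul(t, Tensor(w)))
        np.testing.assert_allclose(out.data, x + x * w, rtol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        x = rng.normal(size=(2, 2)).astype(np.float32)
        with pytest.raises(InvalidParameterError):
            residual_block_forward(x, lambda t: Tensor(np.zeros((3, 3), np.float32)))


class TestDiscriminator:
    def test_outputs_in_open_unit_interval(self, rng):
        disc = build_discriminator(DiscriminatorSpec(in_channels=6, base_width=8,
                                                     n_layers=3), rng=1)
        cond = Tensor(rng.normal(size=(1, 3, 32, 32)).astype(np.float32))
        img = Tensor(rng.normal(size=(1, 3, 32, 32)).astype(np.float32))
        p = disc(cond, img).data
        assert (p > 0.0).all() and (p < 1.0).all()

    def test_zero_init_outputs_exactly_half(self, rng):
        disc = build_discriminator(DiscriminatorSpec(in_channels=6, base_width=8,
                                                     n_layers=3), rng=1)
        zero_parameters(disc)
        x = Tensor(rng.normal(size=(1, 6, 32, 32)).astype(np.float32))
        assert (disc(x).data == 0.5).all()

    def test_fully_convolutional_doubling(self, rng):
        disc = build_discriminator(DiscriminatorSpec(in_channels=6, base_width=8,
                                                     n_layers=3), rng=1)
        p1 = disc(Tensor(np.zeros((1, 6, 32, 32), np.float32))).data
        p2 = disc(Tensor(np.zeros((1, 6, 64, 64), np.float32))).data
        assert p2.shape[2] == 2 * p1.shape[2] and p2.shape[3] == 2 * p1.shape[3]

    def test_channel_mismatch_rejected(self, rng):
        disc = build_discriminator(DiscriminatorSpec(in_channels=6), rng=0)
        with pytest.raises(ConfigurationError):
            disc(Tensor(np.zeros((1, 4, 16, 16), np.float32)))


class TestParameterCounting:
    def test_single_conv_with_bias(self, rng):
        conv = nd.Conv2d(1, 1, 3, rng)
        assert count_parameters(conv) == 10  # 9 weights + 1 bias

    def test_frozen_model_counts_zero(self, rng):
        conv = nd.Conv2d(2, 2, 3, rng)
        for p in conv.parameters():
            p.requires_grad = False
        assert count_parameters(conv) == 0

    def test_additive_over_submodules(self, rng):
        a = nd.Conv2d(1, 4, 3, rng)
        b = nd.Conv2d(4, 1, 3, rng)
        assert count_parameters(nd.Sequential(a, b)) == (
            count_parameters(a) + count_parameters(b)
        )

    def test_resunet_has_more_parameters_than_unet(self):
        unet = build_generator(_tiny_spec("unet"), rng=0)
        resunet = build_generator(_tiny_spec("resunet"), rng=0)
        assert count_parameters(resunet) > count_parameters(unet)

    def test_resnet9_has_more_parameters_than_resnet6(self):
        r6 = build_generator(_tiny_spec("resnet6"), rng=0)
        r9 = build_generator(_tiny_spec("resnet9"), rng=0)
        assert count_parameters(r9) > count_parameters(r6)

    def test_more_res_blocks_more_parameters(self):
        c1 = count_parameters(build_generator(
            GeneratorSpec(family="resunet", base_width=4, depth=2, n_res_blocks=1), 0))
        c3 = count_parameters(build_generator(
            GeneratorSpec(family="resunet", base_width=4, depth=2, n_res_blocks=3), 0))
        assert c3 > c1


class TestGradientFlow:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_every_parameter_receives_gradient(self, family, rng):
        gen = build_generator(_tiny_spec(family), rng=2)
        x = Tensor(rng.normal(size=(1, 3, 16, 16)).astype(np.float32))
        loss = nd.mean_all(nd.square(gen(x)))
        loss.backward()
        for name, p in gen.named_parameters():
            assert p.grad is not None, f"no gradient for {name}"
            assert np.isfinite(p.grad).all(), f"non-finite gradient for {name}"

    def test_discriminator_parameters_receive_gradient(self, rng):
        disc = build_discriminator(DiscriminatorSpec(in_channels=6, base_width=8,
                                                     n_layers=3), rng=3)
        x = Tensor(rng.normal(size=(1, 6, 32, 32)).astype(np.float32))
        loss = nd.mean_all(nd.square(disc(x)))
        loss.backward()
        for name, p in disc.named_parameters():
            assert p.grad is not None and np.isfinite(p.grad).all(), name
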