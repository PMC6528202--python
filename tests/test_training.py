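"""Training loops: bookkeeping, seed determinism, learning trends,
checkpointing and inference."""

import numpy as np
import pytest

from fundusgan import masks
from fundusgan.errors import ConfigurationError, InvalidParameterError
from fundusgan.losses import discriminator_loss
from fundusgan.models import (
    DiscriminatorSpec,
    GeneratorSpec,
    build_discriminator,
    build_generator,
)
from fundusgan.nd import Adam, Tensor
from fundusgan.phantom import PhantomParams, RandomizeFlags, generate_dataset
from fundusgan.training import (
    TrainConfig,
    prepare_paired,
    synthesize,
    train_cyclegan,
    train_pix2pix,
)

SIZE = 32


def _config(encoding="mcml", epochs=2, seed=0, family="unet", width=4, depth=2):
    in_ch = masks.encoding_channels(encoding)
    return TrainConfig(
        input_encoding=encoding,
        generator=GeneratorSpec(family=family, in_channels=in_ch, base_width=width,
                                depth=depth, n_res_blocks=1),
        discriminator=DiscriminatorSpec(in_channels=in_ch + 3, base_width=8, n_layers=2),
        epochs=epochs, seed=seed, image_size=SIZE,
    )


@pytest.fixture(scope="module")
def tiny_dataset():
    samples = generate_dataset(4, PhantomParams(image_size=SIZE, seed=0),
                               RandomizeFlags(), seed=0)
    return prepare_paired(samples, "mcml")


class TestConfigValidation:
    def test_encoding_channel_mismatch_detected_before_training(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(input_encoding="mcml",
                        generator=GeneratorSpec(family="unet", in_channels=1))

    def test_lambda_defaults_by_mode(self):
        assert _config().resolved_lambda == 0.5
        cyc = TrainConfig(mode="cyclegan", input_encoding="mcml",
                          generator=GeneratorSpec(in_channels=3))
        assert cyc.resolved_lambda == 10.0

    def test_empty_dataset_rejected(self):
        with pytest.raises(InvalidParameterError):
            train_pix2pix([], _config())

    def test_invalid_recipe_values_rejected(self):
        with pytest.raises(InvalidParameterError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(InvalidParameterError):
            TrainConfig(epochs=0)


class TestPix2pixBookkeeping:
    def test_history_rows_equal_epochs_times_batches(self, tiny_dataset):
        result = train_pix2pix(tiny_dataset, _config(epochs=1))
        assert len(result.history) == 4  # 1 epoch x 4 samples, batch 1

    def test_same_seed_reproduces_identical_history(self, tiny_dataset):
        r1 = train_pix2pix(tiny_dataset, _config(epochs=2, seed=3))
        r2 = train_pix2pix(tiny_dataset, _config(epochs=2, seed=3))
        for a, b in zip(r1.history, r2.history):
            assert a == b

    def test_different_seeds_differ(self, tiny_dataset):
        r1 = train_pix2pix(tiny_dataset, _config(epochs=1, seed=0))
        r2 = train_pix2pix(tiny_dataset, _config(epochs=1, seed=1))
        assert any(a["total_g"] != b["total_g"] for a, b in zip(r1.history, r2.history))

    def test_mse_warmup_skips_discriminator(self, tiny_dataset):
        cfg = TrainConfig(
            input_encoding="mcml",
            generator=GeneratorSpec(family="unet", in_channels=3, base_width=4, depth=2),
            discriminator=DiscriminatorSpec(in_channels=6, base_width=8, n_layers=2),
            epochs=1, seed=0, image_size=SIZE, mse_warmup_iters=2,
        )
        result = train_pix2pix(tiny_dataset, cfg)
        assert result.history[0]["adv_d"] == 0.0
        assert result.history[-1]["adv_d"] != 0.0


class TestLearningTrends:
    @pytest.mark.parametrize("family", ["unet", "resnet6", "resnet9", "resunet"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_single_pair_l1_decreases_for_every_family(self, family, seed):
        sample = generate_dataset(1, PhantomParams(image_size=SIZE, seed=seed),
                                  RandomizeFlags(), seed=seed)[0]
        data = prepare_paired([sample], "mcml")
        cfg = _config(epochs=60, seed=seed, family=family, width=4, depth=2)
        result = train_pix2pix(data, cfg)
        l1 = [r["l1"] for r in result.history]
        assert np.mean(l1[-5:]) < np.mean(l1[:5])

    def test_discriminator_beats_chance_on_frozen_generator(self):
        # with G frozen at its random init, D alone reaches loss < ln 2
        rng = np.random.default_rng(0)
        gen = build_generator(GeneratorSpec(family="unet", in_channels=3,
                                            base_width=4, depth=2), rng=0)
        disc = build_discriminator(DiscriminatorSpec(in_channels=6, base_width=8,
                                                     n_layers=2), rng=1)
        opt = Adam(disc.parameters(), lr=2e-4, beta1=0.5)
        sample = generate_dataset(1, PhantomParams(image_size=SIZE, seed=0),
                                  RandomizeFlags(), seed=0)[0]
        (_, cond, real), = prepare_paired([sample], "mcml")
        cond_t, real_t = Tensor(cond[None]), Tensor(real[None])
        gen.eval()
        fake = gen(cond_t).detach()
        losses = []
        for _ in range(200):
            opt.zero_grad()
            loss = discriminator_loss(disc(cond_t, real_t), disc(cond_t, fake))
            loss.backward()
            opt.step()
            losses.append(loss.item())
        assert min(losses) < np.log(2)


class TestCycleGAN:
    def _domains(self, n_a=3, n_b=5):
        samples = generate_dataset(max(n_a, n_b), PhantomParams(image_size=32, seed=0),
                                   RandomizeFlags(), seed=0)
        data = prepare_paired(samples, "mcml")
        return [d[1] for d in data[:n_a]], [d[2] for d in data[:n_b]]

    def test_epoch_rows_follow_max_domain_convention(self):
        a, b = self._domains(3, 5)
        cfg = TrainConfig(mode="cyclegan", input_encoding="mcml",
                          generator=GeneratorSpec(family="unet", in_channels=3,
                                                  base_width=4, depth=2),
                          epochs=1, seed=0, image_size=32)
        result = train_cyclegan(a, b, cfg)
        assert len(result.history) == 5

    def test_seed_reproducibility(self):
        a, b = self._domains(2, 2)
        cfg = TrainConfig(mode="cyclegan", input_encoding="mcml",
                          generator=GeneratorSpec(family="unet", in_channels=3,
                                                  base_width=4, depth=2),
                          epochs=2, seed=5, image_size=32)
        r1 = train_cyclegan(a, b, cfg)
        r2 = train_cyclegan(a, b, cfg)
        for x, y in zip(r1.history, r2.history):
            assert x == y

    def test_cycle_term_decreases_on_identical_domains(self):
        _, b = self._domains(3, 3)
        cfg = TrainConfig(mode="cyclegan", input_encoding="mcml",
                          generator=GeneratorSpec(family="unet", in_channels=3,
                                                  base_width=4, depth=2),
                          epochs=12, seed=0, image_size=32, lambda_weight=10.0)
        result = train_cyclegan(b, b, cfg)
        cyc = [r["cycle"] for r in result.history]
        third = len(cyc) // 3
        assert np.mean(cyc[-third:]) < np.mean(cyc[:third])

    def test_empty_domain_rejected(self):
        cfg = TrainConfig(mode="cyclegan", input_encoding="mcml",
                          generator=GeneratorSpec(in_channels=3))
        with pytest.raises(InvalidParameterError):
            train_cyclegan([], [np.zeros((3, 32, 32), np.float32)], cfg)


class TestSynthesize:
    @pytest.fixture(scope="class")
    def trained(self, tmp_path_factory):
        out = tmp_path_factory.mktemp("train")
        samples = generate_dataset(2, PhantomParams(image_size=SIZE, seed=0),
                                   RandomizeFlags(), seed=0)
        data = prepare_paired(samples, "mcml")
        result = train_pix2pix(data, _config(epochs=2), out_dir=out)
        return result, data

    def test_checkpoint_inference_deterministic(self, trained):
        result, data = trained
        img1 = synthesize(result.checkpoint_path, data[0][1])
        img2 = synthesize(result.checkpoint_path, data[0][1])
        np.testing.assert_array_equal(img1, img2)

    def test_output_shape_and_dtype(self, trained):
        result, data = trained
        img = synthesize(result.checkpoint_path, data[0][1])
        assert img.shape == (SIZE, SIZE, 3) and img.dtype == np.uint8

    def test_zero_conditioning_yields_valid_image(self, trained):
        result, _ = trained
        img = synthesize(result.checkpoint_path, np.zeros((3, SIZE, SIZE), np.float32))
        assert np.isfinite(img.astype(float)).all()

    def test_checkpoint_matches_in_memory_model(self, trained):
        result, data = trained
        from_disk = synthesize(result.checkpoint_path, data[1][1])
        cfg_spec = GeneratorSpec(family="unet", in_channels=3, base_width=4, depth=2,
                                 n_res_blocks=1)
        in_memory = synthesize((result.generator, cfg_spec), data[1][1])
        np.testing.assert_array_equal(from_disk, in_memory)

    def test_channel_mismatch_rejected(self, trained):
        result, _ = trained
        with pytest.raises(ConfigurationError):
            synthesize(result.checkpoint_path, np.zeros((1, SIZE, SIZE), np.float32))

    def test_history_csv_written(self, trained):
        result, _ = trained
        assert result.checkpoint_path.with_name("loss_history.csv").exists()
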