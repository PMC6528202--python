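"""Training loops for paired (Pix2pix-style) and unpaired (Cycle-GAN-style)
mask-to-fundus translation.

Recipe defaults: Adam with learning rate 2e-4, beta1 = 0.5, beta2 = 0.999,
batch size 1, 200 epochs, no dropout anywhere, constant learning rate.
The paired objective weights its L1 term with lambda = 0.5; the unpaired
objective weights its cycle term with lambda = 10. An optional MSE-only
warmup can initialize the generator before adversarial updates begin.

Update order per batch is: discriminator step, then generator step. All
randomness (weight init, shuffling, unpaired sampling) derives from the
config seed, so identical (dataset, config) reproduce identical loss
histories.
"""

from __future__ import annotations

import csv
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import losses, masks, nd
from .errors import ConfigurationError, InvalidParameterError
from .io import save_checkpoint, load_checkpoint
from .models import (
    DiscriminatorSpec,
    GeneratorSpec,
    build_discriminator,
    build_generator,
)
from .nd import Adam, Tensor

HISTORY_FIELDS = ("epoch", "iteration", "adv_g", "adv_d", "l1", "cycle", "total_g", "total_d")


@dataclass(frozen=True)
class TrainConfig:
    mode: str = "pix2pix"  # or "cyclegan"
    input_encoding: str = "mcml"  # mcml | fused_one_channel | vessel_only
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    discriminator: DiscriminatorSpec | None = None
    learning_rate: float = 2e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    epochs: int = 200
    batch_size: int = 1
    lambda_weight: float | None = None  # None -> 0.5 (pix2pix) / 10 (cyclegan)
    adv_variant: str = "non_saturating"
    mse_warmup_iters: int = 0
    seed: int = 0
    image_size: int = 256
    checkpoint_every: int = 0  # additionally checkpoint every k epochs; 0 = final only

    def __post_init__(self):
        if self.mode not in ("pix2pix", "cyclegan"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if self.learning_rate <= 0:
            raise InvalidParameterError("learning_rate must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise InvalidParameterError("epochs and batch_size must be >= 1")
        if self.mse_warmup_iters < 0:
            raise InvalidParameterError("mse_warmup_iters must be >= 0")
        if masks.encoding_channels(self.input_encoding) != self.generator.in_channels:
            raise ConfigurationError(
                f"encoding {self.input_encoding!r} provides "
                f"{masks.encoding_channels(self.input_encoding)} channel(s) but the "
                f"generator expects {self.generator.in_channels}"
            )

    @property
    def resolved_lambda(self) -> float:
        if self.lambda_weight is not None:
            return self.lambda_weight
        return 0.5 if self.mode == "pix2pix" else 10.0

    @property
    def resolved_discriminator(self) -> DiscriminatorSpec:
        if self.discriminator is not None:
            return self.discriminator
        cond = self.generator.in_channels if self.mode == "pix2pix" else 0
        return DiscriminatorSpec(in_channels=cond + 3)


@dataclass
class TrainResult:
    checkpoint_path: Path | None
    history: list[dict]
    final_epoch_losses: dict
    wall_time_s: float
    generator: object = None  # in-memory model, for direct synthesis
    extra: dict = field(default_factory=dict)

    def write_history_csv(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=HISTORY_FIELDS)
            writer.writeheader()
            for row in self.history:
                writer.writerow({k: row.get(k, 0.0) for k in HISTORY_FIELDS})


class _SampleView:
    """Raw mask/fundus arrays presented with the phantom-sample attributes."""

    def __init__(self, vessel, disc, cup, fundus):
        self.vessel_mask, self.disc_mask, self.cup_mask, self.fundus = vessel, disc, cup, fundus


def prepare_paired(samples, encoding: str, image_size: int | None = None):
    """Encode phantom samples into (id, conditioning, target) training triples.

    Resizing (when ``image_size`` differs from the sample resolution)
    happens in raw space: nearest-neighbour for masks, bicubic for the
    photograph, before encoding.
    """
    triples = []
    for i, s in enumerate(samples):
        if image_size is not None and s.fundus.shape[0] != image_size:
            tgt = (image_size, image_size)
            s = _SampleView(
                masks.resize_pair(np.asarray(s.vessel_mask, dtype=np.uint8), tgt, "mask"),
                masks.resize_pair(np.asarray(s.disc_mask, dtype=np.uint8), tgt, "mask"),
                masks.resize_pair(np.asarray(s.cup_mask, dtype=np.uint8), tgt, "mask"),
                masks.resize_pair(s.fundus, tgt, "image"),
            )
        cond = masks.encode(encoding, s)
        target = masks.image_to_model_input(s.fundus)
        sid = getattr(s, "id", None) or f"{i:04d}"
        triples.append((sid, cond.astype(np.float32), target.astype(np.float32)))
    return triples


def _epoch_mean(history: list[dict], epoch: int) -> dict:
    rows = [r for r in history if r["epoch"] == epoch]
    return {k: float(np.mean([r[k] for r in rows]))
            for k in HISTORY_FIELDS if k not in ("epoch", "iteration")}


def _batches(order: np.ndarray, batch_size: int):
    for start in range(0, len(order), batch_size):
        yield order[start : start + batch_size]


def train_pix2pix(dataset, config: TrainConfig, out_dir=None,
                  max_iterations: int | None = None) -> TrainResult:
    """Alternating D/G optimization on paired (conditioning, fundus) samples.

    ``dataset`` is a sequence of (id, conditioning CxHxW, target 3xHxW)
    triples in the model value range (see :func:`prepare_paired`).
    ``max_iterations`` optionally stops mid-schedule (scaled-down runs).
    """
    if len(dataset) == 0:
        raise InvalidParameterError("dataset must be non-empty")
    cond_ch = dataset[0][1].shape[0]
    if cond_ch != config.generator.in_channels:
        raise ConfigurationError(
            f"dataset conditioning has {cond_ch} channels, generator expects "
            f"{config.generator.in_channels}"
        )
    t0 = time.time()
    root_rng = np.random.default_rng(config.seed)
    g_seed, d_seed = root_rng.integers(0, 2 ** 31 - 1, size=2)
    gen = build_generator(config.generator, np.random.default_rng(g_seed))
    disc = build_discriminator(config.resolved_discriminator, np.random.default_rng(d_seed))
    opt_g = Adam(gen.parameters(), config.learning_rate, config.adam_beta1, config.adam_beta2)
    opt_d = Adam(disc.parameters(), config.learning_rate, config.adam_beta1, config.adam_beta2)
    lam = config.resolved_lambda

    history: list[dict] = []
    iteration = 0
    stop = False
    for epoch in range(config.epochs):
        order = root_rng.permutation(len(dataset))
        for batch_idx in _batches(order, config.batch_size):
            cond = Tensor(np.stack([dataset[i][1] for i in batch_idx]))
            real = Tensor(np.stack([dataset[i][2] for i in batch_idx]))
            fake = gen(cond)
            warmup = iteration < config.mse_warmup_iters

            if not warmup:
                # discriminator step on the detached fake
                disc.zero_grad()
                p_real = disc(cond, real)
                p_fake_d = disc(cond, fake.detach())
                d_loss = losses.discriminator_loss(p_real, p_fake_d)
                d_loss.backward()
                opt_d.step()
                d_loss_val = d_loss.item()
            else:
                d_loss_val = 0.0

            # generator step (through a fresh discriminator forward)
            gen.zero_grad()
            disc.zero_grad()
            if warmup:
                g_total = losses.mse_loss(fake, real)
                breakdown = losses.LossBreakdown(
                    l1=losses.l1_loss(real, fake).item(), total_g=g_total.item(),
                    lambda_weight=lam,
                )
            else:
                p_fake_g = disc(cond, fake)
                g_total, breakdown = losses.pix2pix_generator_loss(
                    p_fake_g, fake, real, lambda_weight=lam, variant=config.adv_variant
                )
            g_total.backward()
            opt_g.step()

            iteration += 1
            history.append({
                "epoch": epoch, "iteration": iteration,
                "adv_g": breakdown.adv_g, "adv_d": d_loss_val,
                "l1": breakdown.l1, "cycle": 0.0,
                "total_g": breakdown.total_g, "total_d": d_loss_val,
            })
            if max_iterations is not None and iteration >= max_iterations:
                stop = True
                break
        if out_dir is not None and config.checkpoint_every and (epoch + 1) % config.checkpoint_every == 0:
            save_checkpoint(Path(out_dir) / f"generator_epoch{epoch + 1:04d}.npz",
                            gen, config.generator, {"epoch": epoch + 1, "seed": config.seed})
        if stop:
            break

    checkpoint_path = None
    if out_dir is not None:
        checkpoint_path = Path(out_dir) / "generator.npz"
        save_checkpoint(checkpoint_path, gen, config.generator,
                        {"epochs": config.epochs, "seed": config.seed,
                         "encoding": config.input_encoding})
        TrainResult(None, history, {}, 0.0).write_history_csv(Path(out_dir) / "loss_history.csv")
    return TrainResult(
        checkpoint_path=checkpoint_path,
        history=history,
        final_epoch_losses=_epoch_mean(history, history[-1]["epoch"]),
        wall_time_s=time.time() - t0,
        generator=gen,
        extra={"discriminator": disc},
    )


def train_cyclegan(dataset_a, dataset_b, config: TrainConfig, out_dir=None,
                   max_iterations: int | None = None) -> TrainResult:
    """Unpaired two-generator / two-discriminator training.

    ``dataset_a`` holds mask-encoding images (CxHxW), ``dataset_b`` fundus
    images (3xHxW); pairing is not required and each domain is permuted
    independently per epoch. An epoch has max(|A|, |B|) iterations, the
    shorter domain cycling modulo its length.
    """
    if len(dataset_a) == 0 or len(dataset_b) == 0:
        raise InvalidParameterError("both domains must be non-empty")
    ca = dataset_a[0].shape[0]
    if ca != config.generator.in_channels:
        raise ConfigurationError(
            f"domain A has {ca} channels, generator expects {config.generator.in_channels}"
        )
    t0 = time.time()
    root_rng = np.random.default_rng(config.seed)
    seeds = root_rng.integers(0, 2 ** 31 - 1, size=4)
    spec_g1 = config.generator  # A -> B (masks -> fundus)
    spec_g2 = replace(config.generator, in_channels=3, out_channels=ca)
    g1 = build_generator(spec_g1, np.random.default_rng(seeds[0]))
    g2 = build_generator(spec_g2, np.random.default_rng(seeds[1]))
    d1 = build_discriminator(DiscriminatorSpec(in_channels=ca), np.random.default_rng(seeds[2]))
    d2 = build_discriminator(DiscriminatorSpec(in_channels=3), np.random.default_rng(seeds[3]))
    opt_g = Adam(g1.parameters() + g2.parameters(), config.learning_rate,
                 config.adam_beta1, config.adam_beta2)
    opt_d = Adam(d1.parameters() + d2.parameters(), config.learning_rate,
                 config.adam_beta1, config.adam_beta2)
    lam = config.resolved_lambda

    n_iter_per_epoch = max(len(dataset_a), len(dataset_b))
    history: list[dict] = []
    iteration = 0
    stop = False
    for epoch in range(config.epochs):
        perm_a = root_rng.permutation(len(dataset_a))
        perm_b = root_rng.permutation(len(dataset_b))
        for k in range(n_iter_per_epoch):
            a = Tensor(dataset_a[perm_a[k % len(dataset_a)]][None])
            b = Tensor(dataset_b[perm_b[k % len(dataset_b)]][None])
            fake_b = g1(a)
            fake_a = g2(b)

            # discriminators: real vs detached fakes
            d1.zero_grad(); d2.zero_grad()
            d2_loss = losses.discriminator_loss(d2(b), d2(fake_b.detach()))
            d1_loss = losses.discriminator_loss(d1(a), d1(fake_a.detach()))
            total_d = nd.add(d1_loss, d2_loss)
            total_d.backward()
            opt_d.step()

            # generators: adversarial + cycle
            g1.zero_grad(); g2.zero_grad(); d1.zero_grad(); d2.zero_grad()
            adv_g1 = losses.generator_adversarial_loss(d2(fake_b), config.adv_variant)
            adv_g2 = losses.generator_adversarial_loss(d1(fake_a), config.adv_variant)
            cycled_a = g2(fake_b)
            cycled_b = g1(fake_a)
            cyc = losses.cycle_consistency_loss(a, cycled_a, b, cycled_b)
            g_total = nd.add(nd.add(adv_g1, adv_g2), nd.scale(cyc, lam))
            g_total.backward()
            opt_g.step()

            iteration += 1
            history.append({
                "epoch": epoch, "iteration": iteration,
                "adv_g": adv_g1.item() + adv_g2.item(),
                "adv_d": total_d.item(), "l1": 0.0, "cycle": cyc.item(),
                "total_g": g_total.item(), "total_d": total_d.item(),
            })
            if max_iterations is not None and iteration >= max_iterations:
                stop = True
                break
        if stop:
            break

    checkpoint_path = None
    if out_dir is not None:
        checkpoint_path = Path(out_dir) / "generator.npz"
        save_checkpoint(checkpoint_path, g1, spec_g1,
                        {"epochs": config.epochs, "seed": config.seed, "role": "A_to_B"})
        save_checkpoint(Path(out_dir) / "generator_b_to_a.npz", g2, spec_g2,
                        {"epochs": config.epochs, "seed": config.seed, "role": "B_to_A"})
        TrainResult(None, history, {}, 0.0).write_history_csv(Path(out_dir) / "loss_history.csv")
    return TrainResult(
        checkpoint_path=checkpoint_path,
        history=history,
        final_epoch_losses=_epoch_mean(history, history[-1]["epoch"]),
        wall_time_s=time.time() - t0,
        generator=g1,
        extra={"g2": g2, "d1": d1, "d2": d2},
    )


def synthesize(checkpoint, conditioning) -> np.ndarray:
    """Run a trained generator on conditioning input(s) at inference.

    ``checkpoint`` is a path to a saved generator checkpoint or an
    in-memory (model, spec) pair. ``conditioning`` is (C,H,W) or (N,C,H,W)
    in the model value range. Returns 8-bit RGB image(s), H x W x 3,
    deterministic for a fixed checkpoint (normalization in inference mode).
    """
    if isinstance(checkpoint, (str, Path)):
        spec, state, _ = load_checkpoint(checkpoint)
        model = build_generator(spec, np.random.default_rng(0))
        model.load_state_dict(state)
    else:
        model, spec = checkpoint
    cond = np.asarray(conditioning, dtype=np.float32)
    squeeze = cond.ndim == 3
    if squeeze:
        cond = cond[None]
    if cond.shape[1] != spec.in_channels:
        raise ConfigurationError(
            f"conditioning has {cond.shape[1]} channels, generator expects {spec.in_channels}"
        )
    model.eval()
    out = model(Tensor(cond)).data
    model.train()
    images = masks.model_output_to_image(out)
    return images[0] if squeeze else images
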