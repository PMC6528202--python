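"""Adversarial, L1 and cycle-consistency objectives.

Conventions, pinned once for the whole package:

* logarithms are natural, so adversarial losses are reported in nats;
* the discriminator objective is binary cross-entropy against labels
  real=1 / fake=0, i.e. the negation of the maximized min-max value;
* the generator adversarial term comes in two variants: ``literal``
  (mean log(1 - p_fake), the quantity the generator minimizes in the
  min-max game — it saturates when the discriminator wins early) and
  ``non_saturating`` (-mean log p_fake), the standard practical form and
  the training default;
* the paired-translation generator objective is
  adversarial + lambda * L1(target, generated) with lambda = 0.5 by
  default; the unpaired (cycle) objective weights its cycle term with
  lambda = 10 by default;
* an optional MSE-only warmup phase can initialize the generator before
  adversarial training starts (``mse_warmup_iters`` in the train config).

Functions accept numpy arrays or ``nd.Tensor``s; passing Tensors keeps
the computation on the autodiff tape so the same code paths serve both
testing and training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nd
from .errors import InvalidParameterError
from .nd import Tensor, as_tensor


@dataclass
class LossBreakdown:
    """Scalar summary of one optimization step's objective terms (nats / L1 units)."""

    adv_g: float = 0.0
    adv_d: float = 0.0
    l1: float = 0.0
    cycle: float = 0.0
    total_g: float = 0.0
    total_d: float = 0.0
    lambda_weight: float = 0.0


def _check_probs(p: Tensor, name: str) -> None:
    if np.any(p.data <= 0.0) or np.any(p.data >= 1.0):
        raise InvalidParameterError(f"{name} must lie strictly inside (0, 1)")


def _ones_like(p: Tensor) -> Tensor:
    return Tensor(np.ones_like(p.data))


def discriminator_loss(p_real, p_fake) -> Tensor:
    """-mean log p_real - mean log(1 - p_fake): BCE against real=1, fake=0."""
    p_real, p_fake = as_tensor(p_real), as_tensor(p_fake)
    _check_probs(p_real, "p_real")
    _check_probs(p_fake, "p_fake")
    term_real = nd.scale(nd.mean_all(nd.log(p_real)), -1.0)
    term_fake = nd.scale(nd.mean_all(nd.log(nd.sub(_ones_like(p_fake), p_fake))), -1.0)
    return nd.add(term_real, term_fake)


def generator_adversarial_loss(p_fake, variant: str = "non_saturating") -> Tensor:
    """Generator's adversarial term on the discriminator's fake-map output."""
    p_fake = as_tensor(p_fake)
    _check_probs(p_fake, "p_fake")
    if variant == "literal":
        return nd.mean_all(nd.log(nd.sub(_ones_like(p_fake), p_fake)))
    if variant == "non_saturating":
        return nd.scale(nd.mean_all(nd.log(p_fake)), -1.0)
    raise InvalidParameterError(f"unknown adversarial variant {variant!r}")


def l1_loss(a, b) -> Tensor:
    """Mean absolute error in normalized-intensity units."""
    a, b = as_tensor(a), as_tensor(b)
    if a.data.shape != b.data.shape:
        raise InvalidParameterError("l1_loss shape mismatch")
    return nd.mean_all(nd.abs_(nd.sub(a, b)))


def mse_loss(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.data.shape != b.data.shape:
        raise InvalidParameterError("mse_loss shape mismatch")
    return nd.mean_all(nd.square(nd.sub(a, b)))


def pix2pix_generator_loss(p_fake, generated, target, lambda_weight: float = 0.5,
                           variant: str = "non_saturating") -> tuple[Tensor, LossBreakdown]:
    """Combined paired-translation objective: adversarial + lambda * L1.

    Returns the scalar tape node (for backward) and a float breakdown.
    """
    if lambda_weight < 0:
        raise InvalidParameterError("lambda_weight must be >= 0")
    generated, target = as_tensor(generated), as_tensor(target)
    if generated.data.shape != target.data.shape:
        raise InvalidParameterError("generated/target shape mismatch")
    adv = generator_adversarial_loss(p_fake, variant)
    l1 = l1_loss(target, generated)
    total = nd.add(adv, nd.scale(l1, lambda_weight))
    breakdown = LossBreakdown(adv_g=adv.item(), l1=l1.item(), total_g=total.item(),
                              lambda_weight=lambda_weight)
    return total, breakdown


def cycle_consistency_loss(a, a_cycled, b, b_cycled) -> Tensor:
    """mean|G2(G1(a)) - a| + mean|G1(G2(b)) - b| on pre-computed cycles."""
    return nd.add(l1_loss(a_cycled, a), l1_loss(b_cycled, b))


def cyclegan_total_loss(adv_g1: float, adv_d2: float, adv_g2: float, adv_d1: float,
                        cycle: float, lambda_weight: float = 10.0) -> LossBreakdown:
    """Scalar bookkeeping of the unpaired objective:
    L = L_GAN(G1, D2) + L_GAN(G2, D1) + lambda * L_cyc,
    with each adversarial term decomposed into its generator and
    discriminator parts under the package's BCE conventions.
    """
    if lambda_weight < 0:
        raise InvalidParameterError("lambda_weight must be >= 0")
    for v in (adv_g1, adv_d2, adv_g2, adv_d1, cycle):
        if not np.isfinite(v):
            raise InvalidParameterError("loss components must be finite")
    total_g = adv_g1 + adv_g2 + lambda_weight * cycle
    total_d = adv_d1 + adv_d2
    return LossBreakdown(adv_g=adv_g1 + adv_g2, adv_d=total_d, cycle=cycle,
                         total_g=total_g, total_d=total_d, lambda_weight=lambda_weight)
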