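"""Landmark-mask loading and the three conditioning encodings.

The translation model is conditioned on landmark masks. Three encodings
are supported and compared:

* ``mcml`` — multiple-channels-multiple-landmarks: vessel, optic disc and
  optic cup stacked as three independent channels (lossless; overlaps are
  preserved per channel);
* ``fused_one_channel`` — disc and vessel painted into a single channel at
  distinct intensities, vessel over disc. A vessel pixel inside the disc is
  indistinguishable from one outside it, so the encoding is lossy on
  overlaps by construction — that loss is what the baseline measures;
* ``vessel_only`` — the single vessel mask, the conditioning used by prior
  vessel-to-fundus synthesis work.

Value conventions: binary masks are carried as {0,1}; the model-input
mapping sends masks {0,1} -> {-1,+1} and 8-bit images [0,255] -> [-1,+1].
Channel order is fixed as (vessel, disc, cup). Coordinates are row-major,
0-based (row, col).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import InvalidParameterError

Role = Literal["vessel", "disc", "cup"]
CHANNEL_ORDER: tuple[Role, Role, Role] = ("vessel", "disc", "cup")

# single-channel fusion intensity levels (8-bit convention, then normalized)
FUSED_BACKGROUND = 0
FUSED_DISC = 128
FUSED_VESSEL = 255

DEFAULT_THRESHOLD = 127


@dataclass(frozen=True)
class LandmarkMask:
    """A binary mask for one landmark role."""

    pixels: np.ndarray  # uint8 {0,1}, H x W
    role: Role

    def __post_init__(self):
        p = self.pixels
        if p.ndim != 2 or p.shape[0] == 0 or p.shape[1] == 0:
            raise InvalidParameterError("mask must be a non-empty 2-D array")
        vals = np.unique(p)
        if not np.isin(vals, (0, 1)).all():
            raise InvalidParameterError("mask pixels must be binary {0,1}")
        if self.role not in CHANNEL_ORDER:
            raise InvalidParameterError(f"unknown mask role {self.role!r}")


@dataclass(frozen=True)
class MCMLInput:
    """3-channel conditioning image; channel k holds CHANNEL_ORDER[k]'s mask."""

    channels: np.ndarray  # (3, H, W) uint8 {0,1}
    channel_semantics: tuple[Role, Role, Role] = CHANNEL_ORDER

    def split(self) -> tuple[LandmarkMask, LandmarkMask, LandmarkMask]:
        """Recover the three source masks exactly (compose is lossless)."""
        return tuple(
            LandmarkMask(self.channels[k].copy(), role)
            for k, role in enumerate(self.channel_semantics)
        )


def binarize(image: np.ndarray, threshold: int = DEFAULT_THRESHOLD) -> np.ndarray:
    """Threshold a single-channel image: foreground iff value > threshold.

    Idempotent on {0,255} masks at the default midpoint threshold.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise InvalidParameterError("binarize expects a single-channel image")
    if not (0 <= threshold <= 255):
        raise InvalidParameterError("threshold must lie in [0, 255]")
    return (image > threshold).astype(np.uint8)


def _as_binary(mask: LandmarkMask | np.ndarray, role: Role | None = None) -> np.ndarray:
    if isinstance(mask, LandmarkMask):
        if role is not None and mask.role != role:
            raise InvalidParameterError(f"expected a {role!r} mask, got {mask.role!r}")
        return mask.pixels
    arr = np.asarray(mask)
    if arr.dtype == bool:
        return arr.astype(np.uint8)
    return binarize(arr) if arr.max(initial=0) > 1 else arr.astype(np.uint8)


def compose_mcml(vessel, disc, cup) -> MCMLInput:
    """Stack the three masks into the fixed (vessel, disc, cup) channel order."""
    v = _as_binary(vessel, "vessel")
    d = _as_binary(disc, "disc")
    c = _as_binary(cup, "cup")
    if not (v.shape == d.shape == c.shape):
        raise InvalidParameterError("mask dimension mismatch in compose_mcml")
    return MCMLInput(np.stack([v, d, c], axis=0))


def fuse_one_channel(vessel, disc) -> np.ndarray:
    """Disc and vessel as one channel: disc painted first, vessel over it.

    Returns a uint8 image with the documented intensity levels. Inside the
    disc a vessel pixel overwrites the disc level, which is the information
    loss this baseline is designed to exhibit.
    """
    v = _as_binary(vessel, "vessel") if isinstance(vessel, LandmarkMask) else _as_binary(vessel)
    d = _as_binary(disc, "disc") if isinstance(disc, LandmarkMask) else _as_binary(disc)
    if v.shape != d.shape:
        raise InvalidParameterError("mask dimension mismatch in fuse_one_channel")
    out = np.full(v.shape, FUSED_BACKGROUND, dtype=np.uint8)
    out[d.astype(bool)] = FUSED_DISC
    out[v.astype(bool)] = FUSED_VESSEL
    return out


def vessel_only(vessel) -> np.ndarray:
    """The single-vessel baseline encoding: the mask itself, one channel."""
    return _as_binary(vessel, "vessel") if isinstance(vessel, LandmarkMask) else _as_binary(vessel)


# ---------------------------------------------------------------------------
# model-input value convention
# ---------------------------------------------------------------------------

def to_model_input(array: np.ndarray) -> np.ndarray:
    """Map an encoding to the network value range.

    Binary masks / fused-level images are treated as 8-bit-style intensities:
    {0,1} masks map to {-1,+1}; anything on [0,255] maps linearly to [-1,+1].
    Output is float32, channel-first (C, H, W).
    """
    a = np.asarray(array)
    if isinstance(array, MCMLInput):  # pragma: no cover - convenience
        a = array.channels
    if a.ndim == 2:
        a = a[None]
    a = a.astype(np.float32)
    if a.max(initial=0.0) <= 1.0:
        return a * 2.0 - 1.0
    return a / 127.5 - 1.0


def image_to_model_input(image: np.ndarray) -> np.ndarray:
    """8-bit H x W x 3 image -> float32 (3, H, W) on [-1, +1]."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidParameterError("expected an H x W x 3 image")
    return (img / 127.5 - 1.0).transpose(2, 0, 1)


def model_output_to_image(batch: np.ndarray) -> np.ndarray:
    """Float (3, H, W) or (N, 3, H, W) on [-1,+1] -> 8-bit H x W x 3 image(s)."""
    a = np.asarray(batch, dtype=np.float32)
    squeeze = a.ndim == 3
    if squeeze:
        a = a[None]
    imgs = np.clip((a + 1.0) * 127.5, 0.0, 255.0)
    imgs = np.rint(imgs).astype(np.uint8).transpose(0, 2, 3, 1)
    return imgs[0] if squeeze else imgs


def denormalize_mask(array: np.ndarray) -> np.ndarray:
    """Inverse of the {0,1} -> {-1,+1} mask mapping."""
    return (np.asarray(array) > 0).astype(np.uint8)


def encode(encoding: str, sample) -> np.ndarray:
    """Build the conditioning array for one phantom sample.

    ``encoding`` is one of ``mcml``, ``fused_one_channel``, ``vessel_only``.
    Returns float32 (C, H, W) in the model value range.
    """
    if encoding == "mcml":
        mc = compose_mcml(sample.vessel_mask, sample.disc_mask, sample.cup_mask)
        return to_model_input(mc.channels)
    if encoding in ("fused_one_channel", "fused"):
        return to_model_input(fuse_one_channel(sample.vessel_mask, sample.disc_mask))
    if encoding in ("vessel_only", "vessel"):
        return to_model_input(vessel_only(sample.vessel_mask))
    raise InvalidParameterError(f"unknown encoding {encoding!r}")


def encoding_channels(encoding: str) -> int:
    return {"mcml": 3, "fused_one_channel": 1, "fused": 1,
            "vessel_only": 1, "vessel": 1}[encoding]


# ---------------------------------------------------------------------------
# resizing
# ---------------------------------------------------------------------------

def resize_pair(image: np.ndarray, target: tuple[int, int],
                mode: Literal["mask", "image"]) -> np.ndarray:
    """Resize with the convention used for paired data.

    Masks use nearest-neighbour (stay two-valued); photographs use bicubic.
    Direct resize to the target shape — no padding or aspect preservation.
    """
    th, tw = target
    if th <= 0 or tw <= 0:
        raise InvalidParameterError("target dimensions must be positive")
    img = np.asarray(image)
    if img.shape[:2] == (th, tw):
        return img.copy()
    order = 0 if mode == "mask" else 3
    out_shape = (th, tw) + img.shape[2:]
    out = _sk_resize(img, out_shape, order=order, preserve_range=True,
                     anti_aliasing=False)
    if np.issubdtype(img.dtype, np.integer) or img.dtype == bool:
        out = np.clip(np.rint(out), 0, 255).astype(img.dtype if img.dtype != bool else np.uint8)
    return out
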