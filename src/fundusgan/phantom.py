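"""Procedural fundus phantom: paired landmark masks and rendered pseudo-fundus images.

The phantom emulates the structures a mask-to-fundus translation model
has to learn — a dark branching vessel tree over a circular fundus
field, a bright optic disc containing a brighter optic cup with a
controllable cup-to-disc ratio (CDR), radial illumination falloff and
pixel noise — while providing exact ground-truth masks for all three
landmarks. Everything is a pure function of (parameters, seed), so any
sample can be regenerated bit-identically.

Rendering constants (8-bit RGB, painted in this order):

======================  ==================
layer                   color
======================  ==================
outside fundus circle   (8, 8, 8)
fundus base field       (175, 95, 45), radial vignette down to 70% at the rim
optic disc              (220, 170, 100)
optic cup               (245, 215, 150)
vessels (topmost)       (105, 30, 25)
======================  ==================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import draw as skdraw

from .errors import InvalidParameterError

GENERATOR_VERSION = "1.0"

COLOR_OUTSIDE = (8, 8, 8)
COLOR_BASE = (175, 95, 45)
COLOR_DISC = (220, 170, 100)
COLOR_CUP = (245, 215, 150)
COLOR_VESSEL = (105, 30, 25)
VIGNETTE_RIM = 0.7  # multiplicative brightness of the base field at the rim


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters for one phantom sample.

    ``disc_center`` is (row, col) in pixels, 0-based. ``disc_radius`` and
    ``vessel_root_width`` are in pixels; ``branch_angle_jitter`` in degrees;
    ``noise_sigma`` in 8-bit intensity units. ``n_vessel_roots=None`` lets
    the seeded stream pick 2-4 roots on the disc boundary.
    """

    image_size: int = 256
    fundus_radius_frac: float = 0.95
    disc_center: tuple[int, int] | None = None
    disc_radius: int | None = None
    cdr: float = 0.5
    vessel_depth: int = 7
    vessel_root_width: float | None = None
    branch_angle_jitter: float = 18.0
    width_decay: float = 0.8
    noise_sigma: float = 5.0
    seed: int = 0
    n_vessel_roots: int | None = None
    disc_axis_ratio: float = 1.0  # minor/major axis; 1.0 = circle

    def __post_init__(self):
        if self.image_size <= 0:
            raise InvalidParameterError("image_size must be a positive integer")
        if not (0.0 < self.fundus_radius_frac <= 1.0):
            raise InvalidParameterError("fundus_radius_frac must be in (0, 1]")
        if not (0.0 < self.cdr < 1.0):
            raise InvalidParameterError("cdr must lie strictly in (0, 1)")
        if self.vessel_depth < 1:
            raise InvalidParameterError("vessel_depth must be >= 1")
        if self.vessel_root_width is not None and self.vessel_root_width <= 0:
            raise InvalidParameterError("vessel_root_width must be positive")
        if not (0.0 < self.width_decay < 1.0):
            raise InvalidParameterError("width_decay must lie in (0, 1)")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be non-negative")
        if self.seed < 0:
            raise InvalidParameterError("seed must be non-negative")
        if not (0.0 < self.disc_axis_ratio <= 1.0):
            raise InvalidParameterError("disc_axis_ratio must be in (0, 1]")
        if self.n_vessel_roots is not None and self.n_vessel_roots < 1:
            raise InvalidParameterError("n_vessel_roots must be >= 1")
        c = self.resolved_disc_center
        r = self.resolved_disc_radius
        if r < 1:
            raise InvalidParameterError("disc_radius must be >= 1 pixel")
        center = (self.image_size - 1) / 2.0
        dist = math.hypot(c[0] - center, c[1] - center)
        if dist + r > self.fundus_radius + 1e-9:
            raise InvalidParameterError(
                "optic disc (center %s, radius %d) does not fit inside the fundus circle"
                % (c, r)
            )

    # resolved geometry -------------------------------------------------------
    @property
    def fundus_radius(self) -> float:
        return self.fundus_radius_frac * (self.image_size / 2.0)

    @property
    def resolved_disc_center(self) -> tuple[float, float]:
        if self.disc_center is not None:
            return (float(self.disc_center[0]), float(self.disc_center[1]))
        s = self.image_size
        return (0.42 * s, 0.64 * s)  # upper-temporal placement typical of fundus photos

    @property
    def resolved_disc_radius(self) -> int:
        if self.disc_radius is not None:
            return int(self.disc_radius)
        return max(1, round(0.14 * self.image_size))

    @property
    def cup_radius(self) -> int:
        return max(1, round(self.cdr * self.resolved_disc_radius))

    @property
    def resolved_root_width(self) -> float:
        if self.vessel_root_width is not None:
            return float(self.vessel_root_width)
        return max(2.0, self.image_size / 48.0)


@dataclass
class PhantomSample:
    """One paired record: three binary landmark masks + rendered RGB image."""

    vessel_mask: np.ndarray
    disc_mask: np.ndarray
    cup_mask: np.ndarray
    fundus: np.ndarray
    params: PhantomParams


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def fundus_circle_mask(params: PhantomParams) -> np.ndarray:
    s = params.image_size
    yy, xx = np.mgrid[0:s, 0:s]
    center = (s - 1) / 2.0
    return (yy - center) ** 2 + (xx - center) ** 2 <= params.fundus_radius ** 2


def _stamp_segment(mask: np.ndarray, p0, p1, width: float) -> None:
    """Paint a thick segment by stamping disks along it."""
    length = math.hypot(p1[0] - p0[0], p1[1] - p0[1])
    radius = max(0.5, width / 2.0)
    n_steps = max(2, int(length / max(radius * 0.5, 0.5)) + 1)
    for t in np.linspace(0.0, 1.0, n_steps):
        r = p0[0] + t * (p1[0] - p0[0])
        c = p0[1] + t * (p1[1] - p0[1])
        rr, cc = skdraw.disk((r, c), radius, shape=mask.shape)
        mask[rr, cc] = True


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def generate_vessel_tree(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    """Grow a recursive binary branching tree rooted on the disc boundary.

    Each root produces a connected tree; stroke width decays by
    ``width_decay`` per branching level and all strokes are clipped to
    the fundus circle. Returns a boolean H x W mask.
    """
    if params.image_size < 32:
        raise InvalidParameterError("image_size must be >= 32 for vessel generation")
    s = params.image_size
    mask = np.zeros((s, s), dtype=bool)
    center = ((s - 1) / 2.0, (s - 1) / 2.0)
    disc_c = params.resolved_disc_center
    disc_r = params.resolved_disc_radius
    n_roots = params.n_vessel_roots
    if n_roots is None:
        n_roots = int(rng.integers(2, 5))
    jitter = math.radians(params.branch_angle_jitter)
    branch_half_angle = math.radians(32.0)
    base_len = 0.34 * params.fundus_radius

    # segments grow iteratively (stack) to avoid recursion limits
    for k in range(n_roots):
        theta = 2.0 * math.pi * (k / n_roots) + (rng.uniform(-jitter, jitter) if jitter else 0.0)
        root = (disc_c[0] + disc_r * math.sin(theta), disc_c[1] + disc_r * math.cos(theta))
        # initial heading: radially away from the disc center
        heading = theta
        stack = [(root, heading, params.resolved_root_width, base_len, 1)]
        while stack:
            (p0, ang, width, length, depth) = stack.pop()
            p1 = (p0[0] + length * math.sin(ang), p0[1] + length * math.cos(ang))
            _stamp_segment(mask, p0, p1, width)
            if depth < params.vessel_depth:
                for sign in (-1.0, 1.0):
                    child_ang = ang + sign * branch_half_angle
                    if jitter:
                        child_ang += rng.uniform(-jitter, jitter)
                    stack.append((p1, child_ang, width * params.width_decay,
                                  length * 0.82, depth + 1))

    yy, xx = np.mgrid[0:s, 0:s]
    inside = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= params.fundus_radius ** 2
    return mask & inside


def generate_disc_cup(params: PhantomParams) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the optic disc and the concentric optic cup.

    Both are filled ellipses (circles at the default axis ratio 1.0) sharing
    the disc center; the cup radius is ``round(cdr * disc_radius)``, so the
    pixel-area ratio cup/disc approximates cdr**2.
    """
    s = params.image_size
    disc = np.zeros((s, s), dtype=bool)
    cup = np.zeros((s, s), dtype=bool)
    c = params.resolved_disc_center
    r_disc = params.resolved_disc_radius
    r_cup = params.cup_radius
    ar = params.disc_axis_ratio
    rr, cc = skdraw.ellipse(c[0], c[1], r_disc * ar, r_disc, shape=(s, s))
    disc[rr, cc] = True
    rr, cc = skdraw.ellipse(c[0], c[1], r_cup * ar, r_cup, shape=(s, s))
    cup[rr, cc] = True
    cup &= disc
    return disc, cup


def render_fundus(vessel: np.ndarray, disc: np.ndarray, cup: np.ndarray,
                  params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    """Layered painting of the pseudo-fundus photograph (8-bit RGB).

    Layer order: dark exterior, vignetted base field, disc, cup, vessels on
    top (so vessels stay visible inside the disc), then additive Gaussian
    noise with std ``noise_sigma`` clipped to [0, 255]. Deterministic given
    the random stream state.
    """
    for name, m in (("vessel", vessel), ("disc", disc), ("cup", cup)):
        if m.shape != vessel.shape:
            raise InvalidParameterError("mask dimension mismatch: %s" % name)
        if m.dtype != bool and not np.isin(np.unique(m), (0, 1)).all():
            raise InvalidParameterError("mask %r is not binary" % name)
    if np.any(cup & ~disc.astype(bool)):
        raise InvalidParameterError("cup mask is not contained in disc mask")
    vessel, disc, cup = (np.asarray(m, dtype=bool) for m in (vessel, disc, cup))
    s = params.image_size
    if vessel.shape != (s, s):
        raise InvalidParameterError("mask shape does not match params.image_size")

    center = (s - 1) / 2.0
    yy, xx = np.mgrid[0:s, 0:s]
    r2 = ((yy - center) ** 2 + (xx - center) ** 2) / params.fundus_radius ** 2
    inside = r2 <= 1.0

    img = np.empty((s, s, 3), dtype=np.float64)
    img[:] = COLOR_OUTSIDE
    vignette = 1.0 - (1.0 - VIGNETTE_RIM) * np.clip(r2, 0.0, 1.0)
    for ch in range(3):
        img[..., ch][inside] = COLOR_BASE[ch] * vignette[inside]
    img[disc] = COLOR_DISC
    img[cup] = COLOR_CUP
    img[vessel] = COLOR_VESSEL
    if params.noise_sigma > 0:
        img += rng.normal(0.0, params.noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_sample(params: PhantomParams) -> PhantomSample:
    """Generate one fully paired sample from ``params`` (pure in the seed)."""
    ss = np.random.SeedSequence(params.seed)
    vessel_ss, noise_ss = ss.spawn(2)
    vessel = generate_vessel_tree(params, np.random.default_rng(vessel_ss))
    disc, cup = generate_disc_cup(params)
    fundus = render_fundus(vessel, disc, cup, params, np.random.default_rng(noise_ss))
    return PhantomSample(vessel, disc, cup, fundus, params)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomizeFlags:
    """Which parameters vary from sample to sample in a generated dataset.

    ``shared_vessel=True`` reuses one vessel tree for every sample (disc and
    cup still move), which makes the vessel channel uninformative about disc
    placement — the construction behind the multi-channel vs single-vessel
    conditioning comparison.
    """

    disc_center: bool = True
    disc_radius: bool = True
    cdr: bool = True
    vessel: bool = True
    shared_vessel: bool = False


def _randomized_params(base: PhantomParams, flags: RandomizeFlags,
                       rng: np.random.Generator, sample_seed: int) -> PhantomParams:
    s = base.image_size
    kwargs = {"seed": sample_seed}
    if flags.disc_radius:
        kwargs["disc_radius"] = int(rng.uniform(0.10, 0.16) * s)
    if flags.cdr:
        kwargs["cdr"] = float(rng.uniform(0.3, 0.7))
    if flags.disc_center:
        radius = kwargs.get("disc_radius", base.resolved_disc_radius)
        center = (s - 1) / 2.0
        max_off = base.fundus_radius - radius - 1
        for _ in range(64):  # rejection sample a placement inside the fundus
            ang = rng.uniform(0.0, 2.0 * math.pi)
            off = rng.uniform(0.0, 0.75) * max_off
            cand = (center + off * math.sin(ang), center + off * math.cos(ang))
            if math.hypot(cand[0] - center, cand[1] - center) + radius <= base.fundus_radius:
                kwargs["disc_center"] = (int(round(cand[0])), int(round(cand[1])))
                break
    return replace(base, **kwargs)


def generate_dataset(n: int, base_params: PhantomParams,
                     randomize: RandomizeFlags | None = None,
                     seed: int = 0, out_dir=None) -> list[PhantomSample]:
    """Generate ``n`` paired samples; optionally write the on-disk layout.

    Per-sample seeds are spawned from ``seed`` by sample index, so the
    dataset is reproducible as a whole and per sample. When ``out_dir``
    is given, samples are written as ``masks/{vessel,disc,cup}/<id>.png``,
    ``fundus/<id>.png`` plus a ``manifest.yaml`` recording per-id
    parameters.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    randomize = randomize or RandomizeFlags()
    root_ss = np.random.SeedSequence(seed)
    # one child per sample for parameter draws; derived sample seeds stay < 2**31
    param_rngs = [np.random.default_rng(c) for c in root_ss.spawn(n)]

    shared_vessel_mask = None
    samples: list[PhantomSample] = []
    for i in range(n):
        sample_seed = int((seed * 100003 + i * 7919) % (2 ** 31 - 1))
        if randomize.vessel and not randomize.shared_vessel:
            vessel_seed = sample_seed
        else:
            vessel_seed = int(seed % (2 ** 31 - 1))
        p = _randomized_params(base_params, randomize, param_rngs[i], sample_seed)
        ss = np.random.SeedSequence(p.seed)
        _, noise_ss = ss.spawn(2)
        if randomize.shared_vessel:
            if shared_vessel_mask is None:
                vp = replace(base_params, seed=vessel_seed)
                vss = np.random.SeedSequence(vp.seed).spawn(2)[0]
                shared_vessel_mask = generate_vessel_tree(vp, np.random.default_rng(vss))
            vessel = shared_vessel_mask
        else:
            vp = replace(p, seed=vessel_seed)
            vss = np.random.SeedSequence(vp.seed).spawn(2)[0]
            vessel = generate_vessel_tree(vp, np.random.default_rng(vss))
        disc, cup = generate_disc_cup(p)
        fundus = render_fundus(vessel, disc, cup, p, np.random.default_rng(noise_ss))
        samples.append(PhantomSample(vessel, disc, cup, fundus, p))

    if out_dir is not None:
        from . import io as fio

        fio.write_dataset(out_dir, samples, seed=seed, randomize=randomize)
    return samples
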