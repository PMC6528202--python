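"""Image and dataset I/O.

On-disk dataset layout::

    <root>/masks/vessel/<id>.png   single-channel 8-bit, values {0, 255}
    <root>/masks/disc/<id>.png
    <root>/masks/cup/<id>.png
    <root>/fundus/<id>.png         3-channel 8-bit RGB
    <root>/manifest.yaml           per-id parameters, seed, generator version

8-bit PNG round-trips are lossless and bit-identical; 16-bit inputs are
converted to 8-bit (integer division by 257) with a logged warning.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .errors import FundusGANError, InvalidParameterError

logger = logging.getLogger("fundusgan")

MASK_ROLES = ("vessel", "disc", "cup")


def read_image(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FundusGANError(f"image file not found: {path}")
    try:
        img = iio.imread(path)
    except Exception as exc:  # corrupt file
        raise FundusGANError(f"could not read image {path}: {exc}") from exc
    if img.dtype == np.uint16:
        logger.warning("16-bit image %s converted to 8-bit (value // 257)", path)
        img = (img // 257).astype(np.uint8)
    elif img.dtype != np.uint8:
        logger.warning("image %s with dtype %s converted to 8-bit", path, img.dtype)
        img = np.clip(img, 0, 255).astype(np.uint8)
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[:, :, :3]
    return img


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    image = np.asarray(image)
    if image.dtype == bool:
        image = image.astype(np.uint8) * 255
    if image.dtype != np.uint8:
        raise InvalidParameterError("write_image expects uint8 or bool arrays")
    iio.imwrite(path, image)


def read_mask(path) -> np.ndarray:
    """Load a mask PNG as a {0,1} uint8 array."""
    from .masks import binarize

    img = read_image(path)
    if img.ndim == 3:
        img = img[:, :, 0]
    return binarize(img)


# ---------------------------------------------------------------------------
# dataset layout
# ---------------------------------------------------------------------------

def sample_id(index: int) -> str:
    return f"{index:04d}"


def write_dataset(root, samples, seed: int = 0, randomize=None) -> None:
    from .phantom import GENERATOR_VERSION

    root = Path(root)
    manifest: dict = {
        "generator_version": GENERATOR_VERSION,
        "seed": int(seed),
        "n_samples": len(samples),
        "samples": {},
    }
    if randomize is not None:
        manifest["randomize"] = dataclasses.asdict(randomize)
    for i, s in enumerate(samples):
        sid = sample_id(i)
        write_image(root / "masks" / "vessel" / f"{sid}.png", s.vessel_mask.astype(np.uint8) * 255)
        write_image(root / "masks" / "disc" / f"{sid}.png", s.disc_mask.astype(np.uint8) * 255)
        write_image(root / "masks" / "cup" / f"{sid}.png", s.cup_mask.astype(np.uint8) * 255)
        write_image(root / "fundus" / f"{sid}.png", s.fundus)
        p = dataclasses.asdict(s.params)
        p["disc_center"] = list(s.params.resolved_disc_center)
        p["disc_radius"] = int(s.params.resolved_disc_radius)
        manifest["samples"][sid] = p
    with open(root / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def load_dataset(root) -> list[dict]:
    """Load the dataset layout into records of {id, vessel, disc, cup, fundus}."""
    root = Path(root)
    fundus_dir = root / "fundus"
    if not fundus_dir.is_dir():
        raise FundusGANError(f"no fundus/ directory under {root}")
    records = []
    for f in sorted(fundus_dir.glob("*.png")):
        sid = f.stem
        rec = {"id": sid, "fundus": read_image(f)}
        for role in MASK_ROLES:
            mpath = root / "masks" / role / f"{sid}.png"
            rec[role] = read_mask(mpath) if mpath.exists() else None
        records.append(rec)
    if not records:
        raise FundusGANError(f"no samples found under {root}")
    return records


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_FORMAT = 1


def save_checkpoint(path, model, spec, metadata: dict | None = None) -> None:
    """Write model weights + architecture spec to a .npz checkpoint."""
    import json

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "format": CHECKPOINT_FORMAT,
        "spec": dataclasses.asdict(spec),
        "spec_type": type(spec).__name__,
        "metadata": metadata or {},
    }
    arrays = {f"state/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path):
    """Return (spec, state_dict, metadata) from a checkpoint file."""
    import json

    from .models import DiscriminatorSpec, GeneratorSpec

    path = Path(path)
    if not path.exists():
        raise FundusGANError(f"checkpoint not found: {path}")
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        state = {k[len("state/"):]: data[k] for k in data.files if k.startswith("state/")}
    spec_cls = {"GeneratorSpec": GeneratorSpec, "DiscriminatorSpec": DiscriminatorSpec}[
        header["spec_type"]
    ]
    spec_kwargs = header["spec"]
    if "family" in spec_kwargs and isinstance(spec_kwargs.get("family"), str):
        pass
    spec = spec_cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in spec_kwargs.items()})
    return spec, state, header["metadata"]
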