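"""SSIM / PSNR image-quality metrics and the paired-directory evaluation protocol.

Settings follow the canonical structural-similarity formulation: an
11 x 11 Gaussian window with sigma 1.5, k1 = 0.01, k2 = 0.03, data range
255 for 8-bit images. Color images are scored per channel and averaged
for SSIM; PSNR pools the squared error over all pixels and channels.

Identical image pairs have infinite PSNR; the report keeps ``inf`` as an
explicit sentinel and excludes it from the mean with a warning rather
than silently capping it.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.metrics import structural_similarity as _sk_ssim

from .errors import InvalidParameterError

DEFAULT_WINDOW = 11
DEFAULT_SIGMA = 1.5
DEFAULT_K1 = 0.01
DEFAULT_K2 = 0.03


@dataclass
class MetricReport:
    per_image: list[tuple[str, float, float]]  # (id, ssim, psnr_dB)
    mean_ssim: float
    mean_psnr: float
    n_pairs: int
    settings: dict = field(default_factory=dict)

    def write_csv(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "ssim", "psnr_db"])
            for row in self.per_image:
                writer.writerow(row)
            writer.writerow(["mean", self.mean_ssim, self.mean_psnr])


def _check_pair(reference: np.ndarray, test: np.ndarray) -> None:
    if reference.shape != test.shape:
        raise InvalidParameterError(
            f"image shape mismatch: {reference.shape} vs {test.shape}"
        )


def psnr(reference: np.ndarray, test: np.ndarray, data_range: float = 255.0) -> float:
    """10 log10(data_range^2 / MSE) in dB; +inf for identical images."""
    reference, test = np.asarray(reference), np.asarray(test)
    _check_pair(reference, test)
    if data_range <= 0:
        raise InvalidParameterError("data_range must be positive")
    mse = np.mean((reference.astype(np.float64) - test.astype(np.float64)) ** 2)
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(data_range ** 2 / mse)


def ssim(reference: np.ndarray, test: np.ndarray, window: int = DEFAULT_WINDOW,
         k1: float = DEFAULT_K1, k2: float = DEFAULT_K2,
         data_range: float = 255.0, grayscale: bool = False) -> float:
    """Mean structural similarity over Gaussian-weighted sliding windows.

    Multichannel images are scored per channel and averaged unless
    ``grayscale`` converts them first (luminance weights 0.299/0.587/0.114).
    """
    reference, test = np.asarray(reference), np.asarray(test)
    _check_pair(reference, test)
    if window % 2 == 0:
        raise InvalidParameterError("window size must be odd")
    if window > min(reference.shape[0], reference.shape[1]):
        raise InvalidParameterError("window larger than image")
    if grayscale and reference.ndim == 3:
        w = np.array([0.299, 0.587, 0.114])
        reference = reference @ w
        test = test @ w
    kwargs = dict(
        win_size=window, data_range=data_range, K1=k1, K2=k2,
        gaussian_weights=True, sigma=DEFAULT_SIGMA, use_sample_covariance=False,
    )
    if reference.ndim == 3:
        kwargs["channel_axis"] = 2
    return float(_sk_ssim(reference.astype(np.float64), test.astype(np.float64), **kwargs))


def regional_ssim(reference: np.ndarray, test: np.ndarray, roi: np.ndarray,
                  window: int = DEFAULT_WINDOW, **kwargs) -> float:
    """SSIM restricted to a region of interest.

    The images are cropped to the ROI bounding box, the per-pixel SSIM map
    is computed on the crop, the map border of half a window (windows not
    fully inside the bounding box) is discarded, and the remaining map
    values are averaged weighted by the ROI mask. For a rectangular ROI
    this equals plain SSIM of the cropped rectangles; for a full-image ROI
    it equals plain SSIM.
    """
    reference, test = np.asarray(reference), np.asarray(test)
    _check_pair(reference, test)
    roi = np.asarray(roi).astype(bool)
    if roi.shape != reference.shape[:2]:
        raise InvalidParameterError("roi must match image spatial dimensions")
    if not roi.any():
        raise InvalidParameterError("roi is empty")
    rows = np.flatnonzero(roi.any(axis=1))
    cols = np.flatnonzero(roi.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    if (r1 - r0) < window or (c1 - c0) < window:
        raise InvalidParameterError(
            f"roi bounding box {(r1 - r0)}x{(c1 - c0)} smaller than window {window}"
        )
    ref_c = reference[r0:r1, c0:c1]
    test_c = test[r0:r1, c0:c1]
    roi_c = roi[r0:r1, c0:c1]
    sk_kwargs = dict(
        win_size=window, data_range=kwargs.get("data_range", 255.0),
        K1=kwargs.get("k1", DEFAULT_K1), K2=kwargs.get("k2", DEFAULT_K2),
        gaussian_weights=True, sigma=DEFAULT_SIGMA, use_sample_covariance=False,
        full=True,
    )
    if ref_c.ndim == 3:
        sk_kwargs["channel_axis"] = 2
    _, smap = _sk_ssim(ref_c.astype(np.float64), test_c.astype(np.float64), **sk_kwargs)
    if smap.ndim == 3:
        smap = smap.mean(axis=2)
    pad = (window - 1) // 2
    inner = smap[pad:-pad, pad:-pad]
    roi_inner = roi_c[pad:-pad, pad:-pad]
    if roi_inner.any():
        return float(inner[roi_inner].mean())
    return float(inner.mean())


def evaluate_pairs(generated_dir, reference_dir, window: int = DEFAULT_WINDOW,
                   data_range: float = 255.0, resize_to_reference: bool = False,
                   out_csv=None) -> MetricReport:
    """Score identically named images in two directories.

    When ``resize_to_reference`` is set, generated images are resized to
    the reference resolution by bicubic interpolation before scoring.
    """
    from . import io as fio
    from .masks import resize_pair

    generated_dir, reference_dir = Path(generated_dir), Path(reference_dir)
    gen = {p.name: p for p in sorted(generated_dir.glob("*.png"))}
    ref = {p.name: p for p in sorted(reference_dir.glob("*.png"))}
    orphans = sorted(set(gen) ^ set(ref))
    common = sorted(set(gen) & set(ref))
    if not common:
        raise InvalidParameterError(
            f"no identically named image pairs between {generated_dir} and {reference_dir}"
        )
    if orphans:
        raise InvalidParameterError(f"unmatched filenames: {orphans}")

    per_image: list[tuple[str, float, float]] = []
    for name in common:
        g = fio.read_image(gen[name])
        r = fio.read_image(ref[name])
        if g.shape != r.shape:
            if not resize_to_reference:
                raise InvalidParameterError(
                    f"{name}: shape {g.shape} vs {r.shape}; pass resize_to_reference=True"
                )
            g = resize_pair(g, r.shape[:2], mode="image")
        per_image.append((Path(name).stem, ssim(r, g, window=window, data_range=data_range),
                          psnr(r, g, data_range=data_range)))

    ssims = [s for _, s, _ in per_image]
    psnrs = [p for _, _, p in per_image]
    finite = [p for p in psnrs if math.isfinite(p)]
    if len(finite) < len(psnrs):
        warnings.warn("identical image pair(s) with infinite PSNR excluded from the mean")
    report = MetricReport(
        per_image=per_image,
        mean_ssim=float(np.mean(ssims)),
        mean_psnr=float(np.mean(finite)) if finite else math.inf,
        n_pairs=len(per_image),
        settings=dict(window=window, sigma=DEFAULT_SIGMA, k1=DEFAULT_K1, k2=DEFAULT_K2,
                      data_range=data_range),
    )
    if out_csv is not None:
        report.write_csv(out_csv)
    return report
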