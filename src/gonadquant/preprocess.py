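"""Image loading, downsampling, stain normalization, and color-space conversion.

Histology sections are scanned at high magnification (0.25 µm per pixel at
20x); the quantitative analysis runs on images downsampled by an integer
factor (default 8, i.e. 2 µm per pixel), after a Reinhard-style color
normalization that aligns every slide's stain statistics to a common
reference. Segmentation then works in two classical color spaces: HSI
(intensity separates tissue from the white background) and CIE L*a*b*
(lightness and the green-red axis separate the tubule stain from the
surrounding connective tissue).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from skimage import color as skcolor

logger = logging.getLogger(__name__)

__all__ = [
    "RGBImage",
    "ColorReference",
    "load_image",
    "downsample",
    "color_normalize",
    "to_hsi",
    "to_lab",
]


@dataclass(frozen=True)
class RGBImage:
    """An 8-bit RGB section image with its physical pixel size.

    Pixels are stored as an (H, W, 3) uint8 array, row 0 at the top,
    0-based (row, col) indexing.
    """

    pixels: np.ndarray
    microns_per_pixel: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if px.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {px.dtype}")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class ColorReference:
    """Per-channel L*a*b* mean and standard deviation of a reference image."""

    mean: tuple[float, float, float]
    std: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.std):
            raise ValueError("reference standard deviations must be positive")

    @classmethod
    def from_image(cls, image: RGBImage) -> "ColorReference":
        lab = skcolor.rgb2lab(image.pixels)
        mean = tuple(float(m) for m in lab.reshape(-1, 3).mean(axis=0))
        std = tuple(max(float(s), 1e-6) for s in lab.reshape(-1, 3).std(axis=0))
        return cls(mean=mean, std=std)


def load_image(path: str | Path, microns_per_pixel: float = 0.25) -> RGBImage:
    """Read a TIFF or PNG section scan as an :class:`RGBImage`.

    Alpha channels are dropped; grayscale images are replicated to RGB.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return RGBImage(pixels=arr, microns_per_pixel=microns_per_pixel)


def downsample(image: RGBImage, factor: int) -> RGBImage:
    """Block-mean downsampling by an integer factor.

    Each output pixel is the mean of its ``factor`` x ``factor`` source
    block (partial edge blocks are averaged over the pixels present),
    rounded half up. Block means rather than stride sampling keep area
    fractions unbiased, which matters because the downstream indices are
    area ratios. The physical pixel size is multiplied by ``factor``.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"downsample factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return image
    px = image.pixels.astype(np.float64)
    h, w = px.shape[:2]
    row_idx = np.arange(0, h, factor)
    col_idx = np.arange(0, w, factor)
    sums = np.add.reduceat(np.add.reduceat(px, row_idx, axis=0), col_idx, axis=1)
    row_counts = np.diff(np.append(row_idx, h))
    col_counts = np.diff(np.append(col_idx, w))
    counts = np.outer(row_counts, col_counts)[..., None]
    means = sums / counts
    out = np.clip(np.floor(means + 0.5), 0, 255).astype(np.uint8)
    return RGBImage(pixels=out, microns_per_pixel=image.microns_per_pixel * factor)


def color_normalize(image: RGBImage, ref: ColorReference) -> RGBImage:
    """Reinhard mean/std color transfer in L*a*b* space.

    Each Lab channel of the input is shifted and scaled so that its mean
    and standard deviation match the reference, then converted back to
    8-bit RGB. A channel with zero variance is mean-shifted only (scaling
    is undefined), with a warning.
    """
    lab = skcolor.rgb2lab(image.pixels)
    flat = lab.reshape(-1, 3)
    mean = flat.mean(axis=0)
    std = flat.std(axis=0)
    out = np.empty_like(lab)
    for c in range(3):
        if std[c] < 1e-8:
            logger.warning(
                "color_normalize: channel %d has zero variance; mean shift only", c
            )
            out[..., c] = lab[..., c] - mean[c] + ref.mean[c]
        else:
            out[..., c] = (lab[..., c] - mean[c]) / std[c] * ref.std[c] + ref.mean[c]
    rgb = skcolor.lab2rgb(out)  # clips to [0, 1]
    px = np.clip(np.floor(rgb * 255.0 + 0.5), 0, 255).astype(np.uint8)
    return RGBImage(pixels=px, microns_per_pixel=image.microns_per_pixel)


def to_hsi(image: RGBImage) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert to the classical HSI (hue, saturation, intensity) space.

    I = (R+G+B)/(3*255) in [0, 1]; S = 1 - min(R,G,B)/mean(R,G,B) with
    S = 0 for black; H in degrees [0, 360) by the angular formula, with
    undefined hue (achromatic pixels) mapped to 0.
    """
    rgb = image.pixels.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    total = r + g + b
    intensity = total / (3.0 * 255.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        saturation = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / total, 0.0)
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_arg = np.where(den > 0, num / den, 1.0)
    theta = np.degrees(np.arccos(np.clip(cos_arg, -1.0, 1.0)))
    hue = np.where(b <= g, theta, 360.0 - theta)
    hue = np.where(den > 0, hue, 0.0)
    hue = np.where(hue >= 360.0, hue - 360.0, hue)
    return hue, saturation, intensity


def to_lab(image: RGBImage) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert sRGB (D65) to CIE L*a*b* channel grids.

    L* in [0, 100]; a* (green-red) and b* (blue-yellow) signed.
    """
    lab = skcolor.rgb2lab(image.pixels)
    return lab[..., 0], lab[..., 1], lab[..., 2]
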