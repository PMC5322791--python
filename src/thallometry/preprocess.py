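"""Segmentation of a specimen image into a clean binary mask.

A specimen photograph (herbarium sheet, scanned slide, or a synthetic
rendering) is reduced to a boolean raster in three steps: conversion to
8-bit grayscale, global thresholding (Otsu's between-class-variance
criterion, with an optional manual override), and morphological cleanup
(opening to drop stray background speckle, closing to fill pinholes in
the specimen).  Every automatic decision — the threshold level actually
applied, the polarity, the structuring-element radii — is recorded in
the :class:`BinaryImage` provenance so a run can be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage

#: ITU-R BT.601 luminance weights used for RGB -> gray conversion.
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)


class FormatError(ValueError):
    """Raised for rasters with an unsupported layout (channel count etc.)."""


class DegenerateImageError(ValueError):
    """Raised when an image carries no usable intensity contrast."""


@dataclass
class GrayImage:
    """Single-channel 8-bit image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise FormatError("grayscale image must be a non-empty 2D array")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BinaryImage:
    """Boolean specimen mask (True = foreground) with reproducibility metadata.

    ``pixel_scale`` is the physical length of one pixel side (units per px);
    it stays ``None`` until the user calibrates the image.  ``provenance``
    accumulates the segmentation settings that produced the mask.
    """

    mask: np.ndarray
    pixel_scale: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise FormatError("mask must be 2D")
        if self.pixel_scale is not None and self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be strictly positive")

    @property
    def foreground_count(self) -> int:
        return int(self.mask.sum())


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF raster as an array (H, W) or (H, W, C)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return np.asarray(tifffile.imread(path))
    with Image.open(path) as im:
        return np.asarray(im)


def to_grayscale(image: np.ndarray | GrayImage) -> GrayImage:
    """Convert a 1-, 3- or 4-channel raster to 8-bit grayscale.

    Multi-channel input is combined with the BT.601 luminance weights
    (:data:`LUMINANCE_WEIGHTS`); an alpha channel, if present, is ignored.
    Single-channel input passes through unchanged.
    """
    if isinstance(image, GrayImage):
        return image
    arr = np.asarray(image)
    if arr.ndim == 2:
        return GrayImage(np.clip(np.round(arr), 0, 255))
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3].astype(float)
        gray = rgb @ np.asarray(LUMINANCE_WEIGHTS)
        return GrayImage(np.clip(np.round(gray), 0, 255))
    if arr.ndim == 3 and arr.shape[2] == 1:
        return GrayImage(np.clip(np.round(arr[..., 0]), 0, 255))
    raise FormatError(f"unsupported raster shape {arr.shape}")


def otsu_threshold(gray: GrayImage) -> int:
    """Otsu's threshold: the level maximizing between-class variance.

    Exhaustive search over the 256-bin histogram; a pixel with intensity
    <= level falls in the low class.  Deterministic (first maximum wins).
    """
    pixels = gray.pixels
    hist = np.bincount(pixels.ravel(), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError("constant image has no Otsu threshold")
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)
    total = w0[-1]
    w1 = total - w0
    s0 = np.cumsum(hist * levels)
    mu0 = np.divide(s0, w0, out=np.zeros(256), where=w0 > 0)
    mu1 = np.divide(s0[-1] - s0, w1, out=np.zeros(256), where=w1 > 0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    between[w1 == 0] = -1.0  # a split must leave both classes non-empty
    return int(np.argmax(between))


def binarize(
    gray: GrayImage,
    level: int | None = None,
    polarity: str = "dark",
    pixel_scale: float | None = None,
) -> BinaryImage:
    """Threshold a grayscale image into a specimen mask.

    Parameters
    ----------
    level
        Threshold intensity in [0, 255]; ``None`` applies Otsu's method.
    polarity
        ``"dark"`` if the specimen is darker than the background (mask is
        intensity <= level), ``"bright"`` for the opposite.
    """
    if polarity not in ("dark", "bright"):
        raise ValueError("polarity must be 'dark' or 'bright'")
    if level is None:
        level = otsu_threshold(gray)
        source = "otsu"
    else:
        if not 0 <= level <= 255:
            raise ValueError("manual threshold level must lie in [0, 255]")
        level = int(level)
        source = "manual"
    if polarity == "dark":
        mask = gray.pixels <= level
    else:
        mask = gray.pixels > level
    return BinaryImage(
        mask,
        pixel_scale=pixel_scale,
        provenance={"threshold_level": level, "threshold_source": source,
                    "polarity": polarity},
    )


def _disc(radius: int) -> np.ndarray:
    yy, xx = np.ogrid[-radius:radius + 1, -radius:radius + 1]
    return yy * yy + xx * xx <= radius * radius


def clean(binary: BinaryImage, open_radius: int = 1,
          close_radius: int = 1) -> BinaryImage:
    """Morphological opening then closing with disc structuring elements.

    Radius 0 skips the corresponding operation.  Border handling treats
    the outside of the image as background for dilation and as foreground
    for erosion, so specimens touching the frame are not eaten away.
    """
    if open_radius < 0 or close_radius < 0:
        raise ValueError("radii must be >= 0")
    mask = binary.mask
    if open_radius > 0:
        se = _disc(open_radius)
        mask = ndimage.binary_erosion(mask, structure=se, border_value=1)
        mask = ndimage.binary_dilation(mask, structure=se, border_value=0)
    if close_radius > 0:
        se = _disc(close_radius)
        mask = ndimage.binary_dilation(mask, structure=se, border_value=0)
        mask = ndimage.binary_erosion(mask, structure=se, border_value=1)
    prov = dict(binary.provenance)
    prov.update({"open_radius": open_radius, "close_radius": close_radius})
    return BinaryImage(mask, pixel_scale=binary.pixel_scale, provenance=prov)


def save_mask_png(binary: BinaryImage, path: str | Path) -> None:
    """Write the mask as a single-channel PNG (foreground = 255)."""
    Image.fromarray(np.where(binary.mask, 255, 0).astype(np.uint8)).save(path)
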