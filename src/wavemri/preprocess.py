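"""Image preprocessing: grayscale conversion, resizing, global histogram equalization.

Global histogram equalization (GHE) remaps each gray level ``g_k`` through the
normalized cumulative histogram,

    G_k = C(g_k) = sum_{i<=k} P(g_i) = sum_{i<=k} n_i / n,

and the output level is ``floor(G_k * (N-1))`` for an ``N``-level image.  The
transform stretches the occupied dynamic range so that the output intensity
distribution is approximately uniform, which suppresses per-image brightness
and contrast nuisances (lighting, scanner gain) before feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _skimage_resize

__all__ = [
    "GrayImage",
    "EqualizationMap",
    "as_gray_image",
    "to_grayscale",
    "equalize_global",
    "resize_image",
]

#: ITU-R BT.601 luminance weights used for RGB -> gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: A GrayImage is a 2-D integer ndarray with values in [0, N-1]; helper
#: functions below validate the contract.  N defaults to 256 (8-bit).
GrayImage = np.ndarray

DEFAULT_LEVELS = 256


def as_gray_image(pixels: np.ndarray, levels: int = DEFAULT_LEVELS) -> GrayImage:
    """Validate and coerce an array to a GrayImage (2-D ints in [0, levels-1])."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError(f"GrayImage must be 2-D, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("GrayImage must be non-empty")
    arr = np.rint(arr).astype(np.int64)
    if arr.min() < 0 or arr.max() > levels - 1:
        raise ValueError(
            f"pixel values must lie in [0, {levels - 1}], "
            f"got range [{arr.min()}, {arr.max()}]"
        )
    dtype = np.uint8 if levels <= 256 else np.int64
    return arr.astype(dtype)


@dataclass(frozen=True)
class EqualizationMap:
    """Histogram-equalization transform of one image.

    Attributes
    ----------
    pdf : per-level occupancy probabilities P(g_i) (sums to 1).
    cdf : cumulative distribution G_k (non-decreasing, ends at 1).
    lut : level -> level mapping floor(G_k * (N-1)).
    n : total pixel count.
    counts : per-level pixel counts n_i.
    """

    pdf: np.ndarray
    cdf: np.ndarray
    lut: np.ndarray
    n: int
    counts: np.ndarray

    @property
    def levels(self) -> int:
        return self.lut.size


def to_grayscale(rgb_image: np.ndarray) -> GrayImage:
    """Convert a 3-channel integer image to grayscale luminance.

    Uses the BT.601 weighted combination 0.299 R + 0.587 G + 0.114 B,
    rounded to the nearest integer.  A 2-D input is passed through
    unchanged (already grayscale).
    """
    arr = np.asarray(rgb_image)
    if arr.ndim == 2:
        return as_gray_image(arr)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"expected an H x W x 3 RGB image or a 2-D grayscale image, "
            f"got shape {arr.shape}"
        )
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB values must lie in [0, 255]")
    luma = arr.astype(np.float64) @ np.asarray(LUMA_WEIGHTS)
    return as_gray_image(np.rint(luma))


def equalize_global(
    img: GrayImage, levels: int = DEFAULT_LEVELS
) -> tuple[GrayImage, EqualizationMap]:
    """Apply global histogram equalization; return the remapped image and map.

    Each input level g_k maps to floor(G_k * (N-1)) where G_k is the
    cumulative histogram probability of g_k.
    """
    img = as_gray_image(img, levels)
    counts = np.bincount(img.ravel(), minlength=levels).astype(np.int64)
    n = int(img.size)
    pdf = counts / n
    cdf = np.cumsum(pdf)
    # guard against float drift at the top of the range
    cdf = np.minimum(cdf, 1.0)
    lut = np.floor(cdf * (levels - 1)).astype(np.int64)
    out = as_gray_image(lut[img], levels)
    return out, EqualizationMap(pdf=pdf, cdf=cdf, lut=lut, n=n, counts=counts)


def resize_image(img: GrayImage, out_h: int, out_w: int,
                 levels: int = DEFAULT_LEVELS) -> GrayImage:
    """Bilinear resize to (out_h, out_w); values rounded and clipped."""
    if out_h <= 0 or out_w <= 0:
        raise ValueError(f"target size must be positive, got {(out_h, out_w)}")
    img = as_gray_image(img, levels)
    if img.shape == (out_h, out_w):
        return img
    out = _skimage_resize(
        img.astype(np.float64), (out_h, out_w), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return as_gray_image(np.clip(np.rint(out), 0, levels - 1), levels)
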