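"""Reading and writing images and dataset manifests.

A dataset on disk is a directory of per-class subdirectories of PNG/JPEG
files, optionally accompanied by a ``manifest.csv`` with columns
``path,label,seed``.  When a manifest is present it is authoritative;
otherwise labels are taken from subdirectory names.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .preprocess import GrayImage, as_gray_image, to_grayscale

__all__ = [
    "read_image",
    "write_image",
    "read_nifti_slice",
    "load_dataset",
    "write_manifest",
]

_IMAGE_EXTS = {".png", ".jpg", ".jpeg"}


def read_image(path: str | os.PathLike) -> GrayImage:
    """Read a PNG/JPEG file as a grayscale image (RGB is converted)."""
    with Image.open(path) as im:
        if im.mode not in ("L", "RGB"):
            im = im.convert("RGB")
        arr = np.asarray(im)
    if arr.ndim == 3:
        return to_grayscale(arr)
    return as_gray_image(arr)


def write_image(img: GrayImage, path: str | os.PathLike) -> None:
    """Write a grayscale image as 8-bit PNG."""
    arr = as_gray_image(img).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def read_nifti_slice(path: str | os.PathLike, index: int | None = None,
                     axis: int = 2) -> GrayImage:
    """Extract one 2-D slice from a NIfTI volume, rescaled to [0, 255].

    Parameters
    ----------
    index : slice index along ``axis``; the middle slice when None.
    """
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
    if vol.ndim < 2:
        raise ValueError(f"NIfTI volume must be at least 2-D, got {vol.ndim}-D")
    while vol.ndim > 3:
        vol = vol[..., 0]
    if vol.ndim == 3:
        if index is None:
            index = vol.shape[axis] // 2
        vol = np.take(vol, index, axis=axis)
    lo, hi = vol.min(), vol.max()
    if hi > lo:
        vol = (vol - lo) / (hi - lo) * 255.0
    else:
        vol = np.zeros_like(vol)
    return as_gray_image(np.rint(vol))


def load_dataset(root: str | os.PathLike) -> tuple[list[GrayImage], list[str]]:
    """Load all images and labels from a dataset directory.

    Returns (images, labels) in a deterministic (sorted-path) order.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {root}")
    manifest = root / "manifest.csv"
    images, labels = [], []
    if manifest.exists():
        df = pd.read_csv(manifest)
        for _, row in df.iterrows():
            images.append(read_image(root / row["path"]))
            labels.append(str(row["label"]))
    else:
        for cls_dir in sorted(p for p in root.iterdir() if p.is_dir()):
            for f in sorted(cls_dir.iterdir()):
                if f.suffix.lower() in _IMAGE_EXTS:
                    images.append(read_image(f))
                    labels.append(cls_dir.name)
    if not images:
        raise ValueError(f"no images found under {root}")
    if len(set(labels)) < 2:
        raise ValueError("dataset must contain at least 2 classes")
    return images, labels


def write_manifest(rows: list[dict], path: str | os.PathLike) -> None:
    """Write a manifest CSV with columns path,label,seed."""
    pd.DataFrame(rows, columns=["path", "label", "seed"]).to_csv(path, index=False)
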