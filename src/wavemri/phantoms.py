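"""Seeded synthetic phantom generator for multi-class texture classification.

Real brain-MRI archives cannot ship with a library, so every stage of the
pipeline is exercised on procedurally generated "phantom" images instead:
per-class oriented sinusoidal gratings (each class owns a distinct spatial
frequency and orientation), optional Gaussian blob fields and speckle
impulses, a per-image illumination nuisance, and additive noise.

The illumination nuisance has two parts, both scaled by ``illumination``:
a linear shading ramp in a random direction, and a random global gain/offset
jitter.  The gain/offset part is a monotone intensity map, which global
histogram equalization cancels exactly — mirroring the motivation for the
equalization stage.

Class labels reuse the 25 brain-condition abbreviations (FS ... NB) for
report realism.  Default class gratings sit at low spatial frequencies
(0.015-0.035 cycles/pixel) so the class-defining signal lies inside the
passband of the level-4 approximation subband (|f| < 1/32 cycles/pixel),
as anatomy-scale structure does in real MRI.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as wio
from .preprocess import GrayImage, as_gray_image

__all__ = [
    "CLASS_LABELS",
    "ClassTexture",
    "PhantomSpec",
    "default_spec",
    "generate_phantom_image",
    "generate_phantom_arrays",
    "generate_phantom_dataset",
]

#: The 25 brain-condition abbreviations used as phantom class labels.
CLASS_LABELS = (
    "FS", "MN", "GL", "VD", "CA", "HY", "CC", "MA", "CS", "MI", "AD", "CT",
    "ME", "PD", "SR", "AL", "CJ", "MB", "AV", "MS", "LE", "HE", "CH", "HD",
    "NB",
)


@dataclass(frozen=True)
class ClassTexture:
    """Texture parameters of one phantom class."""

    grating_freq: float       # cycles/pixel, in (0, 0.5)
    orientation_deg: float
    blob_count: int = 0
    blob_radius: float = 8.0
    speckle_density: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.grating_freq < 0.5:
            raise ValueError(
                f"grating frequency must lie in (0, 0.5) cycles/pixel, "
                f"got {self.grating_freq}")
        if self.blob_count < 0 or self.blob_radius <= 0:
            raise ValueError("blob count must be >= 0 and radius > 0")
        if not 0.0 <= self.speckle_density < 1.0:
            raise ValueError("speckle density must lie in [0, 1)")


@dataclass
class PhantomSpec:
    """Full description of a phantom dataset."""

    n_classes: int = 5
    images_per_class: int = 20
    height: int = 128
    width: int = 128
    class_textures: list[ClassTexture] = field(default_factory=list)
    illumination: float = 0.3     # fraction of dynamic range
    noise_kind: str = "gaussian"  # none | gaussian | salt-pepper
    noise_level: float = 10.0     # sigma (gaussian) or flip prob (salt-pepper)
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_classes <= len(CLASS_LABELS):
            raise ValueError(f"n_classes must be in [1, {len(CLASS_LABELS)}]")
        if self.images_per_class < 1 or self.height < 1 or self.width < 1:
            raise ValueError("images_per_class, height, width must be positive")
        if self.noise_kind not in ("none", "gaussian", "salt-pepper"):
            raise ValueError(f"unknown noise kind {self.noise_kind!r}")
        if not self.class_textures:
            self.class_textures = _default_textures(self.n_classes)
        if len(self.class_textures) != self.n_classes:
            raise ValueError("one ClassTexture is required per class")
        keys = {(t.grating_freq, t.orientation_deg, t.blob_count,
                 t.blob_radius, t.speckle_density) for t in self.class_textures}
        if len(keys) != self.n_classes:
            raise ValueError("class texture parameter tuples must be pairwise distinct")

    @property
    def labels(self) -> tuple[str, ...]:
        return CLASS_LABELS[: self.n_classes]


def _default_textures(n_classes: int) -> list[ClassTexture]:
    freqs = np.linspace(0.015, 0.035, n_classes)
    orients = np.arange(n_classes) * (180.0 / n_classes)
    return [
        ClassTexture(grating_freq=float(freqs[k]),
                     orientation_deg=float(orients[k]),
                     blob_count=2 + (k % 4), blob_radius=6.0 + 2 * (k % 3),
                     speckle_density=0.0)
        for k in range(n_classes)
    ]


def default_spec(**overrides) -> PhantomSpec:
    """The default benchmark spec: 5 classes x 20 images, 128x128,
    Gaussian sigma=10 noise, illumination amplitude 0.3, seed 0."""
    return PhantomSpec(**overrides)


def generate_phantom_image(spec: PhantomSpec, class_index: int,
                           instance_seed: int) -> GrayImage:
    """Deterministically render one phantom image of a given class."""
    if not 0 <= class_index < spec.n_classes:
        raise ValueError(
            f"class_index must lie in [0, {spec.n_classes - 1}], got {class_index}")
    tex = spec.class_textures[class_index]
    rng = np.random.default_rng([spec.seed, class_index, instance_seed])
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    theta = np.deg2rad(tex.orientation_deg)
    # small phase jitter: instances of a class stay spatially coherent
    # (anatomy does not translate freely) while never being bit-identical
    phase = rng.uniform(0, 0.3)
    carrier = xx * np.cos(theta) + yy * np.sin(theta)
    img = 128.0 + 55.0 * np.sin(2 * np.pi * tex.grating_freq * carrier + phase)

    for _ in range(tex.blob_count):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        amp = rng.uniform(20.0, 40.0) * rng.choice([-1.0, 1.0])
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        img += amp * np.exp(-r2 / (2 * tex.blob_radius ** 2))

    if tex.speckle_density > 0:
        mask = rng.random((h, w)) < tex.speckle_density
        img[mask] += rng.choice([-60.0, 60.0], size=int(mask.sum()))

    if spec.illumination > 0:
        amp = spec.illumination * 255.0
        direction = rng.uniform(0, 2 * np.pi)
        ramp = ((xx / max(w - 1, 1) - 0.5) * np.cos(direction)
                + (yy / max(h - 1, 1) - 0.5) * np.sin(direction))
        img += amp * ramp
        gain = 1.0 + rng.uniform(-spec.illumination / 2, spec.illumination / 2)
        offset = rng.uniform(-amp / 2, amp / 2)
        img = gain * (img - 128.0) + 128.0 + offset

    if spec.noise_kind == "gaussian" and spec.noise_level > 0:
        img += rng.normal(0.0, spec.noise_level, size=(h, w))
    elif spec.noise_kind == "salt-pepper" and spec.noise_level > 0:
        mask = rng.random((h, w)) < spec.noise_level
        img[mask] = rng.choice([0.0, 255.0], size=int(mask.sum()))

    return as_gray_image(np.clip(np.rint(img), 0, 255))


def generate_phantom_arrays(spec: PhantomSpec) -> tuple[list[GrayImage], list[str]]:
    """All images of a spec in memory, with their class labels."""
    images, labels = [], []
    for k, label in enumerate(spec.labels):
        for i in range(spec.images_per_class):
            images.append(generate_phantom_image(spec, k, i))
            labels.append(label)
    return images, labels


def generate_phantom_dataset(spec: PhantomSpec, out_dir: str | os.PathLike) -> Path:
    """Write the phantom set as per-class PNG subdirectories plus a manifest.

    Returns the dataset root; the manifest has columns path,label,seed.
    """
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    if not os.access(root, os.W_OK):
        raise PermissionError(f"output directory {root} is not writable")
    rows = []
    for k, label in enumerate(spec.labels):
        cls_dir = root / label
        cls_dir.mkdir(exist_ok=True)
        for i in range(spec.images_per_class):
            img = generate_phantom_image(spec, k, i)
            rel = f"{label}/{label}_{i:04d}.png"
            wio.write_image(img, root / rel)
            rows.append({"path": rel, "label": label, "seed": i})
    wio.write_manifest(rows, root / "manifest.csv")
    return root
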