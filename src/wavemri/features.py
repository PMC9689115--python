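"""Symlet wavelet features: multilevel decomposition, frequency estimates, MI.

A grayscale image Y is split by a j-level 2-D discrete wavelet transform into
one low-pass ("rough") approximation grid R_j and, per level i = 1..j, three
high-pass ("precise") detail grids (horizontal P_h^i, vertical P_v^i,
diagonal P_d^i):

    Y = R_j + sum_{i=1..j} (P_h^i + P_v^i + P_d^i).

Symlets are the least-asymmetric compactly supported orthogonal wavelets of
the Daubechies family; under periodized boundary handling the transform is
orthonormal, so it conserves energy and inverts exactly.

Feature vectors come in three modes:

* ``rough``      — the flattened R_j grid (the low-frequency content that
  carries anatomy-scale texture; detail bands are noise-dominated).
* ``freq``       — one dominant-frequency estimate per subband, in
  input-image cycles/pixel, followed by their mean f_avg
  (f_avg = (f_1 + ... + f_K) / K over the K subbands).
* ``rough+freq`` — the concatenation (default).

The scale-to-frequency relation f = f_c / (a * delta), with f_c the wavelet
center frequency and delta the sampling period, converts a continuous-wavelet
scale into a signal frequency; `estimate_frequency_cwt` applies it through a
brute-force scale scan.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from .preprocess import GrayImage

__all__ = [
    "DecompositionTree",
    "FrequencySummary",
    "FeatureVector",
    "decompose",
    "reconstruct",
    "max_decomposition_level",
    "center_frequency",
    "scale_to_frequency",
    "cwt_response",
    "estimate_frequency_cwt",
    "subband_frequency",
    "frequency_summary",
    "build_feature_vector",
    "feature_matrix",
    "subband_mutual_information",
    "FEATURE_MODES",
]

DEFAULT_WAVELET = "sym4"
DEFAULT_LEVELS = 4
DEFAULT_MODE = "periodization"
FEATURE_MODES = ("rough", "freq", "rough+freq")


@dataclass
class DecompositionTree:
    """Multilevel 2-D DWT of one image.

    ``details[i]`` holds the (horizontal, vertical, diagonal) grids of level
    i+1, ordered fine-to-coarse (level 1 first).
    """

    wavelet_name: str
    levels: int
    rough: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    boundary_mode: str
    image_shape: tuple[int, int]

    def subbands(self) -> list[tuple[str, int, np.ndarray]]:
        """All subbands as (orientation, level, grid); rough first."""
        out = [("rough", self.levels, self.rough)]
        for i, (h, v, d) in enumerate(self.details, start=1):
            out.append(("horizontal", i, h))
            out.append(("vertical", i, v))
            out.append(("diagonal", i, d))
        return out

    def energy(self) -> float:
        return float(sum((g ** 2).sum() for _, _, g in self.subbands()))


@dataclass
class FrequencySummary:
    """Per-subband frequency estimates and their average (cycles/pixel)."""

    f_c: float
    delta: float
    per_frame_freq: np.ndarray
    K: int = field(init=False)
    f_avg: float = field(init=False)

    def __post_init__(self):
        self.per_frame_freq = np.asarray(self.per_frame_freq, dtype=np.float64)
        self.K = int(self.per_frame_freq.size)
        self.f_avg = float(self.per_frame_freq.mean())


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    image_id: str
    config_digest: str

    @property
    def length(self) -> int:
        return int(self.values.size)


def max_decomposition_level(shape: tuple[int, int]) -> int:
    """Deepest level for which every subband keeps at least one sample."""
    return int(np.floor(np.log2(min(shape))))


def decompose(img: GrayImage, wavelet: str = DEFAULT_WAVELET,
              levels: int = DEFAULT_LEVELS,
              mode: str = DEFAULT_MODE) -> DecompositionTree:
    """Multilevel 2-D DWT of a grayscale image."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("decompose expects a 2-D image")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    max_lvl = max_decomposition_level(arr.shape)
    if levels > max_lvl:
        raise ValueError(
            f"image of shape {arr.shape} supports at most {max_lvl} "
            f"decomposition levels, requested {levels}"
        )
    with warnings.catch_warnings():
        # depth feasibility is checked above; pywt's advisory about
        # boundary effects at depths past dwt_max_level is expected here
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(arr, wavelet, mode=mode, level=levels)
    rough = coeffs[0]
    # wavedec2 orders detail levels coarse-to-fine; store fine-to-coarse
    details = [tuple(np.asarray(a) for a in t) for t in reversed(coeffs[1:])]
    return DecompositionTree(
        wavelet_name=wavelet, levels=levels, rough=np.asarray(rough),
        details=details, boundary_mode=mode, image_shape=arr.shape,
    )


def reconstruct(tree: DecompositionTree) -> np.ndarray:
    """Inverse transform; returns a real-valued grid of the original shape."""
    for h, v, d in tree.details:
        if not (h.shape == v.shape == d.shape):
            raise ValueError("mismatched subband shapes within a level")
    coeffs = [tree.rough] + [tuple(t) for t in reversed(tree.details)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rec = pywt.waverec2(coeffs, tree.wavelet_name, mode=tree.boundary_mode)
    h, w = tree.image_shape
    return np.asarray(rec)[:h, :w]


def center_frequency(wavelet: str = DEFAULT_WAVELET) -> float:
    """Center frequency f_c of a wavelet in cycles/sample.

    The dominant DFT peak of the wavelet function sampled on its support
    (PyWavelets' convention).
    """
    return float(pywt.central_frequency(wavelet, precision=10))


def scale_to_frequency(a: float, f_c: float, delta: float = 1.0) -> float:
    """Convert a wavelet scale to a signal frequency: f = f_c / (a * delta)."""
    if a <= 0 or f_c <= 0 or delta <= 0:
        raise ValueError("scale, center frequency and sampling period must be > 0")
    return f_c / (a * delta)


def _sampled_wavelet(wavelet: str, scale: float) -> np.ndarray:
    """psi(t / a) / sqrt(a) sampled at integer t over the scaled support."""
    w = pywt.Wavelet(wavelet)
    _, psi, grid = w.wavefun(level=10)
    t = np.arange(np.ceil(scale * grid[0]), np.floor(scale * grid[-1]) + 1)
    return np.interp(t / scale, grid, psi) / np.sqrt(scale)


def cwt_response(signal: np.ndarray, scales: np.ndarray,
                 wavelet: str = DEFAULT_WAVELET) -> np.ndarray:
    """Total squared wavelet response sum_b |W(a, b)|^2 per scale.

    W(a, b) is the correlation of the signal with the scaled, normalized
    wavelet psi((t - b)/a) / sqrt(a); positions within half a kernel of the
    signal ends are discarded to avoid boundary bias.
    """
    x = np.asarray(signal, dtype=np.float64)
    out = np.empty(len(scales))
    for i, a in enumerate(np.asarray(scales, dtype=np.float64)):
        if a <= 0:
            raise ValueError("scales must be positive")
        kern = _sampled_wavelet(wavelet, a)
        w = np.convolve(x, kern[::-1], mode="same")
        m = len(kern) // 2
        core = w[m: len(w) - m] if len(w) > 2 * m else w
        out[i] = float((core ** 2).sum())
    return out


def estimate_frequency_cwt(signal: np.ndarray, wavelet: str = DEFAULT_WAVELET,
                           delta: float = 1.0, n_scales: int = 120,
                           f_lo: float = 0.01, f_hi: float = 0.45,
                           oversample: int = 4) -> float:
    """Estimate a signal's dominant frequency by a brute-force scale scan.

    Scans scales a = f_c / (f * delta) over a dense geometric frequency grid
    and returns f = f_c / (a* . delta) for the response-maximizing scale a*.
    The signal is Fourier-resampled ``oversample`` times finer first so the
    sampled wavelet kernel stays well resolved even at the smallest scales
    (highest frequencies) in the scan.
    """
    from scipy.signal import resample

    f_c = center_frequency(wavelet)
    x = np.asarray(signal, dtype=np.float64)
    if oversample > 1:
        x = resample(x, oversample * len(x))
    freqs = np.geomspace(f_lo, f_hi, n_scales)
    # frequencies re-expressed at the oversampled rate
    scales = f_c / (freqs / oversample)
    power = cwt_response(x, scales, wavelet)
    return scale_to_frequency(scales[int(np.argmax(power))], f_c,
                              delta / oversample)


def subband_frequency(grid: np.ndarray) -> float:
    """Energy-weighted mean radial spatial frequency of a coefficient grid.

    Frequencies are in cycles/sample at the subband's own sampling rate;
    the DC component is excluded.  A constant (or empty-spectrum) grid
    yields 0.
    """
    g = np.asarray(grid, dtype=np.float64)
    spec = np.abs(np.fft.fft2(g)) ** 2
    fy = np.fft.fftfreq(g.shape[0])[:, None]
    fx = np.fft.fftfreq(g.shape[1])[None, :]
    radial = np.sqrt(fy ** 2 + fx ** 2)
    spec = spec.copy()
    spec[0, 0] = 0.0
    total = spec.sum()
    if total <= 0:
        return 0.0
    return float((radial * spec).sum() / total)


def frequency_summary(tree: DecompositionTree, delta: float = 1.0) -> FrequencySummary:
    """Per-subband dominant frequencies mapped to input-image cycles/pixel.

    Level-i subbands are sampled every 2^i input pixels, so a subband-plane
    frequency f divides by 2^i to express it at the image sampling rate.
    """
    f_c = center_frequency(tree.wavelet_name)
    freqs = [subband_frequency(grid) / (2.0 ** lvl) * (1.0 / delta)
             for _, lvl, grid in tree.subbands()]
    return FrequencySummary(f_c=f_c, delta=delta,
                            per_frame_freq=np.array(freqs))


def config_digest(image_shape: tuple[int, int], wavelet: str, levels: int,
                  mode: str, feature_mode: str) -> str:
    """Stable identifier of a feature-extraction configuration."""
    key = f"{image_shape[0]}x{image_shape[1]}|{wavelet}|{levels}|{mode}|{feature_mode}"
    return hashlib.sha256(key.encode()).hexdigest()[:16]


def build_feature_vector(tree: DecompositionTree, feature_mode: str = "rough+freq",
                         image_id: str = "") -> FeatureVector:
    """Build the feature vector of one image from its decomposition tree."""
    if feature_mode not in FEATURE_MODES:
        raise ValueError(
            f"unknown feature mode {feature_mode!r}; choose from {FEATURE_MODES}")
    parts = []
    if "rough" in feature_mode:
        parts.append(tree.rough.ravel(order="C"))
    if "freq" in feature_mode:
        fs = frequency_summary(tree)
        parts.append(np.append(fs.per_frame_freq, fs.f_avg))
    values = np.concatenate(parts)
    if not np.all(np.isfinite(values)):
        raise ValueError("feature vector contains non-finite values")
    digest = config_digest(tree.image_shape, tree.wavelet_name, tree.levels,
                           tree.boundary_mode, feature_mode)
    return FeatureVector(values=values, image_id=image_id, config_digest=digest)


def feature_matrix(images: list[GrayImage], wavelet: str = DEFAULT_WAVELET,
                   levels: int = DEFAULT_LEVELS, mode: str = DEFAULT_MODE,
                   feature_mode: str = "rough+freq") -> tuple[np.ndarray, str]:
    """Stack feature vectors of many images; returns (matrix, config digest)."""
    vecs = [build_feature_vector(decompose(im, wavelet, levels, mode),
                                 feature_mode, image_id=str(i))
            for i, im in enumerate(images)]
    lengths = {v.length for v in vecs}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent feature lengths {sorted(lengths)}; "
                         "all images must share one shape and configuration")
    return np.vstack([v.values for v in vecs]), vecs[0].config_digest


def subband_mutual_information(A: np.ndarray, B: np.ndarray,
                               bins: int = 64) -> float:
    """Mutual information (bits) between two coefficient grids.

    Each grid is quantized into equal-width bins over its own observed
    range; MI is computed from the joint histogram of the paired bin
    indices.  Always >= 0 (clipped against float round-off).
    """
    a = np.asarray(A, dtype=np.float64).ravel()
    b = np.asarray(B, dtype=np.float64).ravel()
    if a.size != b.size:
        raise ValueError(f"grids must have equal element counts, "
                         f"got {a.size} and {b.size}")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    mi = float((p[mask] * np.log(p[mask] / (px @ py)[mask])).sum()) / np.log(2.0)
    return max(mi, 0.0)
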