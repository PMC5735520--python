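"""Low-resolution frequency-domain face descriptor.

A deliberately simple, pluggable baseline: downsample to a small square,
optionally equalize, take the 2-D DCT and keep the top-left ``K x K``
low-frequency block.  Dropping the DC coefficient makes the embedding
invariant to uniform brightness shifts.  This is a stand-in for an
external matcher, not a replica of one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft
from PIL import Image

from .errors import ConfigError, DimensionError, FeaturelessImageError

__all__ = ["DescriptorParams", "embed_image", "cosine_similarity"]


@dataclass(frozen=True)
class DescriptorParams:
    target_size: int = 64
    dct_block: int = 8
    exclude_dc: bool = True
    equalize: bool = True

    def __post_init__(self) -> None:
        if self.target_size < 16:
            raise ConfigError("target_size must be >= 16")
        if not 1 <= self.dct_block <= self.target_size:
            raise ConfigError("dct_block must satisfy 1 <= K <= target_size")

    @property
    def dim(self) -> int:
        k2 = self.dct_block**2
        return k2 - 1 if self.exclude_dc else k2


def _to_grayscale_array(img) -> np.ndarray:
    if isinstance(img, Image.Image):
        return np.asarray(img.convert("L"), dtype=np.float64)
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2 or arr.size == 0:
        raise DimensionError("expected a non-empty 2-D (or RGB) image")
    return arr


def _equalize(arr: np.ndarray) -> np.ndarray:
    """Histogram equalization over 256 grey levels."""
    quantized = np.clip(arr, 0, 255).astype(np.uint8)
    hist = np.bincount(quantized.ravel(), minlength=256)
    cdf = np.cumsum(hist).astype(np.float64)
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    denom = cdf[-1] - cdf_min
    if denom == 0:  # constant image
        return arr
    lut = (cdf - cdf_min) / denom * 255.0
    return lut[quantized]


def embed_image(img, params: DescriptorParams = DescriptorParams()) -> np.ndarray:
    """Embed a grayscale image as a unit-norm low-frequency DCT vector.

    Pure function of pixels and params.  Raises
    :class:`FeaturelessImageError` for a constant image when the DC term is
    excluded (there is nothing left to normalise).
    """
    arr = _to_grayscale_array(img)
    if arr.shape != (params.target_size, params.target_size):
        pil = Image.fromarray(np.clip(arr, 0, 255).astype(np.uint8), mode="L")
        pil = pil.resize((params.target_size, params.target_size), Image.BILINEAR)
        arr = np.asarray(pil, dtype=np.float64)
    if params.equalize:
        arr = _equalize(arr)
    coeffs = scipy.fft.dctn(arr, type=2, norm="ortho")
    k = params.dct_block
    block = coeffs[:k, :k].ravel()
    if params.exclude_dc:
        block = block[1:]
    norm = np.linalg.norm(block)
    if norm < 1e-12:
        raise FeaturelessImageError("image carries no non-DC signal")
    return block / norm


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Dot product of two unit-norm vectors; symmetric, in [-1, 1]."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise DimensionError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.clip(np.dot(a, b), -1.0, 1.0))
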