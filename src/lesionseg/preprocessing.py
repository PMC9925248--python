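"""Artifact-removal preprocessing: smoothing, morphological closing, sharpening.

All operations act on float images in [0, 1] with shape (H, W, C) or (H, W),
preserve shape and value range, and are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, disk

__all__ = [
    "PreprocessConfig",
    "gaussian_smooth",
    "morphological_close",
    "sharpen",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    gaussian_sigma: float = 0.0  # 0 disables the optional pre-smoothing
    closing_radius: int = 2
    sharpen_amount: float = 1.0
    sharpen_sigma: float = 1.0

    def __post_init__(self):
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.closing_radius < 1:
            raise ValueError("closing_radius must be >= 1")
        if self.sharpen_amount < 0:
            raise ValueError("sharpen_amount must be >= 0")
        if self.sharpen_sigma <= 0:
            raise ValueError("sharpen_sigma must be > 0")


def _per_channel(image, fn):
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return fn(image)
    out = np.empty_like(image)
    for c in range(image.shape[-1]):
        out[..., c] = fn(image[..., c])
    return out


def gaussian_smooth(image, sigma):
    """Per-channel Gaussian blur; sigma 0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return np.asarray(image, dtype=float).copy()
    out = _per_channel(image, lambda ch: ndimage.gaussian_filter(ch, sigma))
    return np.clip(out, 0.0, 1.0)


def morphological_close(image, radius):
    """Grayscale closing (dilation then erosion) with a disk footprint.

    Fills dark structures narrower than the disk — thin hair strokes in
    particular — and is extensive (output >= input) and idempotent.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    footprint = disk(radius)
    return _per_channel(image, lambda ch: closing(ch, footprint))


def sharpen(image, amount, sigma=1.0):
    """Unsharp masking: image + amount * (image - blur(image)), clipped to [0, 1]."""
    if amount < 0:
        raise ValueError("amount must be >= 0")
    image = np.asarray(image, dtype=float)
    if amount == 0:
        return image.copy()
    blurred = _per_channel(image, lambda ch: ndimage.gaussian_filter(ch, sigma))
    return np.clip(image + amount * (image - blurred), 0.0, 1.0)


def preprocess(image, config: PreprocessConfig | None = None):
    """Full pipeline: optional Gaussian smoothing, then closing, then sharpening."""
    if config is None:
        config = PreprocessConfig()
    out = np.asarray(image, dtype=float)
    if config.gaussian_sigma > 0:
        out = gaussian_smooth(out, config.gaussian_sigma)
    out = morphological_close(out, config.closing_radius)
    out = sharpen(out, config.sharpen_amount, config.sharpen_sigma)
    return np.clip(out, 0.0, 1.0)
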