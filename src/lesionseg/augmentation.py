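"""Deterministic paired image/mask augmentation.

The default registry produces exactly 15 variants per input: rotations by
90/180/270 degrees plus crops of 45, 60 and 90 pixels from each of the four
sides (the crop amounts are in PIXELS; cropped results are resized back to
the input shape).  A left-right flip and a fixed (25, 25) shift are
available behind flags.  Every transform is applied identically to the
image and its mask, with nearest-neighbour resampling for the mask so it
stays binary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

__all__ = [
    "AugmentationSpec",
    "rotate",
    "crop_side",
    "flip_lr",
    "shift",
    "augment_sample",
]

SIDES = ("left", "right", "top", "bottom")


@dataclass(frozen=True)
class AugmentationSpec:
    rotations: tuple = (90, 180, 270)
    crop_amounts: tuple = (45, 60, 90)
    crop_sides: tuple = SIDES
    include_flip: bool = False
    include_shift: bool = False
    shift_offset: tuple = (25, 25)

    def transforms(self):
        """Ordered list of (name, callable(image, mask) -> (image, mask))."""
        ops = []
        for angle in self.rotations:
            ops.append((f"rot{angle}", lambda im, mk, a=angle: rotate(im, mk, a)))
        for side in self.crop_sides:
            for amount in self.crop_amounts:
                ops.append(
                    (
                        f"crop_{side}{amount}",
                        lambda im, mk, s=side, a=amount: crop_side(im, mk, s, a),
                    )
                )
        if self.include_flip:
            ops.append(("flip_lr", flip_lr))
        if self.include_shift:
            off = self.shift_offset
            ops.append(("shift", lambda im, mk: shift(im, mk, off)))
        return ops


def rotate(image, mask, angle):
    """Lossless right-angle rotation of both grids."""
    if angle % 90 != 0:
        raise ValueError(f"angle must be a multiple of 90, got {angle}")
    k = (angle // 90) % 4
    return np.rot90(image, k).copy(), np.rot90(mask, k).copy()


def crop_side(image, mask, side, amount):
    """Remove `amount` pixels from one side, then resize back to the input shape."""
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    H, W = mask.shape[:2]
    if side in ("left", "right") and amount >= W:
        raise ValueError(f"crop amount {amount} >= width {W}")
    if side in ("top", "bottom") and amount >= H:
        raise ValueError(f"crop amount {amount} >= height {H}")
    sl = {
        "left": (slice(None), slice(amount, None)),
        "right": (slice(None), slice(None, W - amount)),
        "top": (slice(amount, None), slice(None)),
        "bottom": (slice(None, H - amount), slice(None)),
    }[side]
    im = image[sl]
    mk = mask[sl]
    if amount == 0:
        return im.copy(), mk.copy()
    im = resize(im, (H, W), order=1, preserve_range=True, anti_aliasing=False)
    mk = resize(
        mk.astype(float), (H, W), order=0, preserve_range=True, anti_aliasing=False
    )
    return im, (mk > 0.5).astype(mask.dtype)


def flip_lr(image, mask):
    """Horizontal mirror of both grids."""
    return image[:, ::-1].copy(), mask[:, ::-1].copy()


def shift(image, mask, offset=(25, 25)):
    """Translate both grids by (rows, cols), zero-filling vacated pixels."""
    dy, dx = offset
    H, W = mask.shape[:2]
    if abs(dy) >= H or abs(dx) >= W:
        raise ValueError(f"offset {offset} too large for shape {(H, W)}")
    im = np.zeros_like(image)
    mk = np.zeros_like(mask)

    def _sl(d, n):
        return (slice(d, None), slice(None, n - d)) if d >= 0 else (
            slice(None, n + d),
            slice(-d, None),
        )
    ry_d, ry_s = _sl(dy, H)
    rx_d, rx_s = _sl(dx, W)
    im[ry_d, rx_d] = image[ry_s, rx_s]
    mk[ry_d, rx_d] = mask[ry_s, rx_s]
    return im, mk


def augment_sample(image, mask, spec: AugmentationSpec | None = None):
    """Apply every transform in the registry; returns a list of (image, mask)."""
    if spec is None:
        spec = AugmentationSpec()
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError("image and mask spatial shapes must match")
    return [fn(image, mask) for _, fn in spec.transforms()]
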