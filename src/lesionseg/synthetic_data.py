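"""Seeded generator of dermoscopy-like scenes with exact ground-truth masks.

Each scene is an irregular dark elliptical blob (the lesion) on a lighter
skin-toned background, with optional dark hair strokes, small bright
bubbles and a linear illumination gradient.  Artifacts corrupt the image
only; the mask is the exact rasterized lesion region.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.morphology import dilation, disk

__all__ = ["SceneSpec", "make_scene", "make_dataset"]


@dataclass(frozen=True)
class SceneSpec:
    size: int = 256
    area_fraction: tuple = (0.05, 0.4)
    border_irregularity: float = 0.15
    lesion_color: tuple = (0.35, 0.22, 0.18)
    skin_color: tuple = (0.82, 0.66, 0.60)
    color_spread: float = 0.05
    hair_count: int = 0
    hair_width: int = 1
    bubble_count: int = 0
    illumination_gradient: float = 0.0
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.area_fraction
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("area_fraction range must lie inside (0, 1)")
        if self.border_irregularity < 0:
            raise ValueError("border_irregularity must be >= 0")
        for c in (*self.lesion_color, *self.skin_color):
            if not 0.0 <= c <= 1.0:
                raise ValueError("colors must lie in [0, 1]")


def _lesion_mask(rng, spec):
    """Rasterize an ellipse with harmonic radial border perturbation."""
    S = spec.size
    frac = rng.uniform(*spec.area_fraction)
    aspect = rng.uniform(0.6, 1.0)
    # semi-axes targeting pi*a*b = frac * S^2
    a = np.sqrt(frac * S * S / (np.pi * aspect))
    b = aspect * a
    if a > 0.47 * S:
        raise ValueError(
            f"area fraction {frac:.3f} infeasible for size {S}: lesion would clip"
        )
    margin = 0.48 * S - a
    cy = S / 2 + rng.uniform(-margin, margin)
    cx = S / 2 + rng.uniform(-margin, margin)
    tilt = rng.uniform(0, np.pi)

    yy, xx = np.mgrid[0:S, 0:S]
    u = (xx - cx) * np.cos(tilt) + (yy - cy) * np.sin(tilt)
    v = -(xx - cx) * np.sin(tilt) + (yy - cy) * np.cos(tilt)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    theta = np.arctan2(v / b, u / a)

    boundary = np.ones_like(rho)
    if spec.border_irregularity > 0:
        n_harm = 8
        amps = rng.normal(0.0, 1.0, n_harm)
        amps *= spec.border_irregularity / (np.abs(amps).sum() + 1e-12)
        phases = rng.uniform(0, 2 * np.pi, n_harm)
        for k in range(1, n_harm + 1):
            boundary += amps[k - 1] * np.sin(k * theta + phases[k - 1])
    return (rho <= boundary), frac


def _draw_hairs(rng, image, spec):
    S = spec.size
    canvas = np.zeros((S, S), dtype=bool)
    t = np.linspace(0.0, 1.0, 4 * S)
    for _ in range(spec.hair_count):
        # quadratic bezier across the frame
        pts = rng.uniform(0, S, size=(3, 2))
        curve = (
            (1 - t)[:, None] ** 2 * pts[0]
            + 2 * (1 - t)[:, None] * t[:, None] * pts[1]
            + t[:, None] ** 2 * pts[2]
        )
        ij = np.round(curve).astype(int)
        keep = (ij[:, 0] >= 0) & (ij[:, 0] < S) & (ij[:, 1] >= 0) & (ij[:, 1] < S)
        canvas[ij[keep, 0], ij[keep, 1]] = True
    if spec.hair_width > 1:
        canvas = dilation(canvas, disk(spec.hair_width // 2))
    image[canvas] *= rng.uniform(0.15, 0.35)
    return image


def _draw_bubbles(rng, image, spec):
    S = spec.size
    for _ in range(spec.bubble_count):
        r = rng.integers(2, max(3, S // 40))
        cy, cx = rng.integers(r, S - r, size=2)
        rr, cc = draw_disk((cy, cx), r, shape=(S, S))
        image[rr, cc] = np.clip(image[rr, cc] + 0.25, 0, 1)
    return image


def make_scene(spec: SceneSpec):
    """Render one (image, mask) pair; image (S, S, 3) in [0,1], mask (S, S) 0/1."""
    rng = np.random.default_rng(spec.seed)
    mask, _ = _lesion_mask(rng, spec)
    S = spec.size

    lesion = np.clip(
        np.array(spec.lesion_color) + rng.normal(0, spec.color_spread, 3), 0, 1
    )
    skin = np.clip(
        np.array(spec.skin_color) + rng.normal(0, spec.color_spread, 3), 0, 1
    )
    image = np.where(mask[..., None], lesion, skin).astype(float)
    if spec.noise_sigma > 0:
        image += rng.normal(0, spec.noise_sigma, image.shape)

    if spec.hair_count > 0:
        image = _draw_hairs(rng, image, spec)
    if spec.bubble_count > 0:
        image = _draw_bubbles(rng, image, spec)
    if spec.illumination_gradient > 0:
        ang = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:S, 0:S]
        proj = (xx * np.cos(ang) + yy * np.sin(ang)) / S
        proj = (proj - proj.min()) / (proj.max() - proj.min() + 1e-12)
        image *= (1.0 + spec.illumination_gradient * (proj - 0.5))[..., None]

    return np.clip(image, 0.0, 1.0), mask.astype(np.uint8)


def make_dataset(n: int, spec: SceneSpec | None = None, seed: int = 0):
    """n scenes with independent per-scene seeds derived from the master seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if spec is None:
        spec = SceneSpec()
    child_seeds = np.random.SeedSequence(seed).generate_state(n)
    return [make_scene(replace(spec, seed=int(s))) for s in child_seeds]
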