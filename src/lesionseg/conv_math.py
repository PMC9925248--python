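"""Reference convolution arithmetic.

Two things live here: closed-form parameter/cost accounting for standard
and depthwise-separable convolutions, and deliberately naive nested-loop
implementations of the convolution variants.  The loops are the ground
truth the vectorized network layers are tested against; they are not meant
to be fast.

All image arguments are rank-3 ``(height, width, channels)`` arrays; the
convention is cross-correlation (no kernel flip), 0-based (row, column)
indexing, "same" zero padding, stride 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConvSpec",
    "ParamCount",
    "standard_conv_params",
    "separable_conv_params",
    "param_ratio",
    "depthwise_conv_ref",
    "pointwise_conv_ref",
    "dilated_conv_ref",
    "effective_extent",
]


class InvalidSpecError(ValueError):
    """A ConvSpec field violates its positivity/extent invariants."""


@dataclass(frozen=True)
class ConvSpec:
    """Geometry of one convolution application.

    kernel_size k (square), in_channels M, out_channels N, spatial extent
    H x W, stride and dilation_rate r.
    """

    kernel_size: int
    in_channels: int
    out_channels: int
    height: int = 1
    width: int = 1
    stride: int = 1
    dilation_rate: int = 1

    def __post_init__(self):
        for name in (
            "kernel_size",
            "in_channels",
            "out_channels",
            "height",
            "width",
            "stride",
            "dilation_rate",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise InvalidSpecError(f"{name} must be a positive integer, got {v!r}")


@dataclass(frozen=True)
class ParamCount:
    parameters: int
    mult_adds: int

    def __post_init__(self):
        if self.parameters < 0 or self.mult_adds < 0:
            raise ValueError("counts must be non-negative")


def effective_extent(kernel_size: int, rate: int) -> int:
    """Spatial footprint of a dilated kernel: k + (k-1)(r-1)."""
    return kernel_size + (kernel_size - 1) * (rate - 1)


def standard_conv_params(spec: ConvSpec) -> ParamCount:
    """Weights and multiply-adds of a standard convolution: k*k*M*N and k*k*M*N*H*W."""
    k, M, N = spec.kernel_size, spec.in_channels, spec.out_channels
    params = k * k * M * N
    return ParamCount(parameters=params, mult_adds=params * spec.height * spec.width)


def separable_conv_params(spec: ConvSpec) -> ParamCount:
    """Weights and multiply-adds of depthwise + pointwise: k*k*M + M*N (x H*W for cost)."""
    k, M, N = spec.kernel_size, spec.in_channels, spec.out_channels
    hw = spec.height * spec.width
    return ParamCount(
        parameters=k * k * M + M * N,
        mult_adds=k * k * M * hw + M * N * hw,
    )


def param_ratio(spec: ConvSpec) -> float:
    """Separable/standard parameter fraction, equal to 1/N + 1/k^2.

    The reciprocal is the parameter-economy factor; for k=3 it approaches 9
    from below as N grows.
    """
    sep = separable_conv_params(spec).parameters
    std = standard_conv_params(spec).parameters
    return sep / std


def _check_image(image):
    image = np.asarray(image, dtype=float)
    if image.ndim != 3:
        raise ValueError(f"expected (H, W, C) image, got shape {image.shape}")
    return image


def depthwise_conv_ref(image, kernels):
    """Nested-loop per-channel correlation; kernels has shape (C, k, k)."""
    image = _check_image(image)
    kernels = np.asarray(kernels, dtype=float)
    H, W, C = image.shape
    if kernels.shape[0] != C:
        raise ValueError(
            f"got {kernels.shape[0]} kernels for {C} channels; counts must match"
        )
    k = kernels.shape[-1]
    p = (k - 1) // 2
    padded = np.pad(image, ((p, p), (p, p), (0, 0)))
    out = np.zeros_like(image)
    for c in range(C):
        for i in range(H):
            for j in range(W):
                acc = 0.0
                for di in range(k):
                    for dj in range(k):
                        acc += padded[i + di, j + dj, c] * kernels[c, di, dj]
                out[i, j, c] = acc
    return out


def pointwise_conv_ref(image, weights):
    """Nested-loop 1x1 convolution; weights has shape (M, N)."""
    image = _check_image(image)
    weights = np.asarray(weights, dtype=float)
    H, W, M = image.shape
    if weights.shape[0] != M:
        raise ValueError(
            f"weights first dimension {weights.shape[0]} != input channels {M}"
        )
    N = weights.shape[1]
    out = np.zeros((H, W, N))
    for i in range(H):
        for j in range(W):
            for n in range(N):
                acc = 0.0
                for m in range(M):
                    acc += image[i, j, m] * weights[m, n]
                out[i, j, n] = acc
    return out


def dilated_conv_ref(image, kernel, rate):
    """Nested-loop dilated correlation on a single-channel-per-plane basis.

    Each channel is correlated with the same (k, k) kernel whose taps are
    spaced `rate` pixels apart; rate 1 reproduces a standard convolution.
    """
    image = _check_image(image)
    kernel = np.asarray(kernel, dtype=float)
    if rate < 1:
        raise ValueError("rate must be >= 1")
    H, W, C = image.shape
    k = kernel.shape[-1]
    ext = effective_extent(k, rate)
    if ext > min(H, W):
        raise ValueError(
            f"effective kernel extent {ext} exceeds input size {min(H, W)}"
        )
    p = (ext - 1) // 2
    padded = np.pad(image, ((p, p), (p, p), (0, 0)))
    out = np.zeros_like(image)
    for c in range(C):
        for i in range(H):
            for j in range(W):
                acc = 0.0
                for di in range(k):
                    for dj in range(k):
                        acc += padded[i + rate * di, j + rate * dj, c] * kernel[di, dj]
                out[i, j, c] = acc
    return out
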