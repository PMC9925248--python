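"""Swish activation, its closed-form derivative, and weight initializers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InitSpec",
    "swish",
    "swish_derivative",
    "sigmoid",
    "he_normal_sample",
    "glorot_uniform_sample",
]


@dataclass(frozen=True)
class InitSpec:
    scheme: str  # "he_normal" or "glorot_uniform"
    fan_in: int
    fan_out: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in ("he_normal", "glorot_uniform"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.fan_in < 1 or self.fan_out < 1:
            raise ValueError("fan_in and fan_out must be positive")


def sigmoid(x):
    x = np.asarray(x, dtype=float)
    return 1.0 / (1.0 + np.exp(-x))


def swish(x):
    """f(x) = x * sigmoid(x); smooth, non-monotonic, unbounded above."""
    x = np.asarray(x, dtype=float)
    return x * sigmoid(x)


def swish_derivative(x):
    """f'(x) = f(x) + sigmoid(x) * (1 - f(x))."""
    x = np.asarray(x, dtype=float)
    f = swish(x)
    return f + sigmoid(x) * (1.0 - f)


def he_normal_sample(spec: InitSpec, shape):
    """Gaussian N(0, sqrt(2 / fan_in)) weights, seeded."""
    if spec.scheme != "he_normal":
        raise ValueError("spec.scheme must be 'he_normal'")
    rng = np.random.default_rng(spec.seed)
    std = np.sqrt(2.0 / spec.fan_in)
    return rng.normal(0.0, std, size=shape)


def glorot_uniform_sample(spec: InitSpec, shape):
    """Uniform on [-limit, limit] with limit = sqrt(6 / (fan_in + fan_out)), seeded."""
    if spec.scheme != "glorot_uniform":
        raise ValueError("spec.scheme must be 'glorot_uniform'")
    rng = np.random.default_rng(spec.seed)
    limit = np.sqrt(6.0 / (spec.fan_in + spec.fan_out))
    return rng.uniform(-limit, limit, size=shape)


def he_normal(rng: np.random.Generator, fan_in: int, shape, dtype=np.float32):
    """In-place-rng variant used by the model builder."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape, dtype=np.float32):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)
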