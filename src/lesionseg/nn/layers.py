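"""Layer objects: parameter containers over the functional ops in tensor.py."""

from __future__ import annotations

import numpy as np

from . import tensor as F
from .tensor import Tensor

__all__ = [
    "BatchNorm2d",
    "Conv2d",
    "ConvTranspose2d",
    "DepthwiseConv2d",
    "Dropout",
    "Module",
]


class Module:
    """Base class; discovers parameters and sub-modules by attribute walk."""

    def parameters(self):
        params = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self):
        mods = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def state_dict(self, prefix=""):
        state = {}
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                state[key] = v.data
            elif isinstance(v, BatchNorm2d):
                state.update(v.state_dict(prefix=key + "."))
                state[key + ".running_mean"] = v.running_mean
                state[key + ".running_var"] = v.running_var
            elif isinstance(v, Module):
                state.update(v.state_dict(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        state.update(item.state_dict(prefix=f"{key}.{i}."))
        return state

    def load_state_dict(self, state, prefix=""):
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                v.data = np.asarray(state[key]).astype(v.data.dtype)
            elif isinstance(v, BatchNorm2d):
                v.load_state_dict(state, prefix=key + ".")
                v.running_mean = np.asarray(state[key + ".running_mean"])
                v.running_var = np.asarray(state[key + ".running_var"])
            elif isinstance(v, Module):
                v.load_state_dict(state, prefix=key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(state, prefix=f"{key}.{i}.")

    def num_parameters(self):
        return int(sum(p.data.size for p in self.parameters()))


class Conv2d(Module):
    """Same-padded stride-1 (optionally dilated) convolution, bias-free."""

    def __init__(self, in_channels, out_channels, kernel_size, dilation=1, weight=None):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        if weight is None:
            weight = np.zeros(
                (out_channels, in_channels, kernel_size, kernel_size), dtype=np.float32
            )
        self.weight = Tensor(weight, requires_grad=True)

    def __call__(self, x, training=False):
        return F.conv2d(x, self.weight, dilation=self.dilation)


class DepthwiseConv2d(Module):
    """One k x k kernel per input channel; channel count preserved."""

    def __init__(self, channels, kernel_size, weight=None):
        self.channels = channels
        self.kernel_size = kernel_size
        if weight is None:
            weight = np.zeros((channels, kernel_size, kernel_size), dtype=np.float32)
        self.weight = Tensor(weight, requires_grad=True)

    def __call__(self, x, training=False):
        return F.depthwise_conv2d(x, self.weight)


class ConvTranspose2d(Module):
    """Learnable upsampling: zero-expand by `stride`, then same-padded conv.

    Output spatial size is exactly stride times the input's.
    """

    def __init__(self, in_channels, out_channels, kernel_size=3, stride=2, weight=None):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        if weight is None:
            weight = np.zeros(
                (out_channels, in_channels, kernel_size, kernel_size), dtype=np.float32
            )
        self.weight = Tensor(weight, requires_grad=True)

    def __call__(self, x, training=False):
        return F.conv2d(F.upsample_zeros(x, self.stride), self.weight)


class BatchNorm2d(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.9):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def __call__(self, x, training=False):
        gamma, beta = self.gamma, self.beta
        if training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mu = self.running_mean.astype(x.data.dtype)
            var = self.running_var.astype(x.data.dtype)
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu[:, None, None]) * istd[:, None, None]
        out = Tensor(
            gamma.data[:, None, None] * xhat + beta.data[:, None, None],
            prev=(x, gamma, beta),
        )

        def _backward(gy):
            gb = gy.sum(axis=(0, 2, 3))
            gg = (gy * xhat).sum(axis=(0, 2, 3))
            if beta.requires_grad:
                beta._accumulate(gb)
            if gamma.requires_grad:
                gamma._accumulate(gg)
            if x.requires_grad:
                scale = (gamma.data * istd)[:, None, None]
                if training:
                    n = gy.shape[0] * gy.shape[2] * gy.shape[3]
                    gx = scale * (
                        gy - gb[:, None, None] / n - xhat * gg[:, None, None] / n
                    )
                else:
                    gx = scale * gy
                x._accumulate(gx)

        out._backward = _backward
        return out


class Dropout(Module):
    """Inverted dropout with a layer-owned RNG for reproducibility."""

    def __init__(self, rate, seed=0):
        self.rate = rate
        self.rng = np.random.default_rng(seed)

    def reseed(self, seed):
        self.rng = np.random.default_rng(seed)

    def __call__(self, x, training=False):
        return F.dropout(x, self.rate, self.rng, training)
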