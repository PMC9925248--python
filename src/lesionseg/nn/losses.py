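"""Segmentation losses on probability maps."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["bce_loss", "dice_loss", "combined_loss"]

_EPS = 1e-7


def bce_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy between probabilities and a 0/1 target."""
    t = np.asarray(target, dtype=pred.data.dtype)
    p = np.clip(pred.data, _EPS, 1.0 - _EPS)
    out = Tensor(
        np.asarray(-np.mean(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))),
        prev=(pred,),
    )

    def _backward(gy):
        if pred.requires_grad:
            pred._accumulate(gy * (p - t) / (p * (1.0 - p) * p.size))

    out._backward = _backward
    return out


def dice_loss(pred: Tensor, target: np.ndarray, smooth: float = 1.0) -> Tensor:
    """1 - soft Dice overlap between probabilities and a 0/1 target."""
    t = np.asarray(target, dtype=pred.data.dtype)
    p = pred.data
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum()) + smooth
    out = Tensor(np.asarray(1.0 - (2.0 * inter + smooth) / denom), prev=(pred,))

    def _backward(gy):
        if pred.requires_grad:
            # d/dp of -(2I+s)/(P+T+s) with I = sum(p*t), P = sum(p)
            g = -(2.0 * t * denom - (2.0 * inter + smooth)) / denom**2
            pred._accumulate(gy * g)

    out._backward = _backward
    return out


def combined_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    a = bce_loss(pred, target)
    b = dice_loss(pred, target)
    out = Tensor(a.data + b.data, prev=(a, b))

    def _backward(gy):
        a._accumulate(gy)
        b._accumulate(gy)

    out._backward = _backward
    return out


LOSSES = {"bce": bce_loss, "dice": dice_loss, "bce+dice": combined_loss}
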