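"""Pixel-overlap evaluation metrics.

Confusion counting plus accuracy, Dice, sensitivity, Jaccard, and the
published specificity formula TP/(TP+FP) — which is algebraically the
precision; it is kept verbatim for fidelity, with the textbook
TN/(TN+FP) available as ``corrected_specificity``.  Batch scores support
three averaging modes: ``none`` (mean of per-image foreground scores),
``micro`` (counts pooled over all images first) and ``macro`` (foreground
and background each scored as the positive class, then averaged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "accuracy",
    "dice",
    "jaccard",
    "sensitivity",
    "specificity",
    "corrected_specificity",
    "compute_report",
    "averaged_scores",
    "per_image_scores",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self):
        return self.tp + self.fp + self.tn + self.fn

    def swapped(self):
        """Counts with background treated as the positive class."""
        return ConfusionCounts(tp=self.tn, fp=self.fn, tn=self.tp, fn=self.fp)

    def __add__(self, other):
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    dice: float
    specificity: float
    sensitivity: float
    jaccard: float
    averaging_mode: str = "none"
    specificity_formula: str = "tp/(tp+fp)"  # as published; see corrected_specificity

    def as_dict(self):
        return {
            "accuracy": self.accuracy,
            "dice": self.dice,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "jaccard": self.jaccard,
            "averaging_mode": self.averaging_mode,
            "specificity_formula": self.specificity_formula,
        }


def confusion_counts(pred, truth) -> ConfusionCounts:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    for name, arr in (("pred", pred), ("truth", truth)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary (0/1)")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def _safe_div(num, den, empty_value):
    return num / den if den > 0 else empty_value


def dice(c: ConfusionCounts, empty_value: float = 1.0) -> float:
    """2*TP / (2*TP + FP + FN); both-empty case defaults to 1."""
    if c.tp + c.fp + c.fn == 0:
        return empty_value
    return 2.0 * c.tp / (2.0 * c.tp + c.fp + c.fn)


def jaccard(c: ConfusionCounts, empty_value: float = 1.0) -> float:
    """TP / (TP + FP + FN); both-empty case defaults to 1."""
    if c.tp + c.fp + c.fn == 0:
        return empty_value
    return c.tp / (c.tp + c.fp + c.fn)


def accuracy(c: ConfusionCounts) -> float:
    return _safe_div(c.tp + c.tn, c.total, 0.0)


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN)."""
    return _safe_div(c.tp, c.tp + c.fn, 0.0)


def specificity(c: ConfusionCounts) -> float:
    """TP / (TP + FP), exactly as published (this is the precision formula)."""
    return _safe_div(c.tp, c.tp + c.fp, 0.0)


def corrected_specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP), the textbook definition."""
    return _safe_div(c.tn, c.tn + c.fp, 0.0)


def compute_report(c: ConfusionCounts, mode: str = "none") -> MetricReport:
    return MetricReport(
        accuracy=accuracy(c),
        dice=dice(c),
        specificity=specificity(c),
        sensitivity=sensitivity(c),
        jaccard=jaccard(c),
        averaging_mode=mode,
    )


def per_image_scores(preds, truths):
    """Per-image foreground MetricReports in input order."""
    return [compute_report(confusion_counts(p, t)) for p, t in zip(preds, truths)]


def _mean_report(reports, mode):
    fields = ("accuracy", "dice", "specificity", "sensitivity", "jaccard")
    means = {f: float(np.mean([getattr(r, f) for r in reports])) for f in fields}
    return MetricReport(averaging_mode=mode, **means)


def averaged_scores(preds, truths, mode: str = "none") -> MetricReport:
    """Batch metrics under 'none', 'micro' or 'macro' averaging."""
    preds = list(preds)
    truths = list(truths)
    if not preds or len(preds) != len(truths):
        raise ValueError("need equal-length, non-empty prediction/truth lists")
    if mode == "none":
        return _mean_report(per_image_scores(preds, truths), "none")
    counts = [confusion_counts(p, t) for p, t in zip(preds, truths)]
    pooled = counts[0]
    for c in counts[1:]:
        pooled = pooled + c
    if mode == "micro":
        return compute_report(pooled, "micro")
    if mode == "macro":
        fg = compute_report(pooled)
        bg = compute_report(pooled.swapped())
        return _mean_report([fg, bg], "macro")
    raise ValueError(f"unknown averaging mode {mode!r}")
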