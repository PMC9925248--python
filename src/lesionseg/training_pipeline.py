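"""Seeded train/predict/evaluate loop.

Defaults follow the published run: Adam, learning rate 0.001, 150 epochs,
binary cross-entropy on the sigmoid output (the loss itself is not stated
in the source method; Dice and BCE+Dice are selectable).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.segmentation import find_boundaries

from . import metrics as M
from . import nn
from .architecture import ModelConfig, SegmentationModel, build_model
from .nn import Adam, Tensor
from .nn.losses import LOSSES

logger = logging.getLogger("lesionseg.train")

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "train",
    "predict",
    "evaluate",
    "contour_overlay",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.001
    epochs: int = 150
    batch_size: int = 8
    loss: str = "bce"
    seed: int = 0
    threshold: float = 0.5
    checkpoint_path: str | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {sorted(LOSSES)}")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class TrainHistory:
    loss: list = field(default_factory=list)
    accuracy: list = field(default_factory=list)
    val_dice: list = field(default_factory=list)

    def to_csv(self, path):
        lines = ["epoch,loss,accuracy,val_dice"]
        for i, (l, a) in enumerate(zip(self.loss, self.accuracy), start=1):
            v = self.val_dice[i - 1] if i <= len(self.val_dice) else ""
            lines.append(f"{i},{l},{a},{v}")
        Path(path).write_text("\n".join(lines) + "\n")


def _to_batches(dataset, batch_size, order):
    images = np.stack([np.asarray(im, dtype=np.float32) for im, _ in dataset])
    masks = np.stack([np.asarray(mk, dtype=np.float32) for _, mk in dataset])
    x = images.transpose(0, 3, 1, 2)
    y = masks[:, None]
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        yield x[idx], y[idx]


def train(model: SegmentationModel, dataset, config: TrainConfig | None = None,
          val_dataset=None):
    """Optimize the model in place; returns (model, TrainHistory)."""
    if config is None:
        config = TrainConfig()
    if not dataset:
        raise ValueError("dataset must be non-empty")
    s = model.config.input_size
    for im, mk in dataset:
        if im.shape[:2] != (s, s) or mk.shape != (s, s):
            raise ValueError(
                f"sample shape {im.shape}/{mk.shape} does not match input_size {s}"
            )

    rng = np.random.default_rng(config.seed)
    model.reseed_dropout(config.seed)
    loss_fn = LOSSES[config.loss]
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = TrainHistory()
    best_loss = np.inf

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(dataset))
        epoch_loss, epoch_acc, n_batches = 0.0, 0.0, 0
        for xb, yb in _to_batches(dataset, config.batch_size, order):
            x = Tensor(xb)
            pred = model.forward(x, training=True)
            loss = loss_fn(pred, yb)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss {loss.data!r} at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            epoch_acc += float(
                ((pred.data > config.threshold) == (yb > 0.5)).mean()
            )
            n_batches += 1
        epoch_loss /= n_batches
        epoch_acc /= n_batches
        history.loss.append(epoch_loss)
        history.accuracy.append(epoch_acc)
        msg = f"epoch={epoch} loss={epoch_loss:.5f} acc={epoch_acc:.4f}"
        if val_dataset:
            report = evaluate(model, val_dataset, threshold=config.threshold)
            history.val_dice.append(report.dice)
            msg += f" val_dice={report.dice:.4f}"
        logger.info(msg)
        if config.checkpoint_path and epoch_loss < best_loss:
            best_loss = epoch_loss
            save_checkpoint(model, config.checkpoint_path)
    return model, history


def predict(model: SegmentationModel, images, threshold: float = 0.5):
    """Binary masks from thresholded probability maps."""
    probs = model.predict_proba(images)
    return (probs > threshold).astype(np.uint8)


def evaluate(model: SegmentationModel, dataset, mode: str = "none",
             threshold: float = 0.5, batch_size: int = 8) -> M.MetricReport:
    """Predict over a mask-paired dataset and score with the requested averaging."""
    if not dataset:
        raise ValueError("dataset must be non-empty")
    preds, truths = [], []
    for start in range(0, len(dataset), batch_size):
        chunk = dataset[start : start + batch_size]
        imgs = np.stack([np.asarray(im, dtype=np.float32) for im, _ in chunk])
        preds.extend(predict(model, imgs, threshold=threshold))
        truths.extend(np.asarray(mk, dtype=np.uint8) for _, mk in chunk)
    return M.averaged_scores(preds, truths, mode=mode)


def contour_overlay(image, mask, color=(1.0, 0.0, 0.0)):
    """Draw the mask boundary onto an RGB image (qualitative panels)."""
    image = np.asarray(image, dtype=float)
    out = image.copy()
    if not np.any(mask):
        return out
    # pad so a mask touching the frame still gets a border along the edge
    padded = np.pad(np.asarray(mask, dtype=bool), 1)
    boundary = find_boundaries(padded, mode="inner")[1:-1, 1:-1]
    out[boundary] = color
    return out


def save_checkpoint(model: SegmentationModel, path):
    """Weights as .npz next to a .json carrying the architecture config."""
    path = Path(path).with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    cfg = asdict(model.config)
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))


def load_checkpoint(path) -> SegmentationModel:
    path = Path(path).with_suffix(".npz")
    cfg = json.loads(path.with_suffix(".json").read_text())
    for key in ("filter_ladder", "dilation_rates"):
        cfg[key] = tuple(cfg[key])
    model = build_model(ModelConfig(**cfg))
    with np.load(path) as data:
        model.load_state_dict(dict(data))
    return model
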