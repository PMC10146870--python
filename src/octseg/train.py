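"""Training loop and cross-validation driver.

Optimization uses Adam (exponential moving averages of gradients and squared
gradients with bias correction) at the stock configuration lr=0.001,
beta1=0.9, beta2=0.999, eps=1e-8, batches drawn randomly under a seed, and a
fixed epoch budget; the deployed checkpoint is the epoch with the highest
pooled pixel accuracy on the validation fold (earliest epoch wins ties).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .losses import LossConfig, compute_class_weights, loss_from_logits
from .metrics import MetricReport, evaluate_pair
from .model import ModelConfig, SegmentationModel, build_model
from .pipeline import FoldSplit, kfold_split

__all__ = [
    "TrainConfig", "TrainHistory", "train", "predict", "cross_validate",
    "CrossValResult", "save_checkpoint", "load_checkpoint",
]

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 8
    epochs: int = 50
    seed: int = 0
    grad_clip: float | None = None
    loss: LossConfig = field(default_factory=LossConfig)
    model: ModelConfig = field(default_factory=ModelConfig)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_ce: list[float] = field(default_factory=list)
    train_dice: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def __len__(self):
        return len(self.train_loss)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(len(self)),
            "train_loss": self.train_loss,
            "train_ce": self.train_ce,
            "train_dice": self.train_dice,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
        })


def _as_batches(pairs, idx_order, batch_size, augment_fn=None, rng=None):
    for start in range(0, len(idx_order), batch_size):
        chunk = idx_order[start:start + batch_size]
        images = [pairs[i][0] for i in chunk]
        if augment_fn is not None:
            images = [augment_fn(img, rng) for img in images]
        imgs = np.stack(images)[:, None].astype(np.float32)
        labels = np.stack([pairs[i][1] for i in chunk]).astype(np.int64)
        yield imgs, labels


def _evaluate_loss_acc(model: SegmentationModel, pairs, cfg: TrainConfig
                       ) -> tuple[float, float]:
    """Mean loss and pooled pixel accuracy over a set, in eval mode."""
    model.eval()
    losses = []
    correct = 0
    total = 0
    with nn.no_grad():
        for imgs, labels in _as_batches(pairs, np.arange(len(pairs)),
                                        cfg.batch_size):
            logits = model.forward(imgs)
            loss, _, _ = loss_from_logits(logits, labels, cfg.loss)
            losses.append(loss.item())
            pred = np.argmax(logits.data, axis=1)
            correct += int((pred == labels).sum())
            total += labels.size
    model.train()
    return float(np.mean(losses)), correct / total


def train(model: SegmentationModel, train_pairs, val_pairs, cfg: TrainConfig,
          augment_fn=None) -> tuple[dict, TrainHistory]:
    """Optimize ``model`` in place; returns (best checkpoint, history).

    ``train_pairs`` / ``val_pairs`` are sequences of (image, labels) arrays.
    ``augment_fn(image, rng) -> image`` is an optional photometric
    augmentation applied to each training image as batches are drawn (labels
    are never touched); validation images are left untouched.  The checkpoint
    is the parameter state at the epoch with the highest validation pixel
    accuracy.  Raises on an empty dataset and aborts with diagnostics if the
    loss becomes non-finite.
    """
    if len(train_pairs) == 0 or len(val_pairs) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate, beta1=cfg.beta1,
                  beta2=cfg.beta2, eps=cfg.epsilon, grad_clip=cfg.grad_clip)
    history = TrainHistory()
    best_acc = -1.0
    best_state: dict | None = None
    model.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_pairs))
        ep_losses, ep_ce, ep_dice = [], [], []
        for b, (imgs, labels) in enumerate(_as_batches(train_pairs, order,
                                                       cfg.batch_size,
                                                       augment_fn, rng)):
            logits = model.forward(imgs)
            loss, ce, dc = loss_from_logits(logits, labels, cfg.loss)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {b}: "
                    f"overall={loss.item()}, ce={ce}, dice={dc}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_losses.append(loss.item())
            ep_ce.append(ce)
            ep_dice.append(dc)
        val_loss, val_acc = _evaluate_loss_acc(model, val_pairs, cfg)
        history.train_loss.append(float(np.mean(ep_losses)))
        history.train_ce.append(float(np.mean(ep_ce)))
        history.train_dice.append(float(np.mean(ep_dice)))
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.state_dict()
            history.best_epoch = epoch
        log.info("epoch %d: train_loss=%.4f val_loss=%.4f val_acc=%.4f",
                 epoch, history.train_loss[-1], val_loss, val_acc)
    model.load_state_dict(best_state)
    return best_state, history


def predict(model: SegmentationModel, images) -> list[np.ndarray]:
    """Argmax label maps for a sequence of (H, W) images."""
    return [model.predict(img) for img in images]


@dataclass
class CrossValResult:
    fold_reports: list[MetricReport]
    mean: dict[str, float]
    std: dict[str, float]
    histories: list[TrainHistory]

    def summary(self) -> pd.DataFrame:
        rows = [{"metric": k, "mean": self.mean[k], "std": self.std[k]}
                for k in self.mean]
        return pd.DataFrame(rows)


def cross_validate(pairs, cfg: TrainConfig, k: int = 5,
                   pixel_pitch: float = 1.0) -> CrossValResult:
    """k-fold cross-validation: train per fold, evaluate on the held-out
    fold, report mean and sample standard deviation per metric."""
    splits = kfold_split(len(pairs), FoldSplit(k=k, seed=cfg.seed))
    n_classes = cfg.model.n_classes
    reports: list[MetricReport] = []
    histories: list[TrainHistory] = []
    for fold, (train_idx, val_idx) in enumerate(splits):
        tr = [pairs[i] for i in train_idx]
        va = [pairs[i] for i in val_idx]
        fold_cfg_loss = LossConfig(
            alpha=cfg.loss.alpha, beta=cfg.loss.beta,
            class_weights=compute_class_weights([p[1] for p in tr], n_classes),
            epsilon=cfg.loss.epsilon)
        fold_cfg = TrainConfig(
            learning_rate=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2,
            epsilon=cfg.epsilon, batch_size=cfg.batch_size, epochs=cfg.epochs,
            seed=cfg.seed + fold, grad_clip=cfg.grad_clip,
            loss=fold_cfg_loss, model=cfg.model)
        model = build_model(cfg.model, seed=cfg.seed + fold)
        _, history = train(model, tr, va, fold_cfg)
        histories.append(history)
        # pooled evaluation over the fold's validation images
        preds = np.concatenate([model.predict(img) for img, _ in va], axis=0)
        truths = np.concatenate([lab for _, lab in va], axis=0)
        reports.append(evaluate_pair(preds, truths, n_classes, pixel_pitch))
    def collect(fn):
        return np.array([fn(r) for r in reports], dtype=float)
    scalars = {
        "accuracy_pct": collect(lambda r: r.accuracy),
        "mean_dsc_pct": collect(lambda r: np.nanmean(r.dsc)),
        "mean_foreground_dsc_pct": collect(lambda r: np.nanmean(r.dsc[1:])),
        "mean_hausdorff": collect(lambda r: r.mean_hausdorff),
    }
    mean = {k: float(np.mean(v)) for k, v in scalars.items()}
    std = {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
           for k, v in scalars.items()}
    return CrossValResult(fold_reports=reports, mean=mean, std=std,
                          histories=histories)


# ---- checkpoints -------------------------------------------------------------

def save_checkpoint(path, model: SegmentationModel, extra: dict | None = None
                    ) -> None:
    """Write parameters + architecture config + build seed to an .npz file."""
    meta = {"config": model.config.to_dict(), "seed": model.seed,
            "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model.state_dict())


def load_checkpoint(path) -> SegmentationModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = build_model(ModelConfig.from_dict(meta["config"]),
                        seed=int(meta["seed"]))
    model.load_state_dict(state)
    return model
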