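"""Compound segmentation objective: frequency-weighted cross-entropy plus
soft Dice, combined as ``alpha * L_ce + beta * L_dice``.

The cross-entropy term is weighted per class by inverse training-set
frequency (mean-normalized to 1) so that thin, low-frequency structures such
as the foveal layers or fluid pockets are not drowned out by background.
The Dice term is computed on soft probabilities (differentiable) and averaged
over the classes present in the ground truth.

Both losses are implemented once, on autodiff tensors, so the same code path
serves training (gradients) and evaluation (floats).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "LossConfig", "compute_class_weights", "one_hot",
    "weighted_cross_entropy", "dice_loss", "overall_loss",
    "weighted_cross_entropy_t", "dice_loss_t", "overall_loss_t",
    "loss_from_logits",
]

log = logging.getLogger(__name__)

EPS = 1e-7


@dataclass
class LossConfig:
    alpha: float = 0.5
    beta: float = 0.5
    class_weights: np.ndarray | None = None   # length K, mean 1; None = uniform
    epsilon: float = EPS

    def validate(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError(
                f"loss weights must be non-negative (alpha={self.alpha}, "
                f"beta={self.beta})")


def compute_class_weights(label_maps, n_classes: int) -> np.ndarray:
    """Inverse-frequency class weights from training label maps.

    ``w_l`` is proportional to 1/frequency(l) and rescaled so the mean weight
    is 1.  A class absent from the training set gets the maximum weight among
    the present classes (never a division by zero), with a logged warning.
    """
    counts = np.zeros(n_classes, dtype=np.int64)
    for lm in label_maps:
        counts += np.bincount(np.asarray(lm).ravel(), minlength=n_classes)
    total = counts.sum()
    if total == 0:
        raise ValueError("no labeled pixels supplied")
    freq = counts / total
    present = counts > 0
    raw = np.zeros(n_classes)
    raw[present] = 1.0 / freq[present]
    if not present.all():
        missing = np.nonzero(~present)[0]
        log.warning("classes %s absent from the training set; their weights "
                    "are clamped to the maximum present-class weight",
                    missing.tolist())
        raw[~present] = raw[present].max()
    return raw / raw.mean()


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(H, W) int labels -> (K, H, W) one-hot float raster."""
    labels = np.asarray(labels)
    k = np.arange(n_classes).reshape((n_classes,) + (1,) * labels.ndim)
    return (labels[None] == k).astype(np.float64)


# ---- tensor (differentiable) forms ------------------------------------------

def weighted_cross_entropy_t(p: Tensor, g: np.ndarray,
                             weights: np.ndarray | None = None,
                             epsilon: float = EPS) -> Tensor:
    """-(1/|pixels|) sum_x sum_l w_l g_l(x) log p_l(x); p is (K, ...) probs."""
    k = p.shape[0]
    n_pix = int(np.prod(p.shape[1:]))
    if weights is None:
        weights = np.ones(k)
    w = np.asarray(weights, dtype=np.float64).reshape((k,) + (1,) * (p.ndim - 1))
    logp = nn.log(nn.clip(p, epsilon, 1.0))
    return nn.tsum(logp * (w * np.asarray(g))) * (-1.0 / n_pix)


def dice_loss_t(p: Tensor, g: np.ndarray, epsilon: float = EPS) -> Tensor:
    """Soft Dice loss, mean over classes present in the ground truth."""
    g = np.asarray(g, dtype=np.float64)
    k = p.shape[0]
    axes = tuple(range(1, p.ndim))
    present = g.sum(axis=axes) > 0
    if not present.any():
        raise ValueError("ground truth contains no class support")
    inter = nn.tsum(p * g, axis=axes)
    denom = nn.tsum(p * p, axis=axes) + np.asarray(g * g).sum(axis=axes)
    dice = inter * 2.0 * nn.power(denom + epsilon, -1.0)
    sel = np.nonzero(present)[0]
    per_class = dice[sel]
    return 1.0 - nn.tmean(per_class) if len(sel) else Tensor(np.float64(0))


def overall_loss_t(p: Tensor, g: np.ndarray, cfg: LossConfig) -> Tensor:
    cfg.validate()
    return (cfg.alpha * weighted_cross_entropy_t(p, g, cfg.class_weights,
                                                 cfg.epsilon)
            + cfg.beta * dice_loss_t(p, g, cfg.epsilon))


# ---- plain float wrappers ----------------------------------------------------

def weighted_cross_entropy(p: np.ndarray, g: np.ndarray,
                           weights: np.ndarray | None = None,
                           epsilon: float = EPS) -> float:
    """Weighted cross-entropy on (K, H, W) probability / one-hot rasters."""
    _check_prob(p, g)
    return weighted_cross_entropy_t(Tensor(np.asarray(p, float)), g,
                                    weights, epsilon).item()


def dice_loss(p: np.ndarray, g: np.ndarray, epsilon: float = EPS) -> float:
    _check_prob(p, g)
    return dice_loss_t(Tensor(np.asarray(p, float)), g, epsilon).item()


def overall_loss(p: np.ndarray, g: np.ndarray, cfg: LossConfig) -> float:
    _check_prob(p, g)
    return overall_loss_t(Tensor(np.asarray(p, float)), g, cfg).item()


def _check_prob(p: np.ndarray, g: np.ndarray) -> None:
    p, g = np.asarray(p), np.asarray(g)
    if p.shape != g.shape:
        raise ValueError(f"prediction shape {p.shape} != truth shape {g.shape}")
    if p.min() < -1e-9 or p.max() > 1 + 1e-9:
        raise ValueError("predictions must be probabilities in [0, 1]")


# ---- training path -----------------------------------------------------------

def loss_from_logits(logits: Tensor, labels: np.ndarray, cfg: LossConfig
                     ) -> tuple[Tensor, float, float]:
    """Overall loss from (N, K, H, W) logits and (N, H, W) integer labels.

    Cross-entropy is evaluated through log-softmax directly (numerically
    stable); Dice through the softmax probabilities.  Returns the scalar loss
    tensor plus the two float components for logging.
    """
    cfg.validate()
    n, k = logits.shape[0], logits.shape[1]
    dt = logits.dtype
    g = np.stack([one_hot(labels[i], k) for i in range(n)]).astype(dt)
    n_pix = int(np.prod(logits.shape)) // k
    weights = cfg.class_weights if cfg.class_weights is not None else np.ones(k)
    w = np.asarray(weights, dtype=dt).reshape(1, k, 1, 1)

    logp = nn.log_softmax(logits, axis=1)
    ce = nn.tsum(logp * (w * g)) * (-1.0 / n_pix)

    p = nn.softmax(logits, axis=1)
    axes = (0, 2, 3)
    present = g.sum(axis=axes) > 0
    inter = nn.tsum(p * g, axis=axes)
    denom = nn.tsum(p * p, axis=axes) + (g * g).sum(axis=axes)
    dice_per_class = inter * 2.0 * nn.power(denom + cfg.epsilon, -1.0)
    sel = np.nonzero(present)[0]
    dice = 1.0 - nn.tmean(dice_per_class[sel])

    total = cfg.alpha * ce + cfg.beta * dice
    return total, ce.item(), dice.item()
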