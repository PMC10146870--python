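"""Reproducible desk-scale benchmark experiments on synthetic phantoms.

Two standard experiments exercise the full stack end to end at sizes chosen
for a single CPU:

* :func:`overfit_capacity` — can a deliberately tiny network memorize two
  64x64 phantom crops to near-perfect pixel accuracy within a fixed number of
  optimizer steps?  A pure capacity/optimization sanity check.
* :func:`generalization_benchmark` — train a compact model on 32 speckled,
  vessel-shadowed 128x128 phantoms and evaluate Dice overlap and boundary
  Hausdorff distance on 8 held-out phantoms, averaged over independent seeds.

Both are deterministic given their seed and are shared by the test suite and
the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .losses import LossConfig, compute_class_weights, loss_from_logits
from .metrics import evaluate_pair
from .model import ModelConfig, build_model
from .phantom import PhantomSpec, generate_dataset
from .train import TrainConfig, train

__all__ = ["OverfitResult", "GeneralizationResult",
           "overfit_capacity", "generalization_benchmark",
           "TINY_MODEL", "BENCH_MODEL"]

# deliberately tiny network for the memorization check
TINY_MODEL = dict(encoder_channels=(8, 16, 32), vit_dim=32, vit_heads=4,
                  vit_blocks=2, vit_mlp_dim=32, patch_size=2, n_classes=9)

# compact benchmark network: one more halving gives the receptive field
# needed to suppress isolated misclassifications that dominate the
# (maximally outlier-sensitive) Hausdorff distance
BENCH_MODEL = dict(encoder_channels=(16, 32, 64, 64), vit_dim=64,
                   vit_heads=4, vit_blocks=2, vit_mlp_dim=64, patch_size=2,
                   n_classes=9)

# step size for the capacity check: memorizing two fixed crops in 200 steps
# warrants a larger step than the full training default
OVERFIT_LR = 5e-3
BENCH_LR = 2e-3


def _overfit_spec() -> PhantomSpec:
    # 64x64 crops: halved layer thicknesses, mild speckle, one vessel
    return PhantomSpec(height=64, width=64,
                       layer_mean_thickness=[4, 6, 4, 3.5, 7, 3, 3, 4],
                       foveal_dip_depth=5, foveal_dip_width=10,
                       boundary_smoothness=1.5, speckle_level=0.2,
                       vessel_count=1, vessel_width=4)


@dataclass
class OverfitResult:
    final_accuracy: float          # training pixel accuracy after the run
    first_iteration_at_99: int | None
    loss_first: float
    loss_last: float
    n_iterations: int


def overfit_capacity(seed: int = 0, n_iterations: int = 200) -> OverfitResult:
    """Memorization check: tiny model, two 64x64 phantom crops, full-batch
    Adam steps; reports training pixel accuracy and the loss trajectory."""
    pairs, _ = generate_dataset(_overfit_spec(), 2, seed=seed)
    imgs = np.stack([p.image for p in pairs])[:, None].astype(np.float32)
    labels = np.stack([p.labels for p in pairs]).astype(np.int64)
    model = build_model(ModelConfig(**TINY_MODEL), seed=seed)
    lcfg = LossConfig(class_weights=compute_class_weights(labels, 9))
    opt = nn.Adam(model.parameters(), lr=OVERFIT_LR)
    loss_first = loss_last = float("nan")
    first_hit = None
    acc = 0.0
    for it in range(n_iterations):
        logits = model.forward(imgs)
        loss, _, _ = loss_from_logits(logits, labels, lcfg)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if it == 0:
            loss_first = loss.item()
        loss_last = loss.item()
        acc = float((np.argmax(logits.data, axis=1) == labels).mean())
        if acc >= 0.99 and first_hit is None:
            first_hit = it + 1
    return OverfitResult(final_accuracy=acc, first_iteration_at_99=first_hit,
                         loss_first=loss_first, loss_last=loss_last,
                         n_iterations=n_iterations)


@dataclass
class GeneralizationResult:
    per_seed_dsc: list[float] = field(default_factory=list)
    per_seed_hd: list[float] = field(default_factory=list)
    per_seed_accuracy: list[float] = field(default_factory=list)

    @property
    def mean_foreground_dsc(self) -> float:
        return float(np.mean(self.per_seed_dsc))

    @property
    def mean_hausdorff(self) -> float:
        return float(np.mean(self.per_seed_hd))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_seed_accuracy))


def _evaluate_heldout(model, held_out) -> tuple[float, float, float]:
    dscs, hds, accs = [], [], []
    for img, lab in held_out:
        rep = evaluate_pair(model.predict(img), lab, 9)
        fg = [l for l in range(1, 9) if (lab == l).any()]
        dscs.append(float(np.nanmean(rep.dsc[fg])) / 100.0)
        hds.append(rep.mean_hausdorff)
        accs.append(rep.accuracy)
    return float(np.mean(dscs)), float(np.mean(hds)), float(np.mean(accs))


def generalization_benchmark(base_seed: int = 0, n_seeds: int = 3,
                             n_train: int = 32, n_heldout: int = 8,
                             epochs: int = 10) -> GeneralizationResult:
    """Train on speckled, vessel-shadowed 128x128 phantoms (generator
    defaults) and evaluate overlap and boundary agreement on held-out
    phantoms; repeated over ``n_seeds`` independent seeds."""
    result = GeneralizationResult()
    for s in range(n_seeds):
        seed = base_seed + s
        pairs, _ = generate_dataset(PhantomSpec(seed=seed),
                                    n_train + n_heldout,
                                    seed=1000 + 100 * seed)
        tr = [(p.image, p.labels) for p in pairs[:n_train]]
        te = [(p.image, p.labels) for p in pairs[n_train:]]
        mcfg = ModelConfig(**BENCH_MODEL)
        tcfg = TrainConfig(
            epochs=epochs, batch_size=1, learning_rate=BENCH_LR, seed=seed,
            loss=LossConfig(
                class_weights=compute_class_weights([l for _, l in tr], 9)),
            model=mcfg)
        model = build_model(mcfg, seed=seed)
        train(model, tr, te, tcfg)
        dsc, hd, acc = _evaluate_heldout(model, te)
        result.per_seed_dsc.append(dsc)
        result.per_seed_hd.append(hd)
        result.per_seed_accuracy.append(acc)
    return result
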