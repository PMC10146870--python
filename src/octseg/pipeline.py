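"""Dataset preparation: sliding-window slicing with coverage guarantees,
photometric augmentation, random erasing, and k-fold cross-validation splits.

Slicing follows two principles: every crop origin is distinct, and the union
of crops covers every labeled (non-background) pixel of the source image —
random origins are drawn first and deterministic grid-anchored crops are
added greedily until coverage holds.  Augmentations are photometric only and
never touch the label maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SliceSpec", "AugmentSpec", "FoldSplit",
    "slice_windows", "photometric_augment", "random_erase", "kfold_split",
]


class PipelineConfigError(ValueError):
    pass


@dataclass
class SliceSpec:
    window: int = 256
    n_slices: int = 4
    seed: int = 0


@dataclass
class AugmentSpec:
    contrast_range: tuple[float, float] = (0.8, 1.2)
    brightness_range: tuple[float, float] = (-0.1, 0.1)
    erase_probability: float = 0.5
    erase_area_range: tuple[float, float] = (0.01, 0.05)
    erase_aspect_range: tuple[float, float] = (0.3, 3.0)
    seed: int = 0

    def validate(self) -> None:
        for name in ("contrast_range", "brightness_range", "erase_area_range",
                     "erase_aspect_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise PipelineConfigError(f"{name} is not well-ordered: "
                                          f"({lo}, {hi})")
        if not 0.0 <= self.erase_probability <= 1.0:
            raise PipelineConfigError("erase_probability must lie in [0, 1]")


@dataclass
class FoldSplit:
    k: int = 5
    seed: int = 0


def _grid_origins(extent: int, window: int) -> list[int]:
    """Origins tiling [0, extent] with the last crop flush to the edge."""
    if extent == window:
        return [0]
    n = int(np.ceil(extent / window))
    return sorted({min(i * window, extent - window) for i in range(n + 1)})


def slice_windows(image: np.ndarray, labels: np.ndarray, spec: SliceSpec
                  ) -> tuple[list[tuple[np.ndarray, np.ndarray]], list[tuple[int, int]]]:
    """Square crops of ``spec.window`` covering all labeled tissue.

    Returns (crops, origins): crops are (image, labels) views copied out of
    the source, origins their (row, col) anchors, all distinct.
    """
    h, w = image.shape
    win = spec.window
    if win > h or win > w:
        raise PipelineConfigError(
            f"window {win} exceeds source extent {h}x{w}")
    rng = np.random.default_rng(spec.seed)
    max_r, max_c = h - win, w - win
    origins: list[tuple[int, int]] = []
    seen = set()
    n_possible = (max_r + 1) * (max_c + 1)
    tries = 0
    while len(origins) < min(spec.n_slices, n_possible) and tries < 1000:
        o = (int(rng.integers(0, max_r + 1)), int(rng.integers(0, max_c + 1)))
        tries += 1
        if o not in seen:
            seen.add(o)
            origins.append(o)

    # coverage enforcement: add grid-anchored crops over uncovered tissue
    covered = np.zeros((h, w), dtype=bool)
    for r, c in origins:
        covered[r:r + win, c:c + win] = True
    tissue = labels > 0
    if (tissue & ~covered).any():
        for r in _grid_origins(h, win):
            for c in _grid_origins(w, win):
                if (r, c) in seen:
                    continue
                if (tissue & ~covered)[r:r + win, c:c + win].any():
                    seen.add((r, c))
                    origins.append((r, c))
                    covered[r:r + win, c:c + win] = True
    crops = [(image[r:r + win, c:c + win].copy(),
              labels[r:r + win, c:c + win].copy()) for r, c in origins]
    return crops, origins


def photometric_augment(crop: np.ndarray, spec: AugmentSpec,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """clip(factor * crop + offset, 0, 1); labels are untouched by design."""
    spec.validate()
    rng = rng or np.random.default_rng(spec.seed)
    factor = rng.uniform(*spec.contrast_range)
    offset = rng.uniform(*spec.brightness_range)
    return np.clip(factor * crop + offset, 0.0, 1.0)


def random_erase(crop: np.ndarray, spec: AugmentSpec,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """With probability ``erase_probability``, fill one axis-aligned
    rectangle (area fraction and aspect drawn from the spec ranges) with the
    crop mean intensity, mimicking a vessel-shadow dropout."""
    spec.validate()
    rng = rng or np.random.default_rng(spec.seed)
    out = crop.copy()
    if rng.random() >= spec.erase_probability:
        return out
    h, w = crop.shape
    area = rng.uniform(*spec.erase_area_range) * h * w
    aspect = rng.uniform(*spec.erase_aspect_range)
    eh = int(np.clip(round(np.sqrt(area * aspect)), 1, h))
    ew = int(np.clip(round(area / eh), 1, w))
    r = int(rng.integers(0, h - eh + 1))
    c = int(rng.integers(0, w - ew + 1))
    out[r:r + eh, c:c + ew] = crop.mean()
    return out


def kfold_split(n_samples: int, split: FoldSplit
                ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Balanced k-fold partition; returns per-iteration (train, val) indices.

    Every sample is validated exactly once across the k iterations and fold
    sizes differ by at most one.
    """
    if n_samples < split.k:
        raise PipelineConfigError(
            f"need at least k={split.k} samples, got {n_samples}")
    rng = np.random.default_rng(split.seed)
    order = rng.permutation(n_samples)
    folds = np.array_split(order, split.k)
    out = []
    for i in range(split.k):
        val = np.sort(folds[i])
        train = np.sort(np.concatenate([folds[j] for j in range(split.k)
                                        if j != i]))
        out.append((train, val))
    return out
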