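"""Evaluation suite for pixel-wise segmentations of layered B-scans.

Per-class one-vs-rest confusion counts; pooled accuracy, per-class precision,
recall and Dice similarity coefficient (DSC = 2TP / (2TP + FP + FN)); and
boundary agreement via the two-way Hausdorff distance between per-class
region-boundary point sets.  A 0/0 score is reported as undefined (NaN plus a
flag) and excluded from means, never silently as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff

__all__ = [
    "ConfusionCounts", "MetricReport", "confusion_counts", "summary_metrics",
    "boundary_points", "hausdorff_distance", "evaluate_pair",
]


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest pixel counts; arrays of length K."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    @property
    def total(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])


@dataclass
class MetricReport:
    """Scores in percent (NaN where undefined) plus per-class Hausdorff
    distances; ``undefined`` flags classes whose precision or recall was 0/0."""

    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    dsc: np.ndarray
    hausdorff: np.ndarray
    mean_hausdorff: float
    class_names: list[str]
    undefined: np.ndarray = field(default=None)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "class": self.class_names,
            "precision_pct": self.precision,
            "recall_pct": self.recall,
            "dsc_pct": self.dsc,
            "hausdorff": self.hausdorff,
        })
        overall = pd.DataFrame({
            "class": ["overall"],
            "precision_pct": [np.nanmean(self.precision)],
            "recall_pct": [np.nanmean(self.recall)],
            "dsc_pct": [np.nanmean(self.dsc)],
            "hausdorff": [self.mean_hausdorff],
        })
        return pd.concat([df, overall], ignore_index=True)

    def to_json_dict(self) -> dict:
        def clean(a):
            return [None if np.isnan(v) else float(v) for v in np.atleast_1d(a)]
        return {
            "accuracy_pct": self.accuracy,
            "precision_pct": clean(self.precision),
            "recall_pct": clean(self.recall),
            "dsc_pct": clean(self.dsc),
            "hausdorff": clean(self.hausdorff),
            "mean_hausdorff": (None if np.isnan(self.mean_hausdorff)
                               else float(self.mean_hausdorff)),
            "class_names": self.class_names,
        }


def confusion_counts(pred: np.ndarray, truth: np.ndarray,
                     n_classes: int) -> ConfusionCounts:
    """One-vs-rest TP/FP/FN/TN per class from aligned integer label maps."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"prediction shape {pred.shape} != truth {truth.shape}")
    if pred.max() >= n_classes or truth.max() >= n_classes:
        raise ValueError("label values must be < n_classes")
    joint = np.bincount(truth.ravel().astype(np.int64) * n_classes
                        + pred.ravel().astype(np.int64),
                        minlength=n_classes * n_classes
                        ).reshape(n_classes, n_classes)
    tp = np.diag(joint).astype(np.int64)
    fn = joint.sum(axis=1) - tp   # truth = l, pred != l
    fp = joint.sum(axis=0) - tp   # pred = l, truth != l
    total = joint.sum()
    tn = total - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def summary_metrics(counts: ConfusionCounts
                    ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(accuracy, precision[], recall[], dsc[], undefined[]) as fractions.

    Accuracy is pooled over all pixels.  Per-class scores with a 0/0
    denominator are NaN with the corresponding ``undefined`` flag set.
    """
    tp, fp, fn = counts.tp.astype(float), counts.fp.astype(float), counts.fn.astype(float)
    accuracy = tp.sum() / counts.total
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        recall = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        dsc = np.where(2 * tp + fp + fn > 0, 2 * tp / (2 * tp + fp + fn), np.nan)
    undefined = np.isnan(precision) | np.isnan(recall)
    return accuracy, precision, recall, dsc, undefined


def boundary_points(labels: np.ndarray, class_id: int) -> np.ndarray:
    """Region-boundary pixels of a class: members with a 4-neighbor of a
    different class, or on the raster edge.  Returns an (M, 2) array of
    (row, col) coordinates."""
    labels = np.asarray(labels)
    mask = labels == class_id
    if not mask.any():
        raise ValueError(f"class {class_id} absent from the label map")
    interior = np.zeros_like(mask)
    interior[1:-1, 1:-1] = (mask[1:-1, 1:-1]
                            & mask[:-2, 1:-1] & mask[2:, 1:-1]
                            & mask[1:-1, :-2] & mask[1:-1, 2:])
    boundary = mask & ~interior
    return np.argwhere(boundary)


def hausdorff_distance(a: np.ndarray, b: np.ndarray,
                       pixel_pitch: float = 1.0
                       ) -> tuple[float, float, float]:
    """One-way distances h(A,B), h(B,A) and the two-way H = max of the two.

    Euclidean point-to-point distances, optionally scaled by ``pixel_pitch``
    (physical distance per pixel).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("Hausdorff distance is undefined for an empty set")
    h_ab = directed_hausdorff(a, b)[0] * pixel_pitch
    h_ba = directed_hausdorff(b, a)[0] * pixel_pitch
    return h_ab, h_ba, max(h_ab, h_ba)


DEFAULT_CLASS_NAMES_9 = ["BG", "NFL", "GCL+IPL", "INL", "OPL", "ONL+IS",
                         "OS", "OPR", "RPE"]
DEFAULT_CLASS_NAMES_10 = DEFAULT_CLASS_NAMES_9 + ["Fluid"]


def default_class_names(n_classes: int) -> list[str]:
    if n_classes == 9:
        return list(DEFAULT_CLASS_NAMES_9)
    if n_classes == 10:
        return list(DEFAULT_CLASS_NAMES_10)
    return [f"class{i}" for i in range(n_classes)]


def evaluate_pair(pred: np.ndarray, truth: np.ndarray, n_classes: int,
                  pixel_pitch: float = 1.0,
                  class_names: list[str] | None = None) -> MetricReport:
    """Full metric report for one prediction/truth pair.

    The mean Hausdorff distance is averaged over non-background classes
    present in the truth; a class missing from the prediction contributes NaN
    and is excluded from the mean.
    """
    counts = confusion_counts(pred, truth, n_classes)
    accuracy, precision, recall, dsc, undefined = summary_metrics(counts)
    hd = np.full(n_classes, np.nan)
    for l in range(1, n_classes):
        if not (truth == l).any():
            continue
        if not (pred == l).any():
            continue
        a = boundary_points(pred, l)
        b = boundary_points(truth, l)
        hd[l] = hausdorff_distance(a, b, pixel_pitch)[2]
    present_fg = [l for l in range(1, n_classes) if (truth == l).any()]
    vals = hd[present_fg]
    mean_hd = float(np.nanmean(vals)) if len(vals) and not np.isnan(vals).all() \
        else float("nan")
    names = class_names or default_class_names(n_classes)
    return MetricReport(
        accuracy=100.0 * accuracy,
        precision=100.0 * precision,
        recall=100.0 * recall,
        dsc=100.0 * dsc,
        hausdorff=hd,
        mean_hausdorff=mean_hd,
        class_names=names,
        undefined=undefined,
    )
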