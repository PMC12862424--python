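"""Segmentation overlap metrics: Dice score and the differentiable Soft IoU loss.

Dice for a class pair of binary masks is ``2|A∩B| / (|A|+|B|)``; a multi-class
report carries per-class values plus two reductions, the macro mean over
classes and the pooled (micro) value computed from summed intersections and
sizes.  The Soft IoU loss for a probabilistic foreground map ``ŷ`` against a
binary truth ``y`` is::

    L = 1 - Σ y·ŷ / (Σ (y + ŷ - y·ŷ) + η)

with smoothing constant ``η >= 0`` (default 1).  For binary ``ŷ`` and η = 0
this reduces to 1 − IoU, and Dice = 2·IoU/(1+IoU).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import SchemaError
from .label_volumes import LabelVolume


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-class foreground probabilities on a voxel grid, values in [0, 1]."""

    values: np.ndarray
    class_count: int = 1

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if self.class_count < 1:
            raise ValueError("class_count must be >= 1")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "values", v)


@dataclass
class MetricReport:
    """Per-class Dice values with macro-mean and pooled reductions."""

    per_class_dice: dict[int, float]
    mean_dice: float
    pooled_dice: float
    class_names: dict[int, str] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "per_class_dice": {str(k): v for k, v in self.per_class_dice.items()},
            "mean_dice": self.mean_dice,
            "pooled_dice": self.pooled_dice,
            "class_names": {str(k): v for k, v in self.class_names.items()},
        }

    def to_csv_rows(self) -> list[dict]:
        rows = [
            {"class": k, "name": self.class_names.get(k, str(k)), "dice": v}
            for k, v in self.per_class_dice.items()
        ]
        rows.append({"class": "macro_mean", "name": "", "dice": self.mean_dice})
        rows.append({"class": "pooled", "name": "", "dice": self.pooled_dice})
        return rows


def _dice_from_counts(inter: float, size_a: float, size_b: float) -> float:
    if size_a + size_b == 0:
        warnings.warn("Dice of two empty masks defined as 1.0 (agreement on "
                      "absence)", stacklevel=3)
        return 1.0
    return 2.0 * inter / (size_a + size_b)


def dice_score(prediction: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap of two binary masks; 1.0 when both are empty."""
    pred = np.asarray(prediction, dtype=bool)
    tru = np.asarray(truth, dtype=bool)
    if pred.shape != tru.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {tru.shape}")
    return _dice_from_counts(float(np.count_nonzero(pred & tru)),
                             float(np.count_nonzero(pred)),
                             float(np.count_nonzero(tru)))


def multiclass_dice(prediction: LabelVolume, truth: LabelVolume,
                    classes: list[int]) -> MetricReport:
    """Per-class binary Dice for each listed class, macro mean and pooled."""
    if prediction.shape != truth.shape:
        raise ValueError("volumes must share a grid shape")
    if prediction.spacing != truth.spacing:
        raise ValueError("volumes must share spacing")
    for c in classes:
        if c not in prediction.label_schema or c not in truth.label_schema:
            raise SchemaError(f"class {c} absent from label schema")
    per_class: dict[int, float] = {}
    tot_inter = tot_size = 0.0
    for c in classes:
        p = prediction.voxels == c
        t = truth.voxels == c
        inter = float(np.count_nonzero(p & t))
        size = float(np.count_nonzero(p) + np.count_nonzero(t))
        per_class[c] = _dice_from_counts(inter, float(np.count_nonzero(p)),
                                         float(np.count_nonzero(t)))
        tot_inter += inter
        tot_size += size
    mean = float(np.mean(list(per_class.values())))
    pooled = _dice_from_counts(tot_inter, tot_size, 0.0) if tot_size else 1.0
    names = {c: truth.label_schema.get(c, str(c)) for c in classes}
    return MetricReport(per_class, mean, pooled, names)


def soft_iou_loss(prediction: np.ndarray, truth: np.ndarray,
                  eta: float = 1.0) -> float:
    """Differentiable Soft IoU loss of a probability map against a binary mask."""
    pred = np.asarray(prediction, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if pred.shape != tru.shape:
        raise ValueError(f"shapes differ: {pred.shape} vs {tru.shape}")
    if eta < 0:
        raise ValueError("eta must be >= 0")
    if pred.size and (pred.min() < 0.0 or pred.max() > 1.0):
        raise ValueError("prediction probabilities must lie in [0, 1]")
    prod = pred * tru
    num = float(prod.sum())
    den = float((tru + pred - prod).sum()) + eta
    if den == 0.0:
        return 0.0  # both empty at eta == 0: perfect agreement on absence
    return 1.0 - num / den
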