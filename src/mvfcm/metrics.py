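"""Segmentation validity indices and cluster-label alignment.

Reference-based overlap metrics (Jaccard JS, Dice DSC, kappa index KI,
misclassification error ME) compare binary masks; reference-free crispness
measures (partition coefficient V_pc, partition entropy V_pe) score a fuzzy
partition directly.  Cluster indices are arbitrary, so per-tissue scoring
first aligns predicted clusters to reference classes by optimal assignment on
the contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import xlogy

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "jaccard",
    "dice",
    "kappa_index",
    "partition_coefficient",
    "partition_entropy",
    "misclassification_error",
    "align_labels",
    "per_class_masks",
    "tissue_report",
]


def _mask(a) -> np.ndarray:
    return np.asarray(a).astype(bool).ravel()


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    ma, mb = np.asarray(a), np.asarray(b)
    if ma.shape != mb.shape:
        raise ValueError(f"mask shapes differ: {ma.shape} vs {mb.shape}")
    return _mask(ma), _mask(mb)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(mask_pred, mask_ref) -> ConfusionCounts:
    a, b = _pair(mask_pred, mask_ref)
    return ConfusionCounts(
        tp=int(np.sum(a & b)), fp=int(np.sum(a & ~b)),
        fn=int(np.sum(~a & b)), tn=int(np.sum(~a & ~b)))


def jaccard(mask_a, mask_b) -> float:
    """JS = |A ∩ B| / |A ∪ B|; larger is better."""
    a, b = _pair(mask_a, mask_b)
    union = np.sum(a | b)
    if union == 0:
        raise ValueError("both masks are empty (0/0)")
    return float(np.sum(a & b) / union)


def dice(mask_a, mask_b) -> float:
    """DSC = 2|A ∩ B| / (|A| + |B|); equals 2*JS/(1+JS)."""
    a, b = _pair(mask_a, mask_b)
    denom = np.sum(a) + np.sum(b)
    if denom == 0:
        raise ValueError("both masks are empty")
    return float(2.0 * np.sum(a & b) / denom)


def kappa_index(counts: ConfusionCounts) -> float:
    """KI = 2TP / (2TP + FP + FN); numerically identical to Dice."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        raise ValueError("degenerate counts: 2TP + FP + FN = 0")
    return float(2.0 * counts.tp / denom)


def partition_coefficient(membership) -> float:
    """V_pc = sum u^2 / n, in [1/C, 1]; 1 for a crisp partition."""
    u = np.asarray(membership, dtype=float)
    return float(np.sum(u ** 2) / u.shape[1])


def partition_entropy(membership) -> float:
    """Partition entropy V_pe = -(1/n) sum u ln u, in [0, ln C]; 0 when crisp."""
    u = np.asarray(membership, dtype=float)
    return float(-xlogy(u, u).sum() / u.shape[1])


def misclassification_error(mask_pred, mask_gold) -> float:
    """ME = (|A ∪ B| - |A ∩ B|) / |B| against the gold mask B; 0 is perfect."""
    a, b = _pair(mask_pred, mask_gold)
    area_b = np.sum(b)
    if area_b == 0:
        raise ValueError("gold-standard mask is empty")
    return float((np.sum(a | b) - np.sum(a & b)) / area_b)


def align_labels(predicted, true, n_classes: int) -> tuple[np.ndarray, np.ndarray]:
    """Match arbitrary cluster indices to reference classes.

    Solves the optimal assignment maximizing total overlap on the C x C
    contingency table.  Returns ``(mapping, relabeled)`` where
    ``mapping[cluster] = class`` and ``relabeled = mapping[predicted]``.
    """
    pred = np.asarray(predicted).ravel()
    ref = np.asarray(true).ravel()
    if pred.shape != ref.shape:
        raise ValueError("label vectors differ in length")
    for name, lab in (("predicted", pred), ("true", ref)):
        if lab.min() < 0 or lab.max() >= n_classes:
            raise ValueError(f"{name} labels outside [0, {n_classes})")
    contingency = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(contingency, (pred, ref), 1)
    rows, cols = linear_sum_assignment(-contingency)
    mapping = np.empty(n_classes, dtype=int)
    mapping[rows] = cols
    return mapping, mapping[pred]


def per_class_masks(labels, n_classes: int) -> list[np.ndarray]:
    lab = np.asarray(labels)
    return [lab == c for c in range(n_classes)]


def tissue_report(predicted, true, n_classes: int,
                  background_label: int = 0,
                  class_names=None) -> dict:
    """Per-class JS/DSC/ME after alignment, plus the tissue mean.

    The mean rows average over the non-background classes only (the tissue
    classes), mirroring how segmentation scores are customarily summarized for
    WM/GM/CSF with a background cluster present.
    """
    _, relabeled = align_labels(predicted, true, n_classes)
    ref = np.asarray(true).ravel()
    per_class = {}
    for c in range(n_classes):
        name = class_names[c] if class_names else str(c)
        a = relabeled == c
        b = ref == c
        if not (a.any() or b.any()):
            per_class[name] = {"js": np.nan, "dsc": np.nan, "me": np.nan}
            continue
        per_class[name] = {
            "js": jaccard(a, b),
            "dsc": dice(a, b),
            "me": misclassification_error(a, b) if b.any() else np.nan,
        }
    tissue = [c for c in range(n_classes) if c != background_label]
    names = [class_names[c] if class_names else str(c) for c in tissue]
    mean = {key: float(np.mean([per_class[n][key] for n in names]))
            for key in ("js", "dsc", "me")}
    return {"per_class": per_class, "mean": mean,
            "accuracy": float(np.mean(relabeled == ref))}
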