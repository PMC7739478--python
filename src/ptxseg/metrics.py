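"""Segmentation and diagnostic evaluation metrics.

Pixel metrics (per image, per class): pixel accuracy p_c / P_c, Dice
2|A ∩ B| / (|A| + |B|), and the symmetric Hausdorff distance between the
two contour point sets.  Empty-class conventions: a class absent from the
ground truth scores 1 for accuracy and Dice when the prediction is also
empty for that class, else 0; the Hausdorff distance is undefined (NaN)
whenever either contour is empty and such images are excluded from
aggregates.  Diagnostic metrics are the standard confusion-matrix ratios
with the lesion-positive class as positive, reported in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import directed_hausdorff
from sklearn.metrics import confusion_matrix as _sk_confusion

from .loss import detect_boundary

PTX, NON_PTX = "PTX", "NonPTX"


def _check_pair(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred.astype(bool), truth.astype(bool)


def _class_ratio(pred_c: np.ndarray, truth_c: np.ndarray) -> float:
    """p_c / P_c with the 0/0 -> 1 empty-class convention."""
    total = truth_c.sum()
    if total == 0:
        return 1.0 if not pred_c.any() else 0.0
    return float((pred_c & truth_c).sum() / total)


def pixel_accuracy(pairs) -> dict:
    """Per-class pixel accuracies, MPA and PA1 over a list of (pred, truth)."""
    if not pairs:
        raise ValueError("need at least one prediction/truth pair")
    per_image = []
    for pred, truth in pairs:
        pred, truth = _check_pair(pred, truth)
        per_image.append([_class_ratio(~pred, ~truth), _class_ratio(pred, truth)])
    arr = np.array(per_image)  # (n, 2)
    return {
        "per_image": arr,
        "mpa": float(arr.mean()),
        "pa1": float(arr[:, 1].mean()),
        "pa1_std": float(arr[:, 1].std()),
    }


def _dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.sum(), b.sum()
    if sa + sb == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / (sa + sb))


def dice(pairs) -> dict:
    """Per-class Dice coefficients, mean DSC and DSC1."""
    if not pairs:
        raise ValueError("need at least one prediction/truth pair")
    per_image = []
    for pred, truth in pairs:
        pred, truth = _check_pair(pred, truth)
        per_image.append([_dice_coefficient(~pred, ~truth), _dice_coefficient(pred, truth)])
    arr = np.array(per_image)
    return {
        "per_image": arr,
        "dsc": float(arr.mean()),
        "dsc1": float(arr[:, 1].mean()),
        "dsc1_std": float(arr[:, 1].std()),
    }


def hausdorff(p_points: np.ndarray, g_points: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets, in pixels.

    Returns NaN when either set is empty (undefined; callers exclude such
    values from aggregates).
    """
    p = np.atleast_2d(np.asarray(p_points, dtype=float))
    g = np.atleast_2d(np.asarray(g_points, dtype=float))
    if p.size == 0 or g.size == 0:
        return float("nan")
    return float(max(directed_hausdorff(p, g)[0], directed_hausdorff(g, p)[0]))


def mask_contour_points(mask: np.ndarray) -> np.ndarray:
    """(row, col) coordinates of the lesion contour of a binary mask."""
    return np.argwhere(detect_boundary(np.asarray(mask).astype(np.uint8)))


def hausdorff_masks(pred: np.ndarray, truth: np.ndarray) -> float:
    """Hausdorff distance between the contours of two binary masks."""
    return hausdorff(mask_contour_points(pred), mask_contour_points(truth))


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(labels, calls) -> ConfusionCounts:
    """2x2 tally of image-level calls with the lesion class as positive."""
    labels = list(labels)
    calls = list(calls)
    if len(labels) != len(calls):
        raise ValueError("labels and calls must have equal length")
    m = _sk_confusion(labels, calls, labels=[NON_PTX, PTX])
    return ConfusionCounts(tp=int(m[1, 1]), fp=int(m[0, 1]),
                           fn=int(m[1, 0]), tn=int(m[0, 0]))


def _ratio_pct(num: float, den: float) -> float:
    return float(100.0 * num / den) if den else float("nan")


def diagnostic_metrics(cc: ConfusionCounts) -> dict:
    """Accuracy, sensitivity, specificity, PPV, NPV and F1, in percent."""
    sens = _ratio_pct(cc.tp, cc.tp + cc.fn)
    ppv = _ratio_pct(cc.tp, cc.tp + cc.fp)
    if np.isnan(sens) or np.isnan(ppv) or (ppv + sens) == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * ppv * sens / (ppv + sens)
    return {
        "accuracy": _ratio_pct(cc.tp + cc.tn, cc.total),
        "sensitivity": sens,
        "specificity": _ratio_pct(cc.tn, cc.tn + cc.fp),
        "ppv": ppv,
        "npv": _ratio_pct(cc.tn, cc.tn + cc.fn),
        "f1": f1,
    }


def dice_ttest(dsc_a, dsc_b) -> tuple[float, float]:
    """Student's t-test (two independent samples) on per-image Dice scores."""
    t, p = stats.ttest_ind(np.asarray(dsc_a, float), np.asarray(dsc_b, float))
    return float(t), float(p)


def write_report(rows: list[dict], summary: dict, out_dir: str | Path) -> None:
    """Write the per-image CSV and the JSON summary of an evaluation."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out_dir / "per_image.csv", index=False)

    def _clean(v):
        if isinstance(v, float) and np.isnan(v):
            return None
        return v
    (out_dir / "summary.json").write_text(
        json.dumps({k: _clean(v) for k, v in summary.items()}, indent=2))
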