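"""Segmentation evaluation: Dice, precision, recall and the aggregated
Jaccard index (AJI).

Pixel metrics come from the binary confusion counts:

    Dice = 2 TP / (2 TP + FP + FN),  Precision = TP / (TP + FP),
    Recall = TP / (TP + FN).

AJI is the instance-aware extension of the Jaccard index: every
ground-truth nucleus, in ascending label order, is matched to the
still-unused predicted component that maximises the pairwise Jaccard
index; the matched intersections accumulate into the numerator, the
matched unions into the denominator, and after all ground-truth instances
the pixels of every unmatched predicted component are added to the
denominator.  Ground-truth instances with no overlapping prediction
contribute their own size to the denominator.  Ties on the maximal Jaccard
break to the smaller predicted label so the score is deterministic.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .data_pipeline import load_mask

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "dice_score",
    "precision",
    "recall",
    "label_components",
    "aji",
    "evaluate_masks",
    "evaluate_dataset",
    "METRIC_NAMES",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("dice", "aji", "precision", "recall")


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(gt: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    """Exact pixel tallies between two binary masks."""
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    g = gt > 0
    p = pred > 0
    return ConfusionCounts(
        tp=int(np.count_nonzero(g & p)),
        fp=int(np.count_nonzero(~g & p)),
        fn=int(np.count_nonzero(g & ~p)),
        tn=int(np.count_nonzero(~g & ~p)),
    )


def dice_score(c: ConfusionCounts) -> float:
    den = 2 * c.tp + c.fp + c.fn
    return 1.0 if den == 0 else 2.0 * c.tp / den


def precision(c: ConfusionCounts) -> float:
    den = c.tp + c.fp
    if den == 0:
        logger.warning("precision undefined (no predicted positives); reporting 1.0")
        return 1.0
    return c.tp / den


def recall(c: ConfusionCounts) -> float:
    den = c.tp + c.fn
    if den == 0:
        logger.warning("recall undefined (no ground-truth positives); reporting 1.0")
        return 1.0
    return c.tp / den


def label_components(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Connected-component labelling of a binary mask, labels 1..k in
    scanline discovery order."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labels, _ = ndimage.label(np.asarray(mask) > 0, structure=structure)
    return labels.astype(np.int32)


def aji(gt: np.ndarray, pred: np.ndarray) -> float:
    """Aggregated Jaccard index between two instance-labelled masks."""
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    gt_labels = np.unique(gt)
    gt_labels = gt_labels[gt_labels > 0]
    pred_labels = np.unique(pred)
    pred_labels = pred_labels[pred_labels > 0]
    if gt_labels.size == 0:
        return 1.0 if pred_labels.size == 0 else 0.0
    if pred_labels.size == 0:
        return 0.0

    pred_sizes = {int(p): int(np.count_nonzero(pred == p)) for p in pred_labels}
    used: set[int] = set()
    inter_sum = 0
    union_sum = 0
    for g in gt_labels:
        g_mask = gt == g
        g_size = int(np.count_nonzero(g_mask))
        overlapping = np.unique(pred[g_mask])
        overlapping = overlapping[overlapping > 0]
        best_j, best_p, best_inter = -1.0, None, 0
        for p in overlapping:
            p = int(p)
            if p in used:
                continue
            inter = int(np.count_nonzero(g_mask & (pred == p)))
            union = g_size + pred_sizes[p] - inter
            j = inter / union
            if j > best_j:  # ties keep the smaller label (ascending scan)
                best_j, best_p, best_inter = j, p, inter
        if best_p is None:
            union_sum += g_size  # missed nucleus penalises the denominator
        else:
            used.add(best_p)
            inter_sum += best_inter
            union_sum += g_size + pred_sizes[best_p] - best_inter
    for p in pred_labels:
        if int(p) not in used:
            union_sum += pred_sizes[int(p)]
    return inter_sum / union_sum


def evaluate_masks(gt_instances: np.ndarray, pred_binary: np.ndarray,
                   connectivity: int = 8) -> dict[str, float]:
    """All four metrics for one image: pixel metrics on the binarised
    masks, AJI between ground-truth instances and the connected components
    of the binary prediction."""
    c = confusion_counts(gt_instances, pred_binary)
    pred_inst = label_components(pred_binary, connectivity)
    return {
        "dice": dice_score(c),
        "aji": aji(gt_instances, pred_inst),
        "precision": precision(c),
        "recall": recall(c),
    }


def evaluate_dataset(pred_dir, gt_dir, connectivity: int = 8,
                     out_csv=None) -> pd.DataFrame:
    """Per-image metrics for matching filenames, plus mean and sample SD.

    Returns a DataFrame with one row per image and two summary rows
    (``mean`` and ``sd``); optionally written to CSV.
    """
    pred_dir, gt_dir = Path(pred_dir), Path(gt_dir)
    pred_files = sorted(p.name for p in pred_dir.glob("*.png"))
    gt_files = {p.name for p in gt_dir.glob("*.png")}
    unmatched = sorted(set(pred_files) ^ gt_files)
    if unmatched:
        raise ValueError(f"unmatched filenames between pred and gt dirs: {unmatched}")
    if not pred_files:
        raise ValueError("no PNG masks found")

    rows = []
    for name in pred_files:
        gt = load_mask(gt_dir / name)
        pred = load_mask(pred_dir / name)
        scores = evaluate_masks(gt, pred, connectivity)
        rows.append({"image": name, **scores})
    df = pd.DataFrame(rows)
    means = {m: float(df[m].mean()) for m in METRIC_NAMES}
    sds = {m: (float(df[m].std(ddof=1)) if len(df) > 1 else 0.0) for m in METRIC_NAMES}
    df = pd.concat(
        [df, pd.DataFrame([{"image": "mean", **means}, {"image": "sd", **sds}])],
        ignore_index=True,
    )
    if out_csv is not None:
        Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_csv, index=False)
    return df
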