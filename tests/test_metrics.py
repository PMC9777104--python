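"""Pixel metrics and the aggregated Jaccard index, with brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from stainseg import data_pipeline as dp
from stainseg.metrics import (
    ConfusionCounts,
    aji,
    confusion_counts,
    dice_score,
    evaluate_dataset,
    evaluate_masks,
    label_components,
    precision,
    recall,
)


# ------------------------------------------------------ confusion + scores
def test_confusion_counts_enumeration():
    gt = np.array([[1, 1], [0, 0]])
    pred = np.array([[1, 0], [1, 0]])
    c = confusion_counts(gt, pred)
    assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)
    assert c.total == 4
    assert dice_score(c) == 0.5 and precision(c) == 0.5 and recall(c) == 0.5


def test_perfect_and_empty_predictions():
    ones = np.ones((3, 3), dtype=int)
    c = confusion_counts(ones, ones)
    assert (c.tp, c.fp, c.fn, c.tn) == (9, 0, 0, 0)
    assert dice_score(c) == precision(c) == recall(c) == 1.0

    c2 = confusion_counts(ones, np.zeros_like(ones))
    assert c2.fn == 9
    assert dice_score(c2) == 0.0 and recall(c2) == 0.0

    both_empty = confusion_counts(np.zeros((2, 2)), np.zeros((2, 2)))
    assert dice_score(both_empty) == 1.0


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)))
    with pytest.raises(ValueError):
        aji(np.zeros((2, 2)), np.zeros((3, 3)))


# ------------------------------------------------------------- components
def test_single_square_is_one_component():
    m = np.zeros((5, 5), dtype=int)
    m[1:4, 1:4] = 1
    assert label_components(m).max() == 1


def test_diagonal_touch_depends_on_connectivity():
    m = np.zeros((3, 3), dtype=int)
    m[0, 0] = m[1, 1] = 1
    assert label_components(m, 8).max() == 1
    assert label_components(m, 4).max() == 2


def test_empty_mask_has_no_components():
    assert label_components(np.zeros((4, 4), dtype=int)).max() == 0
    with pytest.raises(ValueError):
        label_components(np.zeros((4, 4), dtype=int), connectivity=6)


# -------------------------------------------------------------------- AJI
def _aji_oracle(gt: np.ndarray, pred: np.ndarray) -> float:
    """Independent set-based re-derivation: greedy best-Jaccard matching in
    ascending ground-truth label order with usage bookkeeping."""
    gt_sets = {g: set(zip(*np.where(gt == g))) for g in np.unique(gt) if g > 0}
    pr_sets = {p: set(zip(*np.where(pred == p))) for p in np.unique(pred) if p > 0}
    if not gt_sets:
        return 1.0 if not pr_sets else 0.0
    if not pr_sets:
        return 0.0
    used = set()
    inter_total = union_total = 0
    for g in sorted(gt_sets):
        best = None
        for p in sorted(pr_sets):
            if p in used:
                continue
            inter = len(gt_sets[g] & pr_sets[p])
            if inter == 0:
                continue
            union = len(gt_sets[g] | pr_sets[p])
            j = inter / union
            if best is None or j > best[0]:
                best = (j, p, inter, union)
        if best is None:
            union_total += len(gt_sets[g])
        else:
            _, p, inter, union = best
            used.add(p)
            inter_total += inter
            union_total += union
    for p in pr_sets:
        if p not in used:
            union_total += len(pr_sets[p])
    return inter_total / union_total


def test_aji_trivial_cases():
    gt = np.zeros((4, 4), dtype=int)
    gt[1:3, 0:2] = 1
    assert aji(gt, gt) == 1.0
    assert aji(gt, np.zeros_like(gt)) == 0.0
    assert aji(np.zeros_like(gt), np.zeros_like(gt)) == 1.0
    assert aji(np.zeros_like(gt), gt) == 0.0


def test_aji_shifted_square_is_one_third():
    gt = np.zeros((4, 4), dtype=int)
    gt[1:3, 0:2] = 1
    pred = np.zeros((4, 4), dtype=int)
    pred[1:3, 1:3] = 1
    assert np.isclose(aji(gt, pred), 1.0 / 3.0)
    assert np.isclose(_aji_oracle(gt, pred), 1.0 / 3.0)


def test_unmatched_prediction_penalises_denominator():
    gt = np.zeros((6, 6), dtype=int)
    gt[0:2, 0:2] = 1
    pred = gt.copy()
    pred[4:6, 4:6] = 2  # spurious extra nucleus
    # matched: inter 4 / union 4; unmatched pred adds 4 to the denominator
    assert np.isclose(aji(gt, pred), 4.0 / 8.0)


instance_masks = hnp.arrays(
    dtype=np.int8,
    shape=st.tuples(st.integers(2, 6), st.integers(2, 6)),
    elements=st.integers(0, 3),
)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(gt=instance_masks, pred=instance_masks)
def test_aji_matches_set_based_oracle(gt, pred):
    if gt.shape != pred.shape:
        pred = np.resize(pred, gt.shape)
    assert abs(aji(gt, pred) - _aji_oracle(gt, pred)) < 1e-12


@settings(max_examples=200, deadline=None, derandomize=True)
@given(gt=instance_masks, pred=instance_masks)
def test_aji_bounded_by_binary_jaccard_and_unit_interval(gt, pred):
    if gt.shape != pred.shape:
        pred = np.resize(pred, gt.shape)
    score = aji(gt, pred)
    assert 0.0 <= score <= 1.0
    g, p = gt > 0, pred > 0
    if g.any() or p.any():
        binary_jaccard = (g & p).sum() / (g | p).sum()
        assert score <= binary_jaccard + 1e-12


# ---------------------------------------------------------------- dataset
def _write_pair(d, name, arr):
    dp.save_mask(d / name, arr)


def test_evaluate_dataset_mean_and_sample_sd(tmp_path):
    gt_dir = tmp_path / "gt"
    pred_dir = tmp_path / "pred"
    gt_dir.mkdir(), pred_dir.mkdir()
    a = np.zeros((8, 8), dtype=int)
    a[2:5, 2:5] = 1
    _write_pair(gt_dir, "a.png", a)
    _write_pair(pred_dir, "a.png", a)  # dice 1
    b = np.zeros((8, 8), dtype=int)
    b[0:3, 0:3] = 1
    _write_pair(gt_dir, "b.png", b)
    _write_pair(pred_dir, "b.png", np.zeros_like(b))  # dice 0

    df = evaluate_dataset(pred_dir, gt_dir, out_csv=tmp_path / "scores.csv")
    assert len(df) == 2 + 2  # per-image rows + mean + sd
    mean_row = df[df["image"] == "mean"].iloc[0]
    sd_row = df[df["image"] == "sd"].iloc[0]
    assert np.isclose(mean_row["dice"], 0.5)
    assert np.isclose(sd_row["dice"], np.sqrt(0.5), atol=1e-6)  # two-point sample SD
    assert (tmp_path / "scores.csv").exists()
    assert len(pd.read_csv(tmp_path / "scores.csv")) == 4


def test_evaluate_dataset_perfect_single_image(tmp_path):
    for d in ("gt", "pred"):
        (tmp_path / d).mkdir()
    m = np.zeros((8, 8), dtype=int)
    m[1:4, 1:4] = 1
    _write_pair(tmp_path / "gt", "x.png", m)
    _write_pair(tmp_path / "pred", "x.png", m)
    df = evaluate_dataset(tmp_path / "pred", tmp_path / "gt")
    mean_row = df[df["image"] == "mean"].iloc[0]
    sd_row = df[df["image"] == "sd"].iloc[0]
    assert mean_row["dice"] == 1.0 and sd_row["dice"] == 0.0


def test_evaluate_dataset_reports_unmatched_files(tmp_path):
    for d in ("gt", "pred"):
        (tmp_path / d).mkdir()
    m = np.zeros((4, 4), dtype=int)
    _write_pair(tmp_path / "gt", "only_gt.png", m)
    _write_pair(tmp_path / "pred", "only_pred.png", m)
    with pytest.raises(ValueError, match="only_gt.png"):
        evaluate_dataset(tmp_path / "pred", tmp_path / "gt")


def test_evaluate_masks_uses_connected_components(rng):
    gt = np.zeros((10, 10), dtype=int)
    gt[1:4, 1:4] = 1
    gt[6:9, 6:9] = 2
    pred = (gt > 0).astype(np.uint8)  # binary prediction, two blobs
    scores = evaluate_masks(gt, pred)
    assert scores["dice"] == 1.0 and scores["aji"] == 1.0
    assert set(scores) == {"dice", "aji", "precision", "recall"}
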