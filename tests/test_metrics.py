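"""Confusion metrics, Hausdorff distances, case aggregation and AUC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from onet.metrics import (ConfusionCounts, ContourSet, confusion_counts, dice,
                          directed_hausdorff, evaluate_case, extract_contour,
                          hausdorff, rate_metrics, roc_auc)


def toy_4x4():
    """Hand-counted pair: TP=2, FP=1, FN=1, TN=12 for class 1."""
    gt = np.zeros((4, 4), int)
    gt[0, 0] = gt[0, 1] = gt[1, 0] = 1          # 3 reference pixels
    pred = np.zeros((4, 4), int)
    pred[0, 0] = pred[0, 1] = pred[3, 3] = 1    # 2 hits, 1 false alarm
    return pred, gt


def test_confusion_counts_hand_example():
    c = confusion_counts(*toy_4x4(), positive_class=1)
    assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 12)
    assert c.total == 16


def test_confusion_counts_edge_cases():
    gt = np.zeros((3, 3), int)
    gt[1, 1] = gt[1, 2] = 1
    same = confusion_counts(gt, gt, 1)
    assert same.fp == 0 and same.fn == 0
    empty_pred = confusion_counts(np.zeros((3, 3), int), gt, 1)
    assert empty_pred.tp == 0 and empty_pred.fn == 2
    with pytest.raises(ValueError, match="shape"):
        confusion_counts(np.zeros((2, 2)), gt, 1)


def test_dice_values():
    assert dice(ConfusionCounts(5, 0, 0, 11)) == 1.0
    assert dice(ConfusionCounts(0, 3, 4, 9)) == 0.0
    assert np.isclose(dice(ConfusionCounts(2, 1, 1, 12)), 4 / 6)
    assert dice(ConfusionCounts(0, 0, 0, 16)) == 1.0  # both masks empty


def test_rate_metrics_hand_example():
    m = rate_metrics(ConfusionCounts(2, 1, 1, 12))
    assert np.isclose(m["iou"], 0.5)
    assert np.isclose(m["pre"], 2 / 3)
    assert np.isclose(m["pa"], 14 / 16)
    assert np.isclose(m["ac"], m["pa"])  # accuracy == pixel accuracy here
    assert np.isclose(m["recall"], 2 / 3)
    assert np.isclose(m["sp"], 12 / 13)
    # f1 equals the harmonic mean of precision and recall
    assert np.isclose(m["f1"], 2 * m["pre"] * m["recall"] / (m["pre"] + m["recall"]))
    perfect = rate_metrics(ConfusionCounts(4, 0, 0, 12))
    assert all(np.isclose(v, 1.0) for v in perfect.values())


def test_zero_denominator_policy_warns():
    with pytest.warns(RuntimeWarning):
        m = rate_metrics(ConfusionCounts(0, 0, 0, 10))
    assert m["pre"] == 0.0


@settings(derandomize=True, max_examples=50)
@given(tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50))
def test_dice_iou_algebraic_identity(tp, fp, fn):
    c = ConfusionCounts(tp, fp, fn, 10)
    d = dice(c)
    i = rate_metrics(c)["iou"] if tp + fp + fn else None
    if tp + fp + fn == 0:
        return
    assert np.isclose(d, 2 * i / (1 + i))
    assert i <= d + 1e-12


def test_extract_contour_examples():
    full = np.ones((5, 5), int)
    pts = {tuple(p) for p in extract_contour(full).points}
    border = {(r, c) for r in range(5) for c in range(5)
              if r in (0, 4) or c in (0, 4)}
    assert pts == border
    single = np.zeros((5, 5), int)
    single[2, 3] = 1
    assert {tuple(p) for p in extract_contour(single).points} == {(2, 3)}
    square = np.zeros((5, 5), int)
    square[1:4, 1:4] = 1
    pts = extract_contour(square).points
    assert len(pts) == 8 and (2, 2) not in {tuple(p) for p in pts}
    assert extract_contour(np.zeros((4, 4), int)).is_empty


def test_directed_hausdorff_examples():
    a = ContourSet(np.array([[0, 0]]))
    b = ContourSet(np.array([[3, 4]]))
    assert directed_hausdorff(a, b) == 5.0
    a2 = ContourSet(np.array([[0, 0], [10, 0]]))
    b2 = ContourSet(np.array([[0, 0]]))
    assert directed_hausdorff(a2, b2) == 10.0
    assert directed_hausdorff(b2, a2) == 0.0  # B is a subset of A
    with pytest.raises(ValueError, match="A"):
        directed_hausdorff(ContourSet(np.empty((0, 2))), b)


def test_hausdorff_symmetry_and_oracle(rng):
    from scipy.spatial.distance import directed_hausdorff as scipy_dh
    a = ContourSet(rng.integers(0, 30, size=(12, 2)))
    b = ContourSet(rng.integers(0, 30, size=(9, 2)))
    got = hausdorff(a, b)
    want = max(scipy_dh(a.points, b.points)[0], scipy_dh(b.points, a.points)[0])
    assert np.isclose(got, want)
    assert np.isclose(hausdorff(a, b), hausdorff(b, a))
    assert hausdorff(a, a) == 0.0
    a2 = ContourSet(np.array([[0, 0], [10, 0]]))
    b2 = ContourSet(np.array([[0, 0]]))
    assert hausdorff(a2, b2) == 10.0


def test_hausdorff_triangle_inequality(rng):
    sets = [ContourSet(rng.integers(0, 20, size=(rng.integers(3, 8), 2)))
            for _ in range(6)]
    for a in sets:
        for b in sets:
            for c in sets:
                assert hausdorff(a, c) <= hausdorff(a, b) + hausdorff(b, c) + 1e-9


def test_hd95_is_at_most_max_hausdorff(rng):
    a = ContourSet(rng.integers(0, 40, size=(25, 2)))
    b = ContourSet(rng.integers(0, 40, size=(25, 2)))
    assert hausdorff(a, b, percentile=95) <= hausdorff(a, b) + 1e-12


def test_evaluate_case_perfect_and_hand_counts():
    gt = np.zeros((8, 8), int)
    gt[1:4, 1:4] = 1
    gt[5:7, 5:7] = 2
    res = evaluate_case(gt, gt)
    assert res["mean_dice"] == 1.0 and res["mean_hd"] == 0.0
    # 2-class toy with known counts
    pred = gt.copy()
    pred[1, 1] = 0                     # one missed pixel of class 1
    res = evaluate_case(pred, gt, class_ids=[1, 2])
    d1 = dice(confusion_counts(pred, gt, 1))
    assert np.isclose(res["per_class"][1]["dice"], d1)
    assert np.isclose(res["mean_dice"], (d1 + 1.0) / 2)
    assert res["per_class"][2]["hd"] == 0.0


def test_evaluate_case_relabel_invariance(rng):
    pred = rng.integers(0, 3, size=(16, 16))
    gt = rng.integers(0, 3, size=(16, 16))
    base = evaluate_case(pred, gt, class_ids=[1, 2])
    swapped = evaluate_case(np.where(pred == 1, 2, np.where(pred == 2, 1, 0)),
                            np.where(gt == 1, 2, np.where(gt == 2, 1, 0)),
                            class_ids=[1, 2])
    assert np.isclose(base["mean_dice"], swapped["mean_dice"])
    assert np.isclose(base["mean_hd"], swapped["mean_hd"], equal_nan=True)


def test_evaluate_case_agrees_with_per_pixel_recount(rng):
    pred = rng.integers(0, 4, size=(16, 16))
    gt = rng.integers(0, 4, size=(16, 16))
    res = evaluate_case(pred, gt, class_ids=[1, 2, 3])
    for cid in (1, 2, 3):
        tp = fp = fn = 0
        for y in range(16):
            for x in range(16):
                p, g = pred[y, x] == cid, gt[y, x] == cid
                tp += p and g
                fp += p and not g
                fn += g and not p
        want = 1.0 if tp + fp + fn == 0 else 2 * tp / (2 * tp + fp + fn)
        assert np.isclose(res["per_class"][cid]["dice"], want)


def test_evaluate_case_absent_class_convention():
    pred = np.zeros((6, 6), int)
    gt = np.zeros((6, 6), int)
    res = evaluate_case(pred, gt, class_ids=[1])
    assert res["per_class"][1]["dice"] == 1.0
    assert res["mean_hd"] == 0.0  # excluded, empty mean defined as 0


def test_roc_auc_values(rng):
    assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert roc_auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.5
    assert np.isclose(roc_auc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]), 0.75)
    with pytest.raises(ValueError, match="both"):
        roc_auc([0.1, 0.9], [1, 1])


def test_roc_auc_matches_sklearn(rng):
    from sklearn.metrics import roc_auc_score
    scores = rng.normal(size=60)
    labels = rng.integers(0, 2, size=60)
    labels[0], labels[1] = 0, 1
    scores[labels == 1] += 0.4
    scores = np.round(scores, 1)  # force ties
    assert np.isclose(roc_auc(scores, labels), roc_auc_score(labels, scores))
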