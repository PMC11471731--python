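"""Confusion counting, metric formulas, identities and report layout."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jcwmh.classify import LabeledLesionMap, WMHClass
from jcwmh.metrics import (
    ConfusionCounts,
    class_report,
    compute_metrics,
    confusion,
)
from jcwmh.rasters import BinaryMask, VolumeGeometry

from conftest import GEOM09, mask

UNIT = VolumeGeometry(1.0, 1.0)


def test_worked_formula_example():
    rep = compute_metrics(ConfusionCounts(tp=3, fp=1, fn=1, tn=5))
    assert rep.precision == pytest.approx(0.75)
    assert rep.recall == pytest.approx(0.75)
    assert rep.dsc == pytest.approx(0.75)
    assert rep.iou == pytest.approx(0.6)
    assert rep.accuracy == pytest.approx(0.8)
    assert rep.specificity == pytest.approx(5 / 6)
    assert rep.support == 4


def test_perfect_prediction_scores_ones(rng):
    t = rng.random((20, 20)) > 0.7
    c = confusion(mask(t), mask(t))
    rep = compute_metrics(c)
    for name in ("accuracy", "precision", "recall", "specificity", "dsc", "iou"):
        assert getattr(rep, name) == 1.0


def test_complement_prediction_has_no_true_counts(rng):
    t = rng.random((10, 10)) > 0.5
    c = confusion(mask(~t), mask(t))
    assert c.tp == 0 and c.tn == 0
    assert c.fp + c.fn == t.size


def test_confusion_matches_per_pixel_loop(rng):
    for _ in range(20):
        p = rng.random((16, 16)) > 0.5
        t = rng.random((16, 16)) > 0.5
        c = confusion(mask(p), mask(t))
        tp = fp = fn = tn = 0
        for i in range(16):
            for j in range(16):
                if p[i, j] and t[i, j]:
                    tp += 1
                elif p[i, j]:
                    fp += 1
                elif t[i, j]:
                    fn += 1
                else:
                    tn += 1
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)


def test_dsc_iou_identity_holds_to_machine_precision(rng):
    for _ in range(100):
        counts = rng.integers(0, 50, size=4)
        rep = compute_metrics(ConfusionCounts(*map(int, counts)))
        if rep.iou > 0 or not rep.degenerate:
            assert rep.dsc == pytest.approx(
                2 * rep.iou / (1 + rep.iou), abs=1e-15
            )


def test_empty_vs_empty_convention_flags_degenerate():
    rep = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=10))
    assert rep.degenerate
    assert rep.dsc == 1.0 and rep.iou == 1.0
    # empty prediction against non-empty truth scores zero overlap
    rep = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=5, tn=5))
    assert not rep.degenerate
    assert rep.dsc == 0.0 and rep.recall == 0.0


@settings(derandomize=True, max_examples=100, deadline=None)
@given(counts=st.tuples(*[st.integers(0, 10_000)] * 4))
def test_metric_bounds_and_identity_property(counts):
    rep = compute_metrics(ConfusionCounts(*counts))
    for name in ("accuracy", "precision", "recall", "specificity", "dsc", "iou"):
        assert 0.0 <= getattr(rep, name) <= 1.0
    assert rep.dsc == pytest.approx(2 * rep.iou / (1 + rep.iou), abs=1e-12)


def labels_from(grid):
    return LabeledLesionMap(np.asarray(grid, dtype=np.int16), UNIT)


def test_identical_label_maps_score_unity():
    grid = np.zeros((20, 20), dtype=np.int16)
    grid[2:5, 2:5] = 1
    grid[8:11, 8:11] = 2
    grid[14:16, 14:16] = 3
    rep = class_report(labels_from(grid), labels_from(grid))
    assert set(rep.per_class) == {WMHClass.PE, WMHClass.PA, WMHClass.JC}
    for r in rep.per_class.values():
        assert r.dsc == 1.0
    assert rep.weighted_average.dsc == 1.0
    assert rep.macro_average.dsc == 1.0


def test_fully_mislabeled_class_and_support_partition():
    truth = np.zeros((20, 20), dtype=np.int16)
    truth[0:4, 0:4] = 1  # 16 px PE
    truth[10:14, 10:14] = 2  # 16 px PA
    pred = truth.copy()
    pred[pred == 1] = 2  # every PE pixel called PA
    rep = class_report(labels_from(pred), labels_from(truth))
    assert rep.per_class[WMHClass.PE].recall == 0.0
    supports = [r.support for r in rep.per_class.values()]
    assert sum(supports) == int(np.sum(truth > 0))
    assert WMHClass.JC in rep.absent_classes


def test_class_report_counts_match_loop_oracle(rng):
    p = rng.integers(0, 4, size=(15, 15)).astype(np.int16)
    t = rng.integers(0, 4, size=(15, 15)).astype(np.int16)
    rep = class_report(labels_from(p), labels_from(t))
    for cls in WMHClass:
        if cls in rep.absent_classes:
            continue
        tp = int(np.sum((p == cls) & (t == cls)))
        fn = int(np.sum((p != cls) & (t == cls)))
        fp = int(np.sum((p == cls) & (t != cls)))
        r = rep.per_class[cls]
        assert r.support == tp + fn
        assert r.recall == pytest.approx(tp / (tp + fn))
        if tp + fp:
            assert r.precision == pytest.approx(tp / (tp + fp))


def test_metrics_invariant_to_grid_permutation(rng):
    p = rng.integers(0, 4, size=(12, 12)).astype(np.int16)
    t = rng.integers(0, 4, size=(12, 12)).astype(np.int16)
    perm_r = rng.permutation(12)
    perm_c = rng.permutation(12)
    a = class_report(labels_from(p), labels_from(t))
    b = class_report(
        labels_from(p[perm_r][:, perm_c]), labels_from(t[perm_r][:, perm_c])
    )
    for cls in a.per_class:
        assert a.per_class[cls].as_dict() == b.per_class[cls].as_dict()


def test_weighted_recall_equals_micro_recall_over_lesion_pixels(rng):
    t = rng.integers(0, 4, size=(20, 20)).astype(np.int16)
    p = t.copy()
    flip = rng.random((20, 20)) < 0.2
    p[flip] = rng.integers(0, 4, size=int(flip.sum()))
    rep = class_report(labels_from(p), labels_from(t))
    lesion = t > 0
    micro = np.sum((p == t) & lesion) / lesion.sum()
    assert rep.weighted_average.recall == pytest.approx(float(micro))


def test_report_frame_layout():
    grid = np.zeros((10, 10), dtype=np.int16)
    grid[0:2, 0:2] = 1
    frame = class_report(labels_from(grid), labels_from(grid)).to_frame()
    assert list(frame.columns) == [
        "DSC", "Precision", "Sensitivity", "Specificity", "Accuracy", "Support",
    ]
    assert list(frame.index)[-2:] == ["macro avg", "weighted avg"]


def test_roi_restriction(rng):
    t = np.zeros((10, 10), dtype=np.int16)
    t[0:3, 0:3] = 1
    p = t.copy()
    p[5:8, 5:8] = 1  # false positives outside the ROI
    roi = np.zeros((10, 10), bool)
    roi[0:5, 0:5] = True
    full = class_report(labels_from(p), labels_from(t))
    restricted = class_report(
        labels_from(p), labels_from(t), roi=BinaryMask(roi, UNIT)
    )
    assert restricted.per_class[WMHClass.PE].precision == 1.0
    assert full.per_class[WMHClass.PE].precision < 1.0
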