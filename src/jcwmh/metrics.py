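"""Pixel-level segmentation metrics and per-class report layout.

Six metrics are computed from one-vs-rest confusion counts:

    accuracy    = (TP + TN) / (TP + FN + TN + FP)
    recall      = TP / (TP + FN)          (sensitivity, TPR)
    specificity = TN / (TN + FP)          (TNR)
    precision   = TP / (TP + FP)
    DSC         = 2 TP / (2 TP + FP + FN)
    IoU         = TP / (TP + FP + FN)

DSC and IoU are tied by DSC = 2·IoU / (1 + IoU) and that identity is
asserted in tests to machine precision.  Per-class evaluation is
pixel-level one-vs-rest over the full image grid (true negatives include
background), with support = number of truth pixels of the class, and the
report carries both the unweighted (macro) and support-weighted averages.

Zero-denominator policy: empty-prediction vs empty-truth counts as a
perfect match (metric 1, flagged ``degenerate``); empty vs non-empty is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import LabeledLesionMap, WMHClass
from .rasters import BinaryMask, _require_same_geometry

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ClassReport",
    "confusion",
    "compute_metrics",
    "class_report",
]

METRIC_NAMES = ("dsc", "precision", "recall", "specificity", "accuracy", "iou")


@dataclass(frozen=True)
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


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    dsc: float
    iou: float
    support: int
    degenerate: bool = False  # empty-vs-empty convention applied

    def as_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in METRIC_NAMES}
        d["support"] = self.support
        return d


def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Pixel-level confusion counts between a predicted and a truth mask."""
    _require_same_geometry(pred, truth)
    p, t = pred.pixels, truth.pixels
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int, *, empty_value: float) -> float:
    return num / den if den > 0 else empty_value


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """The six metrics from one set of confusion counts."""
    degenerate = (c.tp + c.fp + c.fn) == 0
    empty = 1.0 if degenerate else 0.0
    return MetricsReport(
        accuracy=_ratio(c.tp + c.tn, c.total, empty_value=1.0),
        precision=_ratio(c.tp, c.tp + c.fp, empty_value=empty if c.fn == 0 else 0.0),
        recall=_ratio(c.tp, c.tp + c.fn, empty_value=empty if c.fp == 0 else 0.0),
        specificity=_ratio(c.tn, c.tn + c.fp, empty_value=1.0),
        dsc=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, empty_value=empty),
        iou=_ratio(c.tp, c.tp + c.fp + c.fn, empty_value=empty),
        support=c.tp + c.fn,
        degenerate=degenerate,
    )


def _average(reports: dict[WMHClass, MetricsReport], weighted: bool) -> MetricsReport:
    present = list(reports.values())
    if not present:
        return MetricsReport(1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0, degenerate=True)
    if weighted:
        w = np.array([r.support for r in present], dtype=float)
        if w.sum() == 0:
            w = np.ones(len(present))
    else:
        w = np.ones(len(present))
    w = w / w.sum()
    vals = {
        name: float(np.sum(w * np.array([getattr(r, name) for r in present])))
        for name in METRIC_NAMES
    }
    return MetricsReport(
        support=sum(r.support for r in present), degenerate=False, **vals
    )


@dataclass
class ClassReport:
    """Per-class metrics plus macro and support-weighted averages."""

    per_class: dict[WMHClass, MetricsReport]
    macro_average: MetricsReport
    weighted_average: MetricsReport
    absent_classes: tuple[WMHClass, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: one row per class, then the two average rows.

        Columns follow the conventional report order: DSC, Precision,
        Sensitivity, Specificity, Accuracy, Support.
        """
        rows, index = [], []
        for cls, rep in self.per_class.items():
            rows.append(rep)
            index.append(cls.name)
        rows += [self.macro_average, self.weighted_average]
        index += ["macro avg", "weighted avg"]
        data = {
            "DSC": [r.dsc for r in rows],
            "Precision": [r.precision for r in rows],
            "Sensitivity": [r.recall for r in rows],
            "Specificity": [r.specificity for r in rows],
            "Accuracy": [r.accuracy for r in rows],
            "Support": [r.support for r in rows],
        }
        return pd.DataFrame(data, index=index)

    def summary(self) -> str:
        return self.to_frame().to_string(float_format=lambda v: f"{v:.4f}")


def class_report(
    labels_pred: LabeledLesionMap,
    labels_truth: LabeledLesionMap,
    *,
    roi: BinaryMask | None = None,
) -> ClassReport:
    """One-vs-rest pixel metrics for each WMH class.

    A class absent from the truth map is excluded from the per-class
    table (support 0) and listed in ``absent_classes``.  ``roi``
    restricts evaluation (including true negatives) to a region mask.
    """
    p, t = labels_pred.label_pixels, labels_truth.label_pixels
    if p.shape != t.shape:
        raise ValueError(f"label grid shapes differ: {p.shape} vs {t.shape}")
    if roi is not None:
        sel = roi.pixels
        p, t = p[sel], t[sel]
    per_class: dict[WMHClass, MetricsReport] = {}
    absent: list[WMHClass] = []
    for cls in WMHClass:
        truth_c = t == int(cls)
        if not truth_c.any():
            absent.append(cls)
            continue
        pred_c = p == int(cls)
        c = ConfusionCounts(
            tp=int(np.sum(pred_c & truth_c)),
            fp=int(np.sum(pred_c & ~truth_c)),
            fn=int(np.sum(~pred_c & truth_c)),
            tn=int(np.sum(~pred_c & ~truth_c)),
        )
        per_class[cls] = compute_metrics(c)
    return ClassReport(
        per_class=per_class,
        macro_average=_average(per_class, weighted=False),
        weighted_average=_average(per_class, weighted=True),
        absent_classes=tuple(absent),
    )
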