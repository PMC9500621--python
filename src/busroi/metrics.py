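"""Pixel-overlap evaluation of predicted ROIs against gold-standard ROIs.

A prediction counts as a *detection* when its box shares at least one pixel
with the gold box.  Detected predictions are scored by pixel-overlap
precision, recall and F1:

    precision = |gold ∩ pred| / |pred|
    recall    = |gold ∩ pred| / |gold|
    F1        = 2 P R / (P + R)          (0 when P + R = 0)

Summaries report the detection rate over *all* images of a group and the
mean ± sample standard deviation of P/R/F1 over the *detected* images only,
for the benign, malignant and pooled groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from .boxes import Box, box_area, intersect, overlaps

__all__ = [
    "EvalRecord",
    "MetricsSummary",
    "roi_metrics",
    "detection_rate",
    "aggregate",
    "GROUPS",
]

ClassLabel = Literal["benign", "malignant"]
Group = Literal["benign", "malignant", "all"]

GROUPS: tuple[Group, ...] = ("benign", "malignant", "all")


def roi_metrics(gold: Box, pred: Box) -> tuple[float, float, float]:
    """Pixel-overlap (precision, recall, F1) of a predicted box vs gold."""
    inter = intersect(gold, pred)
    n_overlap = box_area(inter) if inter is not None else 0
    precision = n_overlap / box_area(pred)
    recall = n_overlap / box_area(gold)
    if precision + recall == 0.0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f1


@dataclass(frozen=True)
class EvalRecord:
    """One image's evaluation: gold box, optional prediction, P/R/F1 if detected."""

    image_id: str
    class_label: ClassLabel
    gold: Box
    predicted: Optional[Box]
    precision: Optional[float] = None
    recall: Optional[float] = None
    f1: Optional[float] = None

    @classmethod
    def from_boxes(
        cls,
        image_id: str,
        class_label: ClassLabel,
        gold: Box,
        predicted: Optional[Box],
    ) -> "EvalRecord":
        """Build a record, computing metrics when the prediction overlaps gold."""
        if class_label not in ("benign", "malignant"):
            raise ValueError(f"unknown class label {class_label!r}")
        if predicted is not None and overlaps(gold, predicted):
            p, r, f1 = roi_metrics(gold, predicted)
            return cls(image_id, class_label, gold, predicted, p, r, f1)
        return cls(image_id, class_label, gold, predicted)

    @property
    def detected(self) -> bool:
        return self.precision is not None


@dataclass(frozen=True)
class MetricsSummary:
    """Detection rate and mean±SD of P/R/F1 for one image group."""

    group: Group
    n_images: int
    n_detected: int
    detection_rate: float
    precision_mean: Optional[float]
    precision_sd: Optional[float]
    recall_mean: Optional[float]
    recall_sd: Optional[float]
    f1_mean: Optional[float]
    f1_sd: Optional[float]


def detection_rate(records: Sequence[EvalRecord]) -> float:
    """Percentage of records whose prediction overlaps the gold box."""
    if not records:
        raise ValueError("detection_rate() requires at least one record")
    return 100.0 * sum(r.detected for r in records) / len(records)


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def aggregate(records: Sequence[EvalRecord], group: Group) -> MetricsSummary:
    """Summarize one group: detection rate over all its images, stats over detected.

    Means and sample standard deviations (n−1 denominator) cover only images
    where the method detected the tumor; undetected images lower the detection
    rate but do not enter the P/R/F1 statistics.  A group with zero images is
    an error; zero detections yields a summary with undefined (None) means.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    subset = [r for r in records if group == "all" or r.class_label == group]
    if not subset:
        raise ValueError(f"no records in group {group!r}")
    detected = [r for r in subset if r.detected]
    rate = 100.0 * len(detected) / len(subset)
    if not detected:
        return MetricsSummary(group, len(subset), 0, rate, *([None] * 6))
    p_mean, p_sd = _mean_sd([r.precision for r in detected])
    r_mean, r_sd = _mean_sd([r.recall for r in detected])
    f_mean, f_sd = _mean_sd([r.f1 for r in detected])
    return MetricsSummary(
        group=group,
        n_images=len(subset),
        n_detected=len(detected),
        detection_rate=rate,
        precision_mean=p_mean,
        precision_sd=p_sd,
        recall_mean=r_mean,
        recall_sd=r_sd,
        f1_mean=f_mean,
        f1_sd=f_sd,
    )
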