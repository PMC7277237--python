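"""Segmentation evaluation: pixel-wise IoU, precision, recall, Hausdorff.

Metric definitions (pixel-wise, per tooth instance):

    IoU       = TP / (TP + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)

An IoU of 1 is a perfect segmentation. The Hausdorff distance is computed
between the boundary pixel sets of the two masks (symmetric by default:
the larger of the two directed max-min Euclidean distances, in pixels).
Undefined metrics (zero denominator) are reported as NaN with a warning so
batch evaluation continues.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff

from .annotations_io import BinaryMask, Scene, mask_to_boundary
from .errors import EmptyMaskError, ShapeMismatchError

__all__ = [
    "ConfusionCounts",
    "SegScore",
    "confusion_counts",
    "iou",
    "precision",
    "recall",
    "hausdorff",
    "score_instance",
    "score_scene",
    "SceneScore",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-wise confusion counts for one predicted/reference mask pair."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class SegScore:
    """Derived per-instance segmentation scores."""

    iou: float
    precision: float
    recall: float
    hausdorff_px: float


def confusion_counts(pred: BinaryMask, ref: BinaryMask) -> ConfusionCounts:
    """Pixel-wise cross-tabulation of a prediction against a reference."""
    if pred.pixels.shape != ref.pixels.shape:
        raise ShapeMismatchError(
            f"mask shapes differ: {pred.pixels.shape} vs {ref.pixels.shape}"
        )
    p, r = pred.pixels, ref.pixels
    return ConfusionCounts(
        tp=int((p & r).sum()),
        fp=int((p & ~r).sum()),
        fn=int((~p & r).sum()),
        tn=int((~p & ~r).sum()),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
        return float("nan")
    return num / den


def iou(counts: ConfusionCounts) -> float:
    """Intersection over union, TP/(TP+FP+FN)."""
    return _ratio(counts.tp, counts.tp + counts.fp + counts.fn, "IoU")


def precision(counts: ConfusionCounts) -> float:
    """TP/(TP+FP)."""
    return _ratio(counts.tp, counts.tp + counts.fp, "precision")


def recall(counts: ConfusionCounts) -> float:
    """TP/(TP+FN)."""
    return _ratio(counts.tp, counts.tp + counts.fn, "recall")


def hausdorff(pred: BinaryMask, ref: BinaryMask, directed: bool = False) -> float:
    """Hausdorff distance (pixels) between the two mask boundaries.

    Symmetric by default: max of the two directed max-min Euclidean
    distances between boundary pixel sets. ``directed=True`` returns only
    the prediction-to-reference direction.
    """
    if pred.is_empty() or ref.is_empty():
        raise EmptyMaskError("Hausdorff distance needs two non-empty masks")
    bp = mask_to_boundary(pred)
    br = mask_to_boundary(ref)
    d_pr = directed_hausdorff(bp, br)[0]
    if directed:
        return float(d_pr)
    d_rp = directed_hausdorff(br, bp)[0]
    return float(max(d_pr, d_rp))


def score_instance(pred: BinaryMask, ref: BinaryMask) -> SegScore:
    """All four metrics for one mask pair."""
    counts = confusion_counts(pred, ref)
    return SegScore(
        iou=iou(counts),
        precision=precision(counts),
        recall=recall(counts),
        hausdorff_px=hausdorff(pred, ref),
    )


@dataclass
class SceneScore:
    """Per-tooth scores, per-position/overall means, and unmatched teeth."""

    per_tooth: pd.DataFrame
    summary: pd.DataFrame
    missing_in_pred: list[int]
    missing_in_ref: list[int]


def score_scene(pred: Scene, ref: Scene) -> SceneScore:
    """Score every reference tooth against the matching predicted tooth.

    Teeth are matched by FDI code. Reference teeth without a prediction are
    listed under ``missing_in_pred`` and excluded from the means (the
    summary carries the instance counts). The summary groups means by molar
    position (M1/M2/M3) with an overall row.
    """
    if (pred.image_height, pred.image_width) != (ref.image_height, ref.image_width):
        raise ShapeMismatchError(
            f"scene dimensions differ: "
            f"{(pred.image_height, pred.image_width)} vs "
            f"{(ref.image_height, ref.image_width)}"
        )
    rows = []
    missing_in_pred = []
    for ref_inst in ref.instances:
        fdi = ref_inst.label.fdi_code
        pred_inst = pred.get(fdi)
        if pred_inst is None:
            missing_in_pred.append(fdi)
            continue
        score = score_instance(pred_inst.mask, ref_inst.mask)
        rows.append(
            {
                "image_id": ref.image_id,
                "fdi": fdi,
                "position": ref_inst.label.position.value,
                "iou": score.iou,
                "precision": score.precision,
                "recall": score.recall,
                "hausdorff_px": score.hausdorff_px,
            }
        )
    ref_codes = {i.label.fdi_code for i in ref.instances}
    missing_in_ref = sorted(
        i.label.fdi_code for i in pred.instances if i.label.fdi_code not in ref_codes
    )
    per_tooth = pd.DataFrame(
        rows,
        columns=[
            "image_id",
            "fdi",
            "position",
            "iou",
            "precision",
            "recall",
            "hausdorff_px",
        ],
    )
    metric_cols = ["iou", "precision", "recall", "hausdorff_px"]
    if len(per_tooth):
        by_pos = per_tooth.groupby("position")[metric_cols].mean()
        by_pos["n"] = per_tooth.groupby("position").size()
        overall = per_tooth[metric_cols].mean().to_frame().T
        overall["n"] = len(per_tooth)
        overall.index = ["overall"]
        summary = pd.concat([by_pos, overall])
    else:
        summary = pd.DataFrame(columns=metric_cols + ["n"])
    return SceneScore(
        per_tooth=per_tooth,
        summary=summary,
        missing_in_pred=missing_in_pred,
        missing_in_ref=missing_in_ref,
    )
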