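"""Mask-overlap metrics and statistical comparison of segmentation methods.

IoU, Dice and pixel accuracy score a predicted mask against ground truth;
methods are compared with one-way ANOVA (+ eta^2 effect size), Bonferroni
family adjustment, and a Tukey HSD letter display. Failed segmentations
carry no overlap scores — they are excluded from the metric means and
surface instead through each method's success rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import compare_groups
from .depth_io import ValidationError

__all__ = ["EvalRow", "iou", "dice", "pixel_accuracy", "evaluate_mask", "compare_methods"]

logger = logging.getLogger(__name__)

METRICS = ("iou", "dice", "pixel_accuracy")


@dataclass(frozen=True)
class EvalRow:
    """Overlap scores of one method on one frame; scores absent on failure."""

    frame_id: str
    method: str
    success: bool
    iou: float | None = None
    dice: float | None = None
    pixel_accuracy: float | None = None


def _check_pair(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValidationError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    return pred, truth


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union; 1.0 when both masks are empty."""
    pred, truth = _check_pair(pred, truth)
    union = np.logical_or(pred, truth).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pred, truth).sum() / union)


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice coefficient 2|A.B| / (|A|+|B|); 1.0 when both masks are empty."""
    pred, truth = _check_pair(pred, truth)
    total = pred.sum() + truth.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, truth).sum() / total)


def pixel_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of pixels classified correctly (foreground and background)."""
    pred, truth = _check_pair(pred, truth)
    return float((pred == truth).mean())


def evaluate_mask(
    pred: np.ndarray | None, truth: np.ndarray, frame_id: str, method: str
) -> EvalRow:
    """Score one frame; a None prediction records a failure row."""
    if pred is None:
        return EvalRow(frame_id=frame_id, method=method, success=False)
    return EvalRow(
        frame_id=frame_id,
        method=method,
        success=True,
        iou=iou(pred, truth),
        dice=dice(pred, truth),
        pixel_accuracy=pixel_accuracy(pred, truth),
    )


def compare_methods(rows: list[EvalRow] | pd.DataFrame, family_size: int) -> dict:
    """Compare segmentation methods over a set of scored frames.

    Per metric: one-way ANOVA across methods on the successful frames,
    eta^2, Bonferroni-adjusted p (``family_size`` is explicit — the family
    definition is a reporting choice, not something to infer), and Tukey
    letters. Per method: mean +/- SD per metric and the success rate.
    Methods with fewer than 2 successful frames are excluded with a
    warning.
    """
    if isinstance(rows, list):
        table = pd.DataFrame([r.__dict__ for r in rows])
    else:
        table = rows.copy()
    if table["method"].nunique() < 2:
        raise ValidationError("need at least 2 methods to compare")

    success_rate = table.groupby("method")["success"].mean().to_dict()
    ok = table[table["success"]]
    usable = ok.groupby("method").size()
    dropped = [m for m in table["method"].unique() if usable.get(m, 0) < 2]
    for m in dropped:
        logger.warning("method %r has <2 successful frames; excluded from ANOVA", m)
    ok = ok[~ok["method"].isin(dropped)]
    if ok["method"].nunique() < 2:
        raise ValidationError("fewer than 2 methods have enough successful frames")

    report: dict = {"success_rate": success_rate, "excluded": dropped, "metrics": {}}
    for metric in METRICS:
        groups = {m: g[metric].to_numpy(dtype=float) for m, g in ok.groupby("method")}
        report["metrics"][metric] = compare_groups(groups, family_size=family_size)
    return report
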