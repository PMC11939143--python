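"""Body metrics from a segmented contour and its depth map.

For each successfully segmented frame we measure: bounding-rectangle
width and length (px), filled contour area (px^2), average height above
the floor (mm), and volume (mm * px^2) — the sum of per-pixel heights
over the contour. Heights are camera height minus depth, clipped at 0;
missing depth readings inside the contour ("black pixels") are imputed
with the mean of the valid in-contour heights, so volume = average
height x area holds exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .depth_io import DepthScene, ValidationError
from .threshold_segmentation import SegmentationResult

__all__ = ["BodyMetrics", "MetricError", "height_map", "compute_metrics", "aggregate_median"]


class MetricError(ValueError):
    """The frame cannot yield usable metrics (e.g. depth entirely missing)."""


@dataclass(frozen=True)
class BodyMetrics:
    """Five body metrics for one frame, plus provenance."""

    width_px: float
    length_px: float
    contour_area_px2: float
    avg_height_mm: float
    volume_mm_px2: float
    frame_id: str = "frame"
    calf_id: str | None = None
    date: str | None = None

    def __post_init__(self) -> None:
        for name in ("width_px", "length_px", "contour_area_px2", "avg_height_mm", "volume_mm_px2"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.width_px > self.length_px:
            raise ValidationError("canonical orientation requires width_px <= length_px")


def height_map(scene: DepthScene, mask: np.ndarray) -> np.ndarray:
    """Per-pixel height above the floor (mm) inside the mask, imputed.

    height = camera_height - depth, clipped at 0 (sensor noise can dip
    below the floor plane). Missing in-mask readings (depth 0) are
    replaced with the mean of the valid in-mask heights. Pixels outside
    the mask are returned as 0 and carry no meaning.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != scene.shape:
        raise ValidationError("mask shape does not match scene")
    if not mask.any():
        raise MetricError("empty mask")
    depth = scene.depth
    valid = mask & (depth > 0)
    if not valid.any():
        raise MetricError("all in-mask depth readings are missing")
    heights = np.zeros(scene.shape, dtype=float)
    heights[valid] = np.clip(scene.camera_height_mm - depth[valid], 0.0, None)
    mean_h = heights[valid].mean()
    heights[mask & ~valid] = mean_h
    return heights


def compute_metrics(scene: DepthScene, result: SegmentationResult) -> BodyMetrics:
    """Measure the five body metrics for a successfully segmented frame."""
    if not result.success:
        raise ValidationError(f"cannot compute metrics for status {result.status}")
    contour = result.contour
    mask = result.mask if result.mask is not None else contour.to_mask(scene.shape)
    heights = height_map(scene, mask)
    area = float(np.count_nonzero(mask))
    volume = float(heights[mask.astype(bool)].sum())
    side_a, side_b = contour.bbox_sides
    return BodyMetrics(
        width_px=float(side_a),
        length_px=float(side_b),
        contour_area_px2=area,
        avg_height_mm=volume / area,
        volume_mm_px2=volume,
        frame_id=scene.frame_id,
        calf_id=scene.calf_id,
        date=scene.capture_date,
    )


def aggregate_median(records: list[BodyMetrics] | pd.DataFrame) -> pd.DataFrame:
    """Per (calf_id, date) elementwise medians of the body metrics.

    Each calf contributes many frames per measurement date; the median of
    each metric over those frames is the calf-date value used downstream.
    Even group sizes take the mean of the two middle values.
    """
    if isinstance(records, pd.DataFrame):
        table = records.copy()
    else:
        table = pd.DataFrame([asdict(r) for r in records])
    if table.empty:
        raise ValidationError("no records to aggregate")
    if table["calf_id"].isna().any() or table["date"].isna().any():
        raise ValidationError("every record needs calf_id and date for aggregation")
    metric_cols = ["width_px", "length_px", "contour_area_px2", "avg_height_mm", "volume_mm_px2"]
    out = (
        table.groupby(["calf_id", "date"], sort=True)[metric_cols]
        .median()
        .reset_index()
    )
    return out
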