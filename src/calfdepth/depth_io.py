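"""Input/output for depth scenes, masks, polygon annotations and observation tables.

A *depth scene* pairs a colorized render (8-bit RGB, hue encodes distance)
with a depth map: an H x W matrix of camera-to-surface distances in
millimetres, where 0 marks a missing reading ("black pixel"). Depth maps
are stored as headerless comma-separated matrices, one CSV row per image
row; polygon annotations as JSON ``{"frame_id": ..., "vertices": [[r, c], ...]}``
with 0-based (row, col) vertices; observation tables as plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import shapely

__all__ = [
    "DepthScene",
    "PolygonAnnotation",
    "FormatError",
    "ValidationError",
    "read_depth_csv",
    "write_depth_csv",
    "read_scene",
    "write_scene",
    "polygons_to_mask",
    "read_annotations",
    "write_annotations",
    "read_observations",
    "validate_observations",
    "OBSERVATION_COLUMNS",
    "METRIC_COLUMNS",
]


class FormatError(ValueError):
    """A file does not conform to the documented on-disk format."""


class ValidationError(ValueError):
    """In-memory data violates a documented invariant."""


#: Required columns of a longitudinal observation table.
OBSERVATION_COLUMNS = ("calf_id", "date", "age_days", "bw_lb")

#: Body-metric columns carried alongside observations when present.
METRIC_COLUMNS = (
    "width_px",
    "length_px",
    "avg_height_mm",
    "volume_mm_px2",
    "contour_area_px2",
)


@dataclass
class DepthScene:
    """One dorsal frame: depth map (mm, 0 = missing) plus its color render.

    Parameters
    ----------
    depth
        H x W float array of distances in millimetres; 0 encodes a missing
        reading.
    color
        H x W x 3 uint8 RGB render of the same frame (hue encodes depth).
    frame_id
        Identifier of the frame within its recording.
    calf_id, capture_date
        Provenance, when known.
    camera_height_mm
        Mounting height of the camera above the floor plane.
    """

    depth: np.ndarray
    color: np.ndarray
    frame_id: str = "frame"
    calf_id: str | None = None
    capture_date: str | None = None
    camera_height_mm: float = 1510.0

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.color = np.asarray(self.color)
        if self.depth.ndim != 2:
            raise ValidationError("depth must be a 2-D matrix")
        if self.color.ndim != 3 or self.color.shape[2] != 3:
            raise ValidationError("color must be H x W x 3")
        if self.color.shape[:2] != self.depth.shape:
            raise ValidationError(
                f"color shape {self.color.shape[:2]} != depth shape {self.depth.shape}"
            )
        if np.any(self.depth < 0):
            raise ValidationError("depth values must be >= 0")
        if not self.camera_height_mm > 0:
            raise ValidationError("camera_height_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape


@dataclass
class PolygonAnnotation:
    """Ground-truth outline of one object as an ordered (row, col) polygon."""

    frame_id: str
    vertices: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError("vertices must be an N x 2 array of (row, col)")
        if len(self.vertices) < 3:
            raise ValidationError("a polygon needs at least 3 vertices")


def read_depth_csv(path: str | Path, missing_sentinel: float = 0.0) -> np.ndarray:
    """Read a headerless CSV depth map into an H x W matrix of millimetres.

    Cells equal to ``missing_sentinel`` are mapped to 0 (the internal
    missing-depth code). Ragged or non-numeric grids raise :class:`FormatError`.
    """
    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric cell on line {lineno}") from exc
    if not rows:
        raise FormatError(f"{path}: empty depth map")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")
    depth = np.asarray(rows, dtype=float)
    if missing_sentinel != 0.0:
        depth = np.where(depth == missing_sentinel, 0.0, depth)
    if np.any(depth < 0):
        raise FormatError(f"{path}: negative depth values")
    return depth


def write_depth_csv(depth: np.ndarray, path: str | Path) -> None:
    """Write a depth matrix in the same headerless CSV dialect we read."""
    depth = np.asarray(depth, dtype=float)
    if depth.ndim != 2:
        raise ValidationError("depth must be a 2-D matrix")
    np.savetxt(path, depth, fmt="%.10g", delimiter=",")


def read_scene(
    png_path: str | Path,
    csv_path: str | Path,
    frame_id: str | None = None,
    camera_height_mm: float = 1510.0,
    missing_sentinel: float = 0.0,
) -> DepthScene:
    """Load a paired color render + depth map from disk."""
    color = iio.imread(png_path)
    if color.ndim == 3 and color.shape[2] == 4:  # drop alpha
        color = color[:, :, :3]
    if color.ndim != 3:
        raise FormatError(f"{png_path}: expected a 3-channel color image")
    depth = read_depth_csv(csv_path, missing_sentinel=missing_sentinel)
    return DepthScene(
        depth=depth,
        color=color,
        frame_id=frame_id or Path(png_path).stem,
        camera_height_mm=camera_height_mm,
    )


def write_scene(scene: DepthScene, png_path: str | Path, csv_path: str | Path) -> None:
    iio.imwrite(png_path, scene.color.astype(np.uint8))
    write_depth_csv(scene.depth, csv_path)


def polygons_to_mask(
    annotations: Sequence[PolygonAnnotation], shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize polygon outlines into a solid filled {0,1} mask.

    The fill is inclusive: a pixel belongs to the mask iff its center lies
    inside or on the closed polygon. Multiple polygons are unioned. An
    empty annotation list yields an all-zero mask.
    """
    mask = np.zeros(shape, dtype=np.uint8)
    for ann in annotations:
        verts = ann.vertices
        if np.any(verts < 0) or np.any(verts[:, 0] > shape[0] - 1) or np.any(
            verts[:, 1] > shape[1] - 1
        ):
            raise ValidationError(
                f"annotation {ann.frame_id!r}: vertices outside image bounds {shape}"
            )
        poly = shapely.Polygon([(c, r) for r, c in verts])  # shapely is (x, y)
        shapely.prepare(poly)
        r0, r1 = int(np.floor(verts[:, 0].min())), int(np.ceil(verts[:, 0].max()))
        c0, c1 = int(np.floor(verts[:, 1].min())), int(np.ceil(verts[:, 1].max()))
        rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
        pts = shapely.points(np.column_stack([cc.ravel(), rr.ravel()]))
        covered = shapely.covers(poly, pts).reshape(rr.shape)
        mask[r0 : r1 + 1, c0 : c1 + 1][covered] = 1
    return mask


def read_annotations(path: str | Path) -> list[PolygonAnnotation]:
    """Read polygon annotations from JSON (a single object or a list)."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if isinstance(payload, dict):
        payload = [payload]
    out = []
    for item in payload:
        try:
            out.append(
                PolygonAnnotation(
                    frame_id=str(item["frame_id"]),
                    vertices=np.asarray(item["vertices"], dtype=float),
                )
            )
        except (KeyError, TypeError) as exc:
            raise FormatError(f"{path}: malformed annotation entry") from exc
    return out


def write_annotations(annotations: Sequence[PolygonAnnotation], path: str | Path) -> None:
    payload = [
        {"frame_id": a.frame_id, "vertices": np.asarray(a.vertices).tolist()}
        for a in annotations
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def validate_observations(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a longitudinal observation table.

    Requires :data:`OBSERVATION_COLUMNS`; rejects duplicate (calf_id, date)
    rows and negative ages or body weights. Returns a copy sorted by
    (calf_id, age_days).
    """
    missing = [c for c in OBSERVATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"observation table missing columns: {missing}")
    table = table.copy()
    table["calf_id"] = table["calf_id"].astype(str)
    table["age_days"] = pd.to_numeric(table["age_days"])
    table["bw_lb"] = pd.to_numeric(table["bw_lb"])
    dup = table.duplicated(subset=["calf_id", "date"])
    if dup.any():
        pairs = table.loc[dup, ["calf_id", "date"]].values.tolist()
        raise ValidationError(f"duplicate (calf_id, date) rows: {pairs[:5]}")
    if (table["age_days"] < 0).any():
        raise ValidationError("negative age_days")
    if (table["bw_lb"] < 0).any():
        raise ValidationError("negative bw_lb")
    return table.sort_values(["calf_id", "age_days"], kind="stable").reset_index(drop=True)


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read a calf observation CSV and validate it (see :func:`validate_observations`)."""
    return validate_observations(pd.read_csv(path))
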