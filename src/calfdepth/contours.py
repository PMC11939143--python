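"""Filled-region contours and moment-invariant shape matching.

A :class:`Contour` is the filled-region form of one detected object: a
boolean patch anchored at an offset in the source image, convertible to
and from a boundary polygon. Shape similarity uses the seven Hu moment
invariants of the filled region — invariant to translation, scale and
rotation — combined into the classic reciprocal-log dissimilarity where
0 means identical shapes and larger values mean less similar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .depth_io import PolygonAnnotation, ValidationError, polygons_to_mask

__all__ = ["Contour", "extract_contours", "hu_log_moments", "shape_score"]


@dataclass
class Contour:
    """One filled region, cropped to its bounding box.

    ``patch`` is a boolean array of the filled region; ``offset`` gives the
    (row, col) of ``patch[0, 0]`` in the source image.
    """

    patch: np.ndarray
    offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=bool)
        if self.patch.ndim != 2:
            raise ValidationError("contour patch must be 2-D")

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "Contour":
        """Build a contour from a full-frame binary mask (single region)."""
        mask = np.asarray(mask).astype(bool)
        rows, cols = np.nonzero(mask)
        if rows.size == 0:
            raise ValidationError("cannot build a contour from an empty mask")
        r0, r1 = rows.min(), rows.max()
        c0, c1 = cols.min(), cols.max()
        return cls(patch=mask[r0 : r1 + 1, c0 : c1 + 1], offset=(int(r0), int(c0)))

    @classmethod
    def from_polygon(cls, vertices: np.ndarray) -> "Contour":
        """Rasterize a (row, col) polygon into a filled contour (inclusive fill)."""
        vertices = np.asarray(vertices, dtype=float)
        if vertices.ndim != 2 or len(vertices) < 3:
            raise ValidationError("polygon needs >= 3 (row, col) vertices")
        r0 = int(np.floor(vertices[:, 0].min()))
        c0 = int(np.floor(vertices[:, 1].min()))
        local = vertices - [r0, c0]
        h = int(np.ceil(local[:, 0].max())) + 1
        w = int(np.ceil(local[:, 1].max())) + 1
        mask = polygons_to_mask([PolygonAnnotation("contour", local)], (h, w))
        return cls(patch=mask.astype(bool), offset=(r0, c0))

    # -- geometry --------------------------------------------------------
    @property
    def area(self) -> int:
        """Filled-region pixel count."""
        return int(self.patch.sum())

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """Axis-aligned bounding rectangle as (row, col, height, width)."""
        return (self.offset[0], self.offset[1], self.patch.shape[0], self.patch.shape[1])

    @property
    def bbox_sides(self) -> tuple[int, int]:
        """Bounding-rectangle sides, canonically (short, long)."""
        h, w = self.patch.shape
        return (min(h, w), max(h, w))

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Paint the filled region into a full-frame {0,1} mask."""
        r0, c0 = self.offset
        h, w = self.patch.shape
        if r0 < 0 or c0 < 0 or r0 + h > shape[0] or c0 + w > shape[1]:
            raise ValidationError(f"contour at {self.offset} does not fit in {shape}")
        mask = np.zeros(shape, dtype=np.uint8)
        mask[r0 : r0 + h, c0 : c0 + w][self.patch] = 1
        return mask

    def polygon(self) -> np.ndarray:
        """Boundary polygon (row, col) of the largest outline, in image coords."""
        padded = np.pad(self.patch.astype(float), 1)
        lines = measure.find_contours(padded, 0.5)
        if not lines:
            raise ValidationError("empty contour has no boundary")
        boundary = max(lines, key=len) - 1.0  # undo pad
        return boundary + np.asarray(self.offset, dtype=float)


def extract_contours(mask: np.ndarray, min_area: int = 1) -> list[Contour]:
    """Split a binary mask into per-connected-component filled contours.

    8-connectivity, matching the usual contour-tracing convention. Components
    smaller than ``min_area`` pixels are dropped.
    """
    labels = measure.label(np.asarray(mask).astype(bool), connectivity=2)
    out: list[Contour] = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        r0, c0, _, _ = region.bbox
        out.append(Contour(patch=region.image, offset=(int(r0), int(c0))))
    out.sort(key=lambda c: c.area, reverse=True)
    return out


def hu_log_moments(contour: Contour) -> np.ndarray:
    """Seven signed-log Hu invariants of the filled region.

    Returns ``sign(h) * log10(|h|)`` per invariant; invariants with
    magnitude below machine noise come back as NaN (carrying no shape
    information at this resolution).
    """
    img = contour.patch.astype(float)
    if img.sum() == 0:
        raise ValidationError("zero-area contour has no moments")
    mu = measure.moments_central(img)
    hu = measure.moments_hu(measure.moments_normalized(mu))
    # conventional cutoff: invariants this small are rasterization noise
    eps = 1e-5
    out = np.full(7, np.nan)
    ok = np.abs(hu) > eps
    out[ok] = np.sign(hu[ok]) * np.log10(np.abs(hu[ok]))
    return out


def shape_score(contour: Contour, template: Contour) -> float:
    """Moment-invariant dissimilarity between two filled contours.

    ``sum_i |1/m_i(A) - 1/m_i(B)|`` over the signed-log Hu invariants
    ``m_i``, skipping invariants that vanish for both shapes. 0 means
    identical shapes; degenerate (zero-area) inputs score +inf.
    """
    try:
        ma = hu_log_moments(contour)
        mb = hu_log_moments(template)
    except ValidationError:
        return float("inf")
    both = ~np.isnan(ma) & ~np.isnan(mb)
    either = ~np.isnan(ma) | ~np.isnan(mb)
    if not both.any():
        # no invariant is informative for both shapes: identical only if
        # neither shape has any, otherwise incomparable
        return 0.0 if not either.any() else float("inf")
    return float(np.sum(np.abs(1.0 / ma[both] - 1.0 / mb[both])))
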