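"""Coordinate conventions, instance geometry and overlap measures.

All coordinates are 0-based, half-open pixel indices with x = column and
y = row, origin at the top-left — the COCO convention.  A pixel (x, y)
covers the unit square [x, x+1) × [y, y+1), so polygon vertices exported
for COCO lie on pixel *corners* and a 10×10 pixel square has polygon area
exactly 100.

Two overlap measures are used throughout the pipeline:

* IoU, intersection over union — the detection-evaluation metric.
* IoS, intersection over the *smaller* area — the merge criterion used to
  fuse duplicate detections across tile borders (threshold 0.5) and, at a
  2 % threshold, the mask-overlap criterion of the clustering rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon, box as shapely_box
from shapely.ops import unary_union


class FrameMismatchError(ValueError):
    """Raised when geometry from different coordinate frames is combined."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box [x0, x1) × [y0, y1) in integer pixels.

    ``frame`` tags whether coordinates are relative to a tile or to the
    full image ("global"); operations refuse to mix frames.
    """

    x0: int
    y0: int
    x1: int
    y1: int
    frame: str = "global"

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"degenerate box {self}")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"negative origin in {self}")
        if self.frame not in ("tile", "global"):
            raise ValueError(f"unknown frame {self.frame!r}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def intersection(self, other: "BoundingBox") -> int:
        """Pixel count of the overlap of two boxes in the same frame."""
        if self.frame != other.frame:
            raise FrameMismatchError(
                f"cannot intersect {self.frame!r} box with {other.frame!r} box"
            )
        w = min(self.x1, other.x1) - max(self.x0, other.x0)
        h = min(self.y1, other.y1) - max(self.y0, other.y0)
        return max(w, 0) * max(h, 0)

    def shifted(self, dx: int, dy: int, frame: str | None = None) -> "BoundingBox":
        return BoundingBox(
            self.x0 + dx, self.y0 + dy, self.x1 + dx, self.y1 + dy,
            frame if frame is not None else self.frame,
        )

    def as_xywh(self) -> list[int]:
        return [self.x0, self.y0, self.width, self.height]


@dataclass
class InstanceMask:
    """Binary raster over its tight bounding box plus a global offset.

    ``pixels`` is a (height, width) boolean array; pixel ``pixels[r, c]``
    sits at image coordinates (x0 + c, y0 + r).
    """

    pixels: np.ndarray
    x0: int = 0
    y0: int = 0
    frame: str = "global"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or not self.pixels.any():
            raise ValueError("instance mask must be a non-empty 2-D raster")

    @classmethod
    def from_raster(
        cls, raster: np.ndarray, x0: int = 0, y0: int = 0, frame: str = "global"
    ) -> "InstanceMask":
        """Build a mask from any raster, cropping it to the tight box."""
        raster = np.asarray(raster, dtype=bool)
        rows = np.flatnonzero(raster.any(axis=1))
        cols = np.flatnonzero(raster.any(axis=0))
        if rows.size == 0:
            raise ValueError("empty raster")
        r0, r1 = rows[0], rows[-1] + 1
        c0, c1 = cols[0], cols[-1] + 1
        return cls(raster[r0:r1, c0:c1], x0 + int(c0), y0 + int(r0), frame)

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    @property
    def bbox(self) -> BoundingBox:
        h, w = self.pixels.shape
        return BoundingBox(self.x0, self.y0, self.x0 + w, self.y0 + h, self.frame)

    def shifted(self, dx: int, dy: int, frame: str | None = None) -> "InstanceMask":
        return InstanceMask(
            self.pixels, self.x0 + dx, self.y0 + dy,
            frame if frame is not None else self.frame,
        )

    def to_full(self, width: int, height: int) -> np.ndarray:
        """Paint the mask on a (height, width) canvas at its offset."""
        canvas = np.zeros((height, width), dtype=bool)
        h, w = self.pixels.shape
        canvas[self.y0 : self.y0 + h, self.x0 : self.x0 + w] = self.pixels
        return canvas

    def centroid(self) -> tuple[float, float]:
        """Center of mass (x, y) in global pixel-index coordinates."""
        rr, cc = np.nonzero(self.pixels)
        return float(cc.mean() + self.x0), float(rr.mean() + self.y0)


@dataclass
class Detection:
    """One predicted or annotated nucleus instance."""

    mask: InstanceMask
    score: float = 1.0
    instance_id: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def box(self) -> BoundingBox:
        return self.mask.bbox

    @property
    def frame(self) -> str:
        return self.mask.frame

    def shifted(self, dx: int, dy: int, frame: str | None = None) -> "Detection":
        return Detection(self.mask.shifted(dx, dy, frame), self.score, self.instance_id)


def iou_boxes(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint."""
    inter = a.intersection(b)
    union = a.area + b.area - inter
    return inter / union if union else 0.0


def _mask_intersection(a: InstanceMask, b: InstanceMask) -> int:
    if a.frame != b.frame:
        raise FrameMismatchError(
            f"cannot intersect {a.frame!r} mask with {b.frame!r} mask"
        )
    x0 = max(a.x0, b.x0)
    y0 = max(a.y0, b.y0)
    x1 = min(a.bbox.x1, b.bbox.x1)
    y1 = min(a.bbox.y1, b.bbox.y1)
    if x1 <= x0 or y1 <= y0:
        return 0
    sub_a = a.pixels[y0 - a.y0 : y1 - a.y0, x0 - a.x0 : x1 - a.x0]
    sub_b = b.pixels[y0 - b.y0 : y1 - b.y0, x0 - b.x0 : x1 - b.x0]
    return int(np.logical_and(sub_a, sub_b).sum())


def ios_masks(a: InstanceMask, b: InstanceMask) -> float:
    """Intersection over the smaller mask area.

    The merge criterion for duplicate detections across tile borders
    (threshold 0.5) and — at a 2 % threshold — the mask-overlap criterion
    of the nuclei-clustering rule.
    """
    return _mask_intersection(a, b) / min(a.area, b.area)


def iou_masks(a: InstanceMask, b: InstanceMask) -> float:
    """Pixel-wise intersection over union of two masks."""
    inter = _mask_intersection(a, b)
    union = a.area + b.area - inter
    return inter / union if union else 0.0


def merge_masks(a: InstanceMask, b: InstanceMask) -> InstanceMask:
    """Union of two masks as a single instance (frame must match)."""
    if a.frame != b.frame:
        raise FrameMismatchError("cannot merge masks from different frames")
    x0 = min(a.x0, b.x0)
    y0 = min(a.y0, b.y0)
    x1 = max(a.bbox.x1, b.bbox.x1)
    y1 = max(a.bbox.y1, b.bbox.y1)
    canvas = np.zeros((y1 - y0, x1 - x0), dtype=bool)
    for m in (a, b):
        h, w = m.pixels.shape
        canvas[m.y0 - y0 : m.y0 - y0 + h, m.x0 - x0 : m.x0 - x0 + w] |= m.pixels
    return InstanceMask(canvas, x0, y0, a.frame)


def _prune_collinear(coords: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Drop vertices lying on the segment between their neighbors."""
    pts = np.asarray(coords, dtype=float)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    keep = []
    n = len(pts)
    for i in range(n):
        prev_pt = pts[i - 1]
        cur = pts[i]
        nxt = pts[(i + 1) % n]
        cross = (cur[0] - prev_pt[0]) * (nxt[1] - prev_pt[1]) - (
            cur[1] - prev_pt[1]
        ) * (nxt[0] - prev_pt[0])
        if abs(cross) > tol:
            keep.append(i)
    return pts[keep] if keep else pts


def mask_to_polygons(mask: InstanceMask) -> list[list[float]]:
    """Convert a mask to COCO-style closed polygons on pixel corners.

    The polygon is the boundary of the union of the mask's pixel squares,
    so re-rasterization (pixel centers inside the polygon) reproduces the
    mask exactly.  Holes are dropped: only exterior rings are exported,
    since nuclei masks are effectively simply connected.

    Returns a list of flat ``[x1, y1, x2, y2, …]`` vertex lists in the
    mask's frame (global coordinates for global masks).
    """
    rr, cc = np.nonzero(mask.pixels)
    squares = [
        shapely_box(mask.x0 + x, mask.y0 + y, mask.x0 + x + 1, mask.y0 + y + 1)
        for y, x in zip(rr.tolist(), cc.tolist())
    ]
    merged = unary_union(squares)
    if isinstance(merged, Polygon):
        parts: Sequence[Polygon] = [merged]
    elif isinstance(merged, MultiPolygon):
        parts = list(merged.geoms)
    else:  # pragma: no cover - union of squares is always polygonal
        raise ValueError(f"unexpected union geometry {merged.geom_type}")
    polygons = []
    for part in parts:
        ring = _prune_collinear(np.asarray(part.exterior.coords))
        polygons.append([float(v) for pt in ring for v in pt])
    return polygons


def polygons_to_mask(
    polygons: Sequence[Sequence[float]],
    frame_width: int,
    frame_height: int,
    frame: str = "global",
) -> InstanceMask:
    """Rasterize COCO polygons: a pixel is set iff its center lies inside.

    The exact inverse of :func:`mask_to_polygons`.  Self-intersecting or
    zero-area polygons raise ``ValueError``.
    """
    canvas = np.zeros((frame_height, frame_width), dtype=bool)
    for flat in polygons:
        if len(flat) < 6:
            raise ValueError("polygon needs at least 3 vertices")
        pts = np.asarray(flat, dtype=float).reshape(-1, 2)
        poly = Polygon(pts)
        if not poly.is_valid:
            raise ValueError("self-intersecting polygon")
        if poly.area <= 0:
            raise ValueError("zero-area polygon")
        x0 = max(int(math.floor(poly.bounds[0])), 0)
        y0 = max(int(math.floor(poly.bounds[1])), 0)
        x1 = min(int(math.ceil(poly.bounds[2])), frame_width)
        y1 = min(int(math.ceil(poly.bounds[3])), frame_height)
        if x1 <= x0 or y1 <= y0:
            continue
        xs, ys = np.meshgrid(
            np.arange(x0, x1) + 0.5, np.arange(y0, y1) + 0.5
        )
        inside = shapely.contains_xy(poly, xs.ravel(), ys.ravel())
        canvas[y0:y1, x0:x1] |= inside.reshape(y1 - y0, x1 - x0)
    return InstanceMask.from_raster(canvas, frame=frame)


def equivalent_radius(area: float) -> float:
    """Radius of the circle with the given area: sqrt(area / π).

    The notion of "nucleus radius" used by the adaptive clustering
    distance; well defined for arbitrarily shaped nuclei.
    """
    if area < 1:
        raise ValueError(f"area must be >= 1 pixel, got {area}")
    return math.sqrt(area / math.pi)


def iter_mask_pixels(mask: InstanceMask) -> Iterator[tuple[int, int]]:
    """Yield global (x, y) coordinates of every foreground pixel."""
    rr, cc = np.nonzero(mask.pixels)
    for r, c in zip(rr.tolist(), cc.tolist()):
        yield mask.x0 + c, mask.y0 + r
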