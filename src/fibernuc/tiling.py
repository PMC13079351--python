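"""Deterministic slicing of full-scale images into overlapping tiles.

A 2,048 × 2,048 px image sliced into 400 × 400 px tiles with 20 %
fractional overlap (an 80 px band shared between neighbors) yields a
7 × 7 = 49-tile grid: the stride is 320 px and the last tile of each row
and column is shifted back so it ends exactly at the image border —
tiles are never padded and never partial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import BoundingBox, Detection, InstanceMask
from .io_formats import CocoAnnotation, CocoDataset, CocoImage, annotation_to_detection, detection_to_annotation


@dataclass(frozen=True)
class TileRect:
    """One tile of a grid: its row-major index and global-frame rectangle."""

    index: int
    rect: BoundingBox
    is_boundary_shifted: bool = False


@dataclass
class TileGrid:
    width: int
    height: int
    tile_size: int = 400
    overlap_fraction: float = 0.2
    tiles: list[TileRect] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tiles)

    @property
    def overlap_px(self) -> int:
        """Nominal overlap between adjacent tiles in pixels."""
        return self.tile_size - _stride(self.tile_size, self.overlap_fraction)


def _stride(tile_size: int, overlap_fraction: float) -> int:
    return int(round(tile_size * (1.0 - overlap_fraction)))


def _starts(extent: int, tile_size: int, stride: int) -> list[int]:
    starts: list[int] = []
    pos = 0
    while True:
        if pos + tile_size > extent:
            final = extent - tile_size
            if final not in starts:
                starts.append(final)
            break
        starts.append(pos)
        if pos + tile_size == extent:
            break
        pos += stride
    return starts


def compute_tile_grid(
    width: int,
    height: int,
    tile_size: int = 400,
    overlap_fraction: float = 0.2,
) -> TileGrid:
    """Compute the deterministic row-major tile grid covering an image.

    Tile starts advance by ``stride = round(tile_size·(1−overlap))``; when
    the next tile would overrun the image, one final tile is emitted
    flush with the border instead.  Raises when a tile cannot fit.
    """
    if tile_size > min(width, height):
        raise ValueError(
            f"tile size {tile_size} exceeds image extent {width}×{height}"
        )
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError(f"overlap fraction {overlap_fraction} outside [0, 1)")
    stride = _stride(tile_size, overlap_fraction)
    xs = _starts(width, tile_size, stride)
    ys = _starts(height, tile_size, stride)
    nominal_x = set(range(0, width, stride))
    nominal_y = set(range(0, height, stride))
    tiles = []
    for iy, y in enumerate(ys):
        for ix, x in enumerate(xs):
            tiles.append(
                TileRect(
                    index=iy * len(xs) + ix,
                    rect=BoundingBox(x, y, x + tile_size, y + tile_size, "global"),
                    is_boundary_shifted=(x not in nominal_x) or (y not in nominal_y),
                )
            )
    return TileGrid(width, height, tile_size, overlap_fraction, tiles)


def slice_image(
    image: np.ndarray, grid: TileGrid
) -> list[tuple[TileRect, np.ndarray]]:
    """Crop every tile of the grid out of the image (exact views)."""
    if image.shape[0] != grid.height or image.shape[1] != grid.width:
        raise ValueError(
            f"image shape {image.shape[:2]} does not match grid "
            f"{grid.height}×{grid.width}"
        )
    return [
        (t, image[t.rect.y0 : t.rect.y1, t.rect.x0 : t.rect.x1])
        for t in grid.tiles
    ]


def _clip_detection(det: Detection, rect: BoundingBox) -> Detection | None:
    """Clip a global-frame detection into a tile; None if no overlap."""
    b = det.box
    x0 = max(b.x0, rect.x0)
    y0 = max(b.y0, rect.y0)
    x1 = min(b.x1, rect.x1)
    y1 = min(b.y1, rect.y1)
    if x1 <= x0 or y1 <= y0:
        return None
    sub = det.mask.pixels[
        y0 - det.mask.y0 : y1 - det.mask.y0, x0 - det.mask.x0 : x1 - det.mask.x0
    ]
    if not sub.any():
        return None
    mask = InstanceMask.from_raster(sub, x0 - rect.x0, y0 - rect.y0, frame="tile")
    return Detection(mask, det.score, det.instance_id)


def slice_annotations(
    dataset: CocoDataset,
    tile_size: int = 400,
    overlap_fraction: float = 0.2,
    min_visible_fraction: float = 0.1,
) -> CocoDataset:
    """Slice a full-scale annotated dataset into per-tile datasets.

    Each instance is geometrically clipped into every tile it intersects;
    clips retaining less than ``min_visible_fraction`` of the original
    instance area are dropped.  Tile images are named
    ``<original>#tile<index>`` and annotations are in tile-frame
    coordinates.
    """
    tile_images: list[CocoImage] = []
    tile_annotations: list[CocoAnnotation] = []
    next_image_id = 1
    next_ann_id = 1
    for img in dataset.images:
        grid = compute_tile_grid(img.width, img.height, tile_size, overlap_fraction)
        dets = [
            annotation_to_detection(a, img.width, img.height)
            for a in dataset.annotations_for(img.id)
        ]
        for tile in grid.tiles:
            tile_img_id = next_image_id
            next_image_id += 1
            tile_images.append(
                CocoImage(
                    id=tile_img_id,
                    file_name=f"{img.file_name}#tile{tile.index}",
                    width=tile_size,
                    height=tile_size,
                )
            )
            for det in dets:
                clipped = _clip_detection(det, tile.rect)
                if clipped is None:
                    continue
                if clipped.mask.area / det.mask.area < min_visible_fraction:
                    continue
                ann = detection_to_annotation(clipped, next_ann_id, tile_img_id)
                next_ann_id += 1
                tile_annotations.append(ann)
    return CocoDataset(images=tile_images, annotations=tile_annotations)


def to_global(
    detections: Sequence[Detection], tile: TileRect
) -> list[Detection]:
    """Shift tile-frame detections into the global image frame."""
    out = []
    for det in detections:
        if det.box.x1 > tile.rect.width or det.box.y1 > tile.rect.height:
            raise ValueError(
                f"detection {det.instance_id} exceeds tile extent"
            )
        out.append(det.shifted(tile.rect.x0, tile.rect.y0, frame="global"))
    return out
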