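"""External representations: COCO JSON, TIFF/PNG images, CSV reports, crops.

The COCO dialect written here is the one CVAT imports: polygon
segmentations as flat ``[x1, y1, x2, y2, …]`` float lists, bounding boxes
as ``[x, y, width, height]``, a single category ``"nucleus"``.  RLE-only
segmentations are rejected with an error naming the offending annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .geometry import Detection, InstanceMask, mask_to_polygons, polygons_to_mask

NUCLEUS_CATEGORY = {"id": 1, "name": "nucleus", "supercategory": ""}

_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


class CocoFormatError(ValueError):
    """Raised for structurally invalid COCO data."""


@dataclass(frozen=True)
class CocoImage:
    id: int
    file_name: str
    width: int
    height: int


@dataclass
class CocoAnnotation:
    id: int
    image_id: int
    segmentation: list[list[float]]
    bbox: list[float]  # [x, y, w, h]
    area: float
    category_id: int = 1
    score: float | None = None


@dataclass
class CocoDataset:
    """Images plus polygonal instance annotations of the single category."""

    images: list[CocoImage] = field(default_factory=list)
    annotations: list[CocoAnnotation] = field(default_factory=list)
    categories: list[dict] = field(default_factory=lambda: [dict(NUCLEUS_CATEGORY)])

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        image_ids = {img.id for img in self.images}
        if len(image_ids) != len(self.images):
            raise CocoFormatError("duplicate image ids")
        for ann in self.annotations:
            if ann.image_id not in image_ids:
                raise CocoFormatError(
                    f"annotation {ann.id} references missing image id {ann.image_id}"
                )
            if not isinstance(ann.segmentation, list) or not all(
                isinstance(p, list) for p in ann.segmentation
            ):
                raise CocoFormatError(
                    f"annotation {ann.id}: only polygon segmentations are "
                    "supported (RLE is not)"
                )

    def image_by_id(self, image_id: int) -> CocoImage:
        for img in self.images:
            if img.id == image_id:
                return img
        raise CocoFormatError(f"no image with id {image_id}")

    def annotations_for(self, image_id: int) -> list[CocoAnnotation]:
        return [a for a in self.annotations if a.image_id == image_id]

    def to_dict(self) -> dict:
        return {
            "images": [
                {
                    "id": i.id,
                    "file_name": i.file_name,
                    "width": i.width,
                    "height": i.height,
                }
                for i in self.images
            ],
            "annotations": [
                {
                    "id": a.id,
                    "image_id": a.image_id,
                    "category_id": a.category_id,
                    "segmentation": [
                        [round(float(v), 2) for v in poly] for poly in a.segmentation
                    ],
                    "bbox": [round(float(v), 2) for v in a.bbox],
                    "area": round(float(a.area), 2),
                    "iscrowd": 0,
                    **({"score": round(float(a.score), 6)} if a.score is not None else {}),
                }
                for a in self.annotations
            ],
            "categories": self.categories,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CocoDataset":
        images = [
            CocoImage(
                id=int(i["id"]),
                file_name=str(i.get("file_name", "")),
                width=int(i["width"]),
                height=int(i["height"]),
            )
            for i in data.get("images", [])
        ]
        annotations = []
        for a in data.get("annotations", []):
            seg = a.get("segmentation", [])
            if isinstance(seg, dict) or (
                isinstance(seg, list) and seg and not isinstance(seg[0], list)
            ):
                raise CocoFormatError(
                    f"annotation {a.get('id')}: RLE-only segmentation is unsupported"
                )
            annotations.append(
                CocoAnnotation(
                    id=int(a["id"]),
                    image_id=int(a["image_id"]),
                    segmentation=[[float(v) for v in poly] for poly in seg],
                    bbox=[float(v) for v in a.get("bbox", [0, 0, 0, 0])],
                    area=float(a.get("area", 0.0)),
                    category_id=int(a.get("category_id", 1)),
                    score=float(a["score"]) if "score" in a else None,
                )
            )
        categories = list(data.get("categories", [dict(NUCLEUS_CATEGORY)]))
        return cls(images=images, annotations=annotations, categories=categories)


def read_coco(path: str | Path) -> CocoDataset:
    """Read a COCO JSON file into a :class:`CocoDataset`."""
    with open(path) as fh:
        return CocoDataset.from_dict(json.load(fh))


def write_coco(dataset: CocoDataset, path: str | Path) -> None:
    """Write a dataset as CVAT-importable COCO JSON (2-decimal precision)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(dataset.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def detection_to_annotation(
    det: Detection, ann_id: int, image_id: int
) -> CocoAnnotation:
    box = det.box
    return CocoAnnotation(
        id=ann_id,
        image_id=image_id,
        segmentation=mask_to_polygons(det.mask),
        bbox=[float(box.x0), float(box.y0), float(box.width), float(box.height)],
        area=float(det.mask.area),
        score=det.score,
    )


def annotation_to_detection(
    ann: CocoAnnotation, frame_width: int, frame_height: int, frame: str = "global"
) -> Detection:
    mask = polygons_to_mask(ann.segmentation, frame_width, frame_height, frame=frame)
    return Detection(
        mask=mask,
        score=1.0 if ann.score is None else ann.score,
        instance_id=ann.id,
    )


def detections_to_coco(
    detections_per_image: Mapping[int, Sequence[Detection]],
    images: Sequence[CocoImage],
) -> CocoDataset:
    """Bundle per-image detections into one dataset, ids assigned by order."""
    annotations = []
    ann_id = 1
    for img in images:
        for det in detections_per_image.get(img.id, []):
            annotations.append(detection_to_annotation(det, ann_id, img.id))
            ann_id += 1
    return CocoDataset(images=list(images), annotations=annotations)


def coco_to_detections(dataset: CocoDataset) -> dict[int, list[Detection]]:
    """Convert every annotation back to a mask-backed :class:`Detection`."""
    out: dict[int, list[Detection]] = {img.id: [] for img in dataset.images}
    for img in dataset.images:
        for ann in dataset.annotations_for(img.id):
            out[img.id].append(annotation_to_detection(ann, img.width, img.height))
    return out


def load_image(path: str | Path, channel_policy: str = "blue") -> tuple[np.ndarray, int]:
    """Load a TIFF/PNG/JPEG image as a single grayscale channel.

    RGB inputs are reduced to one channel according to ``channel_policy``
    ("red" / "green" / "blue"); the blue channel is the default because
    DAPI fluorescence is imaged in blue.  Returns ``(image, bit_depth)``.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            img = tifffile.imread(path)
        else:
            img = iio.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    img = np.asarray(img)
    if img.ndim == 3:
        if channel_policy not in _CHANNEL_INDEX:
            raise ValueError(f"unknown channel policy {channel_policy!r}")
        img = img[..., _CHANNEL_INDEX[channel_policy]]
    elif img.ndim != 2:
        raise IOError(f"cannot interpret {path} as a 2-D image")
    depth = 16 if img.dtype == np.uint16 else 8
    return img, depth


def convert_16_to_8(image16: np.ndarray) -> np.ndarray:
    """Full-range linear 16-bit → 8-bit conversion: v8 = round(v16 / 257).

    Rounding is half-up so the mapping is monotone and surjective
    (0 → 0, 65535 → 255).  A linear transfer keeps mean intensities
    comparable across images, unlike per-image min–max stretching.
    """
    image16 = np.asarray(image16)
    if image16.dtype != np.uint16:
        raise ValueError(f"expected uint16 input, got {image16.dtype}")
    return np.floor(image16.astype(np.float64) / 257.0 + 0.5).astype(np.uint8)


def export_reports(
    summaries: pd.DataFrame | Sequence,
    clusters: pd.DataFrame | Sequence,
    records: pd.DataFrame | Sequence,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the three report tables as CSV with deterministic row order.

    ``image_summary.csv`` — one row per image; ``clusters.csv`` — one row
    per nuclei cluster; ``nuclei.csv`` — one row per nucleus.  Headers are
    written even for empty analyses.
    """
    from .analysis import cluster_frame, record_frame, summary_frame

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = {
        "image_summary.csv": summaries
        if isinstance(summaries, pd.DataFrame)
        else summary_frame(summaries),
        "clusters.csv": clusters
        if isinstance(clusters, pd.DataFrame)
        else cluster_frame(clusters),
        "nuclei.csv": records
        if isinstance(records, pd.DataFrame)
        else record_frame(records),
    }
    paths = {}
    for name, frame in frames.items():
        if len(frame):
            frame = frame.sort_values(list(frame.columns[:2]), kind="mergesort")
        path = out_dir / name
        frame.to_csv(path, index=False, lineterminator="\n")
        paths[name] = path
    return paths


def export_instance_crops(
    detections: Sequence[Detection],
    image: np.ndarray,
    out_dir: str | Path,
    margin: int = 8,
) -> Path:
    """Export each nucleus as a JPEG crop plus one COCO JSON indexing them.

    Crops are the detection's tight box grown by ``margin`` pixels and
    clipped to the image; files are named by nucleus id.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    height, width = image.shape[:2]
    images: list[CocoImage] = []
    annotations: list[CocoAnnotation] = []
    for det in detections:
        b = det.box
        x0 = max(b.x0 - margin, 0)
        y0 = max(b.y0 - margin, 0)
        x1 = min(b.x1 + margin, width)
        y1 = min(b.y1 + margin, height)
        crop = image[y0:y1, x0:x1]
        if crop.dtype == np.uint16:
            crop = convert_16_to_8(crop)
        name = f"nucleus_{det.instance_id:05d}.jpg"
        iio.imwrite(out_dir / name, np.ascontiguousarray(crop), quality=95)
        img_id = det.instance_id + 1
        images.append(CocoImage(id=img_id, file_name=name, width=x1 - x0, height=y1 - y0))
        local = det.shifted(-x0, -y0)
        annotations.append(
            detection_to_annotation(local, ann_id=det.instance_id + 1, image_id=img_id)
        )
    coco_path = out_dir / "crops_coco.json"
    write_coco(CocoDataset(images=images, annotations=annotations), coco_path)
    return coco_path
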