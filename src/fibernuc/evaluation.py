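"""Validation machinery: per-tile statistics, Mann–Whitney U, expert
deviation and average precision at IoU 0.50.

AP follows the COCO convention: predictions sorted by descending score
are greedily matched to the best still-unmatched ground-truth instance
with IoU ≥ 0.5; precision is interpolated at 101 recall points
{0, 0.01, …, 1} and averaged, reported on a 0–100 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .geometry import Detection, iou_boxes, iou_masks
from .io_formats import CocoDataset, coco_to_detections


@dataclass
class TileStats:
    """Per-tile ground-truth vs prediction counts and relative areas."""

    tile_id: int
    gt_count: int
    pred_count: int
    gt_relative_area: float
    pred_relative_area: float


def _relative_union_area(dets: Sequence[Detection], width: int, height: int) -> float:
    if not dets:
        return 0.0
    canvas = np.zeros((height, width), dtype=bool)
    for d in dets:
        h, w = d.mask.pixels.shape
        canvas[d.mask.y0 : d.mask.y0 + h, d.mask.x0 : d.mask.x0 + w] |= d.mask.pixels
    return float(canvas.sum()) / (width * height)


def per_tile_stats(
    pred: CocoDataset, gt: CocoDataset
) -> tuple[list[TileStats], dict[str, float]]:
    """Per-tile nuclei counts and union-of-mask relative areas.

    Both datasets must share image ids and extents.  Returns the per-tile
    rows plus a summary of mean and median of each column.
    """
    gt_images = {img.id: img for img in gt.images}
    for img in pred.images:
        if img.id not in gt_images:
            raise ValueError(f"prediction image id {img.id} missing from ground truth")
        ref = gt_images[img.id]
        if (img.width, img.height) != (ref.width, ref.height):
            raise ValueError(f"extent mismatch for image id {img.id}")
    pred_dets = coco_to_detections(pred)
    gt_dets = coco_to_detections(gt)
    rows = []
    for img in gt.images:
        g = gt_dets.get(img.id, [])
        p = pred_dets.get(img.id, [])
        rows.append(
            TileStats(
                tile_id=img.id,
                gt_count=len(g),
                pred_count=len(p),
                gt_relative_area=_relative_union_area(g, img.width, img.height),
                pred_relative_area=_relative_union_area(p, img.width, img.height),
            )
        )
    summary = {}
    for col in ("gt_count", "pred_count", "gt_relative_area", "pred_relative_area"):
        values = np.array([getattr(r, col) for r in rows], dtype=float)
        summary[f"mean_{col}"] = float(values.mean()) if len(values) else math.nan
        summary[f"median_{col}"] = float(np.median(values)) if len(values) else math.nan
    return rows, summary


def mann_whitney_u(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of sample_a, p).

    Small untied samples (both n ≤ 20) are evaluated exactly; larger or
    tied samples use the normal approximation with tie correction and
    continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def relative_deviation(predicted_count: float, reference_count: float) -> float:
    """Percent deviation from a reference count, to one decimal.

    Used against the median of independent expert counts:
    100·|predicted − reference| / reference.
    """
    if reference_count <= 0:
        raise ValueError("reference count must be positive")
    return round(100.0 * abs(predicted_count - reference_count) / reference_count, 1)


def _match_greedy(
    preds: Sequence[Detection],
    gts: Sequence[Detection],
    iou_threshold: float,
    match_on: str,
) -> list[bool]:
    """For score-sorted predictions of one image: True per pred if matched."""
    unmatched = list(range(len(gts)))
    flags = []
    for p in preds:
        best_j, best_val = -1, -1.0
        for j in unmatched:
            if match_on == "box":
                value = iou_boxes(p.box, gts[j].box)
            else:
                value = iou_masks(p.mask, gts[j].mask)
            if value >= iou_threshold and value > best_val:
                best_j, best_val = j, value
        if best_j >= 0:
            unmatched.remove(best_j)
            flags.append(True)
        else:
            flags.append(False)
    return flags


def ap_at_iou(
    preds: Mapping[int, Sequence[Detection]],
    gts: Mapping[int, Sequence[Detection]],
    iou_threshold: float = 0.5,
    match_on: str = "box",
) -> float | None:
    """Average precision at one IoU threshold, 0–100 scale.

    ``preds`` and ``gts`` map image id → detections.  Matching is greedy
    per image in score order against the highest-IoU unmatched ground
    truth; the precision–recall curve is pooled over images and
    101-point interpolated.  Returns None when there is no ground truth.
    """
    if match_on not in ("box", "mask"):
        raise ValueError(f"match_on must be 'box' or 'mask', got {match_on!r}")
    n_gt = sum(len(v) for v in gts.values())
    if n_gt == 0:
        return None
    entries: list[tuple[float, int, int, bool]] = []
    for image_id, dets in preds.items():
        dets_sorted = sorted(dets, key=lambda d: (-d.score, d.instance_id))
        flags = _match_greedy(
            dets_sorted, list(gts.get(image_id, [])), iou_threshold, match_on
        )
        for d, flag in zip(dets_sorted, flags):
            entries.append((-d.score, image_id, d.instance_id, flag))
    entries.sort(key=lambda e: e[:3])
    tp = fp = 0
    precisions, recalls = [], []
    for _, _, _, matched in entries:
        if matched:
            tp += 1
        else:
            fp += 1
        precisions.append(tp / (tp + fp))
        recalls.append(tp / n_gt)
    # 101-point interpolation: max precision at recall >= r
    precisions = np.array(precisions, dtype=float)
    recalls = np.array(recalls, dtype=float)
    ap = 0.0
    for r in np.linspace(0.0, 1.0, 101):
        mask = recalls >= r - 1e-12
        ap += float(precisions[mask].max()) if mask.any() else 0.0
    return 100.0 * ap / 101.0


def ap_from_coco(
    pred: CocoDataset,
    gt: CocoDataset,
    iou_threshold: float = 0.5,
    match_on: str = "box",
) -> float | None:
    """AP between two COCO datasets sharing image ids."""
    return ap_at_iou(
        coco_to_detections(pred), coco_to_detections(gt), iou_threshold, match_on
    )
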