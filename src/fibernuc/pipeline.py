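"""Orchestration: image → tiles → detect → fuse → analyze → reports.

``run_pipeline`` executes the full chain deterministically for a fixed
config and logs per-image instance counts at every fusion stage
(detected → after score filter → after NMS → after NMM), which are
monotonically non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .analysis import Cluster, ImageSummary, NucleusRecord, analyze_detections
from .config import PipelineConfig
from .evaluation import (
    ap_from_coco,
    mann_whitney_u,
    per_tile_stats,
    relative_deviation,
)
from .fusion import FusionConfig, get_backend, reconstruct_predictions
from .geometry import Detection
from .io_formats import (
    CocoDataset,
    CocoImage,
    convert_16_to_8,
    detections_to_coco,
    export_reports,
    load_image,
    write_coco,
)
from .tiling import compute_tile_grid, slice_image

logger = logging.getLogger("fibernuc")


@dataclass
class ImageResult:
    """Everything the pipeline produced for one image."""

    image_id: int
    name: str
    detections: list[Detection]
    records: list[NucleusRecord]
    clusters: list[Cluster]
    summary: ImageSummary
    stage_counts: dict


def _resolve_score_threshold(config: PipelineConfig, backend) -> float:
    if config.fusion.score_threshold is not None:
        return config.fusion.score_threshold
    return getattr(backend, "default_score_threshold", 0.98)


def process_image(
    image: np.ndarray,
    config: PipelineConfig,
    backend=None,
    image_id: int = 1,
    name: str = "image",
) -> ImageResult:
    """Run tiling, detection, fusion and analysis on one loaded image."""
    backend = backend or get_backend(config.backend)
    if image.dtype == np.uint16:
        image = convert_16_to_8(image)
    height, width = image.shape[:2]
    grid = compute_tile_grid(
        width, height, config.tile_size, config.overlap_fraction
    )
    per_tile = [(tile, backend.detect(crop)) for tile, crop in slice_image(image, grid)]
    fusion_cfg = FusionConfig(
        score_threshold=_resolve_score_threshold(config, backend),
        nms_iou_threshold=config.fusion.nms_iou_threshold,
        nmm_ios_threshold=config.fusion.nmm_ios_threshold,
        nmm_single_pass=config.fusion.nmm_single_pass,
    )
    stage_counts: dict = {}
    detections = reconstruct_predictions(per_tile, grid, fusion_cfg, stage_counts)
    records, clusters, summary = analyze_detections(
        detections,
        image,
        vicinity_radius=config.clustering.vicinity_radius,
        overlap_threshold=config.clustering.overlap_threshold,
        alpha=config.clustering.alpha,
        beta=config.clustering.beta,
        image_id=image_id,
    )
    logger.info(
        "image=%s detected=%d after_filter=%d after_nms=%d after_nmm=%d",
        name,
        stage_counts["detected"],
        stage_counts["after_filter"],
        stage_counts["after_nms"],
        stage_counts["after_nmm"],
    )
    return ImageResult(
        image_id=image_id,
        name=name,
        detections=detections,
        records=records,
        clusters=clusters,
        summary=summary,
        stage_counts=stage_counts,
    )


def run_pipeline(
    image_paths: list[str | Path],
    config: PipelineConfig,
    loaded_images: list[np.ndarray] | None = None,
) -> list[ImageResult]:
    """End-to-end run over images; writes reports and COCO predictions.

    ``loaded_images`` bypasses disk I/O (used by the `simulate`-then-run
    path and by tests); otherwise images are read from ``image_paths``.
    All validation happens before any output is written.
    """
    backend = get_backend(config.backend)
    out_dir = Path(config.output_dir)
    images: list[tuple[str, np.ndarray]] = []
    if loaded_images is not None:
        images = [(str(p), img) for p, img in zip(image_paths, loaded_images)]
    else:
        for path in image_paths:
            img, depth = load_image(path, config.channel_policy)
            images.append((Path(path).name, img))

    results: list[ImageResult] = []
    all_records: list[NucleusRecord] = []
    all_clusters: list[Cluster] = []
    summaries: list[ImageSummary] = []
    coco_images: list[CocoImage] = []
    dets_by_image: dict[int, list[Detection]] = {}
    for image_id, (name, img) in enumerate(images, start=1):
        result = process_image(img, config, backend, image_id, name)
        results.append(result)
        all_records.extend(result.records)
        all_clusters.extend(result.clusters)
        summaries.append(result.summary)
        h, w = img.shape[:2]
        coco_images.append(CocoImage(id=image_id, file_name=name, width=w, height=h))
        dets_by_image[image_id] = result.detections

    out_dir.mkdir(parents=True, exist_ok=True)
    export_reports(summaries, all_clusters, all_records, out_dir)
    write_coco(
        detections_to_coco(dets_by_image, coco_images), out_dir / "predictions.json"
    )
    config.save(out_dir / "config.yaml")
    return results


def run_compare(
    pred_sets: dict[str, CocoDataset],
    gt: CocoDataset,
    out_dir: str | Path | None = None,
) -> dict[str, dict]:
    """Compare prediction sets against expert ground truth.

    Per set: per-tile count/area statistics, pooled two-sided
    Mann–Whitney U tests on per-tile nuclei count and relative area, the
    percent deviation of the total count from the ground-truth total,
    and AP@0.5 on boxes and masks.
    """
    import pandas as pd

    results: dict[str, dict] = {}
    gt_total = len(gt.annotations)
    for name, pred in pred_sets.items():
        rows, summary = per_tile_stats(pred, gt)
        counts_gt = [r.gt_count for r in rows]
        counts_pred = [r.pred_count for r in rows]
        areas_gt = [r.gt_relative_area for r in rows]
        areas_pred = [r.pred_relative_area for r in rows]
        u_count, p_count = mann_whitney_u(counts_pred, counts_gt)
        u_area, p_area = mann_whitney_u(areas_pred, areas_gt)
        block = {
            "tile_stats": rows,
            "summary": summary,
            "mwu_count": {"U": u_count, "p": p_count},
            "mwu_area": {"U": u_area, "p": p_area},
            "count_deviation_pct": relative_deviation(sum(counts_pred), gt_total)
            if gt_total
            else None,
            "ap_box": ap_from_coco(pred, gt, match_on="box"),
            "ap_mask": ap_from_coco(pred, gt, match_on="mask"),
        }
        results[name] = block
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(
                [
                    {
                        "tile_id": r.tile_id,
                        "gt_count": r.gt_count,
                        "pred_count": r.pred_count,
                        "gt_relative_area": r.gt_relative_area,
                        "pred_relative_area": r.pred_relative_area,
                    }
                    for r in rows
                ]
            ).to_csv(out / f"tile_stats_{name}.csv", index=False, lineterminator="\n")
            pd.DataFrame(
                [
                    {
                        "metric": "count",
                        "U": u_count,
                        "p": p_count,
                        "ap_box": block["ap_box"],
                        "ap_mask": block["ap_mask"],
                        "deviation_pct": block["count_deviation_pct"],
                    },
                    {
                        "metric": "relative_area",
                        "U": u_area,
                        "p": p_area,
                        "ap_box": block["ap_box"],
                        "ap_mask": block["ap_mask"],
                        "deviation_pct": block["count_deviation_pct"],
                    },
                ]
            ).to_csv(out / f"evaluation_{name}.csv", index=False, lineterminator="\n")
    return results
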