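"""Fuse raw per-tile detections into one coherent set of global instances.

The reconstruction sequence mirrors sliced inference: per tile the raw
detections are filtered at the confidence threshold (detections scored
*below* the threshold are discarded, so an exact-threshold score is
kept) and deduplicated with greedy box NMS; all survivors are shifted to
the global frame; finally non-maximum merging (NMM) unions detections of
the same nucleus seen from adjacent tiles whenever their intersection
over the smaller mask (IoS) reaches the merge threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np

from .geometry import Detection, ios_masks, iou_boxes, merge_masks
from .tiling import TileGrid, TileRect, to_global


@runtime_checkable
class DetectorBackend(Protocol):
    """Contract every pluggable detector must honor.

    ``detect`` maps a grayscale tile to tile-frame detections with scores
    in [0, 1] and masks inside the tile extent, deterministically for a
    fixed input unless the backend declares otherwise.
    """

    name: str
    version: str
    default_score_threshold: float

    def detect(self, tile: np.ndarray) -> list[Detection]: ...


_BACKEND_REGISTRY: dict[str, Callable[[], DetectorBackend]] = {}


def register_backend(name: str, factory: Callable[[], DetectorBackend]) -> None:
    _BACKEND_REGISTRY[name] = factory


def get_backend(name: str) -> DetectorBackend:
    try:
        factory = _BACKEND_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"no detector backend {name!r}; registered: "
            f"{sorted(_BACKEND_REGISTRY)}"
        ) from None
    return factory()


def available_backends() -> list[str]:
    return sorted(_BACKEND_REGISTRY)


@dataclass
class FusionConfig:
    """Thresholds of the score-filter → NMS → NMM cascade.

    ``score_threshold`` defaults to 0.98, the operating point of the
    trained network backends; toy backends register a calibrated
    threshold of their own (resolved by the pipeline when
    ``score_threshold`` is None).
    """

    score_threshold: float | None = 0.98
    nms_iou_threshold: float = 0.5
    nmm_ios_threshold: float = 0.5
    nmm_single_pass: bool = False

    def __post_init__(self) -> None:
        for name in ("score_threshold", "nms_iou_threshold", "nmm_ios_threshold"):
            v = getattr(self, name)
            if v is not None and not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")


def filter_by_score(
    detections: Sequence[Detection], threshold: float
) -> list[Detection]:
    """Keep detections with score ≥ threshold, preserving order."""
    return [d for d in detections if d.score >= threshold]


def _score_order(detections: Sequence[Detection]) -> list[Detection]:
    return sorted(detections, key=lambda d: (-d.score, d.instance_id))


def nms(detections: Sequence[Detection], iou_threshold: float = 0.5) -> list[Detection]:
    """Greedy box non-maximum suppression.

    Detections are visited by descending score (ties: lower instance id
    first); one is suppressed when its box IoU with any already-kept
    detection exceeds the threshold.
    """
    kept: list[Detection] = []
    for det in _score_order(detections):
        if all(iou_boxes(det.box, k.box) <= iou_threshold for k in kept):
            kept.append(det)
    return kept


def nmm_merge(
    detections: Sequence[Detection],
    ios_threshold: float = 0.5,
    single_pass: bool = False,
) -> list[Detection]:
    """Greedy non-maximum merging of global-frame detections.

    Iterating by descending score, the current survivor absorbs every
    remaining detection whose mask IoS with it reaches ``ios_threshold``:
    the merged mask is the union, the score the maximum, the box the
    tight box of the union.  By default merged survivors are re-tested
    against the remaining candidates until stable, so chains of
    pairwise-overlapping fragments collapse into one instance;
    ``single_pass`` disables the re-test.  Output ids are sequential.
    """
    pending = _score_order(detections)
    survivors: list[Detection] = []
    while pending:
        current = pending.pop(0)
        if single_pass:
            # candidates are tested against the original seed mask only
            seed_mask = current.mask
            rest = []
            for cand in pending:
                if ios_masks(seed_mask, cand.mask) >= ios_threshold:
                    current = Detection(
                        merge_masks(current.mask, cand.mask),
                        max(current.score, cand.score),
                        current.instance_id,
                    )
                else:
                    rest.append(cand)
            pending = rest
        else:
            changed = True
            while changed:
                changed = False
                rest = []
                for cand in pending:
                    if ios_masks(current.mask, cand.mask) >= ios_threshold:
                        current = Detection(
                            merge_masks(current.mask, cand.mask),
                            max(current.score, cand.score),
                            current.instance_id,
                        )
                        changed = True
                    else:
                        rest.append(cand)
                pending = rest
        survivors.append(current)
    return [
        Detection(d.mask, d.score, i) for i, d in enumerate(survivors)
    ]


def reconstruct_predictions(
    per_tile_detections: Sequence[tuple[TileRect, Sequence[Detection]]],
    grid: TileGrid,
    config: FusionConfig | None = None,
    stage_counts: dict | None = None,
) -> list[Detection]:
    """Full-image reconstruction from per-tile detections.

    Per tile: score filter then box NMS; then shift to the global frame;
    then one NMM pass over all tiles merges duplicate predictions of
    nuclei that straddle tile borders.  The result is independent of
    tile processing order.  When ``stage_counts`` is given it is filled
    with the instance counts after each stage (detected / after_filter /
    after_nms / after_nmm).
    """
    config = config or FusionConfig()
    threshold = config.score_threshold if config.score_threshold is not None else 0.98
    grid_indices = {t.index for t in grid.tiles}
    merged: list[Detection] = []
    n_detected = n_filtered = 0
    for tile, dets in sorted(per_tile_detections, key=lambda td: td[0].index):
        if tile.index not in grid_indices:
            raise ValueError(f"tile index {tile.index} not part of the grid")
        filtered = filter_by_score(dets, threshold)
        kept = nms(filtered, config.nms_iou_threshold)
        n_detected += len(dets)
        n_filtered += len(filtered)
        merged.extend(to_global(kept, tile))
    # deterministic global ids before the score-ordered merge
    merged = [
        Detection(d.mask, d.score, i) for i, d in enumerate(merged)
    ]
    fused = nmm_merge(merged, config.nmm_ios_threshold, config.nmm_single_pass)
    if stage_counts is not None:
        stage_counts.update(
            detected=n_detected,
            after_filter=n_filtered,
            after_nms=len(merged),
            after_nmm=len(fused),
        )
    return fused
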