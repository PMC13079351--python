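"""Graph-based nuclei clustering and per-nucleus morphometry.

Two nuclei are considered connected when they either share a relevant
mask overlap (IoS > 2 % by default) or lie within an adaptive distance
threshold that grows with the nuclei's area-equivalent radii and shrinks
with local crowding:

    T(i, j) = alpha * (r_i + r_j) / (1 + beta * rho_ij)

where rho_ij is the mean of the two nuclei's local densities (neighbor
counts within the vicinity radius).  Clusters are the connected
components of the resulting graph; isolated nuclei receive cluster id 0
and clusters are numbered 1, 2, … by their topmost-then-leftmost member.

Per-nucleus descriptors follow standard raster morphometry: area is the
foreground pixel count, the centroid the mask's center of mass,
eccentricity comes from the moment-fit ellipse (eigenvalues λ1 ≥ λ2 of
the pixel-coordinate covariance give e = sqrt(1 − λ2/λ1)), and the
perimeter is the length of the sub-pixel marching-squares contour at
level 0.5 (a pixel-edge count is available as an option).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage import measure

from .geometry import Detection, equivalent_radius, ios_masks

DEFAULT_OVERLAP_THRESHOLD = 0.02
DEFAULT_ALPHA = 1.2
DEFAULT_BETA = 0.05
DEFAULT_VICINITY_RADIUS = 100.0


@dataclass
class NucleusRecord:
    """Morphometric and spatial feature row for one nucleus."""

    nucleus_id: int
    centroid_x: float
    centroid_y: float
    area: int
    perimeter: float
    eccentricity: float
    mean_intensity: float
    local_density: int = 0
    nearest_neighbor_distance: float = math.nan
    cluster_id: int = 0


@dataclass
class Cluster:
    """Connected group of ≥ 2 nuclei with aggregate statistics."""

    cluster_id: int
    member_ids: list[int]
    nuclei_count: int = 0
    total_area: int = 0
    count_ratio: float = 0.0
    area_ratio: float = 0.0


@dataclass
class ImageSummary:
    """Per-image totals (counts, clusters, covered area)."""

    image_id: int
    total_nuclei: int
    n_clusters: int
    n_isolated: int
    covered_area: int
    relative_covered_area: float


def _contour_perimeter(mask_pixels: np.ndarray) -> float:
    padded = np.pad(mask_pixels.astype(float), 1)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        diffs = np.diff(contour, axis=0)
        total += float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())
    return total


def _pixel_edge_perimeter(mask_pixels: np.ndarray) -> float:
    padded = np.pad(mask_pixels, 1)
    edges = 0
    for axis in (0, 1):
        edges += int(np.abs(np.diff(padded.astype(np.int8), axis=axis)).sum())
    return float(edges)


def nucleus_morphometrics(
    det: Detection,
    image: np.ndarray,
    perimeter_mode: str = "contour",
) -> NucleusRecord:
    """Geometry and intensity descriptors of one detected nucleus.

    ``perimeter_mode`` selects the sub-pixel marching-squares contour
    length ("contour", default) or the boundary pixel-edge count
    ("pixel-edge").
    """
    mask = det.mask
    rr, cc = np.nonzero(mask.pixels)
    if rr.size == 0:
        raise ValueError("empty mask")
    cx = float(cc.mean() + mask.x0)
    cy = float(rr.mean() + mask.y0)
    if rr.size == 1:
        ecc = 0.0
    else:
        coords = np.stack([cc.astype(float), rr.astype(float)])
        cov = np.cov(coords, bias=True)
        lam = np.sort(np.linalg.eigvalsh(cov))
        lam2, lam1 = float(lam[0]), float(lam[1])
        ecc = math.sqrt(max(0.0, 1.0 - lam2 / lam1)) if lam1 > 0 else 0.0
    if perimeter_mode == "contour":
        perimeter = _contour_perimeter(mask.pixels)
    elif perimeter_mode == "pixel-edge":
        perimeter = _pixel_edge_perimeter(mask.pixels)
    else:
        raise ValueError(f"unknown perimeter mode {perimeter_mode!r}")
    patch = image[
        mask.y0 : mask.y0 + mask.pixels.shape[0],
        mask.x0 : mask.x0 + mask.pixels.shape[1],
    ]
    mean_intensity = float(np.asarray(patch, dtype=float)[mask.pixels].mean())
    return NucleusRecord(
        nucleus_id=det.instance_id,
        centroid_x=cx,
        centroid_y=cy,
        area=mask.area,
        perimeter=perimeter,
        eccentricity=min(ecc, math.nextafter(1.0, 0.0)),
        mean_intensity=mean_intensity,
    )


def _centroid_array(records: Sequence[NucleusRecord]) -> np.ndarray:
    return np.array([[r.centroid_x, r.centroid_y] for r in records], dtype=float)


def local_density(
    records: Sequence[NucleusRecord],
    vicinity_radius: float = DEFAULT_VICINITY_RADIUS,
) -> list[int]:
    """Neighbor count within the vicinity radius, per nucleus (self excluded)."""
    if not records:
        return []
    pts = _centroid_array(records)
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, r=vicinity_radius, return_length=True)
    return [int(c) - 1 for c in counts]


def nearest_neighbor_distance(records: Sequence[NucleusRecord]) -> list[float]:
    """Min centroid-to-centroid distance per nucleus; NaN for a lone nucleus."""
    if len(records) < 2:
        return [math.nan] * len(records)
    pts = _centroid_array(records)
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=2)
    return [float(d) for d in dists[:, 1]]


def adaptive_distance_threshold(
    r_i: float,
    r_j: float,
    mean_local_density: float,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
) -> float:
    """Linking distance for a nucleus pair: alpha·(r_i+r_j)/(1+beta·rho).

    Grows with the pair's area-equivalent radii so big nuclei link over
    larger gaps, and shrinks in crowded neighborhoods so dense fields are
    not fused into one giant component.
    """
    if r_i <= 0 or r_j <= 0:
        raise ValueError("radii must be positive")
    if mean_local_density < 0:
        raise ValueError("density must be non-negative")
    return alpha * (r_i + r_j) / (1.0 + beta * mean_local_density)


def build_cluster_graph(
    detections: Sequence[Detection],
    records: Sequence[NucleusRecord],
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
) -> nx.Graph:
    """Connectivity graph over nucleus ids.

    An undirected edge joins two nuclei iff their mask IoS exceeds
    ``overlap_threshold`` OR their centroid distance is within the
    adaptive threshold evaluated at the pair's mean local density.
    """
    if len(detections) != len(records):
        raise ValueError("detections and records must be aligned")
    graph = nx.Graph()
    graph.add_nodes_from(r.nucleus_id for r in records)
    if len(records) < 2:
        return graph
    radii = [equivalent_radius(r.area) for r in records]
    pts = _centroid_array(records)
    # candidate pairs: within the largest possible adaptive threshold or
    # close enough that their boxes could intersect
    max_r = max(radii)
    max_diag = max(
        math.hypot(d.box.width, d.box.height) for d in detections
    )
    r_cand = max(alpha * 2.0 * max_r, 2.0 * max_diag)
    tree = cKDTree(pts)
    for i, j in sorted(tree.query_pairs(r=r_cand)):
        dist = float(np.hypot(*(pts[i] - pts[j])))
        rho = 0.5 * (records[i].local_density + records[j].local_density)
        threshold = adaptive_distance_threshold(radii[i], radii[j], rho, alpha, beta)
        connected = dist <= threshold
        if not connected and detections[i].box.intersection(detections[j].box) > 0:
            connected = ios_masks(detections[i].mask, detections[j].mask) > overlap_threshold
        if connected:
            graph.add_edge(records[i].nucleus_id, records[j].nucleus_id)
    return graph


def assign_cluster_ids(
    graph: nx.Graph, records: Sequence[NucleusRecord]
) -> list[Cluster]:
    """Label connected components; singletons get cluster id 0.

    Components of size ≥ 2 are numbered 1, 2, … ordered by their
    topmost-then-leftmost member centroid.  Mutates ``cluster_id`` on
    the records and returns the cluster list (aggregates unfilled).
    """
    by_id = {r.nucleus_id: r for r in records}
    for r in records:
        r.cluster_id = 0
    components = [c for c in nx.connected_components(graph) if len(c) >= 2]

    def anchor(component: set[int]) -> tuple[float, float]:
        return min((by_id[n].centroid_y, by_id[n].centroid_x) for n in component)

    clusters = []
    for cid, component in enumerate(sorted(components, key=anchor), start=1):
        members = sorted(component)
        for nid in members:
            by_id[nid].cluster_id = cid
        clusters.append(Cluster(cluster_id=cid, member_ids=members))
    return clusters


def cluster_aggregates(
    clusters: Sequence[Cluster],
    detections: Sequence[Detection],
    image_width: int,
    image_height: int,
) -> list[Cluster]:
    """Fill per-cluster statistics: count, union area, count/area ratios.

    Covered areas are unions of member masks, so overlapping nuclei are
    counted once.
    """
    by_id = {d.instance_id: d for d in detections}
    total = len(detections)
    image_area = image_width * image_height
    for cluster in clusters:
        members = [by_id[n] for n in cluster.member_ids]
        x0 = min(d.box.x0 for d in members)
        y0 = min(d.box.y0 for d in members)
        x1 = max(d.box.x1 for d in members)
        y1 = max(d.box.y1 for d in members)
        canvas = np.zeros((y1 - y0, x1 - x0), dtype=bool)
        for d in members:
            h, w = d.mask.pixels.shape
            canvas[
                d.mask.y0 - y0 : d.mask.y0 - y0 + h,
                d.mask.x0 - x0 : d.mask.x0 - x0 + w,
            ] |= d.mask.pixels
        cluster.nuclei_count = len(members)
        cluster.total_area = int(canvas.sum())
        cluster.count_ratio = len(members) / total
        cluster.area_ratio = cluster.total_area / image_area
    return list(clusters)


def union_area(
    detections: Sequence[Detection], image_width: int, image_height: int
) -> int:
    """Pixel count of the union of all detection masks."""
    canvas = np.zeros((image_height, image_width), dtype=bool)
    for d in detections:
        h, w = d.mask.pixels.shape
        canvas[d.mask.y0 : d.mask.y0 + h, d.mask.x0 : d.mask.x0 + w] |= d.mask.pixels
    return int(canvas.sum())


def image_summary(
    detections: Sequence[Detection],
    records: Sequence[NucleusRecord],
    clusters: Sequence[Cluster],
    image_width: int,
    image_height: int,
    image_id: int = 0,
) -> ImageSummary:
    """Per-image totals: counts, cluster counts and covered area."""
    covered = union_area(detections, image_width, image_height) if detections else 0
    n_isolated = sum(1 for r in records if r.cluster_id == 0)
    return ImageSummary(
        image_id=image_id,
        total_nuclei=len(records),
        n_clusters=len(clusters),
        n_isolated=n_isolated,
        covered_area=covered,
        relative_covered_area=covered / (image_width * image_height),
    )


def analyze_detections(
    detections: Sequence[Detection],
    image: np.ndarray,
    vicinity_radius: float = DEFAULT_VICINITY_RADIUS,
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    image_id: int = 0,
    perimeter_mode: str = "contour",
) -> tuple[list[NucleusRecord], list[Cluster], ImageSummary]:
    """Full post-processing of one image's detections.

    Computes morphometrics, spatial context, the clustering graph and
    aggregates; returns (records, clusters, summary).
    """
    height, width = image.shape[:2]
    records = [
        nucleus_morphometrics(d, image, perimeter_mode) for d in detections
    ]
    densities = local_density(records, vicinity_radius)
    nn = nearest_neighbor_distance(records)
    for rec, rho, d in zip(records, densities, nn):
        rec.local_density = rho
        rec.nearest_neighbor_distance = d
    graph = build_cluster_graph(
        detections, records, overlap_threshold, alpha, beta
    )
    clusters = assign_cluster_ids(graph, records)
    clusters = cluster_aggregates(clusters, detections, width, height)
    summary = image_summary(detections, records, clusters, width, height, image_id)
    return records, clusters, summary


RECORD_COLUMNS = [
    "nucleus_id", "centroid_x", "centroid_y", "area", "perimeter",
    "eccentricity", "mean_intensity", "local_density",
    "nearest_neighbor_distance", "cluster_id",
]
CLUSTER_COLUMNS = [
    "cluster_id", "nuclei_count", "total_area", "count_ratio", "area_ratio",
    "member_ids",
]
SUMMARY_COLUMNS = [
    "image_id", "total_nuclei", "n_clusters", "n_isolated", "covered_area",
    "relative_covered_area",
]


def record_frame(records: Sequence[NucleusRecord]) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in RECORD_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def cluster_frame(clusters: Sequence[Cluster]) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": c.cluster_id,
            "nuclei_count": c.nuclei_count,
            "total_area": c.total_area,
            "count_ratio": c.count_ratio,
            "area_ratio": c.area_ratio,
            "member_ids": ";".join(str(m) for m in c.member_ids),
        }
        for c in clusters
    ]
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS)


def summary_frame(summaries: Sequence[ImageSummary]) -> pd.DataFrame:
    rows = [{c: getattr(s, c) for c in SUMMARY_COLUMNS} for s in summaries]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
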