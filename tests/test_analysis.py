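"""Morphometry, spatial context and graph-based clustering."""

import math

import networkx as nx
import numpy as np
import pytest

from fibernuc import (
    Detection,
    InstanceMask,
    adaptive_distance_threshold,
    analyze_detections,
    assign_cluster_ids,
    build_cluster_graph,
    cluster_aggregates,
    equivalent_radius,
    image_summary,
    ios_masks,
    local_density,
    nearest_neighbor_distance,
    nucleus_morphometrics,
)
from fibernuc.analysis import NucleusRecord
from conftest import disk_mask, square_det


def ellipse_mask(cx, cy, a, b, theta=0.0):
    r = int(math.ceil(max(a, b))) + 1
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    ct, st = math.cos(theta), math.sin(theta)
    u = xx * ct + yy * st
    v = -xx * st + yy * ct
    return InstanceMask.from_raster(
        (u / a) ** 2 + (v / b) ** 2 <= 1.0, cx - r, cy - r
    )


def record_at(nid, x, y, area=314, density=0):
    return NucleusRecord(
        nucleus_id=nid, centroid_x=x, centroid_y=y, area=area,
        perimeter=0.0, eccentricity=0.0, mean_intensity=0.0,
        local_density=density,
    )


class TestMorphometrics:
    def test_disk_is_nearly_circular(self):
        det = Detection(disk_mask(40, 40, 20), 1.0, 0)
        image = np.full((80, 80), 100, dtype=np.uint8)
        rec = nucleus_morphometrics(det, image)
        assert rec.eccentricity <= 0.05
        assert rec.area == pytest.approx(math.pi * 400, rel=0.02)
        assert rec.mean_intensity == pytest.approx(100.0)
        assert (rec.centroid_x, rec.centroid_y) == pytest.approx((40.0, 40.0), abs=0.01)

    @pytest.mark.parametrize("theta", [0.0, 0.5, 1.1])
    def test_ellipse_eccentricity_matches_analytic(self, theta):
        det = Detection(ellipse_mask(40, 40, 20, 10, theta), 1.0, 0)
        rec = nucleus_morphometrics(det, np.zeros((80, 80)))
        analytic = math.sqrt(1 - (10 / 20) ** 2)
        assert rec.eccentricity == pytest.approx(analytic, abs=0.02)

    @pytest.mark.parametrize("a, b", [(8, 8), (12, 8), (30, 9)])
    def test_eccentricity_sweep_rasterized_ellipses(self, a, b):
        det = Detection(ellipse_mask(64, 64, a, b), 1.0, 0)
        rec = nucleus_morphometrics(det, np.zeros((128, 128)))
        analytic = math.sqrt(1 - (b / a) ** 2)
        assert rec.eccentricity == pytest.approx(analytic, abs=0.02)

    def test_disk_contour_perimeter_bounds(self):
        # the sub-pixel contour is a staircase-smoothed polygon: at least
        # the analytic circumference, at most the axis-aligned pixel
        # boundary (8r for a digitized disk)
        det = Detection(disk_mask(40, 40, 20), 1.0, 0)
        rec = nucleus_morphometrics(det, np.zeros((80, 80)))
        assert 2 * math.pi * 20 <= rec.perimeter <= 8 * 20
        pixel_edge = nucleus_morphometrics(
            det, np.zeros((80, 80)), perimeter_mode="pixel-edge"
        ).perimeter
        assert rec.perimeter < pixel_edge

    def test_pixel_edge_perimeter_of_square(self):
        det = square_det(10, 10, 10)
        rec = nucleus_morphometrics(det, np.zeros((40, 40)), perimeter_mode="pixel-edge")
        assert rec.perimeter == 40.0


class TestSpatialContext:
    def test_single_nucleus_zero_density_and_nan_distance(self):
        recs = [record_at(0, 50, 50)]
        assert local_density(recs, 100) == [0]
        assert math.isnan(nearest_neighbor_distance(recs)[0])

    def test_pair_within_radius(self):
        recs = [record_at(0, 0, 0), record_at(1, 50, 0)]
        assert local_density(recs, 100) == [1, 1]
        assert nearest_neighbor_distance(recs) == pytest.approx([50.0, 50.0])

    def test_grid_density_matches_brute_force(self):
        # 3×3 grid, spacing 60, radius 100: the center sees all 8 others;
        # a corner sees two at 60 px and the center at 60·√2 ≈ 84.9 px
        recs = [
            record_at(3 * iy + ix, 60 * ix, 60 * iy)
            for iy in range(3)
            for ix in range(3)
        ]
        dens = local_density(recs, 100)
        pts = [(r.centroid_x, r.centroid_y) for r in recs]
        brute = [
            sum(
                1
                for j, q in enumerate(pts)
                if j != i and math.dist(p, q) <= 100
            )
            for i, p in enumerate(pts)
        ]
        assert dens == brute
        assert dens[4] == 8  # center
        assert dens[0] == 3  # corner

    def test_nearest_neighbor_matches_brute_force(self, rng):
        pts = rng.uniform(0, 500, (15, 2))
        recs = [record_at(i, x, y) for i, (x, y) in enumerate(pts)]
        nn = nearest_neighbor_distance(recs)
        for i, p in enumerate(pts):
            brute = min(math.dist(p, q) for j, q in enumerate(pts) if j != i)
            assert nn[i] == pytest.approx(brute)


class TestAdaptiveThreshold:
    def test_closed_form(self):
        assert adaptive_distance_threshold(10, 10, 0) == pytest.approx(24.0)

    def test_symmetric(self):
        assert adaptive_distance_threshold(8, 14, 3) == pytest.approx(
            adaptive_distance_threshold(14, 8, 3)
        )

    def test_monotonicity(self):
        base = adaptive_distance_threshold(10, 10, 2)
        assert adaptive_distance_threshold(10, 10, 5) < base
        assert adaptive_distance_threshold(12, 10, 2) > base

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            adaptive_distance_threshold(0, 10, 1)
        with pytest.raises(ValueError):
            adaptive_distance_threshold(10, 10, -1)


def brute_force_components(dets, records, overlap_threshold=0.02,
                           alpha=1.2, beta=0.05):
    """Transitive closure of the pairwise rule, as an independent oracle."""
    n = len(dets)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ri = equivalent_radius(records[i].area)
            rj = equivalent_radius(records[j].area)
            rho = 0.5 * (records[i].local_density + records[j].local_density)
            dist = math.dist(
                (records[i].centroid_x, records[i].centroid_y),
                (records[j].centroid_x, records[j].centroid_y),
            )
            linked = dist <= alpha * (ri + rj) / (1 + beta * rho)
            if not linked and ios_masks(dets[i].mask, dets[j].mask) > overlap_threshold:
                linked = True
            if linked:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(records[i].nucleus_id)
    return {frozenset(g) for g in groups.values() if len(g) >= 2}


class TestClusterGraph:
    def _dets_records(self, masks):
        dets = [Detection(m, 1.0, i) for i, m in enumerate(masks)]
        records = []
        for d in dets:
            cx, cy = d.mask.centroid()
            records.append(record_at(d.instance_id, cx, cy, area=d.mask.area))
        return dets, records

    def test_small_overlap_far_centroids_edge(self):
        # two large thin rectangles overlapping slightly at their tips:
        # IoS 0.05, centroids far apart relative to radii
        a = InstanceMask(np.ones((4, 100), bool), 0, 0)
        b = InstanceMask(np.ones((4, 100), bool), 95, 0)
        dets, records = self._dets_records([a, b])
        assert ios_masks(a, b) == pytest.approx(0.05)
        graph = build_cluster_graph(dets, records, alpha=0.1)
        assert graph.has_edge(0, 1)

    def test_tiny_overlap_and_distance_fail_no_edge(self):
        a = InstanceMask(np.ones((4, 100), bool), 0, 0)
        b = InstanceMask(np.ones((4, 100), bool), 99, 0)  # IoS 0.01
        dets, records = self._dets_records([a, b])
        assert ios_masks(a, b) == pytest.approx(0.01)
        graph = build_cluster_graph(dets, records, alpha=0.1)
        assert not graph.has_edge(0, 1)

    def test_mixed_chain_edges(self):
        # A overlaps B; C is linked to B only by distance; no A-C edge
        a = disk_mask(50, 50, 10)
        b = disk_mask(62, 50, 10)  # overlaps a
        c = disk_mask(85, 50, 10)  # 23 px from b: within T = 1.2·20 = 24
        dets, records = self._dets_records([a, b, c])
        graph = build_cluster_graph(dets, records)
        assert graph.has_edge(0, 1)
        assert graph.has_edge(1, 2)
        assert not graph.has_edge(0, 2)

    def test_matches_brute_force_transitive_closure(self, rng):
        for trial in range(5):
            masks = [
                disk_mask(int(x), int(y), int(r))
                for x, y, r in zip(
                    rng.uniform(30, 470, 30),
                    rng.uniform(30, 470, 30),
                    rng.integers(5, 15, 30),
                )
            ]
            dets, records = self._dets_records(masks)
            for rec, rho in zip(records, local_density(records, 100)):
                rec.local_density = rho
            graph = build_cluster_graph(dets, records)
            clusters = assign_cluster_ids(graph, records)
            ours = {frozenset(c.member_ids) for c in clusters}
            oracle = brute_force_components(dets, records)
            assert ours == oracle


class TestClusterAssignment:
    def test_edgeless_graph_all_isolated(self):
        records = [record_at(i, 10 * i, 0) for i in range(5)]
        graph = nx.Graph()
        graph.add_nodes_from(range(5))
        clusters = assign_cluster_ids(graph, records)
        assert clusters == []
        assert all(r.cluster_id == 0 for r in records)

    def test_chain_of_three_single_cluster(self):
        records = [record_at(i, 10 * i, 0) for i in range(3)]
        graph = nx.Graph([(0, 1), (1, 2)])
        clusters = assign_cluster_ids(graph, records)
        assert len(clusters) == 1
        assert clusters[0].cluster_id == 1
        assert clusters[0].member_ids == [0, 1, 2]
        assert all(r.cluster_id == 1 for r in records)

    def test_numbering_by_topmost_then_leftmost(self):
        records = [
            record_at(0, 100, 100), record_at(1, 110, 100),  # lower cluster
            record_at(2, 200, 10), record_at(3, 210, 10),  # upper cluster
        ]
        graph = nx.Graph([(0, 1), (2, 3)])
        clusters = assign_cluster_ids(graph, records)
        assert clusters[0].member_ids == [2, 3]  # topmost first
        assert clusters[0].cluster_id == 1


class TestAggregatesAndSummary:
    def test_count_ratio(self):
        dets = [square_det(30 * i, 0, 10, 1.0, i) for i in range(10)]
        records = [record_at(i, 30 * i + 5, 5, area=100) for i in range(10)]
        graph = nx.Graph([(0, 1), (1, 2)])
        graph.add_nodes_from(range(10))
        clusters = assign_cluster_ids(graph, records)
        clusters = cluster_aggregates(clusters, dets, 400, 400)
        assert clusters[0].nuclei_count == 3
        assert clusters[0].count_ratio == pytest.approx(0.3)

    def test_union_area_of_overlapping_members(self):
        a = square_det(0, 0, 10, 1.0, 0)  # 100 px²
        b = Detection(InstanceMask(np.ones((10, 20), bool), 5, 0), 1.0, 1)  # 200 px²
        records = [record_at(0, 5, 5, 100), record_at(1, 15, 5, 200)]
        graph = nx.Graph([(0, 1)])
        clusters = assign_cluster_ids(graph, records)
        clusters = cluster_aggregates(clusters, [a, b], 400, 400)
        assert clusters[0].total_area == 250  # overlap of 50 counted once

    def test_empty_cluster_list(self):
        assert cluster_aggregates([], [square_det(0, 0, 10)], 400, 400) == []

    def test_no_detections_zero_summary(self):
        s = image_summary([], [], [], 400, 400)
        assert s.total_nuclei == 0
        assert s.relative_covered_area == 0.0

    def test_single_nucleus_relative_area(self):
        det = square_det(100, 100, 10)
        rec = record_at(0, 105, 105, 100)
        s = image_summary([det], [rec], [], 400, 400)
        assert s.relative_covered_area == pytest.approx(100 / 160000)

    def test_partition_conservation_on_random_scene(self, rng):
        masks = [
            disk_mask(int(x), int(y), int(r))
            for x, y, r in zip(
                rng.uniform(30, 470, 40),
                rng.uniform(30, 470, 40),
                rng.integers(5, 12, 40),
            )
        ]
        dets = [Detection(m, 1.0, i) for i, m in enumerate(masks)]
        records, clusters, summary = analyze_detections(
            dets, np.zeros((500, 500), dtype=np.uint8)
        )
        assert summary.n_isolated + sum(c.nuclei_count for c in clusters) == 40
        # every nucleus has exactly one cluster id
        for rec in records:
            owners = [c for c in clusters if rec.nucleus_id in c.member_ids]
            if rec.cluster_id == 0:
                assert owners == []
            else:
                assert len(owners) == 1 and owners[0].cluster_id == rec.cluster_id
        for c in clusters:
            assert 0 < c.count_ratio <= 1
            assert 0 < c.area_ratio <= 1
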