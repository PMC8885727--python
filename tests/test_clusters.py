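"""Voronoi density, cluster segmentation, metrics and colocalisation."""

import numpy as np
import pytest

from synapse_corr import (
    Cluster,
    ContractError,
    DegenerateGeometryError,
    PipelineConfig,
    cluster_metrics,
    colocalise,
    segment_clusters,
    simulate_synapse_scene,
    voronoi_density,
)


def cubic_grid(n=5, spacing=100.0):
    g = np.arange(n) * spacing
    return np.array(np.meshgrid(g, g, g)).reshape(3, -1).T


class TestVoronoiDensity:
    def test_interior_grid_cell_density_is_exact(self):
        # interior cells of a cubic grid are the spacing-cube
        pts = cubic_grid(5, 100.0)
        dm = voronoi_density(pts, first_rank_average=False)
        centre = np.flatnonzero((pts == [200.0, 200.0, 200.0]).all(axis=1))[0]
        assert dm.density[centre] == pytest.approx(1e-6, rel=1e-9)

    def test_uniform_scaling_scales_density_by_inverse_cube(self, rng):
        pts = rng.uniform(0, 1000, (200, 3))
        a = voronoi_density(pts, first_rank_average=False)
        b = voronoi_density(pts * 2.0, first_rank_average=False)
        sel = a.finite & b.finite
        np.testing.assert_allclose(b.density[sel], a.density[sel] / 8.0, rtol=1e-9)

    def test_mean_finite_cell_volume_tracks_box_volume(self, rng):
        # uniform points: average bounded cell volume ~ box volume / n
        n = 2000
        box = 5000.0
        pts = rng.uniform(0, box, (n, 3))
        dm = voronoi_density(pts, first_rank_average=False)
        mean_vol = (1.0 / dm.density[dm.finite]).mean()
        assert mean_vol == pytest.approx(box**3 / n, rel=0.10)

    def test_coplanar_points_rejected(self, rng):
        pts = rng.uniform(0, 100, (50, 3))
        pts[:, 2] = 0.0
        with pytest.raises(DegenerateGeometryError):
            voronoi_density(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ContractError):
            voronoi_density(np.zeros((4, 3)))


class TestSegmentation:
    def test_two_well_separated_clusters_fully_recovered(self, cfg, rng):
        pts = np.vstack(
            [rng.normal(0, 30, (300, 3)), rng.normal([2000, 0, 0], 30, (300, 3))]
        )
        dm = voronoi_density(pts)
        clusters = segment_clusters(pts, dm, colour=2, cfg=cfg)
        assert len(clusters) == 2
        for cl, lo, hi in ((clusters[0], 0, 300), (clusters[1], 300, 600)):
            captured = np.isin(cl.members, np.arange(lo, hi)).sum()
            assert captured >= 0.95 * 300

    def test_min_molecule_filter_colour1(self, cfg, rng):
        # 150 points cannot form a colour-1 cluster (minimum is 200)
        pts = rng.normal(0, 30, (150, 3))
        dm = voronoi_density(pts)
        assert segment_clusters(pts, dm, colour=1, cfg=cfg) == []
        # the same cloud passes the colour-2 minimum of 20
        assert len(segment_clusters(pts, dm, colour=2, cfg=cfg)) == 1

    def test_empty_input_gives_empty_list(self, cfg):
        dm = None
        assert segment_clusters(np.empty((0, 3)), dm, 1, cfg) == []

    def test_threshold_monotonicity(self, rng):
        points, _ = simulate_synapse_scene(3, seed=13)
        pts = points[2]
        dm = voronoi_density(pts)
        counts = []
        for factor in (0.5, 1.0, 2.0, 5.0):
            cfg = PipelineConfig(density_factor=factor)
            counts.append(len(segment_clusters(pts, dm, 2, cfg)))
        assert counts == sorted(counts, reverse=True)
        sizes = []
        for min2 in (10, 40, 120):
            cfg = PipelineConfig(min_molecules=(200, min2))
            sizes.append(len(segment_clusters(pts, dm, 2, cfg)))
        assert sizes == sorted(sizes, reverse=True)

    def test_rigid_motion_invariance(self, cfg, rng):
        pts = np.vstack(
            [rng.normal(0, 40, (250, 3)), rng.normal([1500, 500, 100], 40, (250, 3))]
        )
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = pts @ rot.T + np.array([5000.0, -2000.0, 300.0])
        out_a = segment_clusters(pts, voronoi_density(pts), 2, cfg)
        out_b = segment_clusters(moved, voronoi_density(moved), 2, cfg)
        assert len(out_a) == len(out_b) == 2
        for a, b in zip(out_a, out_b):
            assert a.n_detections == b.n_detections
            assert b.volume == pytest.approx(a.volume, rel=1e-9)
            assert b.density == pytest.approx(a.density, rel=1e-9)

    def test_cluster_membership_is_a_partition(self, cfg):
        points, _ = simulate_synapse_scene(3, seed=14)
        pts = points[2]
        clusters = segment_clusters(pts, voronoi_density(pts), 2, cfg)
        all_members = np.concatenate([c.members for c in clusters])
        assert len(np.unique(all_members)) == len(all_members)
        assert len(all_members) <= len(pts)


class TestClusterMetrics:
    def test_cube_hull_volume(self):
        corners = np.array(
            [[i, j, k] for i in (0, 100.0) for j in (0, 100.0) for k in (0, 100.0)]
        )
        interior = np.array([[50.0, 50.0, 50.0]])
        pts = np.vstack([corners, interior])
        cl = cluster_metrics(Cluster(2, np.arange(9)), pts)
        assert cl.volume == pytest.approx(1e6, rel=1e-12)
        assert cl.density == pytest.approx(9 / 1e6, rel=1e-12)

    def test_collinear_points_degenerate(self):
        pts = np.outer(np.arange(10.0), [1.0, 0.0, 0.0])
        cl = cluster_metrics(Cluster(2, np.arange(10)), pts)
        assert cl.degenerate and np.isnan(cl.volume)

    def test_similarity_scaling(self, rng):
        pts = rng.normal(0, 50, (40, 3))
        a = cluster_metrics(Cluster(2, np.arange(40)), pts)
        b = cluster_metrics(Cluster(2, np.arange(40)), pts * 2.0)
        assert b.volume == pytest.approx(8 * a.volume, rel=1e-9)
        assert b.density == pytest.approx(a.density / 8, rel=1e-9)

    def test_out_of_range_membership_rejected(self, rng):
        pts = rng.normal(0, 50, (10, 3))
        with pytest.raises(ContractError):
            cluster_metrics(Cluster(2, np.array([0, 99])), pts)


class TestColocalise:
    @staticmethod
    def _synapse_cluster(rng, centre=(0.0, 0.0, 0.0), n=300, sigma=150.0):
        pts = np.asarray(centre) + rng.normal(0, sigma, (n, 3))
        return pts, cluster_metrics(Cluster(1, np.arange(n)), pts)

    def test_overlapping_ssd_associated_by_overlap(self, rng):
        pts1, c1 = self._synapse_cluster(rng)
        pts2 = rng.normal(0, 20, (50, 3))  # inside the colour-1 hull
        c2 = cluster_metrics(Cluster(2, np.arange(50)), pts2)
        structures, unassigned = colocalise([c1], [c2], pts1, pts2)
        assert structures[0].n_ssd == 1
        assert structures[0].provenance == ["overlap"]
        assert not unassigned

    def test_nearby_outside_ssd_orphan_assigned(self, rng):
        pts1, c1 = self._synapse_cluster(rng, n=200, sigma=50.0)
        pts2 = np.array([300.0, 0.0, 0.0]) + rng.normal(0, 10, (30, 3))
        c2 = cluster_metrics(Cluster(2, np.arange(30)), pts2)
        structures, unassigned = colocalise([c1], [c2], pts1, pts2, orphan_dist=500.0)
        assert structures[0].provenance == ["orphan-assigned"]

    def test_distant_ssd_left_unassigned(self, rng):
        pts1, c1 = self._synapse_cluster(rng, n=200, sigma=50.0)
        pts2 = np.array([2000.0, 0.0, 0.0]) + rng.normal(0, 10, (30, 3))
        c2 = cluster_metrics(Cluster(2, np.arange(30)), pts2)
        structures, unassigned = colocalise([c1], [c2], pts1, pts2, orphan_dist=500.0)
        assert structures[0].n_ssd == 0
        assert len(unassigned) == 1

    def test_scene_ssd_count_recovery(self, cfg):
        from synapse_corr.pipeline import segment_scene

        ok = total = 0
        for seed in (0, 1):
            points, truth = simulate_synapse_scene(5, seed=seed)
            structures, _ = segment_scene(points, cfg)
            for s in structures:
                d = np.linalg.norm(truth.centres_nm - s.cluster1.centroid, axis=1)
                total += 1
                if s.n_ssd == truth.ssd_counts[int(np.argmin(d))]:
                    ok += 1
            total += 5 - len(structures)
        assert ok / total >= 0.9
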