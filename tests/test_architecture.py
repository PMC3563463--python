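"""Spatial-graph architecture features: geometry oracles and invariants."""

import numpy as np
import pytest

from histocascade import architecture as arch
from histocascade.errors import DegenerateGeometryError, DegenerateInputError

from oracles import circumcircle_contains, mst_weight_subsets


class TestSummarize:
    @pytest.mark.parametrize(
        "values, mean, std, disorder, ratio",
        [
            ([5, 5, 5], 5.0, 0.0, 0.0, 1.0),
            ([1, 3], 2.0, 1.0, 1.0 / 3.0, 1.0 / 3.0),
            ([0, 0], 0.0, 0.0, 0.0, 1.0),
        ],
    )
    def test_known_pools(self, values, mean, std, disorder, ratio):
        s = arch.summarize(values)
        assert s.mean == pytest.approx(mean)
        assert s.std == pytest.approx(std)
        assert s.disorder == pytest.approx(disorder)
        assert s.min_max_ratio == pytest.approx(ratio)

    def test_disorder_half_when_std_equals_mean(self):
        # population std of {0, 2} is 1 and the mean is 1
        assert arch.summarize([0, 2]).disorder == pytest.approx(0.5)

    def test_empty_pool_rejected(self):
        with pytest.raises(DegenerateInputError):
            arch.summarize([])


class TestVoronoi:
    def test_square_of_points_gives_congruent_quarter_cells(self):
        pts = np.array([[25, 25], [25, 75], [75, 25], [75, 75]], float)
        tess, feats = arch.voronoi_features(pts, (100, 100))
        assert len(feats) == 12
        assert np.allclose(tess.areas, 2500.0)
        # area summary: mean = image_area / 4, zero spread
        assert feats[0] == pytest.approx(2500.0)
        assert feats[1] == pytest.approx(0.0, abs=1e-9)
        assert feats[2] == pytest.approx(0.0, abs=1e-9)
        assert feats[3] == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            arch.voronoi_features(np.array([[1.0, 2.0], [3.0, 4.0]]), (10, 10))

    @pytest.mark.parametrize("seed", range(10))
    def test_cell_areas_partition_the_image(self, seed):
        pts = np.random.default_rng(seed).uniform(0, 100, (30, 2))
        tess, _ = arch.voronoi_features(pts, (100, 100))
        assert abs(tess.areas.sum() - 10000.0) / 10000.0 < 1e-6
        assert len(tess.polygons) == len(pts)


class TestDelaunay:
    def test_right_triangle_metrics(self):
        pts = np.array([[0, 0], [3, 0], [0, 4]], float)
        graph, feats = arch.delaunay_features(pts)
        assert len(feats) == 8
        assert feats[0] == pytest.approx(6.0)  # area mean
        assert feats[1] == pytest.approx(0.0)  # single triangle: no spread
        assert feats[4] == pytest.approx(12.0)  # perimeter mean
        assert len(graph.edges) == 3

    def test_four_convex_points_two_triangles(self):
        pts = np.array([[0, 0], [10, 1], [11, 9], [1, 10]], float)
        graph, feats = arch.delaunay_features(pts)
        assert len(graph.edges) == 5  # 4 hull edges + 1 diagonal

    @pytest.mark.parametrize("seed", range(10))
    def test_empty_circumcircle_property(self, seed):
        """Direct check of the Delaunay definition on random point sets."""
        pts = np.random.default_rng(100 + seed).uniform(0, 50, (15, 2))
        from scipy.spatial import Delaunay

        tri = Delaunay(pts)
        for simplex in tri.simplices:
            others = np.setdiff1d(np.arange(len(pts)), simplex)
            for o in others:
                assert not circumcircle_contains(pts[simplex], pts[o])

    def test_voronoi_delaunay_duality(self):
        """Interior Delaunay edges correspond to shared Voronoi boundaries."""
        rng = np.random.default_rng(3)
        pts = rng.uniform(20, 80, (25, 2))
        tess, _ = arch.voronoi_features(pts, (100, 100))
        graph, _ = arch.delaunay_features(pts)
        rings = [np.round(p, 6) for p in tess.polygons]

        def clipped(ring):  # cell touches the image rectangle
            return bool(
                np.any(ring <= 1e-6)
                or np.any(ring[:, 0] >= 100 - 1e-6)
                or np.any(ring[:, 1] >= 100 - 1e-6)
            )

        checked = 0
        for i, j in graph.edges:
            if clipped(rings[i]) or clipped(rings[j]):
                continue  # boundary-clipped cells are exempt
            shared = 0
            for va in rings[i]:
                if np.any(np.all(np.abs(rings[j] - va) < 1e-5, axis=1)):
                    shared += 1
            # interior adjacent cells share a whole boundary segment
            assert shared >= 2
            checked += 1
        assert checked > 5


class TestMst:
    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_subset_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 60, (6, 2))
        graph, _ = arch.delaunay_features(pts)
        tree, feats = arch.mst_features(graph)
        assert tree.total_weight == pytest.approx(mst_weight_subsets(pts), abs=1e-9)
        assert len(feats) == 4
        assert len(tree.edges) == len(pts) - 1

    def test_mst_subset_of_delaunay(self, rng):
        pts = rng.uniform(0, 100, (30, 2))
        graph, _ = arch.delaunay_features(pts)
        tree, _ = arch.mst_features(graph)
        delaunay_edges = {tuple(e) for e in graph.edges.tolist()}
        assert all(tuple(e) in delaunay_edges for e in tree.edges.tolist())

    def test_evenly_spaced_points(self):
        rng = np.random.default_rng(1)
        pts = np.array([[rng.normal(0, 1e-3), 10.0 * i] for i in range(5)])
        graph, _ = arch.delaunay_features(pts)
        tree, feats = arch.mst_features(graph)
        assert tree.total_weight == pytest.approx(40.0, rel=1e-4)
        assert feats[0] == pytest.approx(10.0, rel=1e-4)  # mean branch
        assert feats[3] == pytest.approx(1.0, rel=1e-4)  # min/max ratio


class TestDensity:
    def test_counting_kernel_inclusive_radius(self):
        # three collinear points spaced 5 px; radius 7 reaches one hop only
        pts = np.array([[0, 0], [0, 5], [0, 10]], float)
        assert arch.neighbor_counts(pts, 7).tolist() == [1, 2, 1]
        # radius equal to a pairwise distance counts that neighbour
        assert arch.neighbor_counts(pts, 5).tolist() == [1, 2, 1]
        assert arch.neighbor_counts(pts, 4.99).tolist() == [0, 0, 0]

    def test_grid_knn_distance(self):
        pts = np.array([[r * 20, c * 20] for r in range(5) for c in range(5)], float)
        knn3 = arch.knn_mean_distances(pts, 3).reshape(5, 5)
        assert knn3[2, 2] == pytest.approx(20.0)

    def test_vector_length_and_guard(self, rng):
        pts = rng.uniform(0, 100, (20, 2))
        assert len(arch.density_features(pts)) == 24
        with pytest.raises(DegenerateInputError):
            arch.density_features(pts[:7])


class TestArchitectureVector:
    def test_length_and_name_registry(self, rng):
        pts = rng.uniform(0, 128, (40, 2))
        vec = arch.architecture_vector(pts, (128, 128))
        assert vec.shape == (48,)
        assert len(arch.ARCHITECTURE_FEATURE_NAMES) == 48
        assert len(set(arch.ARCHITECTURE_FEATURE_NAMES)) == 48

    def test_input_order_invariance(self, rng):
        pts = rng.uniform(0, 128, (30, 2))
        v1 = arch.architecture_vector(pts, (128, 128))
        v2 = arch.architecture_vector(pts[::-1], (128, 128))
        assert np.allclose(v1, v2)

    def test_translation_invariance_of_unclipped_families(self, rng):
        """Delaunay, MST and density features ignore translation; Voronoi
        cells are exempt because clipping depends on position."""
        pts = rng.uniform(30, 70, (25, 2))
        v1 = arch.architecture_vector(pts, (200, 200))
        v2 = arch.architecture_vector(pts + 40.0, (200, 200))
        assert np.allclose(v1[12:], v2[12:], rtol=1e-9)

    def test_dense_tile_has_smaller_voronoi_cells(self, rng):
        dense = rng.uniform(0, 128, (90, 2))
        sparse = rng.uniform(0, 128, (15, 2))
        v_dense = arch.architecture_vector(dense, (128, 128))
        v_sparse = arch.architecture_vector(sparse, (128, 128))
        assert v_dense[0] < v_sparse[0]  # voronoi area mean

    def test_duplicate_centroids_deduplicated_with_warning(self, rng):
        pts = rng.uniform(0, 100, (20, 2))
        doubled = np.vstack([pts, pts[:5]])
        with pytest.warns(UserWarning, match="duplicate"):
            v = arch.architecture_vector(doubled, (100, 100))
        assert np.allclose(v, arch.architecture_vector(pts, (100, 100)))
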