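"""Nuclei detection: thresholding, distance transform, watershed."""

import numpy as np
import pytest
from scipy import stats

from histocascade import architecture as arch
from histocascade import nuclei as nd
from histocascade import synthetic as syn
from histocascade.errors import DegenerateInputError


def disc_mask(shape, center, radius):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestBinarizeOtsu:
    def test_bimodal_separation(self, rng):
        plane = np.full(1000, 10.0)
        plane[:100] = 200.0
        rng.shuffle(plane)
        plane = plane.reshape(20, 50)
        mask = nd.binarize_otsu(plane)
        assert 10 < mask.threshold < 200
        assert np.array_equal(mask.foreground, plane == 200.0)

    def test_boundary_is_eight_connected_ring(self):
        plane = np.zeros((11, 11))
        plane[3:8, 3:8] = 1.0  # 5x5 solid square
        mask = nd.binarize_otsu(plane)
        assert mask.boundary.sum() == 24  # the 7x7 exterior ring of a 5x5 square
        assert not np.any(mask.boundary & mask.foreground)

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateInputError):
            nd.binarize_otsu(np.full((8, 8), 3.0))


class TestDistanceTransform:
    def test_three_row_strip_centre_distance(self):
        plane = np.zeros((9, 30))
        plane[3:6, :] = 1.0
        mask = nd.binarize_otsu(plane)
        d = nd.distance_transform(mask)
        # centre row is two rows from the nearest exterior boundary pixel
        assert np.allclose(d[4, 5:25], 2.0)
        assert np.all(d[mask.boundary] == 0)
        assert np.all(d[~mask.foreground] == 0)

    def test_single_pixel_distance_one(self):
        plane = np.zeros((7, 7))
        plane[3, 3] = 1.0
        d = nd.distance_transform(nd.binarize_otsu(plane))
        assert d[3, 3] == 1.0

    def test_disc_maximum_matches_radius(self):
        plane = disc_mask((40, 40), (20, 20), 10).astype(float)
        d = nd.distance_transform(nd.binarize_otsu(plane))
        assert 9.0 <= d.max() <= 11.0

    def test_lipschitz_property(self, rng):
        plane = (rng.random((40, 40)) > 0.6).astype(float)
        mask = nd.binarize_otsu(plane)
        d = nd.distance_transform(mask)
        fg = np.argwhere(mask.foreground)
        idx = rng.choice(len(fg), size=min(200, len(fg)), replace=False)
        pts = fg[idx]
        for i in range(0, len(pts) - 1, 2):
            p, q = pts[i], pts[i + 1]
            assert abs(d[tuple(p)] - d[tuple(q)]) <= np.linalg.norm(p - q) + 1e-9


class TestWatershedCentroids:
    def test_single_disc_single_centroid(self):
        plane = disc_mask((50, 50), (25, 25), 10).astype(float)
        mask = nd.binarize_otsu(plane)
        cs = nd.watershed_centroids(nd.distance_transform(mask), mask)
        assert len(cs) == 1
        assert np.linalg.norm(cs.coords[0] - [25, 25]) < 1.0

    def test_two_separated_discs(self):
        plane = (
            disc_mask((60, 80), (30, 20), 8) | disc_mask((60, 80), (30, 60), 8)
        ).astype(float)
        mask = nd.binarize_otsu(plane)
        cs = nd.watershed_centroids(nd.distance_transform(mask), mask)
        assert len(cs) == 2
        found = sorted(tuple(c) for c in cs.coords)
        for est, true in zip(found, [(30, 20), (30, 60)]):
            assert np.linalg.norm(np.array(est) - true) < 2.0

    def test_overlapping_discs_split_into_two_segments(self):
        # centres 14 px apart with radius 8: overlap of 2 px = 25% of radius
        plane = (
            disc_mask((40, 60), (20, 22), 8) | disc_mask((40, 60), (20, 36), 8)
        ).astype(float)
        mask = nd.binarize_otsu(plane)
        cs = nd.watershed_centroids(nd.distance_transform(mask), mask)
        assert len(cs) == 2
        # the splitting line is perpendicular to the centre-centre axis:
        # segment membership flips along columns, not rows
        labels = cs.region_labels
        left = labels[20, 24]
        right = labels[20, 34]
        assert left != right and left > 0 and right > 0

    def test_foreground_partition(self):
        plane = (
            disc_mask((60, 80), (30, 20), 9) | disc_mask((60, 80), (30, 60), 9)
        ).astype(float)
        mask = nd.binarize_otsu(plane)
        cs = nd.watershed_centroids(
            nd.distance_transform(mask), mask, min_area=0
        )
        # every foreground pixel receives exactly one positive label
        assert np.all(cs.region_labels[mask.foreground] > 0)
        assert np.all(cs.region_labels[~mask.foreground] == 0)
        assert cs.region_labels.max() == len(cs)


class TestDetect:
    def test_planted_nuclei_recovered(self, he_matrix):
        spec = syn.detection_benchmark_specs()[2]
        image, truth = syn.generate_roi(spec, 128, 128, he_matrix, seed=21)
        cs = nd.detect(image, he_matrix)
        matched, _, spurious = nd.match_centroids(cs.coords, truth.centroids, 3.0)
        assert matched >= 0.95 * truth.n_nuclei
        assert spurious <= 0.10 * truth.n_nuclei

    def test_blank_eosin_tile_yields_no_centroids(self, he_matrix):
        spec = syn.ClassSpec(
            "BS", 0, "sparse_random", 3.5, texture_noise_sd=0.0, eosin_level=0.4
        )
        image, _ = syn.generate_roi(spec, 64, 64, he_matrix, seed=1)
        with pytest.warns(UserWarning):
            cs = nd.detect(image, he_matrix)
        assert len(cs) == 0

    def test_detection_deterministic(self, sample_roi, he_matrix):
        image, _ = sample_roi
        a = nd.detect(image, he_matrix)
        b = nd.detect(image, he_matrix)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.region_labels, b.region_labels)


class TestMatchCentroids:
    def test_empty_inputs(self):
        assert nd.match_centroids(np.empty((0, 2)), np.ones((3, 2))) == (0, 3, 0)
        assert nd.match_centroids(np.ones((2, 2)), np.empty((0, 2))) == (0, 0, 2)

    def test_one_to_one_within_radius(self):
        truth = np.array([[10.0, 10.0], [30.0, 30.0]])
        det = np.array([[11.0, 10.0], [30.0, 31.0], [50.0, 50.0]])
        assert nd.match_centroids(det, truth, 3.0) == (2, 0, 1)


class TestDetectedVsPlantedFeatures:
    def test_architecture_features_statistically_similar(self, benchmark_rois, he_matrix):
        """Architecture features from detected centroids match those from
        planted centroids (no significant two-sample t-test difference for
        the majority of the 48 features), mirroring a manual-vs-automatic
        annotation comparison."""
        by_class: dict[str, dict[str, list]] = {}
        for image, truth in benchmark_rois:
            cs = nd.detect(image, he_matrix)
            det_vec = arch.architecture_vector(cs.coords, image.shape[:2])
            true_vec = arch.architecture_vector(truth.centroids, image.shape[:2])
            rec = by_class.setdefault(truth.label, {"det": [], "true": []})
            rec["det"].append(det_vec)
            rec["true"].append(true_vec)
        for label, rec in by_class.items():
            det = np.array(rec["det"])
            true = np.array(rec["true"])
            n_similar = 0
            for j in range(det.shape[1]):
                if np.allclose(det[:, j], true[:, j]):
                    n_similar += 1
                    continue
                _, p = stats.ttest_ind(det[:, j], true[:, j])
                if p > 0.05:
                    n_similar += 1
            assert n_similar > 24, f"class {label}: only {n_similar}/48 similar"
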