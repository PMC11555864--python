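import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhizospec.classify import (
    CLASS_IDS,
    CLASS_NAMES,
    ClassMap,
    ReferenceSpectra,
    ROISet,
    class_mean_spectra,
    kmeans_classify,
    map_clusters_to_classes,
    relabel,
    roi_mean_spectra,
    sam_classify,
    spectral_angle,
)
from rhizospec.cube_io import Datacube, Wavelengths


def _cube_from(data):
    data = np.asarray(data, dtype=float)
    return Datacube(data, Wavelengths(np.linspace(470, 900, data.shape[2])))


class TestSpectralAngle:
    def test_identical_spectra_zero(self):
        v = np.array([0.2, 0.5, 0.9])
        assert spectral_angle(v, v) == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_ninety(self):
        assert spectral_angle([1, 0], [0, 1]) == pytest.approx(90.0)

    def test_analytic_forty_five(self):
        assert spectral_angle([1, 1], [1, 0]) == pytest.approx(45.0)

    def test_symmetry_and_zero_norm_error(self):
        a, b = np.array([0.1, 0.7, 0.3]), np.array([0.4, 0.2, 0.9])
        assert spectral_angle(a, b) == pytest.approx(spectral_angle(b, a))
        with pytest.raises(ValueError):
            spectral_angle(a, np.zeros(3))

    @settings(deadline=None, derandomize=True)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(0, 100),
    )
    def test_invariant_to_positive_scaling(self, scale, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(0.01, 1, 8), rng.uniform(0.01, 1, 8)
        assert spectral_angle(a * scale, b) == pytest.approx(
            spectral_angle(a, b), abs=1e-8
        )


class TestRoiMeanSpectra:
    def test_constant_rois_recovered(self):
        data = np.zeros((4, 6, 3))
        data[0, :2] = 0.2
        data[1, :2] = 0.4
        data[2, :2] = 0.6
        cube = _cube_from(data)
        rois = ROISet(
            {
                "soil": [(0, 0), (0, 1)],
                "interface": [(1, 0), (1, 1)],
                "root": [(2, 0), (2, 1)],
            }
        )
        refs = roi_mean_spectra(cube, rois)
        np.testing.assert_allclose(refs.spectra["soil"], 0.2)
        np.testing.assert_allclose(refs.spectra["interface"], 0.4)
        np.testing.assert_allclose(refs.spectra["root"], 0.6)

    def test_mixed_roi_is_pixel_average(self):
        data = np.zeros((2, 2, 3))
        data[0, 0], data[0, 1] = 0.2, 0.4
        cube = _cube_from(data)
        cube.data[1, 0] = cube.data[1, 1] = 0.5  # fill other classes
        rois = ROISet(
            {"soil": [(0, 0), (0, 1)], "interface": [(1, 0)], "root": [(1, 1)]}
        )
        np.testing.assert_allclose(
            roi_mean_spectra(cube, rois).spectra["soil"], 0.3
        )

    def test_matches_loop_oracle_and_skips_masked(self, small_cube):
        rng = np.random.default_rng(1)
        coords = [(int(r), int(c)) for r, c in
                  zip(rng.integers(0, 12, 30), rng.integers(0, 10, 30))]
        coords = list(dict.fromkeys(coords))
        small_cube.pixel_mask[coords[0]] = False
        small_cube.data[coords[0]] = 0.0
        rois = ROISet({"soil": coords, "interface": [(11, 9)], "root": [(11, 8)]})
        refs = roi_mean_spectra(small_cube, rois)
        usable = [rc for rc in coords if small_cube.pixel_mask[rc]]
        oracle = np.mean([small_cube.data[rc] for rc in usable], axis=0)
        np.testing.assert_allclose(refs.spectra["soil"], oracle)
        assert refs.pixel_counts["soil"] == len(usable)

    def test_empty_usable_roi_is_error(self, small_cube):
        small_cube.pixel_mask[0, 0] = False
        rois = ROISet({"soil": [(0, 0)], "interface": [(1, 1)], "root": [(2, 2)]})
        with pytest.raises(ValueError, match="no usable"):
            roi_mean_spectra(small_cube, rois)

    def test_small_roi_warns(self):
        with pytest.warns(UserWarning, match="only"):
            ROISet({"soil": [(0, 0)], "interface": [], "root": []})


def _three_class_cube():
    """Rows 0-1 soil-like, 2-3 interface-like, 4-5 root-like."""
    refs = ReferenceSpectra(
        {
            "soil": np.array([0.2, 0.1, 0.1]),
            "interface": np.array([0.3, 0.3, 0.3]),
            "root": np.array([0.2, 0.5, 0.7]),
        }
    )
    data = np.zeros((6, 4, 3))
    data[0:2] = refs.spectra["soil"]
    data[2:4] = refs.spectra["interface"]
    data[4:6] = refs.spectra["root"]
    return _cube_from(data), refs


class TestSamClassify:
    def test_exact_references_recovered(self):
        cube, refs = _three_class_cube()
        cmap = sam_classify(cube, refs)
        expected = np.repeat([[1], [2], [3]], 2, axis=0).repeat(4, axis=1)
        np.testing.assert_array_equal(cmap.labels, expected)

    def test_above_threshold_stays_unlabeled(self):
        cube, refs = _three_class_cube()
        cube.data[0, 0] = [0.9, 0.05, 0.9]  # far from every reference
        cmap = sam_classify(cube, refs, threshold_deg=10.0)
        assert cmap.labels[0, 0] == 0

    def test_masked_and_zero_pixels_unlabeled(self):
        cube, refs = _three_class_cube()
        cube.pixel_mask[1, 1] = False
        cube.data[2, 2] = 0.0
        cmap = sam_classify(cube, refs)
        assert cmap.labels[1, 1] == 0 and cmap.labels[2, 2] == 0

    def test_scale_invariance_of_labels(self):
        cube, refs = _three_class_cube()
        scaled = cube.copy()
        scaled.data[4, 0] *= 7.3  # positive scalar on one pixel
        a = sam_classify(cube, refs)
        b = sam_classify(scaled, refs)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_noiseless_scene_matches_ground_truth(self, noiseless_scene):
        refs = roi_mean_spectra(noiseless_scene.cube, noiseless_scene.rois)
        cmap = sam_classify(noiseless_scene.cube, refs)
        np.testing.assert_array_equal(cmap.labels, noiseless_scene.truth.labels)


def _lloyd_oracle(pixels, centroids0, max_iter):
    """Naive loop Lloyd's algorithm used as a step-wise oracle."""
    centroids = centroids0.copy()
    assignment = np.full(pixels.shape[0], -1)
    history = []
    for _ in range(max_iter):
        d = np.array(
            [[np.sum((p - c) ** 2) for c in centroids] for p in pixels]
        )
        new_assignment = d.argmin(axis=1)
        if np.array_equal(new_assignment, assignment):
            break
        assignment = new_assignment
        for j in range(centroids.shape[0]):
            members = pixels[assignment == j]
            if len(members):
                centroids[j] = members.mean(axis=0)
        inertia = sum(
            np.sum((pixels[i] - centroids[assignment[i]]) ** 2)
            for i in range(len(pixels))
        )
        history.append(inertia)
    return assignment, centroids, history


class TestKMeans:
    def test_separable_blobs_partitioned(self):
        data = np.zeros((6, 6, 3))
        data[:2] = [0.1, 0.1, 0.1]
        data[2:4] = [0.5, 0.5, 0.5]
        data[4:] = [0.9, 0.9, 0.9]
        cmap, _ = kmeans_classify(_cube_from(data), k=3, seed=0)
        blocks = [cmap.labels[:2], cmap.labels[2:4], cmap.labels[4:]]
        labels = [np.unique(b) for b in blocks]
        assert all(len(l) == 1 for l in labels)
        assert len({l[0] for l in labels}) == 3

    def test_k_one_centroid_is_global_mean(self, small_cube):
        _, centroids = kmeans_classify(small_cube, k=1, seed=0)
        np.testing.assert_allclose(
            centroids[0], small_cube.spectra_2d().mean(axis=0)
        )

    def test_matches_naive_lloyd_step_for_step(self, small_cube):
        from rhizospec.classify import _farthest_point_init

        cmap, centroids = kmeans_classify(small_cube, k=3, max_iter=20, seed=11)
        pixels = small_cube.spectra_2d()
        rng = np.random.default_rng(11)
        init = _farthest_point_init(pixels, 3, rng)
        oracle_assign, oracle_centroids, history = _lloyd_oracle(pixels, init, 20)
        np.testing.assert_array_equal(
            cmap.labels.ravel() - 1, oracle_assign
        )
        np.testing.assert_allclose(centroids, oracle_centroids)
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    def test_deterministic_for_fixed_seed(self, small_cube):
        a, ca = kmeans_classify(small_cube, seed=4)
        b, cb = kmeans_classify(small_cube, seed=4)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(ca, cb)

    def test_every_unmasked_pixel_labeled(self, default_scene):
        cube = default_scene.cube
        cmap, _ = kmeans_classify(cube, seed=0)
        assert (cmap.labels[cube.pixel_mask] > 0).all()

    def test_agrees_with_sklearn_on_final_inertia(self, small_cube):
        from sklearn.cluster import KMeans

        pixels = small_cube.spectra_2d()
        _, centroids = kmeans_classify(small_cube, k=3, max_iter=50, seed=2)
        d2 = ((pixels[:, None, :] - centroids[None]) ** 2).sum(-1)
        ours = d2.min(axis=1).sum()
        ref = KMeans(n_clusters=3, n_init=10, random_state=0).fit(pixels)
        assert ours <= ref.inertia_ * 1.05  # near-optimal partition

    def test_too_few_distinct_pixels_is_error(self):
        cube = _cube_from(np.full((2, 2, 3), 0.5))
        with pytest.raises(ValueError, match="distinct"):
            kmeans_classify(cube, k=3)


class TestClusterNaming:
    def _refs(self):
        return ReferenceSpectra(
            {
                "soil": np.array([0.2, 0.1, 0.1]),
                "interface": np.array([0.3, 0.3, 0.3]),
                "root": np.array([0.2, 0.5, 0.7]),
            }
        )

    def test_identity_mapping_for_exact_centroids(self):
        refs = self._refs()
        mapping = map_clusters_to_classes(refs.matrix(), refs)
        assert mapping == {1: 1, 2: 2, 3: 3}

    def test_permuted_centroids_recover_inverse(self):
        refs = self._refs()
        perm = [2, 0, 1]  # centroid order root, soil, interface
        mapping = map_clusters_to_classes(refs.matrix()[perm], refs)
        assert mapping == {1: 3, 2: 1, 3: 2}

    def test_noisy_centroids_match_exhaustive_assignment(self):
        refs = self._refs()
        rng = np.random.default_rng(0)
        centroids = refs.matrix() + rng.normal(0, 0.01, (3, 3))
        mapping = map_clusters_to_classes(centroids, refs)
        for j in range(3):
            angles = [
                spectral_angle(centroids[j], refs.spectra[name])
                for name in CLASS_NAMES
            ]
            assert mapping[j + 1] == int(np.argmin(angles)) + 1

    def test_reflectance_ordering_heuristic(self):
        centroids = np.array([[0.6, 0.6], [0.1, 0.1], [0.3, 0.3]])
        mapping = map_clusters_to_classes(centroids, refs=None)
        assert mapping == {2: 1, 3: 2, 1: 3}  # dark->soil ... bright->root


class TestClassMeanSpectra:
    def test_single_class_equals_global_mean(self, small_cube):
        cmap = ClassMap(np.full((12, 10), CLASS_IDS["root"]))
        with pytest.warns(UserWarning):
            table = class_mean_spectra(small_cube, cmap)
        root = table[table["class"] == "root"]["mean_reflectance"].to_numpy()
        np.testing.assert_allclose(root, small_cube.spectra_2d().mean(axis=0))

    def test_checkerboard_of_constants(self):
        data = np.zeros((4, 4, 3))
        labels = np.zeros((4, 4), dtype=int)
        for i in range(4):
            for j in range(4):
                if (i + j) % 2 == 0:
                    data[i, j], labels[i, j] = 0.2, 1
                else:
                    data[i, j], labels[i, j] = 0.6, 3
        with pytest.warns(UserWarning):  # interface class empty
            table = class_mean_spectra(_cube_from(data), ClassMap(labels))
        means = table.groupby("class")["mean_reflectance"].mean()
        assert means["soil"] == pytest.approx(0.2)
        assert means["root"] == pytest.approx(0.6)

    def test_scene_class_means_near_endmembers(self, default_scene):
        table = class_mean_spectra(default_scene.cube, default_scene.truth)
        for name in CLASS_NAMES:
            got = (
                table[table["class"] == name]
                .sort_values("wavelength_nm")["mean_reflectance"]
                .to_numpy()
            )
            want = default_scene.endmembers[name]
            n_pix = (default_scene.truth.labels == CLASS_IDS[name]).sum()
            # a few standard errors of the compound per-band noise
            sigma = np.sqrt(0.01**2 + (0.03 * want) ** 2)
            assert np.all(np.abs(got - want) < 6 * sigma / np.sqrt(n_pix))


class TestRelabelAndPng:
    def test_relabel_lut(self):
        cmap = ClassMap(np.array([[0, 1], [2, 3]]))
        out = relabel(cmap, {1: 3, 2: 1, 3: 2})
        np.testing.assert_array_equal(out.labels, [[0, 3], [1, 2]])

    def test_png_round_trip(self, tmp_path):
        labels = np.random.default_rng(0).integers(0, 4, (9, 7))
        cmap = ClassMap(labels)
        cmap.to_png(tmp_path / "m.png")
        back = ClassMap.from_png(tmp_path / "m.png")
        np.testing.assert_array_equal(back.labels, cmap.labels)
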