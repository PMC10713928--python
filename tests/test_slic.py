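"""SLIC-Occ distances, seeding and the clustering itself."""

import numpy as np
import pytest

from slicocc import (
    OccupancySeries,
    SLICOcc,
    cluster_mean_curves,
    feature_distance,
    grid_spacing,
    initialize_centers,
    run_slic_occ,
    spatial_distance,
    total_distance,
)


def _uniform_series(shape=(20, 20, 20), V=3, value=0.5):
    mask = np.ones(shape, dtype=bool)
    data = np.full((V,) + shape, value)
    return OccupancySeries(data, np.arange(1.0, V + 1), mask, stage="ideal")


class TestDistances:
    @pytest.mark.parametrize(
        "N,K,expected",
        [(8000, 1000, 2.0), (121 * 145 * 121, 8000, 6.4262), (64, 64, 1.0)],
    )
    def test_grid_spacing(self, N, K, expected):
        assert grid_spacing(N, K) == pytest.approx(expected, abs=5e-4)

    def test_grid_spacing_rejects_K_above_N(self):
        with pytest.raises(ValueError):
            grid_spacing(10, 11)

    @pytest.mark.parametrize(
        "c,v,expected",
        [((0, 0, 0), (3, 4, 0), 5.0), ((1, 2, 3), (1, 2, 3), 0.0), ((1, 2, 3), (4, 6, 3), 5.0)],
    )
    def test_spatial_distance(self, c, v, expected):
        assert spatial_distance(c, v) == pytest.approx(expected)

    def test_feature_distance(self):
        assert feature_distance(np.zeros(10), np.full(10, 0.1)) == pytest.approx(
            np.sqrt(0.1), abs=1e-12
        )
        assert feature_distance([0.2], [0.5]) == pytest.approx(0.3)
        assert feature_distance([1.0, 2.0], [1.0, 2.0]) == 0.0
        with pytest.raises(ValueError):
            feature_distance([1.0], [1.0, 2.0])

    def test_total_distance(self):
        # m = 0: pure feature distance; spatial = S contributes exactly m
        assert total_distance(0.7, 123.0, 5.0, 0.0) == pytest.approx(0.7)
        assert total_distance(0.0, 6.426, 6.426, 0.5) == pytest.approx(0.5)
        assert total_distance(0.3, 6.426, 6.426, 0.5) == pytest.approx(0.5831, abs=1e-4)


class TestSeeding:
    def test_cubic_mask_regular_grid(self):
        series = _uniform_series((20, 20, 20))
        centers = initialize_centers(series, 1000)
        assert len(centers) == 1000
        xs = sorted({c.spatial[0] for c in centers})
        assert len(xs) == 10
        assert np.diff(xs) == pytest.approx(np.full(9, 2.0))

    def test_single_center_at_box_middle(self):
        series = _uniform_series((10, 10, 10))
        centers = initialize_centers(series, 1)
        assert len(centers) == 1
        assert centers[0].spatial == pytest.approx([4.5, 4.5, 4.5])

    def test_spherical_mask_centers_intersect_mask(self):
        shape = (24, 24, 24)
        idx = np.indices(shape)
        mask = ((idx[0] - 11.5) ** 2 + (idx[1] - 11.5) ** 2 + (idx[2] - 11.5) ** 2) <= 10**2
        data = np.where(mask, 0.3, np.nan)[None].repeat(2, axis=0)
        series = OccupancySeries(data, np.array([1.0, 2.0]), mask, stage="ideal")
        centers = initialize_centers(series, 50)
        for c in centers:
            lo = np.floor(c.spatial).astype(int)
            cell = mask[lo[0] : lo[0] + 2, lo[1] : lo[1] + 2, lo[2] : lo[2] + 2]
            assert cell.any()

    def test_K_larger_than_mask_rejected(self):
        series = _uniform_series((4, 4, 4))
        with pytest.raises(ValueError):
            initialize_centers(series, 65)


def _canonical_partition(labels, mask):
    """Map each label to the sorted tuple of member flat indices."""
    flat = np.flatnonzero(mask.ravel())
    lab = labels.ravel()[flat]
    out = {}
    for f, l in zip(flat, lab):
        out.setdefault(l, []).append(f)
    return sorted(tuple(v) for v in out.values())


class TestClustering:
    def test_uniform_features_give_spatial_voronoi(self):
        # identical features everywhere: Eq for D reduces to the spatial term,
        # so the converged labeling is the Voronoi partition of the centers
        series = _uniform_series((16, 16, 16), V=2)
        lab = run_slic_occ(series, K=8, m=1.0, max_iter=20, tol=1e-6)
        coords = np.argwhere(series.brain_mask).astype(float)
        centers = np.array([c.spatial for c in lab.centers])
        d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        voronoi = d2.argmin(axis=1) + 1
        assert np.array_equal(lab.label_image[series.brain_mask], voronoi)

    def test_feature_boundary_beats_spatial_midline(self):
        # two-value feature image split off-center: with small m, K = 2, the
        # labeling follows the feature boundary, matching a brute-force
        # global k-means with the same distance
        shape = (10, 10, 10)
        mask = np.ones(shape, dtype=bool)
        data = np.zeros((2,) + shape)
        data[:, 3:, :, :] = 0.8  # boundary at x = 3, spatial midline at x = 5
        series = OccupancySeries(data, np.array([1.0, 2.0]), mask, stage="ideal")
        m = 0.01
        lab = run_slic_occ(series, K=2, m=m, max_iter=30, tol=1e-9)
        got = lab.label_image[mask]
        split = (np.argwhere(mask)[:, 0] >= 3).astype(int)
        # same partition up to label naming
        same = np.array_equal(got - 1, split) or np.array_equal(2 - got, split)
        assert same

        # brute-force global k-means oracle with identical distance and seeds
        coords = np.argwhere(mask).astype(float)
        feats = series.masked_curves()
        centers0 = initialize_centers(series, 2)
        cpos = np.array([c.spatial for c in centers0])
        cfeat = np.array([c.feature for c in centers0])
        S = grid_spacing(mask.sum(), 2)
        w = m**2 / S**2
        for _ in range(30):
            d2 = ((feats[:, None, :] - cfeat[None]) ** 2).sum(2) + (
                ((coords[:, None, :] - cpos[None]) ** 2).sum(2)
            ) * w
            assign = d2.argmin(axis=1)
            for k in range(2):
                sel = assign == k
                if sel.any():
                    cpos[k] = coords[sel].mean(0)
                    cfeat[k] = feats[sel].mean(0)
        assert np.array_equal(got - 1, assign) or np.array_equal(2 - got, assign)

    def test_partition_property(self, small_series):
        N = int(small_series.brain_mask.sum())
        lab = run_slic_occ(small_series, K=max(2, N // 260), m=0.5)
        inm = lab.label_image[small_series.brain_mask]
        assert inm.min() >= 1 and inm.max() == lab.K_final
        assert np.all(lab.label_image[~small_series.brain_mask] == 0)
        counts = np.array([c.member_count for c in lab.centers])
        assert counts.sum() == N
        assert counts.min() >= 1
        assert lab.K_final <= lab.K_initial

    def test_assigned_center_minimizes_distance(self, small_series):
        # argmin property at a fixed point: after convergence the centers are
        # stationary, so no voxel may prefer (lower D) another center whose
        # search window reaches it
        lab = run_slic_occ(small_series, K=40, m=0.5, max_iter=300, tol=1e-9)
        assert lab.converged
        mask = small_series.brain_mask
        coords = np.argwhere(mask).astype(float)
        feats = small_series.masked_curves()
        cpos = np.array([c.spatial for c in lab.centers])
        cfeat = np.array([c.feature for c in lab.centers])
        S = lab.S
        w = lab.m**2 / S**2
        rng = np.random.default_rng(0)
        pick = rng.choice(coords.shape[0], size=500, replace=False)
        assign = lab.label_image[mask][pick] - 1
        d2 = ((feats[pick, None, :] - cfeat[None]) ** 2).sum(2) + (
            ((coords[pick, None, :] - cpos[None]) ** 2).sum(2)
        ) * w
        covered = np.all(np.abs(coords[pick, None, :] - cpos[None]) <= S, axis=2)
        own = d2[np.arange(pick.size), assign]
        better = (d2 < own[:, None] - 1e-6) & covered
        assert not better.any()

    def test_reproducible_across_runs(self, small_series):
        a = run_slic_occ(small_series, K=50, m=0.5)
        b = run_slic_occ(small_series, K=50, m=0.5)
        assert np.array_equal(a.label_image, b.label_image)

    @pytest.mark.parametrize(
        "transform,inverse",
        [
            (lambda x: x[..., ::-1, :, :], lambda x: x[::-1, :, :]),
            (lambda x: x[..., :, ::-1, :], lambda x: x[:, ::-1, :]),
            (lambda x: x[..., ::-1, ::-1, ::-1], lambda x: x[::-1, ::-1, ::-1]),
            (
                lambda x: np.swapaxes(x, -3, -2),
                lambda x: np.swapaxes(x, 0, 1),
            ),
        ],
    )
    def test_orientation_invariance(self, small_series, transform, inverse):
        # clustering a flipped/permuted series and mapping back yields the
        # identical partition
        lab = run_slic_occ(small_series, K=45, m=0.5)
        flipped = OccupancySeries(
            np.ascontiguousarray(transform(small_series.data)),
            small_series.concentrations,
            np.ascontiguousarray(transform(small_series.brain_mask[None])[0]),
            stage=small_series.stage,
        )
        lab_f = run_slic_occ(flipped, K=45, m=0.5)
        back = np.ascontiguousarray(inverse(lab_f.label_image))
        assert _canonical_partition(lab.label_image, small_series.brain_mask) == (
            _canonical_partition(back, small_series.brain_mask)
        )

    def test_large_m_approaches_voronoi_of_seeds(self, small_series):
        # m >> feature scale: the feature term is negligible and the
        # converged partition is the spatial Voronoi diagram of its own
        # centers (voxels on exact midplanes are tie-broken and excluded)
        lab = run_slic_occ(small_series, K=45, m=1e6, max_iter=80, tol=1e-9)
        assert lab.converged
        mask = small_series.brain_mask
        coords = np.argwhere(mask).astype(float)
        centers = np.array([c.spatial for c in lab.centers])
        d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        order = np.sort(d2, axis=1)
        clear = order[:, 1] - order[:, 0] > 1e-6
        voronoi = d2.argmin(axis=1) + 1
        got = lab.label_image[mask]
        assert clear.mean() > 0.95
        assert np.array_equal(got[clear], voronoi[clear])

    def test_mean_cluster_size_close_to_N_over_K(self):
        # default-scale phantom: requested K sets the approximate cluster
        # volume N/K
        from slicocc import PhantomSpec, simulate_study

        _, series = simulate_study(PhantomSpec(seed=4))
        N = int(series.brain_mask.sum())
        K = max(2, round(N / 265.4))
        lab = run_slic_occ(series, K=K, m=0.5)
        sizes = np.bincount(lab.label_image[series.brain_mask])[1:]
        assert sizes.mean() == pytest.approx(N / K, rel=0.2)

    def test_sklearn_estimator_interface(self, small_series):
        from sklearn.base import clone

        est = SLICOcc(n_clusters=30, compactness=0.5)
        assert clone(est).get_params()["n_clusters"] == 30
        est.set_params(max_iter=5).fit(small_series)
        assert est.labels_.shape == small_series.brain_mask.shape
        assert est.n_clusters_ == len(est.centers_)


class TestClusterCurves:
    def test_mean_curves_match_direct_average(self, small_series):
        lab = run_slic_occ(small_series, K=30, m=0.5)
        curves, counts = cluster_mean_curves(lab, small_series)
        mask = small_series.brain_mask
        k = int(counts.argmax()) + 1
        sel = lab.label_image == k
        np.testing.assert_allclose(
            curves[k - 1], small_series.data[:, sel].mean(axis=1), atol=1e-12
        )
        assert counts.sum() == mask.sum()

    def test_two_voxel_cluster_mean(self):
        shape = (2, 1, 1)
        mask = np.ones(shape, dtype=bool)
        a, b = np.array([0.1, 0.2]), np.array([0.3, 0.6])
        data = np.stack([np.array([[[a[0]]], [[b[0]]]]), np.array([[[a[1]]], [[b[1]]]])])
        series = OccupancySeries(data, np.array([1.0, 2.0]), mask, stage="ideal")
        from slicocc import ClusterLabeling

        lab = ClusterLabeling(
            label_image=np.ones(shape, dtype=np.int32),
            centers=[],
            K_initial=1,
            K_final=1,
            m=0.5,
            S=1.0,
            n_iterations=0,
            converged=True,
        )
        curves, counts = cluster_mean_curves(lab, series)
        np.testing.assert_allclose(curves[0], (a + b) / 2)
        assert counts[0] == 2

    def test_hotspot_cluster_noise_free_curve(self, noiseless_small):
        # a cluster fully inside the EC50 = 50 region has exactly the Emax
        # curve of that region
        spec, truth, series = noiseless_small
        lab = run_slic_occ(series, K=50, m=0.5)
        put = truth.region_mask("putamen")
        curves, _ = cluster_mean_curves(lab, series)
        labs_in = np.unique(lab.label_image[put])
        inner = [k for k in labs_in if np.all(truth.label_image[lab.label_image == k] == truth.region_labels["putamen"])]
        assert inner, "no cluster fully inside the putamen-like region"
        c = spec.concentrations
        expected = 0.85 * c / (c + 50.0)
        np.testing.assert_allclose(curves[inner[0] - 1], expected, atol=1e-12)
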