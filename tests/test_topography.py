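"""Registration, lesion metrics, coverage, heatmaps and the logistic model."""
import numpy as np
import pytest
from shapely.geometry import box

from fcdq import synthio as sy
from fcdq import topography as tp


class TestSimilarityTransform:
    def test_identity(self):
        pts = np.array([[0.0, 0.0], [1.0, 2.0], [3.0, -1.0]])
        t = tp.fit_similarity_transform(pts, pts)
        assert t.scale == pytest.approx(1.0)
        assert t.rotation == pytest.approx(0.0)
        assert np.allclose(t.translation, 0.0)

    def test_pure_translation(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0]])
        t = tp.fit_similarity_transform(src, src + [2.0, 3.0])
        assert t.scale == pytest.approx(1.0)
        assert t.rotation == pytest.approx(0.0)
        assert np.allclose(t.translation, [2.0, 3.0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_known_similarity(self, seed):
        rng = np.random.default_rng(seed)
        src = rng.normal(0, 2, (4, 2))
        s, theta = 1.3, 0.4
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        dst = s * src @ R.T + [0.5, -1.0]
        t = tp.fit_similarity_transform(src, dst)
        assert t.scale == pytest.approx(s, abs=1e-9)
        assert t.rotation == pytest.approx(theta, abs=1e-9)
        assert np.allclose(t.apply(src), dst, atol=1e-9)
        # cross-check against the scikit-image estimator
        from skimage.transform import SimilarityTransform as SkSim
        sk = SkSim.from_estimate(src, dst)
        assert t.scale == pytest.approx(sk.scale, abs=1e-9)

    def test_coincident_sources_rejected(self):
        with pytest.raises(tp.DegenerateLandmarksError):
            tp.fit_similarity_transform([[1.0, 1.0], [1.0, 1.0]],
                                        [[0.0, 0.0], [2.0, 2.0]])

    def test_inverse_round_trip(self):
        t = tp.SimilarityTransform(1.7, 0.3, (2.0, -1.0))
        pts = np.array([[0.5, 1.5], [-2.0, 0.1]])
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-12)


class TestProjection:
    def test_identity_landmarks_preserve_mask(self, refmap, map_grid):
        # a mask already sampled on the map grid projects onto itself
        g = map_grid
        raster = np.zeros(g.shape, dtype=np.uint8)
        raster[200:260, 80:150] = 1
        H = g.shape[0]

        def px_of(p):
            col = (p[0] - g.x0) / g.scale - 0.5
            row = (g.y_max - p[1]) / g.scale - 0.5
            return (col, row)

        mask = tp.DorsalImageMask(raster=raster, pixel_scale=g.scale,
                                  bregma_px=px_of(refmap.bregma),
                                  lambda_px=px_of(refmap.lambda_))
        proj = tp.project_mask_to_map(mask, refmap, grid=g)
        assert np.array_equal(proj, raster.astype(bool))

    def test_projected_area_matches_truth(self, refmap, map_grid, small_cohort):
        masks, truth = small_cohort
        for m, (_, row) in zip(masks, truth.iterrows()):
            proj = tp.project_mask_to_map(m, refmap, grid=map_grid)
            rec = tp.lesion_metrics(proj, refmap, map_grid)
            assert rec.area == pytest.approx(row.area_mm2, rel=0.02)
            assert rec.frontal_edge == pytest.approx(row.frontal_edge_mm, abs=0.05)

    def test_empty_mask_projects_empty(self, refmap):
        mask = tp.DorsalImageMask(raster=np.zeros((50, 50), np.uint8),
                                  pixel_scale=0.1, bregma_px=(25.0, 10.0),
                                  lambda_px=(25.0, 40.0))
        assert not tp.project_mask_to_map(mask, refmap).any()

    def test_missing_landmark_raises(self, refmap):
        mask = tp.DorsalImageMask(raster=np.ones((5, 5), np.uint8),
                                  pixel_scale=0.1, bregma_px=None,
                                  lambda_px=(2.0, 2.0))
        with pytest.raises(ValueError, match="bregma"):
            tp.project_mask_to_map(mask, refmap)


class TestLesionMetrics:
    def test_area_from_pixel_count(self, refmap, map_grid):
        raster = np.zeros(map_grid.shape, dtype=bool)
        raster[100:200, 50:150] = True  # 10,000 px at 0.02 mm/px
        rec = tp.lesion_metrics(raster, refmap, map_grid)
        assert rec.area == pytest.approx(4.0)

    def test_lsi_recomposition(self, refmap, map_grid, small_cohort):
        masks, _ = small_cohort
        proj = tp.project_mask_to_map(masks[0], refmap, grid=map_grid)
        rec = tp.lesion_metrics(proj, refmap, map_grid)
        assert rec.lsi == pytest.approx(np.sqrt(rec.area) + rec.frontal_edge)

    def test_frontal_edge_of_known_rectangle(self, refmap, map_grid):
        g = map_grid
        raster = np.zeros(g.shape, dtype=bool)
        rows = (g.y_max - np.array([7.0, 5.0])) / g.scale - 0.5
        raster[int(np.ceil(rows[0])):int(rows[1]), 100:120] = True
        rec = tp.lesion_metrics(raster, refmap, g)
        assert rec.frontal_edge == pytest.approx(7.0, abs=g.scale)

    def test_empty_mask_raises(self, refmap, map_grid):
        with pytest.raises(ValueError):
            tp.lesion_metrics(np.zeros(map_grid.shape, bool), refmap, map_grid)


class TestCoverage:
    def test_full_polygon_coverage(self, refmap, map_grid):
        X, Y = map_grid.pixel_centers()
        import shapely
        poly = refmap.area("M1").polygon
        mask = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(map_grid.shape)
        cov = tp.area_coverage(mask, refmap, map_grid)
        assert cov["M1"] == pytest.approx(1.0)
        assert all(v == pytest.approx(0.0, abs=1e-12)
                   for k, v in cov.items() if k != "M1")

    def test_empty_mask_all_zero(self, refmap, map_grid):
        cov = tp.area_coverage(np.zeros(map_grid.shape, bool), refmap, map_grid)
        assert all(v == 0.0 for v in cov.values())

    def test_half_plane_covers_half_square(self, map_grid):
        # a synthetic single-square atlas clipped by a half-plane mask
        square = tp.ReferenceMap(
            areas=(tp.CorticalArea("sq", "SQ", box(1.0, 1.0, 3.0, 3.0)),),
            domains={"SQ": "Sensory"}, bregma=(0.0, 4.2), lambda_=(0.0, 0.0))
        g = tp.MapGrid.for_map(square)
        X, _ = g.pixel_centers()
        mask = X < 2.0
        cov = tp.area_coverage(mask, square, g)
        assert cov["SQ"] == pytest.approx(0.5, abs=0.02)

    def test_domain_coverage_unweighted_mean(self, refmap):
        cov = {a: 0.0 for a in refmap.abbreviations}
        cov["M1"] = 1.0  # Executive has 4 members
        dom = tp.domain_coverage(cov, refmap)
        assert dom["Executive"] == pytest.approx(0.25)
        assert dom["Sensory"] == 0.0


class TestHeatmap:
    def test_single_seizing_mask(self):
        m = np.zeros((4, 4), bool)
        m[1, 1] = True
        heat = tp.build_group_heatmap([m], [])
        assert heat[1, 1] == 1.0 and heat.sum() == 1.0

    def test_identical_groups_cancel(self):
        m = np.random.default_rng(0).random((6, 6)) > 0.5
        heat = tp.build_group_heatmap([m, m], [m, m])
        assert np.allclose(heat, 0.0)

    def test_printed_group_weights(self):
        # 12 seizing and 14 non-seizing single-pixel disjoint masks
        shape = (1, 26)
        seizing = []
        for i in range(12):
            m = np.zeros(shape, bool); m[0, i] = True
            seizing.append(m)
        nonseizing = []
        for i in range(14):
            m = np.zeros(shape, bool); m[0, 12 + i] = True
            nonseizing.append(m)
        heat = tp.build_group_heatmap(seizing, nonseizing)
        assert np.allclose(heat[0, :12], 1 / 12)
        assert np.allclose(heat[0, 12:], -1 / 14)

    def test_both_groups_empty_rejected(self):
        with pytest.raises(ValueError):
            tp.build_group_heatmap([], [])

    def test_linearity_over_group_concatenation(self):
        rng = np.random.default_rng(3)
        ms = [rng.random((5, 5)) > 0.5 for _ in range(4)]
        h_all = tp.build_group_heatmap(ms, [])
        h_sum = sum(np.asarray(m, float) / 4 for m in ms)
        assert np.allclose(h_all, h_sum)


class TestLogisticModel:
    def test_symmetric_data(self):
        m = tp.fit_seizure_logistic([-1, -1, 1, 1], [0, 0, 1, 1])
        assert m.beta0 == pytest.approx(0.0, abs=1e-8)
        assert m.halfway_point == pytest.approx(0.0, abs=1e-8)
        assert m.separated  # perfectly classified data

    def test_halfway_point_probability(self):
        rng = np.random.default_rng(1)
        x = rng.normal(6.5, 1.0, 30)
        y = (rng.random(30) < 1 / (1 + np.exp(-(x - 6.5) * 2))).astype(int)
        m = tp.fit_seizure_logistic(x, y)
        assert m.predict(m.halfway_point) == pytest.approx(0.5, abs=1e-9)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 50)
        y = (rng.random(50) < 1 / (1 + np.exp(-(0.3 + 1.1 * x)))).astype(int)
        m = tp.fit_seizure_logistic(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert m.beta0 == pytest.approx(ref.params[0], abs=1e-6)
        assert m.beta1 == pytest.approx(ref.params[1], abs=1e-6)
        assert m.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_accuracy_at_least_prevalence_with_signal(self):
        # holds whenever position carries signal; for pure-noise labels the
        # in-sample accuracy of the MLE can dip just below the majority rate
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 40)
            y = (rng.random(40) < 1 / (1 + np.exp(-2.0 * x))).astype(int)
            if y.sum() in (0, 40):
                continue
            m = tp.fit_seizure_logistic(x, y)
            prev = max(y.mean(), 1 - y.mean())
            assert m.accuracy >= prev - 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tp.fit_seizure_logistic([1, 2, 3, 4], [1, 1, 1, 1])

    def test_lsi_monotone_in_area_and_position(self, refmap, map_grid):
        base = tp.LesionRecord("a", area=4.0, frontal_edge=6.0,
                               lsi=np.sqrt(4.0) + 6.0)
        bigger = np.sqrt(5.0) + 6.0
        more_frontal = np.sqrt(4.0) + 6.5
        assert bigger > base.lsi and more_frontal > base.lsi
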