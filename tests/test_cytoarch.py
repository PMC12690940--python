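"""3D cell detection, intensity thresholds, densities, cortex geometry."""
import numpy as np
import pytest

from fcdq import cytoarch as cy
from fcdq import synthio as sy


def _match_errors(dets, truth):
    centers = truth[["x_um", "y_um", "z_um"]].to_numpy()
    return [float(np.linalg.norm(centers - np.asarray(d.centroid), axis=1).min())
            for d in dets]


class TestDetectCells3D:
    def test_single_sphere_detected_at_equator(self):
        p = sy.CellFieldSimParams(n_cells=1, diameter_low=12.0, fraction_high=0.0,
                                  seed=31)
        stack, truth = sy.simulate_cell_stack(p, with_intensity=False)
        dets = cy.detect_cells_3d(stack, seed=0)
        assert len(dets) == 1
        equator = truth.z_um[0] / p.z_step
        assert abs(dets[0].max_area_frame - equator) <= 1.0

    def test_sphere_below_persistence_threshold_ignored(self):
        p = sy.CellFieldSimParams(n_cells=1, diameter_low=2.8, diameter_high=2.8,
                                  fraction_high=0.0, min_separation=5.0, seed=32)
        stack, _ = sy.simulate_cell_stack(p, with_intensity=False)
        frames_hit = np.unique(np.nonzero(stack.label_frames)[0])
        assert len(frames_hit) <= 3  # spans fewer frames than count_threshold
        assert cy.detect_cells_3d(stack, seed=0) == []

    def test_twenty_spheres_recovered_within_2um(self):
        p = sy.CellFieldSimParams(n_cells=20, frame_shape=(320, 320),
                                  diameter_low=12.0, diameter_high=16.0,
                                  fraction_high=0.5, min_separation=24.0,
                                  min_xy_separation=24.0, seed=33)
        stack, truth = sy.simulate_cell_stack(p, with_intensity=False)
        dets = cy.detect_cells_3d(stack, seed=0)
        assert len(dets) == 20
        assert max(_match_errors(dets, truth)) <= 2.0

    def test_effective_diameter_within_5pc(self, default_stack):
        stack, truth = default_stack
        dets = cy.detect_cells_3d(stack, seed=0)
        centers = truth[["x_um", "y_um", "z_um"]].to_numpy()
        for d in dets:
            j = int(np.argmin(np.linalg.norm(
                centers - np.asarray(d.centroid), axis=1)))
            assert d.effective_diameter == pytest.approx(
                truth.diameter_um[j], rel=0.05)
            assert d.minor_axis <= d.effective_diameter <= d.major_axis + 1e-9

    def test_non_integer_labels_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            cy.CellStack(label_frames=np.zeros((12, 8, 8), float),
                         intensity_frames=None, xy_scale=1.0, z_step=1.0)

    def test_too_few_frames_rejected(self):
        stack = cy.CellStack(label_frames=np.zeros((8, 8, 8), np.uint8),
                             intensity_frames=None, xy_scale=1.0, z_step=1.0)
        with pytest.raises(ValueError, match="margin"):
            cy.detect_cells_3d(stack, margin_frames=5)


class TestContrastStretchMIP:
    @staticmethod
    def _stack_from_intensity(frames):
        frames = np.asarray(frames, float)
        return cy.CellStack(label_frames=np.zeros(frames.shape, np.uint8),
                            intensity_frames=frames, xy_scale=1.0, z_step=1.0)

    def test_mip_of_repeated_frame_is_the_frame(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(20, 200, (50, 50))
        stack = self._stack_from_intensity(np.stack([f] * 12))
        mip = cy.stretch_contrast_mip(stack)
        expect = np.clip((f - np.percentile(f, 1)) * 255
                         / (np.percentile(f, 99) - np.percentile(f, 1)), 0, 255)
        assert np.allclose(mip, expect)

    def test_two_value_image_maps_to_extremes(self):
        img = np.full((100, 100), 200.0)
        img.ravel()[:200] = 10.0  # 2% low pixels: p1 = 10, p99 = 200
        stack = self._stack_from_intensity(img[None])
        mip = cy.stretch_contrast_mip(stack)
        assert set(np.unique(mip)) == {0.0, 255.0}

    def test_output_percentiles_pinned(self):
        rng = np.random.default_rng(1)
        stack = self._stack_from_intensity(rng.normal(100, 30, (12, 64, 64)))
        mip = cy.stretch_contrast_mip(stack)
        assert np.percentile(mip, 1) == pytest.approx(0.0, abs=1.0)
        assert np.percentile(mip, 99) == pytest.approx(255.0, abs=1.0)

    def test_constant_image_rejected(self):
        stack = self._stack_from_intensity(np.full((12, 10, 10), 7.0))
        with pytest.raises(ValueError, match="constant"):
            cy.stretch_contrast_mip(stack)


class TestCellMeanIntensity:
    @staticmethod
    def _det(cx, cy_, major, minor, theta=0.0):
        return cy.CellDetection(centroid=(cx, cy_, 0.0), max_area_frame=0,
                                major_axis=major, minor_axis=minor,
                                orientation=theta,
                                effective_diameter=np.sqrt(major * minor))

    def test_uniform_image(self):
        img = np.full((40, 40), 7.0)
        assert cy.cell_mean_intensity(img, self._det(20, 20, 10, 6)) == 7.0

    def test_indicator_image(self):
        img = np.zeros((60, 60))
        det = self._det(30, 30, 16, 10, theta=0.5)
        # paint exactly the ellipse's pixels, then the mean inside is 100
        probe = cy.cell_mean_intensity(img + 100.0, det)
        assert probe == 100.0

    def test_gradient_matches_pixel_loop_oracle(self):
        H = W = 50
        img = np.add.outer(np.arange(H), 2.0 * np.arange(W))
        det = self._det(24.0, 26.0, 18.0, 9.0, theta=0.7)
        got = cy.cell_mean_intensity(img, det)
        vals = []
        a, b = det.major_axis / 2, det.minor_axis / 2
        th = det.orientation
        for r in range(H):
            for c in range(W):
                dx, dy = c - det.centroid[0], r - det.centroid[1]
                u = dx * np.sin(th) + dy * np.cos(th)
                v = dx * np.cos(th) - dy * np.sin(th)
                if (u / a) ** 2 + (v / b) ** 2 <= 1:
                    vals.append(img[r, c])
        assert got == pytest.approx(np.mean(vals), abs=1e-9)

    def test_fitted_ellipse_overlaps_its_mask(self):
        # regionprops orientation convention must match the sampling ellipse
        from skimage.measure import regionprops
        rr, cc = np.mgrid[0:80, 0:80]
        u = (cc - 40) * np.cos(0.6) + (rr - 40) * np.sin(0.6)
        v = -(cc - 40) * np.sin(0.6) + (rr - 40) * np.cos(0.6)
        mask = ((u / 25) ** 2 + (v / 10) ** 2 <= 1).astype(np.uint8)
        rp = regionprops(mask)[0]
        det = cy.CellDetection(
            centroid=(rp.centroid[1], rp.centroid[0], 0.0), max_area_frame=0,
            major_axis=rp.axis_major_length, minor_axis=rp.axis_minor_length,
            orientation=rp.orientation,
            effective_diameter=1.0)
        frac = cy.cell_mean_intensity(mask.astype(float), det)
        assert frac > 0.95  # ellipse covers almost exclusively mask pixels

    def test_ellipse_outside_image_rejected(self):
        img = np.zeros((20, 20))
        with pytest.raises(ValueError):
            cy.cell_mean_intensity(img, self._det(100.0, 100.0, 4, 2))


class TestThresholds:
    def test_two_narrow_populations_midpoint(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(50, 1.5, 400), rng.normal(200, 1.5, 400)])
        model = cy.threshold_bigauss(x)
        assert model.threshold == pytest.approx(125.0, abs=2.0)

    def test_matches_em_oracle(self):
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(60, 10, 2500), rng.normal(180, 15, 2500)])
        model = cy.threshold_bigauss(x)
        gm = GaussianMixture(2, random_state=0).fit(x.reshape(-1, 1))
        means = np.sort(gm.means_.ravel())
        assert model.mu1 == pytest.approx(means[0], abs=2.0)
        assert model.mu2 == pytest.approx(means[1], abs=2.0)

    def test_unimodal_histogram_raises(self):
        rng = np.random.default_rng(4)
        with pytest.raises(cy.UnimodalIntensityError):
            cy.threshold_bigauss(rng.normal(100, 3, 1000))

    def test_shift_equivariance(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(60, 4, 800), rng.normal(150, 6, 800)])
        t0 = cy.threshold_bigauss(x).threshold
        t1 = cy.threshold_bigauss(x + 20.0).threshold
        assert t1 - t0 == pytest.approx(20.0, abs=1.0)

    @pytest.mark.parametrize("factor, expected", [(3.0, 120.0), (1.5, 60.0)])
    def test_background_factors(self, factor, expected):
        img = np.full((10, 10), 40.0)
        pts = [(0, 0), (5, 5), (9, 9)]
        assert cy.threshold_background(img, pts, factor) == pytest.approx(expected)

    def test_zero_background(self):
        assert cy.threshold_background(np.zeros((5, 5)), [(2, 2)], 3.0) == 0.0

    def test_no_points_rejected(self):
        with pytest.raises(ValueError):
            cy.threshold_background(np.zeros((5, 5)), [], 3.0)


class TestClassifyAndReport:
    @staticmethod
    def _dets(intensities, spacing=20.0):
        return [cy.CellDetection(centroid=(i * spacing, 0.0, 0.0),
                                 max_area_frame=0, major_axis=10, minor_axis=8,
                                 orientation=0.0, effective_diameter=9.0,
                                 mean_intensity=v)
                for i, v in enumerate(intensities)]

    def test_density_arithmetic(self):
        dets = self._dets([200.0] * 100)
        rep = cy.classify_and_report(dets, threshold=100.0, counting_volume=0.01)
        assert rep.density == pytest.approx(1e4)
        assert rep.fraction_high == 1.0

    def test_threshold_above_all(self):
        rep = cy.classify_and_report(self._dets([10, 20, 30]), threshold=100.0,
                                     counting_volume=1.0)
        assert rep.fraction_high == 0.0 and rep.n_cells == 0

    def test_density_scaling(self):
        dets = self._dets([200.0] * 30)
        r1 = cy.classify_and_report(dets, 100.0, counting_volume=0.5)
        r2 = cy.classify_and_report(dets, 100.0, counting_volume=1.0)
        assert r1.density == pytest.approx(2 * r2.density)

    def test_recovered_fraction_high_within_binomial_ci(self, default_stack):
        stack, truth = default_stack
        dets = cy.detect_cells_3d(stack, seed=0)
        thr = (60.0 + 180.0) / 2
        rep = cy.classify_and_report(dets, thr, counting_volume=1.0)
        n = len(dets)
        p = 0.3
        half = 1.96 * np.sqrt(p * (1 - p) / n)
        assert abs(rep.fraction_high - truth.population.eq("high").mean()) <= half + 0.1

    def test_overlap_fraction_matching(self):
        dets = self._dets([200.0, 10.0, 200.0])
        refs = self._dets([0.0, 0.0])  # coincide with dets 0 and 1
        rep = cy.classify_and_report(dets, 100.0, 1.0, reference_dets=refs)
        assert rep.overlap_fraction == pytest.approx(0.5)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            cy.classify_and_report([], 1.0, counting_volume=0.0)


class TestTangentialExtent:
    def test_excludes_one_point_each_side_at_n100(self):
        rng = np.random.default_rng(6)
        x = rng.permutation(np.linspace(0, 99, 100))
        lo, hi = cy.tangential_extent(x, trim=0.01)
        assert (np.sort(x)[1], np.sort(x)[-2]) == (lo, hi)

    def test_zero_trim_gives_min_max(self):
        x = [3.0, 1.0, 2.0]
        assert cy.tangential_extent(x, trim=0.0) == (1.0, 3.0)

    def test_uniform_large_sample_quantiles(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, 10_000)
        lo, hi = cy.tangential_extent(x, trim=0.01)
        assert lo == pytest.approx(0.01, abs=0.005)
        assert hi == pytest.approx(0.99, abs=0.005)


class TestCorticalThickening:
    def test_parallel_lines(self):
        x = np.linspace(-500, 500, 21)
        surf = np.column_stack([x, np.zeros_like(x)])
        gwm = np.column_stack([x, np.full_like(x, -1000.0)])
        g = cy.CortexGeometry(surf, gwm, center=(0.0, 0.0))
        t_l, t_c, pct = cy.cortical_thickening(g, g)
        assert t_l == pytest.approx(1000.0, rel=1e-6)
        assert pct == pytest.approx(0.0, abs=1e-9)

    def test_concentric_arcs(self):
        th = np.linspace(np.pi / 3, 2 * np.pi / 3, 200)
        surf = np.column_stack([2000 * np.cos(th), 2000 * np.sin(th)])
        gwm = np.column_stack([1200 * np.cos(th), 1200 * np.sin(th)])
        g = cy.CortexGeometry(surf, gwm, center=(0.0, 2000.0))
        t_l, _, _ = cy.cortical_thickening(g, g)
        assert t_l == pytest.approx(800.0, rel=0.01)

    def test_missing_boundary_raises(self):
        surf = np.array([[-10.0, 0.0], [10.0, 0.0]])
        gwm = np.array([[100.0, -50.0], [120.0, -50.0]])  # not under the center
        g = cy.CortexGeometry(surf, gwm, center=(0.0, 0.0))
        with pytest.raises(ValueError):
            cy.cortical_thickening(g, g)
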