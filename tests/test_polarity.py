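"""Cdc42 cluster morphometry and local curvature."""

import math

import numpy as np
import pytest

from ringscale.exceptions import DegenerateFitError, EmptyMaskError
from ringscale.geometry import CellMask
from ringscale.polarity import (
    cluster_area,
    cluster_axes,
    cluster_contour_length,
    cluster_pixels,
    cluster_threshold,
    curvature_radius_median,
    fit_circle,
    local_curvature_radius,
)
from ringscale.ring import resample_contour
from ringscale.synthetic import (
    PopulationConfig,
    RenderConfig,
    cell_contour,
    generate_population,
    generate_timecourse,
)

from conftest import circle_contour


def mixture_image(n_low=900, n_high=100, low=100.0, high=1000.0, shape=(25, 40)):
    n = n_low + n_high
    assert shape[0] * shape[1] == n
    img = np.full(n, low)
    img[:n_high] = high
    return img.reshape(shape)


class TestClusterThreshold:
    def test_hand_computed_mixture(self):
        # 900 px at 100 + 100 px at 1000: median 100, population SD 270
        img = mixture_image()
        mask = CellMask(np.ones_like(img, bool), 0.1)
        assert cluster_threshold(img, mask) == pytest.approx(640.0)

    def test_uniform_gives_empty_cluster(self):
        img = np.full((20, 20), 55.0)
        mask = CellMask(np.ones_like(img, bool), 0.1)
        assert cluster_threshold(img, mask) == pytest.approx(55.0)
        assert cluster_pixels(img, mask).sum() == 0  # strictly-above rule

    def test_pixels_outside_mask_ignored(self):
        img = mixture_image()
        half = np.zeros_like(img, bool)
        half[:15, :] = True  # covers all 100 bright + 350 dim pixels
        t_masked = cluster_threshold(img, CellMask(half, 0.1))
        img_noise = img.copy()
        img_noise[~half] = 1e6  # garbage outside the mask
        assert cluster_threshold(img_noise, CellMask(half, 0.1)) == t_masked

    def test_gain_equivariance_and_area_invariance(self):
        img = mixture_image()
        mask = CellMask(np.ones_like(img, bool), 0.1)
        assert cluster_threshold(img * 3.0, mask) == pytest.approx(
            3.0 * cluster_threshold(img, mask)
        )
        a1 = cluster_area([img] * 3, mask, 0.1)
        a2 = cluster_area([img * 2.0 + 7.0] * 3, mask, 0.1)
        assert a2 == pytest.approx(a1)

    def test_empty_mask_errors(self):
        with pytest.raises(EmptyMaskError):
            CellMask(np.zeros((5, 5), bool), 0.1)


class TestClusterArea:
    def test_threshold_example_area(self):
        img = mixture_image()
        mask = CellMask(np.ones_like(img, bool), 0.1)
        # 100 suprathreshold px at 0.1 µm/px -> 1.0 µm²
        assert cluster_area([img] * 3, mask, 0.1) == pytest.approx(1.0)

    def test_median_over_frames(self):
        mask = CellMask(np.ones((30, 30), bool), 0.1)
        frames = []
        for count in (98, 100, 104):
            img = np.full(900, 100.0)
            img[:count] = 1000.0
            frames.append(img.reshape(30, 30))
        assert cluster_area(frames, mask, 1.0) == pytest.approx(100.0)

    def test_all_empty_invalid(self):
        mask = CellMask(np.ones((10, 10), bool), 0.1)
        assert math.isnan(cluster_area([np.full((10, 10), 9.0)] * 3, mask, 0.1))


class TestClusterAxes:
    def test_rectangle_moment_oracle(self):
        rect = np.zeros((20, 20), bool)
        rect[5:9, 4:14] = True  # 10 x 4 px
        major, minor = cluster_axes(rect, 1.0)
        assert major == pytest.approx(4 * math.sqrt((100 - 1) / 12 + 1 / 12), abs=0.01)
        assert minor == pytest.approx(4 * math.sqrt((16 - 1) / 12 + 1 / 12), abs=0.01)

    def test_disk_symmetric(self):
        yy, xx = np.mgrid[0:41, 0:41]
        disk = (xx - 20) ** 2 + (yy - 20) ** 2 <= 15**2
        major, minor = cluster_axes(disk, 0.1)
        assert major == pytest.approx(minor, rel=0.02)

    def test_largest_component_rule(self):
        rect = np.zeros((30, 30), bool)
        rect[5:9, 4:14] = True
        with_blob = rect.copy()
        with_blob[20:23, 20:23] = True  # smaller disconnected blob
        assert cluster_axes(with_blob, 1.0) == cluster_axes(rect, 1.0)

    def test_empty_cluster_invalid(self):
        with pytest.raises(EmptyMaskError):
            cluster_axes(np.zeros((10, 10), bool), 1.0)


class TestClusterContourLength:
    def _arc_frames(self, contour, lo, hi, shape=(81, 81)):
        # bright arc on a dim in-cell background; threshold = median + 2SD
        # of in-mask pixels sits between the two levels
        img = np.full(shape, 50.0)
        for k in range(lo, hi + 1):
            x, y = contour[k % len(contour)]
            img[int(round(y)), int(round(x))] = 2000.0
        return img

    def test_arc_length_oracle(self):
        contour = circle_contour(20.0, 65, center=40.0)
        mask = CellMask(np.ones((81, 81), bool), 0.1)
        img = self._arc_frames(contour, 10, 20)
        length = cluster_contour_length([img] * 3, mask, contour, 0.1)
        gap = 2 * math.pi * 2.0 / 65
        assert length == pytest.approx(10 * gap, abs=2 * gap)

    def test_circular_shift_invariance(self):
        contour = circle_contour(20.0, 65, center=40.0)
        mask = CellMask(np.ones((81, 81), bool), 0.1)
        wrap = cluster_contour_length(
            [self._arc_frames(contour, 60, 70)] * 3, mask, contour, 0.1
        )
        mid = cluster_contour_length(
            [self._arc_frames(contour, 25, 35)] * 3, mask, contour, 0.1
        )
        assert wrap == pytest.approx(mid, rel=0.2)

    def test_no_suprathreshold_vertex_invalid(self):
        contour = circle_contour(20.0, 65, center=40.0)
        mask = CellMask(np.ones((81, 81), bool), 0.1)
        # cluster far from the contour: vertices stay below threshold
        img = np.full((81, 81), 50.0)
        img[38:43, 38:43] = 2000.0
        assert math.isnan(cluster_contour_length([img] * 3, mask, contour, 0.1))


class TestCurvature:
    def test_exact_circle(self):
        contour = circle_contour(20.0, 65)
        meas = local_curvature_radius(contour, anchor=7, pixel_size=0.1)
        assert meas.radius == pytest.approx(2.0, abs=1e-9)
        assert meas.residual == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        pts = circle_contour(17.0, 65) + rng.normal(0, 0.3, (65, 2))
        r0 = local_curvature_radius(pts, 12, 1.0).radius
        th = 0.7
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        moved = pts @ rot.T + np.array([13.0, -4.0])
        assert local_curvature_radius(moved, 12, 1.0).radius == pytest.approx(
            r0, abs=1e-9
        )

    def test_noise_recovery_monte_carlo(self):
        # vertex noise sigma = 0.01 µm on a 2 µm circle. The 7-vertex
        # window spans only ~33° of arc, where the algebraic fit is known
        # to bias slightly low under noise; the median over 100 trials
        # stays within 10% of the generating radius and the bias shrinks
        # with the noise.
        rng = np.random.default_rng(7)

        def median_radius(sigma_px):
            radii = [
                local_curvature_radius(
                    circle_contour(20.0, 65) + rng.normal(0, sigma_px, (65, 2)),
                    30,
                    0.1,
                ).radius
                for _ in range(100)
            ]
            return float(np.median(radii))

        assert median_radius(0.1) == pytest.approx(2.0, rel=0.10)
        assert abs(median_radius(0.02) - 2.0) < abs(median_radius(0.1) - 2.0)

    def test_collinear_degenerate(self):
        line = np.column_stack([np.arange(10.0), 2.0 * np.arange(10.0)])
        with pytest.raises(DegenerateFitError):
            fit_circle(line)
        with pytest.raises(DegenerateFitError):
            local_curvature_radius(line, 5, 0.1)

    def test_median_over_frames(self):
        contours = [circle_contour(r, 65) for r in (18.0, 20.0, 22.0, 20.0, 20.0)]
        assert curvature_radius_median(contours, 10, 0.1) == pytest.approx(2.0, abs=1e-6)

    def test_ellipse_tip_curvature(self):
        # analytic radius of curvature at the major-axis tip is b²/a
        cfg = PopulationConfig(n_cells=1, seed=21, aspect_ratio_mean=1.3,
                               aspect_ratio_sd=0.0, diameter_noise_cv=0.0)
        cell = generate_population(cfg)[0]
        contour = cell_contour(cell, RenderConfig(), 129)
        meas = local_curvature_radius(contour, 0, cell.pixel_size)
        expected = cell.semi_axis_b**2 / cell.semi_axis_a
        assert meas.radius == pytest.approx(expected, rel=0.05)


class TestSyntheticClusterIntegration:
    def _peak_frames(self, tc):
        p = tc.cluster_peak_frame
        return [tc.frames[t].cluster_image for t in (p - 1, p, p + 1)]

    def test_monotone_ladder(self):
        # larger rendered clusters -> strictly larger measured area
        from dataclasses import replace

        cfg = PopulationConfig(n_cells=1, seed=4, diameter_noise_cv=0.0)
        base = generate_population(cfg)[0]
        render = RenderConfig()
        areas = []
        for d in (0.6, 0.8, 1.0, 1.2, 1.4):
            cell = replace(base, cluster_diameter_true=d)
            tc = generate_timecourse(cell, render)
            mask = tc.frames[0].mask
            areas.append(cluster_area(self._peak_frames(tc), mask, cell.pixel_size))
        assert all(b > a for a, b in zip(areas, areas[1:]))

    def test_measure_cluster_bundle(self):
        cfg = PopulationConfig(n_cells=1, seed=4, diameter_noise_cv=0.0)
        cell = generate_population(cfg)[0]
        render = RenderConfig()
        tc = generate_timecourse(cell, render)
        from ringscale.polarity import measure_cluster

        meas = measure_cluster(
            self._peak_frames(tc),
            tc.frames[0].mask,
            cell_contour(cell, render, 65),
            cell.pixel_size,
        )
        assert meas.valid
        assert meas.area > 0
        assert meas.major_axis >= meas.minor_axis
        assert meas.contour_length > 0
        assert meas.threshold > 0

    def test_axes_and_contour_length_correlate(self):
        # the two cluster size measures agree (Pearson R > 0.5) across a
        # population with varying cluster size
        cfg = PopulationConfig(n_cells=25, seed=17, diameter_noise_cv=0.0)
        render = RenderConfig()
        majors, lengths = [], []
        for cell in generate_population(cfg):
            tc = generate_timecourse(cell, render)
            mask = tc.frames[0].mask
            frames = self._peak_frames(tc)
            cl = cluster_pixels(frames[1], mask)
            if not cl.any():
                continue
            major, _ = cluster_axes(cl, cell.pixel_size)
            contour = cell_contour(cell, render, 65)
            length = cluster_contour_length(frames, mask, contour, cell.pixel_size)
            if not math.isnan(length):
                majors.append(major)
                lengths.append(length)
        assert len(majors) >= 15
        r = np.corrcoef(majors, lengths)[0, 1]
        assert r > 0.5
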