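"""Boundary tracing, smoothing, circumradius curvature, blebbing rule."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skimage.draw import polygon2mask

from blebquant import (
    BlebbingThresholds,
    BoundaryTrace,
    CellFeatures,
    apply_cell_filters,
    classify_blebbing,
    intensity_ratio,
    mean_cell_curvature,
    point_curvature,
    smooth_boundary,
    trace_boundary,
)
from blebquant.morphometry import polygon_area


def _circle_trace(radius=50.0, n=720):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return BoundaryTrace(points=np.column_stack([radius * np.sin(th), radius * np.cos(th)]))


class TestTraceBoundary:
    def test_square_contour_point_count_and_area(self):
        mask = np.zeros((14, 14), bool)
        mask[2:12, 2:12] = True  # 10x10 filled square
        tr = trace_boundary(mask)
        assert 32 <= len(tr) <= 40
        assert abs(polygon_area(tr.points) - 100) / 100 < 0.05

    def test_disk_contour_length_matches_circumference(self):
        # the raw marching-squares trace carries a staircase length excess
        # (~6% on a disk); the smoothed trace is the curve the pipeline
        # measures, and its length matches the circumference closely
        rr, cc = np.mgrid[:70, :70]
        mask = (rr - 35) ** 2 + (cc - 35) ** 2 <= 30**2
        tr = smooth_boundary(trace_boundary(mask), 9, 3)
        closed = np.vstack([tr.points, tr.points[:1]])
        length = np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1))
        assert abs(length - 2 * np.pi * 30) / (2 * np.pi * 30) < 0.03

    def test_one_pixel_line_is_degenerate(self):
        mask = np.zeros((40, 40), bool)
        mask[20, 5:35] = True
        with pytest.raises(ValueError, match="degenerate|interior"):
            trace_boundary(mask)

    def test_multiple_components_rejected(self):
        mask = np.zeros((40, 40), bool)
        mask[5:15, 5:15] = True
        mask[25:35, 25:35] = True
        with pytest.raises(ValueError, match="component"):
            trace_boundary(mask)

    def test_no_duplicate_consecutive_points(self):
        rr, cc = np.mgrid[:50, :50]
        tr = trace_boundary((rr - 25) ** 2 + (cc - 25) ** 2 <= 15**2)
        assert np.all(np.any(np.diff(tr.points, axis=0) != 0, axis=1))


class TestSmoothBoundary:
    def test_straight_runs_are_reproduced(self):
        """Away from corners a rectangle's sides are polynomial (linear)."""
        mask = np.zeros((60, 80), bool)
        mask[10:50, 10:70] = True
        tr = trace_boundary(mask)
        sm = smooth_boundary(tr, 9, 3)
        # points whose full window lies on one straight side are unmoved
        corner_dist = np.min(
            np.abs(tr.points[:, None, :] - np.array(
                [[9.5, 9.5], [9.5, 69.5], [49.5, 9.5], [49.5, 69.5]]
            )[None]).sum(axis=2),
            axis=1,
        )
        interior = corner_dist > 9
        np.testing.assert_allclose(
            sm.points[interior], tr.points[interior], atol=1e-9
        )

    def test_noise_reduced_on_circle(self):
        rng = np.random.default_rng(0)
        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        r = 50 + rng.normal(0, 1.0, th.size)
        tr = BoundaryTrace(points=np.column_stack([r * np.sin(th), r * np.cos(th)]))
        sm = smooth_boundary(tr, 9, 3)
        rms_before = np.sqrt(np.mean((np.hypot(*tr.points.T) - 50) ** 2))
        rms_after = np.sqrt(np.mean((np.hypot(*sm.points.T) - 50) ** 2))
        assert rms_after < rms_before

    def test_window_equal_polyorder_plus_one_is_identity(self):
        tr = _circle_trace(n=64)
        sm = smooth_boundary(tr, 5, 4)
        np.testing.assert_allclose(sm.points, tr.points, atol=1e-9)

    @pytest.mark.parametrize(
        "window,polyorder,msg",
        [(8, 3, "odd"), (5, 5, "polyorder"), (999, 3, "points")],
    )
    def test_parameter_validation(self, window, polyorder, msg):
        with pytest.raises(ValueError, match=msg):
            smooth_boundary(_circle_trace(n=100), window, polyorder)


class TestPointCurvature:
    def test_collinear_points_have_zero_curvature(self):
        assert point_curvature((0, 0), (1, 0), (2, 0)) == 0.0

    def test_three_points_on_radius_ten_circle(self):
        assert point_curvature((10, 0), (0, 10), (-10, 0)) == pytest.approx(0.1)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            point_curvature((1, 1), (1, 1), (2, 2))

    @given(
        st.tuples(*[st.floats(-100, 100) for _ in range(6)]).filter(
            lambda t: len({t[:2], t[2:4], t[4:]}) == 3
        )
    )
    def test_matches_bruteforce_circumcenter(self, coords):
        """kappa equals 1/distance-to-circumcenter solved from the normal equations."""
        pa, pb, pc = np.array(coords[:2]), np.array(coords[2:4]), np.array(coords[4:])
        u, v = pb - pa, pc - pa
        area2 = abs(u[0] * v[1] - u[1] * v[0])
        if area2 < 1e-9:  # (near-)collinear: definition gives 0
            assert point_curvature(pa, pb, pc) <= 1e-6 * 4 / max(
                np.prod([np.linalg.norm(x - y) for x, y in ((pa, pb), (pb, pc), (pa, pc))]),
                1e-12,
            )
            return
        # circumcenter from perpendicular-bisector linear system
        A = 2 * np.array([pb - pa, pc - pa])
        b = np.array([pb @ pb - pa @ pa, pc @ pc - pa @ pa])
        center = np.linalg.solve(A, b)
        r = np.linalg.norm(pa - center)
        assert point_curvature(pa, pb, pc) == pytest.approx(1.0 / r, rel=1e-6)


class TestMeanCellCurvature:
    def test_circle_r50_gives_one_over_r(self):
        k = mean_cell_curvature(smooth_boundary(_circle_trace(), 9, 3), step=2)
        assert abs(k - 0.02) / 0.02 < 0.05

    def test_ellipse_matches_closed_form_mean(self):
        a, b = 60.0, 30.0
        t = np.linspace(0, 2 * np.pi, 1440, endpoint=False)
        pts = np.column_stack([b * np.sin(t), a * np.cos(t)])
        k = mean_cell_curvature(BoundaryTrace(points=pts), step=2)
        closed_form = np.mean(a * b / (a * a * np.sin(t) ** 2 + b * b * np.cos(t) ** 2) ** 1.5)
        assert abs(k - closed_form) / closed_form < 0.10

    def test_scale_law(self):
        """Scaling coordinates by s scales curvature by 1/s."""
        tr = _circle_trace(radius=50)
        for s in (0.5, 2.0, 10.0):
            scaled = BoundaryTrace(points=tr.points * s)
            k1 = mean_cell_curvature(tr, step=4)
            k2 = mean_cell_curvature(scaled, step=4)
            assert abs(k2 - k1 / s) < 1e-9

    def test_curvature_is_unsigned(self):
        rng = np.random.default_rng(1)
        th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        r = 40 + rng.normal(0, 2, th.size)
        tr = BoundaryTrace(points=np.column_stack([r * np.sin(th), r * np.cos(th)]))
        mean_cell_curvature(tr, step=3)
        assert np.all(tr.curvatures >= 0)

    def test_step_bounds_enforced(self):
        with pytest.raises(ValueError):
            mean_cell_curvature(_circle_trace(n=30), step=10)


class TestIntensityRatio:
    def test_uniform_channel_gives_unity(self):
        cell = np.zeros((20, 20), bool)
        cell[2:18, 2:18] = True
        nuc = np.zeros_like(cell)
        nuc[6:14, 6:14] = True
        assert intensity_ratio(np.full((20, 20), 7.0), nuc, cell) == 1.0

    def test_constructed_means_give_half(self):
        cell = np.zeros((20, 20), bool)
        cell[2:18, 2:18] = True
        nuc = np.zeros_like(cell)
        nuc[6:14, 6:14] = True
        img = np.full((20, 20), 100.0)
        img[nuc] = 50.0
        assert intensity_ratio(img, nuc, cell) == pytest.approx(0.5)

    def test_empty_cytoplasm_rejected(self):
        cell = np.zeros((10, 10), bool)
        cell[2:8, 2:8] = True
        with pytest.raises(ValueError, match="cytoplasm"):
            intensity_ratio(np.ones((10, 10)), cell.copy(), cell)


def _features(kappa, ratio, area_ratio, nucleus_area=5000.0, cell_area=20000.0):
    return CellFeatures(
        cell_id=1,
        cell_area=cell_area,
        nucleus_area=nucleus_area,
        mean_curvature=kappa,
        intensity_ratio_nuc_cyto=ratio,
        area_ratio_cell_nuc=area_ratio,
    )


class TestClassifyBlebbing:
    @pytest.mark.parametrize(
        "kappa,ratio,area_ratio,expected",
        [
            (0.030, 1.10, 4.0, True),   # all three criteria met
            (0.030, 1.20, 4.0, False),  # intensity criterion fails
            (0.005, 1.00, 10.0, False), # smooth large-spread cell
            (0.029, 1.10, 4.0, False),  # strict inequality at the cutoff
            (0.030, 1.15, 4.0, False),
            (0.030, 1.10, 4.5, False),
        ],
    )
    def test_three_feature_rule(self, kappa, ratio, area_ratio, expected):
        assert classify_blebbing(_features(kappa, ratio, area_ratio)) is expected

    def test_raising_curvature_cutoff_never_adds_calls(self):
        rng = np.random.default_rng(0)
        recs = [
            _features(k, r, a)
            for k, r, a in zip(
                rng.uniform(0, 0.1, 200), rng.uniform(0.5, 2, 200), rng.uniform(1, 8, 200)
            )
        ]
        calls = [
            sum(
                classify_blebbing(rec, BlebbingThresholds(curvature_min=c))
                for rec in recs
            )
            for c in (0.01, 0.029, 0.05, 0.09)
        ]
        assert all(a >= b for a, b in zip(calls, calls[1:]))


class TestApplyCellFilters:
    def test_small_nucleus_excluded_with_rule_name(self):
        retained, excluded = apply_cell_filters([_features(0.03, 1.0, 4.0, nucleus_area=900)])
        assert not retained
        assert excluded[0].excluded_by == ["nucleus_area_min"]

    def test_huge_cell_excluded_with_rule_name(self):
        retained, excluded = apply_cell_filters(
            [_features(0.03, 1.0, 4.0, cell_area=160000)]
        )
        assert not retained
        assert excluded[0].excluded_by == ["cell_area_max"]

    def test_typical_cell_retained(self):
        # the dataset's median-sized cell passes both filters
        retained, excluded = apply_cell_filters(
            [_features(0.03, 1.0, 4.1, nucleus_area=8638, cell_area=35665)]
        )
        assert len(retained) == 1 and not excluded

    def test_filtering_is_idempotent_subset(self):
        rng = np.random.default_rng(2)
        recs = [
            _features(0.03, 1.0, 4.0, nucleus_area=n, cell_area=c)
            for n, c in zip(
                rng.uniform(100, 20000, 50), rng.uniform(1000, 300000, 50)
            )
        ]
        retained, _ = apply_cell_filters(recs)
        again, none_excluded = apply_cell_filters(retained)
        assert [r.cell_id for r in again] == [r.cell_id for r in retained]
        assert not none_excluded
        assert set(id(r) for r in retained) <= set(id(r) for r in recs)


def test_raster_scale_law_on_polygon_fixture():
    """kappa(s * shape) = kappa(shape) / s to high precision."""
    th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    r = 50 + 3 * np.cos(5 * th)
    base = np.column_stack([r * np.sin(th), r * np.cos(th)])
    k_base = mean_cell_curvature(BoundaryTrace(points=base), step=2)
    for s in (2.0, 5.0):
        k_s = mean_cell_curvature(BoundaryTrace(points=base * s), step=2)
        assert abs(k_s - k_base / s) <= 1e-6
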