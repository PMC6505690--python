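"""Geometric primitives: spline fitting, curvature, lengths, resampling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from spinemorph.geometry import (
    GeometryError,
    Polyline3,
    arc_length,
    chord_length,
    curvature_at,
    fit_smoothing_spline,
    project_to_plane,
    resample_uniform,
    signed_curvature_at,
)


def circle_points(radius, n, theta0=0.0, theta1=2 * np.pi, centre=(0.0, 0.0)):
    theta = np.linspace(theta0, theta1, n)
    return np.column_stack(
        [centre[0] + radius * np.cos(theta), centre[1] + radius * np.sin(theta),
         np.zeros(n)]
    )


class TestSplineFit:
    def test_interpolating_fit_has_zero_residual(self):
        pts = circle_points(2.0, 20, theta1=1.5 * np.pi)
        curve = fit_smoothing_spline(pts)
        assert np.max(curve.residuals(pts)) < 1e-9

    def test_collinear_points_give_zero_curvature(self):
        pts = np.column_stack([np.linspace(0, 5, 10), np.linspace(0, 5, 10),
                               np.zeros(10)])
        curve = fit_smoothing_spline(pts)
        assert np.max(curve.residuals(pts)) < 1e-9
        gc = curvature_at(curve, curve.knots)
        assert np.allclose(gc, 0.0, atol=1e-9)

    def test_parabola_second_derivative_matches_analytic(self):
        # y = x^2 sampled at x = -2..2 step 0.5: d2y/dp2 = 2 * (dx/dp)^2 = 0.5
        x = np.arange(-2.0, 2.01, 0.5)
        pts = np.column_stack([x, x**2, np.zeros_like(x)])
        curve = fit_smoothing_spline(pts)
        d2 = curve.derivative(curve.knots[2:-2], order=2)
        assert np.allclose(d2[:, 1], 2.0 * 0.5**2, rtol=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(GeometryError, match="insufficient points"):
            fit_smoothing_spline(np.zeros((3, 3)))

    def test_duplicate_knots_rejected(self):
        pts = circle_points(1.0, 5)
        with pytest.raises(GeometryError, match="invalid parameterization"):
            fit_smoothing_spline(pts, knots=np.array([1.0, 2.0, 2.0, 3.0, 4.0]))

    def test_residual_cap_bounds_smoothing(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 10, 30)
        pts = np.column_stack([x, 0.05 * rng.normal(size=30), np.zeros(30)])
        curve = fit_smoothing_spline(pts, max_rms_residual=0.04)
        rms = float(np.sqrt(np.mean(curve.residuals(pts) ** 2)))
        assert rms <= 0.04
        assert curve.smoothing is not None and curve.smoothing > 0


class TestCurvature:
    def test_circle_curvature_is_inverse_radius(self):
        pts = circle_points(2.0, 200, theta1=1.5 * np.pi)
        curve = fit_smoothing_spline(pts)
        gc = curvature_at(curve, curve.knots[5:-5])
        assert np.allclose(gc, 0.5, rtol=0.01)

    def test_parabola_apex_curvature(self):
        x = np.linspace(-0.5, 0.5, 101)
        pts = np.column_stack([x, x**2, np.zeros_like(x)])
        curve = fit_smoothing_spline(pts)
        apex = curve.knots[50]
        assert curvature_at(curve, apex) == pytest.approx(2.0, rel=1e-3)

    def test_random_circles_median_error_below_one_percent(self):
        rng = np.random.default_rng(42)
        errors = []
        for _ in range(50):
            radius = rng.uniform(0.5, 20.0)
            centre = rng.uniform(-10, 10, size=2)
            theta0 = rng.uniform(0, 2 * np.pi)
            pts = circle_points(radius, 200, theta0, theta0 + 1.5 * np.pi, centre)
            curve = fit_smoothing_spline(pts)
            gc = curvature_at(curve, curve.knots[5:-5])
            errors.append(np.median(np.abs(gc - 1 / radius) * radius))
        assert np.median(errors) < 0.01

    def test_parameterization_invariance(self):
        pts = circle_points(3.0, 50, theta1=np.pi)
        knots = np.arange(1.0, 51.0)
        c1 = fit_smoothing_spline(pts, knots=knots)
        c2 = fit_smoothing_spline(pts, knots=2 * knots)
        p = knots[10:-10]
        g1 = curvature_at(c1, p)
        g2 = curvature_at(c2, 2 * p)
        assert np.allclose(g1, g2, rtol=1e-6)

    def test_3d_form_on_tilted_circle(self):
        theta = np.linspace(0, 1.5 * np.pi, 200)
        pts = np.column_stack(
            [2 * np.cos(theta), 2 * np.sin(theta) / np.sqrt(2),
             2 * np.sin(theta) / np.sqrt(2)]
        )
        curve = fit_smoothing_spline(pts)
        gc = curvature_at(curve, curve.knots[5:-5], plane=None)
        assert np.allclose(gc, 0.5, rtol=0.01)

    def test_signed_curvature_sign_tracks_bending_direction(self):
        x = np.linspace(-1, 1, 51)
        up = np.column_stack([x, x**2, np.zeros_like(x)])
        down = np.column_stack([x, -(x**2), np.zeros_like(x)])
        cu = fit_smoothing_spline(up)
        cd = fit_smoothing_spline(down)
        mid = cu.knots[25]
        assert signed_curvature_at(cu, mid) > 0
        assert signed_curvature_at(cd, mid) < 0

    def test_degenerate_projected_tangent_raises(self):
        z = np.linspace(0, 5, 10)
        pts = np.column_stack([np.zeros(10), np.zeros(10), z])
        curve = fit_smoothing_spline(pts)
        with pytest.raises(GeometryError, match="degenerate tangent"):
            curvature_at(curve, curve.knots[4], plane="sagittal")


class TestLengths:
    def test_unit_segment(self):
        poly = Polyline3(np.array([[0, 0, 0], [1, 0, 0]], dtype=float))
        assert arc_length(poly) == pytest.approx(1.0)
        assert chord_length(poly) == pytest.approx(1.0)

    def test_square_wave_arc_length(self):
        poly = Polyline3(np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [2, 1, 0]], dtype=float))
        assert arc_length(poly) == pytest.approx(3.0)

    def test_near_closed_loop_has_near_zero_chord(self):
        theta = np.linspace(0, 2 * np.pi, 100)
        pts = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(100)])
        poly = Polyline3(pts)
        assert chord_length(poly) == pytest.approx(0.0, abs=1e-12)

    def test_semicircle_chord_is_diameter(self):
        pts = circle_points(1.0, 200, theta1=np.pi)
        assert chord_length(Polyline3(pts)) == pytest.approx(2.0, rel=1e-9)

    def test_sine_period_arc_length_matches_quadrature(self):
        expected, _ = quad(lambda x: np.sqrt(1 + np.cos(x) ** 2), 0, 2 * np.pi)
        x = np.linspace(0, 2 * np.pi, 1000)
        poly = Polyline3(np.column_stack([x, np.sin(x), np.zeros_like(x)]))
        assert arc_length(poly) == pytest.approx(expected, rel=1e-4)

    @given(
        st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False),
                st.floats(-50, 50, allow_nan=False),
                st.floats(-50, 50, allow_nan=False),
            ),
            min_size=2,
            max_size=20,
        )
    )
    def test_arc_never_shorter_than_chord(self, coords):
        pts = np.array(coords, dtype=float)
        if np.any(np.linalg.norm(np.diff(pts, axis=0), axis=1) <= 1e-12):
            return  # invalid polyline by construction
        poly = Polyline3(pts)
        assert arc_length(poly) >= chord_length(poly) - 1e-9


class TestResampling:
    def test_unit_segment_midpoint(self):
        poly = Polyline3(np.array([[0, 0, 0], [1, 0, 0]], dtype=float))
        out = resample_uniform(poly, 3)
        assert np.allclose(out.points[:, 0], [0.0, 0.5, 1.0])

    def test_identity_on_uniform_polyline(self):
        x = np.linspace(0, 4, 9)
        poly = Polyline3(np.column_stack([x, np.zeros(9), np.zeros(9)]))
        out = resample_uniform(poly, 9)
        assert np.allclose(out.points, poly.points, atol=1e-9)

    def test_quarter_circle_arc_preserved(self):
        pts = circle_points(1.0, 400, theta1=np.pi / 2)
        out = resample_uniform(Polyline3(pts), 101)
        assert arc_length(out) == pytest.approx(np.pi / 2, rel=0.005)
        assert np.allclose(out.points[0], pts[0])
        assert np.allclose(out.points[-1], pts[-1])

    def test_invalid_count_rejected(self):
        poly = Polyline3(np.array([[0, 0, 0], [1, 0, 0]], dtype=float))
        with pytest.raises(GeometryError, match="invalid count"):
            resample_uniform(poly, 1)


class TestProjection:
    @pytest.mark.parametrize(
        "plane,expected",
        [("sagittal", (1.0, 2.0)), ("frontal", (2.0, 3.0)), ("axial", (1.0, 3.0))],
    )
    def test_named_planes(self, plane, expected):
        assert tuple(project_to_plane(np.array([1.0, 2.0, 3.0]), plane)) == expected

    def test_collinearity_survives_projection(self):
        t = np.linspace(0, 1, 7)[:, None]
        pts = np.array([0.0, 0.0, 0.0]) + t * np.array([1.0, 2.0, 3.0])
        for plane in ("sagittal", "frontal", "axial"):
            proj = project_to_plane(pts, plane)
            d = np.diff(proj, axis=0)
            cross = d[:-1, 0] * d[1:, 1] - d[:-1, 1] * d[1:, 0]
            assert np.allclose(cross, 0.0, atol=1e-12)

    def test_unknown_plane_rejected(self):
        with pytest.raises(GeometryError, match="unknown plane"):
            project_to_plane(np.zeros(3), "coronal-ish")
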