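"""Geometric primitives for landmark-curve morphometry.

Everything downstream — vertebral-line curvature, rib tortuosity, spine
height — is built on the operations here: 3D polylines, cubic (smoothing)
spline fits through ordered landmarks, osculating-circle curvature,
arc/chord lengths, uniform arc-length resampling, and projection onto the
named anatomical planes.

Coordinate convention (right-handed, millimetres):

* +x anterior, -x posterior
* +y cranial,  -y caudal
* +z left,     -z right

The sagittal plane is x-y, the frontal plane y-z and the axial plane x-z.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline

__all__ = [
    "GeometryError",
    "Polyline3",
    "SplineCurve",
    "fit_smoothing_spline",
    "curvature_at",
    "signed_curvature_at",
    "arc_length",
    "chord_length",
    "resample_uniform",
    "project_to_plane",
]

#: axes kept by each anatomical plane projection
PLANE_AXES = {"sagittal": (0, 1), "frontal": (1, 2), "axial": (0, 2)}

_DEGENERATE_SPEED = 1e-9  # mm per unit parameter; below this the tangent is undefined


class GeometryError(ValueError):
    """Raised for geometrically invalid input (too few points, degenerate tangent, ...)."""


@dataclasses.dataclass(frozen=True)
class Polyline3:
    """An ordered sequence of 3D points (mm) with strictly positive segment lengths."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise GeometryError(f"expected (n, 3) coordinates, got shape {pts.shape}")
        if pts.shape[0] < 2:
            raise GeometryError("a polyline needs at least 2 points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= 0.0):
            raise GeometryError("consecutive polyline points must be distinct")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)


def arc_length(poly: Polyline3) -> float:
    """Curved length L_C: the sum of Euclidean segment lengths (mm)."""
    return float(poly.segment_lengths.sum())


def chord_length(poly: Polyline3) -> float:
    """Chord L_S: the straight-line distance between the polyline endpoints (mm)."""
    return float(np.linalg.norm(poly.points[-1] - poly.points[0]))


def resample_uniform(poly: Polyline3, n: int) -> Polyline3:
    """Resample a polyline at ``n`` points equally spaced in arc length.

    Endpoints are preserved exactly; interior points are linearly
    interpolated along the original segments.
    """
    if n < 2:
        raise GeometryError("invalid count: resampling needs n >= 2")
    cum = np.concatenate([[0.0], np.cumsum(poly.segment_lengths)])
    targets = np.linspace(0.0, cum[-1], n)
    out = np.column_stack(
        [np.interp(targets, cum, poly.points[:, k]) for k in range(3)]
    )
    out[0] = poly.points[0]
    out[-1] = poly.points[-1]
    return Polyline3(out)


def project_to_plane(points: np.ndarray, plane: str) -> np.ndarray:
    """Orthogonally project 3D points onto a named anatomical plane.

    sagittal keeps (x, y); frontal keeps (y, z); axial keeps (x, z).
    """
    try:
        i, j = PLANE_AXES[plane]
    except KeyError:
        raise GeometryError(
            f"unknown plane {plane!r}; expected one of {sorted(PLANE_AXES)}"
        ) from None
    pts = np.asarray(points, dtype=float)
    return pts[..., [i, j]]


class SplineCurve:
    """A piecewise-cubic curve C(p) fitted through ordered 3D landmarks.

    The parameter ``p`` is the vertebra ordinal (dimensionless); coordinates
    are millimetres. Derivative evaluators dC/dp and d2C/dp2 feed the
    osculating-circle curvature.
    """

    def __init__(self, knots: np.ndarray, splines: Sequence, smoothing: float | None):
        self.knots = np.asarray(knots, dtype=float)
        self._splines = list(splines)
        self._d1 = [s.derivative(1) for s in self._splines]
        self._d2 = [s.derivative(2) for s in self._splines]
        self.smoothing = smoothing

    def __call__(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return np.stack([s(p) for s in self._splines], axis=-1)

    def derivative(self, p, order: int = 1) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        if order == 1:
            return np.stack([d(p) for d in self._d1], axis=-1)
        if order == 2:
            return np.stack([d(p) for d in self._d2], axis=-1)
        raise GeometryError("only first and second derivatives are provided")

    def residuals(self, centres: np.ndarray) -> np.ndarray:
        """Per-knot distance between the fitted curve and the input points (mm)."""
        return np.linalg.norm(self(self.knots) - np.asarray(centres, float), axis=-1)


def fit_smoothing_spline(
    centres: np.ndarray,
    knots: np.ndarray | None = None,
    smoothing: float | None = None,
    max_rms_residual: float | None = None,
) -> SplineCurve:
    """Fit a cubic (smoothing) spline per coordinate through ordered landmarks.

    Parameters
    ----------
    centres
        (n, 3) ordered points, cranial to caudal; n >= 4.
    knots
        Strictly increasing parameter values, one per point. Defaults to the
        1-based ordinal 1..n.
    smoothing
        Regularisation weight ``lam`` of a penalised smoothing spline.
        ``None`` or 0 gives the interpolating extreme (zero residual at every
        knot, not-a-knot boundary).
    max_rms_residual
        If given (and ``smoothing`` is not), the largest smoothing weight is
        chosen, by bisection, whose RMS knot residual stays within this cap
        (mm). A cap of 0 reduces to interpolation.
    """
    pts = np.asarray(centres, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError(f"expected (n, 3) coordinates, got shape {pts.shape}")
    if pts.shape[0] < 4:
        raise GeometryError("insufficient points: a cubic fit needs at least 4")
    if knots is None:
        knots = np.arange(1, pts.shape[0] + 1, dtype=float)
    else:
        knots = np.asarray(knots, dtype=float)
        if knots.shape != (pts.shape[0],):
            raise GeometryError("invalid parameterization: one knot per point required")
    if np.any(np.diff(knots) <= 0):
        raise GeometryError("invalid parameterization: knots must be strictly increasing")

    def _fit(lam: float | None) -> SplineCurve:
        if lam is None or lam == 0.0:
            spl = [CubicSpline(knots, pts[:, k], bc_type="not-a-knot") for k in range(3)]
            return SplineCurve(knots, spl, smoothing=None)
        spl = [make_smoothing_spline(knots, pts[:, k], lam=lam) for k in range(3)]
        return SplineCurve(knots, spl, smoothing=lam)

    if smoothing is not None and smoothing > 0:
        return _fit(float(smoothing))
    if max_rms_residual is not None and max_rms_residual > 0:
        lo, hi = 0.0, 1.0
        # grow until the cap is violated, then bisect back
        while hi < 1e8:
            curve = _fit(hi)
            if float(np.sqrt(np.mean(curve.residuals(pts) ** 2))) > max_rms_residual:
                break
            hi *= 10.0
        else:
            return _fit(hi)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            curve = _fit(mid) if mid > 0 else _fit(None)
            if float(np.sqrt(np.mean(curve.residuals(pts) ** 2))) <= max_rms_residual:
                lo = mid
            else:
                hi = mid
        return _fit(lo) if lo > 0 else _fit(None)
    return _fit(None)


def _derivatives(curve: SplineCurve, p):
    p_arr = np.asarray(p, dtype=float)
    lo, hi = curve.knots[0], curve.knots[-1]
    if np.any(p_arr < lo - 1e-9) or np.any(p_arr > hi + 1e-9):
        raise GeometryError(f"parameter outside knot range [{lo}, {hi}]")
    return curve.derivative(p_arr, 1), curve.derivative(p_arr, 2)


def curvature_at(curve: SplineCurve, p, plane: str | None = "sagittal"):
    """Geometric curvature GC(p) = 1/R(p) of the osculating circle (mm^-1).

    With ``plane`` set (default sagittal), the planar specialisation
    ``|x'y'' - y'x''| / (x'^2 + y'^2)^(3/2)`` is used on the projected curve;
    with ``plane=None`` (or "3d") the full 3D form
    ``|C' x C''| / |C'|^3`` is used, as appropriate for rib centerlines.

    The value is parameterization-invariant and non-negative.
    """
    d1, d2 = _derivatives(curve, p)
    if plane in (None, "3d"):
        speed = np.linalg.norm(d1, axis=-1)
        if np.any(speed < _DEGENERATE_SPEED):
            raise GeometryError("degenerate tangent: |C'(p)| ~ 0")
        num = np.linalg.norm(np.cross(d1, d2), axis=-1)
        return num / speed**3
    i, j = PLANE_AXES[plane] if plane in PLANE_AXES else (None, None)
    if i is None:
        raise GeometryError(f"unknown plane {plane!r}")
    speed2 = d1[..., i] ** 2 + d1[..., j] ** 2
    if np.any(np.sqrt(speed2) < _DEGENERATE_SPEED):
        raise GeometryError("degenerate tangent: projected |C'(p)| ~ 0")
    num = np.abs(d1[..., i] * d2[..., j] - d1[..., j] * d2[..., i])
    return num / speed2**1.5


def signed_curvature_at(curve: SplineCurve, p, plane: str = "sagittal"):
    """Signed planar curvature ``(x'y'' - y'x'') / (x'^2 + y'^2)^(3/2)``.

    On the sagittal plane, with the curve traversed cranial to caudal
    (+x anterior, +y cranial), positive values bow the spine posteriorly
    (kyphotic) and negative values anteriorly (lordotic).
    """
    d1, d2 = _derivatives(curve, p)
    try:
        i, j = PLANE_AXES[plane]
    except KeyError:
        raise GeometryError(f"unknown plane {plane!r}") from None
    speed2 = d1[..., i] ** 2 + d1[..., j] ** 2
    if np.any(np.sqrt(speed2) < _DEGENERATE_SPEED):
        raise GeometryError("degenerate tangent: projected |C'(p)| ~ 0")
    return (d1[..., i] * d2[..., j] - d1[..., j] * d2[..., i]) / speed2**1.5
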