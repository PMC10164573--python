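"""Closed 3-D centerlines represented by periodic cubic splines.

A :class:`ClosedCurve` interpolates an ordered set of control points (Å) with
a twice continuously-differentiable periodic cubic spline, which gives smooth
curvature everywhere including across the seam.  The curve is parametrised by
``t`` in ``[0, n_nodes]`` with node ``i`` at ``t = i``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import pdist

from .exceptions import InvalidParameterError

__all__ = ["ClosedCurve", "build_circle", "curvature_profile", "min_self_distance"]


class ClosedCurve:
    """A smooth closed centerline through ordered 3-D control points (Å).

    Parameters
    ----------
    control_points : (n, 3) array_like
        Ordered control points; the closure back to the first point is
        implicit (do not repeat it).
    """

    spline_order = 3
    closure = "periodic"

    def __init__(self, control_points: Sequence | np.ndarray):
        pts = np.asarray(control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise InvalidParameterError(
                f"control_points must be (n, 3), got shape {pts.shape}"
            )
        if pts.shape[0] < 4:
            raise InvalidParameterError("a closed cubic spline needs >= 4 control points")
        if not np.all(np.isfinite(pts)):
            raise InvalidParameterError("control points contain non-finite values")
        # reject degenerate (coincident consecutive) nodes instead of smoothing them
        seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
        if np.any(seg < 1e-9):
            raise InvalidParameterError("coincident consecutive control points")
        self.control_points = pts
        self.n_nodes = pts.shape[0]
        closed = np.vstack([pts, pts[:1]])
        t = np.arange(self.n_nodes + 1, dtype=float)
        self._spline = CubicSpline(t, closed, axis=0, bc_type="periodic")
        self._d1 = self._spline.derivative(1)
        self._d2 = self._spline.derivative(2)
        self._arclength: float | None = None

    # -- evaluation ---------------------------------------------------------

    @property
    def period(self) -> float:
        return float(self.n_nodes)

    def position(self, t) -> np.ndarray:
        return self._spline(np.mod(t, self.period))

    def velocity(self, t) -> np.ndarray:
        """dr/dt (not unit speed)."""
        return self._d1(np.mod(t, self.period))

    def acceleration(self, t) -> np.ndarray:
        return self._d2(np.mod(t, self.period))

    def tangent(self, t) -> np.ndarray:
        v = np.atleast_2d(self.velocity(t))
        u = v / np.linalg.norm(v, axis=1, keepdims=True)
        return u[0] if np.isscalar(t) else u

    def curvature(self, t) -> np.ndarray:
        """Unsigned curvature κ(t) = |r' x r''| / |r'|^3 in 1/Å."""
        scalar = np.isscalar(t)
        v = np.atleast_2d(self.velocity(t))
        a = np.atleast_2d(self.acceleration(t))
        cross = np.cross(v, a)
        speed = np.linalg.norm(v, axis=1)
        kappa = np.linalg.norm(cross, axis=1) / speed**3
        return float(kappa[0]) if scalar else kappa

    # -- integral quantities ------------------------------------------------

    def arclength(self) -> float:
        """Total contour length via adaptive quadrature (cached)."""
        if self._arclength is None:
            speed = lambda t: float(np.linalg.norm(self._d1(t)))
            total = 0.0
            # integrate interval by interval so the quadrature never straddles
            # spline knots (each piece is smooth)
            for i in range(self.n_nodes):
                val, _ = quad(speed, i, i + 1, epsabs=1e-10, epsrel=1e-10)
                total += val
            self._arclength = total
        return self._arclength

    def sample(self, n: int) -> np.ndarray:
        """n points equally spaced in the spline parameter."""
        t = np.linspace(0.0, self.period, n, endpoint=False)
        return self.position(t)

    def arclength_parameter(self, n_dense: int = 2048):
        """Cumulative arclength table (t_dense, s_dense) for resampling."""
        t = np.linspace(0.0, self.period, n_dense + 1)
        speed = np.linalg.norm(self._d1(t), axis=1)
        # composite Simpson on the uniform grid (n_dense even)
        ds = np.empty(n_dense + 1)
        ds[0] = 0.0
        h = t[1] - t[0]
        # cumulative trapezoid refined by midpoint speeds
        tm = 0.5 * (t[:-1] + t[1:])
        sm = np.linalg.norm(self._d1(tm), axis=1)
        seg = h * (speed[:-1] + 4.0 * sm + speed[1:]) / 6.0
        ds[1:] = np.cumsum(seg)
        return t, ds

    def sample_arclength(self, n: int) -> np.ndarray:
        """n points equally spaced in arclength."""
        t, s = self.arclength_parameter()
        targets = np.linspace(0.0, s[-1], n, endpoint=False)
        tt = np.interp(targets, s, t)
        return self.position(tt)

    # -- rigid transforms (convenience for tests and tooling) --------------

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    scale: float = 1.0) -> "ClosedCurve":
        pts = self.control_points * scale
        if rotation is not None:
            pts = pts @ np.asarray(rotation).T
        if translation is not None:
            pts = pts + np.asarray(translation)
        return ClosedCurve(pts)

    def mirrored(self) -> "ClosedCurve":
        pts = self.control_points.copy()
        pts[:, 2] *= -1.0
        return ClosedCurve(pts)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ClosedCurve(n_nodes={self.n_nodes}, L={self.arclength():.1f} Å)"


def build_circle(contour_length: float, n_nodes: int = 16) -> ClosedCurve:
    """Planar circle of circumference ``contour_length`` in the xy plane.

    The control polygon is inscribed with a radius correction so the *spline*
    arclength matches ``contour_length`` to high accuracy.
    """
    if contour_length <= 0:
        raise InvalidParameterError("contour_length must be positive")
    if n_nodes < 8:
        raise InvalidParameterError("need at least 8 nodes for a faithful circle")
    radius = contour_length / (2.0 * np.pi)
    theta = np.linspace(0.0, 2.0 * np.pi, n_nodes, endpoint=False)
    pts = radius * np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n_nodes)])
    curve = ClosedCurve(pts)
    # one multiplicative correction is enough: spline arclength of an
    # inscribed polygon differs from 2 pi R by O(n^-4)
    curve = ClosedCurve(pts * (contour_length / curve.arclength()))
    return curve


def curvature_profile(curve: ClosedCurve, n_samples: int = 400,
                      origin_t: float = 0.0) -> np.ndarray:
    """Curvature along the loop as ``(position in [0,1), κ in 1/Å)`` rows.

    ``origin_t`` shifts the arclength origin (e.g. to a self-contact point or
    a symmetry center) so profiles of different shapes can be aligned.
    """
    t_tab, s_tab = curve.arclength_parameter()
    total = s_tab[-1]
    s0 = np.interp(np.mod(origin_t, curve.period), t_tab, s_tab)
    targets = np.mod(s0 + np.linspace(0.0, total, n_samples, endpoint=False), total)
    tt = np.interp(targets, s_tab, t_tab)
    kappa = curve.curvature(tt)
    return np.column_stack([np.linspace(0.0, 1.0, n_samples, endpoint=False), kappa])


def min_self_distance(curve: ClosedCurve, n_samples: int = 400,
                      exclusion_arc: float | None = None) -> float:
    """Minimum distance between non-neighbouring centerline samples.

    Pairs whose contour separation is below ``exclusion_arc`` (default: 5 % of
    the contour length) are skipped — nearby points along a smooth curve are
    trivially close without implying self-contact.
    """
    pts = curve.sample_arclength(n_samples)
    length = curve.arclength()
    spacing = length / n_samples
    if exclusion_arc is None:
        exclusion_arc = 0.05 * length
    window = max(1, int(np.ceil(exclusion_arc / spacing)))
    d = pdist(pts)
    n = n_samples
    best = np.inf
    # map condensed index -> (i, j) exclusion on circular index distance
    idx_i, idx_j = np.triu_indices(n, k=1)
    circ = np.minimum(idx_j - idx_i, n - (idx_j - idx_i))
    mask = circ > window
    if np.any(mask):
        best = float(np.min(d[mask]))
    return best
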