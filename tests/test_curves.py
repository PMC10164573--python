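import numpy as np
import pytest
from scipy.special import ellipe

from _oracles import ellipse_curvature_extrema
from minicircle.curves import (ClosedCurve, build_circle, curvature_profile,
                               min_self_distance)
from minicircle.exceptions import InvalidParameterError


def _ellipse(a, b, n=256):
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return ClosedCurve(np.column_stack([a * np.cos(t), b * np.sin(t),
                                        np.zeros(n)]))


class TestBuildCircle:
    def test_unit_circle_geometry(self):
        c = build_circle(2.0 * np.pi, 16)
        radii = np.linalg.norm(c.control_points, axis=1)
        assert np.allclose(radii, 1.0, atol=1e-4)
        assert abs(c.arclength() - 2.0 * np.pi) < 1e-9

    def test_minicircle_radius(self):
        c = build_circle(1142.4, 32)
        assert np.linalg.norm(c.control_points[0]) == pytest.approx(
            1142.4 / (2.0 * np.pi), rel=1e-5)

    @pytest.mark.parametrize("bad", [dict(contour_length=-1.0, n_nodes=16),
                                     dict(contour_length=0.0, n_nodes=16),
                                     dict(contour_length=100.0, n_nodes=4)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            build_circle(**bad)

    def test_circle_curvature_uniform(self):
        # interpolating spline: ~1 % ripple at 16 nodes, 1e-6 at 256
        t16 = build_circle(2.0 * np.pi, 16)
        k16 = t16.curvature(np.linspace(0, 16, 200))
        assert np.max(np.abs(k16 - 1.0)) < 2e-2
        # interpolation error in curvature decays as ~h^2
        t256 = build_circle(2.0 * np.pi, 256)
        k256 = t256.curvature(np.linspace(0, 256, 400))
        assert np.max(np.abs(k256 - 1.0)) < 1e-4


class TestClosedCurve:
    def test_rejects_degenerate_input(self):
        pts = np.zeros((6, 3))
        pts[:, 0] = [0, 1, 1, 2, 3, 4]  # coincident consecutive points
        pts[2] = pts[1]
        with pytest.raises(InvalidParameterError):
            ClosedCurve(pts[:5])

    def test_rejects_wrong_shape_and_too_few(self):
        with pytest.raises(InvalidParameterError):
            ClosedCurve(np.zeros((5, 2)))
        with pytest.raises(InvalidParameterError):
            ClosedCurve(np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]))

    def test_seam_continuity(self):
        c = build_circle(100.0, 16)
        eps = 1e-7
        for order in ("position", "velocity", "acceleration"):
            f = getattr(c, order)
            left = f(c.period - eps)
            right = f(eps)
            assert np.allclose(left, right, atol=1e-4)

    def test_arclength_matches_analytic_ellipse(self):
        a, b = 2.0, 1.0
        c = _ellipse(a, b)
        exact = 4.0 * a * ellipe(1.0 - (b / a) ** 2)
        assert c.arclength() == pytest.approx(exact, rel=1e-6)

    def test_arclength_resampling_uniform(self):
        c = _ellipse(3.0, 1.0, 128)
        pts = c.sample_arclength(200)
        seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
        assert seg.std() / seg.mean() < 1e-3

    def test_ellipse_curvature_extrema(self):
        a, b = 2.0, 1.0
        c = _ellipse(a, b, 512)
        kappa = c.curvature(np.linspace(0, 512, 4096))
        k_max, k_min = ellipse_curvature_extrema(a, b)
        assert kappa.max() == pytest.approx(k_max, rel=1e-4)
        assert kappa.min() == pytest.approx(k_min, rel=1e-4)

    def test_transforms_preserve_arclength(self, rng):
        c = build_circle(50.0, 16)
        from scipy.spatial.transform import Rotation
        R = Rotation.random(rng=rng).as_matrix()
        moved = c.transformed(rotation=R, translation=np.array([5.0, -2.0, 1.0]))
        assert moved.arclength() == pytest.approx(c.arclength(), rel=1e-9)
        scaled = c.transformed(scale=2.5)
        assert scaled.arclength() == pytest.approx(2.5 * c.arclength(), rel=1e-9)


class TestCurvatureProfile:
    def test_circle_profile_constant(self):
        L = 1142.4
        prof = curvature_profile(build_circle(L, 256), 128)
        assert prof.shape == (128, 2)
        assert np.all((prof[:, 0] >= 0) & (prof[:, 0] < 1))
        assert np.allclose(prof[:, 1], 2.0 * np.pi / L, rtol=1e-4)

    def test_origin_shift_rolls_profile(self):
        from minicircle.fixtures import generate_fixture
        c = generate_fixture("perturbed_loop", {"amplitude": 0.15}, seed=3)
        p0 = curvature_profile(c, 64)
        p_shift = curvature_profile(c, 64, origin_t=c.period / 2.0)
        # different origin, same underlying curvature field
        assert not np.allclose(p0[:, 1], p_shift[:, 1])
        assert np.mean(p_shift[:, 1]) == pytest.approx(np.mean(p0[:, 1]),
                                                       rel=2e-2)
        assert p_shift[0, 1] == pytest.approx(
            float(c.curvature(c.period / 2.0)), rel=1e-6)


def test_min_self_distance_of_circle():
    L = 100.0
    c = build_circle(L, 32)
    d = min_self_distance(c, 400, exclusion_arc=0.05 * L)
    # smallest non-excluded chord: 2R sin(pi * 0.05-ish)
    assert 0 < d < 2.0 * L / (2.0 * np.pi)
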