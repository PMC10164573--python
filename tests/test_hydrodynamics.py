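import warnings

import numpy as np
import pytest

from minicircle.curves import ClosedCurve, build_circle
from minicircle.exceptions import (ConfigurationError, FitError,
                                   InvalidParameterError)
from minicircle.hydrodynamics import (BeadModel, HydroEnvironment,
                                      bead_model_rh, build_bead_model,
                                      calibrate_dh, predict_rh_for_dlk,
                                      rh_from_axisymmetric_mobilities,
                                      straight_rod_beads, torus_rh_exactish,
                                      torus_rh_slender)

DH = 29.4


class TestTorusClosedForms:
    def test_reference_values(self):
        assert torus_rh_exactish(1142.4, DH) == pytest.approx(128.0, abs=0.05)
        assert torus_rh_slender(1142.4, DH) == pytest.approx(125.4, abs=0.05)
        assert torus_rh_slender(2284.8, DH) == pytest.approx(220.1, abs=0.05)

    def test_dimensional_homogeneity(self):
        r1 = torus_rh_exactish(1000.0, 25.0)
        assert torus_rh_exactish(3000.0, 75.0) == pytest.approx(3.0 * r1,
                                                                rel=1e-12)

    def test_sublinear_growth_with_length(self):
        assert torus_rh_slender(2284.8, DH) < 2.0 * torus_rh_slender(1142.4, DH)

    def test_slender_limit_rh_over_l_vanishes(self):
        ratios = [torus_rh_exactish(DH * x, DH) / (DH * x)
                  for x in (1e2, 1e4, 1e6)]
        assert ratios[0] > ratios[1] > ratios[2]

    def test_forms_agree_in_slender_regime(self):
        # the gap between the two forms falls below 2.5 % from L/dh ~ 32
        for ratio in np.linspace(32, 150, 12):
            L = DH * ratio
            a, b = torus_rh_exactish(L, DH), torus_rh_slender(L, DH)
            assert abs(a - b) / a < 0.025

    def test_self_overlapping_torus_rejected(self):
        with pytest.raises(InvalidParameterError):
            torus_rh_exactish(50.0, 29.4)

    def test_slender_form_warns_out_of_range(self):
        with pytest.warns(UserWarning):
            torus_rh_slender(100.0, 29.4)


class TestAxisymmetricAverage:
    def test_sphere_identity(self):
        eta = 1.0
        R = 10.0
        mu = 1.0 / (6.0 * np.pi * eta * R)
        assert rh_from_axisymmetric_mobilities(mu, mu, eta) == \
            pytest.approx(R, rel=1e-12)

    def test_anisotropic_combination(self):
        eta, mu_z = 1.0, 1.0
        rh = rh_from_axisymmetric_mobilities(2.0 * mu_z, mu_z, eta)
        assert rh == pytest.approx((3.0 / 5.0) / (6.0 * np.pi * eta * mu_z),
                                   rel=1e-12)

    def test_result_between_single_axis_radii(self, rng):
        eta = 1.0
        for _ in range(10):
            mx, mz = rng.uniform(0.5, 3.0, 2)
            rh = rh_from_axisymmetric_mobilities(mx, mz, eta)
            bounds = sorted([1.0 / (6.0 * np.pi * eta * mx),
                             1.0 / (6.0 * np.pi * eta * mz)])
            assert bounds[0] <= rh <= bounds[1]

    def test_nonpositive_mobilities_rejected(self):
        with pytest.raises(InvalidParameterError):
            rh_from_axisymmetric_mobilities(0.0, 1.0, 1.0)


class TestBeadModelConstruction:
    def test_ring_spacing_and_length(self):
        c = build_circle(1142.4, 64)
        m = build_bead_model(c, DH, 400)
        assert m.n_beads == 400
        spacing = np.linalg.norm(np.diff(np.vstack([m.centers, m.centers[:1]]),
                                         axis=0), axis=1)
        assert spacing.mean() == pytest.approx(1142.4 / 400, rel=1e-3)
        assert np.all(spacing < DH)
        assert abs(m.traversed_length - 1142.4) / 1142.4 < 0.005

    def test_beads_lie_on_circle(self):
        c = build_circle(1142.4, 64)
        m = build_bead_model(c, DH, 400)
        radii = np.linalg.norm(m.centers - m.centers.mean(axis=0), axis=1)
        assert np.allclose(radii, 1142.4 / (2.0 * np.pi), rtol=1e-3)

    def test_insufficient_beads_rejected(self):
        c = build_circle(1142.4, 64)
        with pytest.raises(ConfigurationError):
            build_bead_model(c, DH, 10)


class TestBeadRh:
    def test_single_bead_is_exact_sphere(self):
        m = BeadModel(centers=np.zeros((1, 3)), bead_diameter_dh=10.0)
        assert bead_model_rh(m).rh == pytest.approx(5.0, rel=1e-9)
        r = bead_model_rh(m, method="montecarlo", seed=0, n_walkers=20000)
        assert r.rh == pytest.approx(5.0, rel=0.02)
        assert r.stderr > 0

    def test_touching_dumbbell_capacitance(self):
        """Two touching spheres: stochastic engine vs the known ~1.38 a."""
        m = BeadModel(centers=np.array([[0.0, 0, 0], [0, 0, 10.0]]),
                      bead_diameter_dh=10.0)
        r = bead_model_rh(m, method="montecarlo", seed=3, n_walkers=60000)
        assert r.rh / 5.0 == pytest.approx(1.38, rel=0.03)

    def test_ring_matches_torus_closed_form(self):
        c = build_circle(1142.4, 64)
        m = build_bead_model(c, DH, 400)
        target = torus_rh_exactish(1142.4, DH)
        assert bead_model_rh(m).rh == pytest.approx(target, rel=0.05)
        r = bead_model_rh(m, method="montecarlo", seed=5, n_walkers=25000)
        assert r.rh == pytest.approx(target, rel=0.05)

    def test_rh_monotone_in_thickness_and_length(self):
        c = build_circle(1142.4, 64)
        rh_thin = bead_model_rh(build_bead_model(c, 25.0, 400)).rh
        rh_thick = bead_model_rh(build_bead_model(c, 32.0, 400)).rh
        assert rh_thick > rh_thin
        c_long = build_circle(1600.0, 64)
        assert bead_model_rh(build_bead_model(c_long, 25.0, 400)).rh > rh_thin

    def test_bead_count_converged_at_400(self):
        c = build_circle(1142.4, 64)
        rh400 = bead_model_rh(build_bead_model(c, DH, 400)).rh
        rh800 = bead_model_rh(build_bead_model(c, DH, 800)).rh
        assert abs(rh400 - rh800) / rh400 < 0.01

    def test_linear_exceeds_circular(self):
        """Straight rod vs ring of equal L and d_h: ratio near 7:6."""
        ring = bead_model_rh(build_bead_model(build_circle(1142.4, 64),
                                              DH, 400)).rh
        rod = bead_model_rh(straight_rod_beads(1142.4, DH, 400)).rh
        assert rod > ring
        assert rod / ring == pytest.approx(7.0 / 6.0, rel=0.02)

    def test_unknown_method_rejected(self):
        m = BeadModel(centers=np.zeros((1, 3)), bead_diameter_dh=10.0)
        with pytest.raises(InvalidParameterError):
            bead_model_rh(m, method="magic")


class TestCalibrateDh:
    def test_parameter_recovery_on_synthetic_data(self, rng):
        """Recover d_h = 25 Å from 1 %-noisy synthetic torus measurements."""
        true_dh = 25.0
        lengths = [900.0, 1400.0, 2100.0, 2800.0]
        data = [(L, torus_rh_exactish(L, true_dh)
                 * (1.0 + 0.01 * rng.standard_normal())) for L in lengths]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dh, residuals = calibrate_dh(data)
        assert dh == pytest.approx(true_dh, abs=1.0)
        assert residuals.shape == (4,)

    def test_single_point_solved_exactly(self):
        rh = torus_rh_exactish(1142.4, 27.0)
        dh, residuals = calibrate_dh([(1142.4, rh)])
        assert dh == pytest.approx(27.0, abs=0.01)
        assert abs(residuals[0]) < 1e-6

    def test_requires_data(self):
        with pytest.raises(FitError):
            calibrate_dh([])

    def test_one_sided_residuals_warn(self):
        # data generated beyond the admissible thickness range: the fit pegs
        # at its bound and undershoots every point
        data = [(200.0, torus_rh_exactish(200.0, 54.0) + 15.0),
                (2000.0, torus_rh_exactish(2000.0, 54.0) + 15.0)]
        with pytest.warns(UserWarning):
            calibrate_dh(data)


def test_relative_rh_is_unity_below_threshold():
    rh, rel = predict_rh_for_dlk(-0.2, 1130.8, DH)
    assert rel == 1.0
    assert rh == pytest.approx(torus_rh_exactish(1130.8, DH), rel=0.06)


def test_environment_validation_and_units():
    env = HydroEnvironment.from_cp(1.02667)
    assert env.eta_cp == pytest.approx(1.02667)
    with pytest.raises(InvalidParameterError):
        HydroEnvironment(viscosity_eta=-1.0)
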