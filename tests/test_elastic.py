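import warnings

import numpy as np
import pytest

from minicircle.curves import build_circle, min_self_distance
from minicircle.elastic import (ElasticParams, MinimizerConfig, circle_shape,
                                lk_crit_empirical, lk_max, minimize_shape,
                                rod_energy, stability_regime)
from minicircle.exceptions import InvalidParameterError, StericViolationError
from minicircle.fixtures import generate_fixture
from minicircle.topology import TopologyState


class TestRodEnergy:
    def test_circle_bend_energy_closed_form(self):
        """(A/2)∫κ²ds of a circle is 2π²A/L; no residual twist when relaxed."""
        L = 1142.4
        curve = build_circle(L, 64)
        topo = TopologyState(length_bp=336, helical_repeat_h=10.5, Lk=32)
        params = ElasticParams(contour_length_L=L)
        e = rod_energy(curve, topo, params)
        assert e.bend == pytest.approx(2.0 * np.pi**2 * 500.0 / L, rel=1e-6)
        assert e.twist == pytest.approx(0.0, abs=1e-9)
        assert e.total == e.bend + e.twist

    def test_twist_energy_quadratic_in_deficit(self):
        L = 1142.4
        curve = build_circle(L, 64)
        params = ElasticParams(contour_length_L=L)
        energies = []
        for dlk in (1, 2):
            topo = TopologyState(length_bp=336, helical_repeat_h=10.5,
                                 Lk=32 + dlk)
            energies.append(rod_energy(curve, topo, params).twist)
        assert energies[1] / energies[0] == pytest.approx(4.0, rel=1e-6)
        # closed form: 2π²Aω dLk²/L
        assert energies[1] == pytest.approx(
            2.0 * np.pi**2 * 500.0 * (2.0 / 3.0) * 4.0 / L, rel=1e-6)

    def test_self_intersecting_curve_rejected(self):
        c = generate_fixture("figure8", {"apex_separation": 0.01,
                                         "contour_length": 1142.4,
                                         "n_nodes": 48})
        topo = TopologyState(length_bp=336, helical_repeat_h=10.5, Lk=32)
        params = ElasticParams(contour_length_L=1142.4,
                               steric_thickness_ds=20.0)
        with pytest.raises(StericViolationError):
            rod_energy(c, topo, params)


class TestThresholds:
    @pytest.mark.parametrize("aspect, expected", [
        (0.0, 1.0),
        (0.0082, 1.0906),   # 718 bp geometry
        (0.018, 1.1899),    # 336 bp geometry: sqrt(1 + 23.1*0.018)
    ])
    def test_critical_deficit_empirical_form(self, aspect, expected):
        assert lk_crit_empirical(aspect) == pytest.approx(expected, abs=2e-4)

    def test_critical_deficit_monotone_in_thickness(self):
        grid = np.linspace(0.0, 0.09, 50)
        vals = [lk_crit_empirical(a) for a in grid]
        assert np.all(np.diff(vals) > 0)

    def test_critical_deficit_domain(self):
        with pytest.raises(InvalidParameterError):
            lk_crit_empirical(-0.01)
        with pytest.raises(InvalidParameterError):
            lk_crit_empirical(0.2)

    @pytest.mark.parametrize("omega, expected", [
        (2.0 / 3.0, 2.598), (np.sqrt(3.0), 1.0), (1.0, 1.732)])
    def test_circle_instability_threshold(self, omega, expected):
        assert lk_max(omega) == pytest.approx(expected, abs=1e-3)

    def test_lk_max_requires_positive_omega(self):
        with pytest.raises(InvalidParameterError):
            lk_max(0.0)

    @pytest.mark.parametrize("dlk, expected", [
        (0.0, "circle_only"),
        (-1.0, "circle_only"),
        (-2.0, "multistable"),
        (-2.5, "multistable"),
        (-3.2, "writhed_only"),
    ])
    def test_stability_regimes_336(self, dlk, expected, params_336):
        assert stability_regime(dlk, params_336) == expected


class TestMinimizeShape:
    def test_relaxed_loop_is_open_circle(self, params_336, fast_config):
        s = minimize_shape(-0.2, params_336, fast_config)
        assert abs(s.writhe) < 0.05
        assert s.contact_type == "none"
        assert s.energy_total == pytest.approx(
            circle_shape(-0.2, params_336).energy_total, rel=1e-9)

    def test_writhed_shape_beats_circle(self, writhed_shape_336, params_336):
        circle = circle_shape(-3.2, params_336)
        assert writhed_shape_336.energy_total < circle.energy_total
        assert -3.2 < writhed_shape_336.writhe < -1.5

    def test_writhed_shape_respects_constraints(self, writhed_shape_336,
                                                params_336):
        L = params_336.contour_length_L
        assert abs(writhed_shape_336.curve.arclength() - L) / L <= 1e-3
        dmin = min_self_distance(writhed_shape_336.curve, 800,
                                 exclusion_arc=1.5 * 20.0)
        assert dmin >= params_336.steric_thickness_ds - 0.1

    def test_deep_supercoiling_reaches_line_contact(self, writhed_shape_336):
        assert writhed_shape_336.n_contacts >= 1
        assert writhed_shape_336.contact_type == "line"

    def test_writhed_shape_bends_tighter_than_circle(self, writhed_shape_336,
                                                     params_336):
        kappa = writhed_shape_336.curve.curvature(
            np.linspace(0, writhed_shape_336.curve.period, 400))
        r_min = 1.0 / kappa.max()
        assert r_min < params_336.contour_length_L / (2.0 * np.pi)

    def test_fixed_seed_is_reproducible(self, params_336):
        cfg = MinimizerConfig(mc_steps=500, quench_maxfev=400, rng_seed=11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = minimize_shape(-2.2, params_336, cfg)
            b = minimize_shape(-2.2, params_336, cfg)
        assert np.array_equal(a.curve.control_points, b.curve.control_points)
        assert a.energy_total == b.energy_total

    def test_seed_to_seed_energy_spread_small(self, params_336):
        energies = []
        for seed in range(5):
            cfg = MinimizerConfig(mc_steps=4000, quench_maxfev=3000,
                                  rng_seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                energies.append(minimize_shape(-3.2, params_336,
                                               cfg).energy_total)
        energies = np.array(energies)
        assert (energies.max() - energies.min()) / energies.mean() < 0.02

    def test_invalid_inputs_rejected(self, params_336):
        with pytest.raises(InvalidParameterError):
            minimize_shape(np.inf, params_336)
        with pytest.raises(InvalidParameterError):
            MinimizerConfig(n_nodes=13)
        with pytest.raises(InvalidParameterError):
            ElasticParams(contour_length_L=100.0, steric_thickness_ds=200.0)


def test_branches_reported_in_multistable_band(params_336, fast_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s = minimize_shape(-2.2, params_336, fast_config)
    assert set(s.branches) >= {"circle", "figure8"}
    # both branches are genuine minima with distinct writhe
    assert abs(s.branches["circle"].writhe) < 1e-9
    assert abs(s.branches["figure8"].writhe) > 0.5
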