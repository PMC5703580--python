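"""xi-scan machinery: concentrations, toxicity, washout, depth, phases."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemoflux.fixtures import FixtureSpec, generate_fixture
from chemoflux.model import Medium
from chemoflux.steady_state import (
    DegenerateMediumError,
    ToxicitySpec,
    detect_phases,
    effective_growth,
    find_xi_max,
    scan,
    steady_concentrations,
    washout_rate,
)
from chemoflux.units import convert


class TestSteadyConcentrations:
    def test_no_exchange_leaves_medium_unchanged(self):
        s = steady_concentrations({"a": 0.0}, 7.0, Medium({"a": 3.0}))
        assert s == {"a": 3.0}

    def test_consumption_depletes(self):
        s = steady_concentrations({"glc": 0.5}, 10.0, Medium({"glc": 15.0}))
        assert s["glc"] == pytest.approx(10.0)

    def test_secretion_accumulates(self):
        s = steady_concentrations({"lac": -0.05}, 10.0, Medium({}))
        assert s["lac"] == pytest.approx(0.5)

    def test_violated_bound_raises(self):
        with pytest.raises(RuntimeError, match="negative steady"):
            steady_concentrations({"glc": 2.0}, 10.0, Medium({"glc": 15.0}))


class TestEffectiveGrowth:
    def test_yield_factor_without_toxins_is_identity(self):
        tox = ToxicitySpec("yield_factor", {"nh4": 1.05, "lac": 8.0})
        assert effective_growth(0.04, {"nh4": 0.0, "lac": 0.0}, tox) == 0.04

    def test_yield_factor_quarters_growth_at_half_inhibition(self):
        tox = ToxicitySpec("yield_factor", {"nh4": 1.05, "lac": 8.0})
        mu = effective_growth(0.04, {"nh4": 1.05, "lac": 8.0}, tox)
        assert mu == pytest.approx(0.01)

    def test_death_rate_is_linear_in_concentration(self):
        tox = ToxicitySpec("death_rate", {"w": 0.0022})
        mu = effective_growth(0.05, {"w": 1.5}, tox)
        assert 0.05 - mu == pytest.approx(0.0033)

    def test_unknown_mechanism_rejected(self):
        with pytest.raises(ValueError):
            ToxicitySpec("magic", {})


class TestScan:
    def test_growth_decreases_along_small_grid(self, toy_system):
        model, medium, tox = toy_system
        curve = scan(model, medium, tox, [0.0, 10.0, 20.0], phi=1.0)
        mu = curve.array("mu_star")
        assert mu[0] == pytest.approx(0.048958333, abs=1e-8)
        assert np.all(np.diff(mu) < 0)

    def test_bleeding_rescales_D_and_X_only(self, toy_system):
        model, medium, tox = toy_system
        grid = [0.0, 10.0, 20.0]
        full = scan(model, medium, tox, grid, phi=1.0)
        half = scan(model, medium, tox, grid, phi=0.5)
        for a, b in zip(full.feasible_points, half.feasible_points):
            assert b.D_star == pytest.approx(2 * a.D_star)
            assert b.X_star == pytest.approx(2 * a.X_star)
            assert b.u_star == pytest.approx(a.u_star)
            assert b.mu_star == pytest.approx(a.mu_star)

    def test_points_beyond_depth_marked_infeasible(self, toy_system):
        model, medium, tox = toy_system
        curve = scan(model, medium, tox, [10.0, 600.0, 700.0], phi=1.0)
        flags = [p.feasible for p in curve.points]
        assert flags == [True, False, False]
        assert curve.points[0].mu_star == pytest.approx(0.047858333, abs=1e-8)

    def test_mass_balance_at_every_feasible_point(self, toy_curve, toy_system):
        _, medium, _ = toy_system
        for p in toy_curve.feasible_points:
            for m, u in p.u_star.items():
                lhs = u * p.X_star
                rhs = (medium.conc(m) - p.s_star[m]) * p.D_star
                assert lhs == pytest.approx(rhs, abs=1e-8 * max(1.0, abs(lhs)))

    def test_empty_and_invalid_grids_rejected(self, toy_system):
        model, medium, tox = toy_system
        with pytest.raises(ValueError):
            scan(model, medium, tox, [], phi=1.0)
        with pytest.raises(ValueError):
            scan(model, medium, tox, [1.0, 1.0], phi=1.0)
        with pytest.raises(DegenerateMediumError):
            scan(model, medium, tox, [600.0, 700.0], phi=1.0)


class TestWashoutRate:
    def test_toy_value(self, toy_system):
        model, medium, tox = toy_system
        d = washout_rate(model, medium, tox, phi=1.0)
        assert d * 24 == pytest.approx(1.175, abs=1e-3)

    def test_cell_retention_raises_washout_rate(self, toy_system):
        model, medium, tox = toy_system
        assert washout_rate(model, medium, tox, phi=0.5) == pytest.approx(
            2 * washout_rate(model, medium, tox, phi=1.0))

    def test_toxicity_does_not_affect_washout(self, toy_system):
        model, medium, tox = toy_system
        assert washout_rate(model, medium, tox) == pytest.approx(
            washout_rate(model, medium, ToxicitySpec.none()))

    def test_every_steady_state_is_below_washout(self, toy_curve, toy_system):
        model, medium, tox = toy_system
        d_max = washout_rate(model, medium, tox, phi=toy_curve.phi)
        for p in toy_curve.feasible_points:
            if p.X_star > 0:
                assert p.D_star < d_max


class TestMediumDepth:
    def test_toy_depth(self, toy_system, thresholds):
        model, medium, _ = toy_system
        assert find_xi_max(model, medium) == pytest.approx(
            thresholds.xi_m, rel=1e-5)

    def test_depth_scales_linearly_with_medium(self, toy_system, thresholds):
        model, medium, _ = toy_system
        assert find_xi_max(model, medium.scaled(2.0)) == pytest.approx(
            2 * thresholds.xi_m, rel=1e-5)

    def test_no_maintenance_means_unbounded_depth(self, toy_params):
        from chemoflux.toy import toy_as_generic_model

        model, medium, _ = toy_as_generic_model(toy_params)
        model.maintenance = {}
        assert find_xi_max(model, medium, upper_probe=1e6) == np.inf


class TestPhases:
    def test_toy_has_two_boundaries(self, toy_curve, toy_system, thresholds):
        model, medium, _ = toy_system
        bounds = detect_phases(toy_curve, model, medium)
        assert len(bounds) == 2
        assert bounds[0].xi == pytest.approx(thresholds.xi_0, rel=1e-4)
        assert bounds[1].xi == pytest.approx(thresholds.xi_sec, rel=1e-4)
        # S becomes limiting at xi_0; W secretion stops at xi_sec
        assert "S" in bounds[0].right.limiting
        assert "W" in bounds[1].left.secreted
        assert "W" not in bounds[1].right.secreted

    def test_boundaries_are_toxicity_independent(self, toy_curve_notox,
                                                 toy_system, thresholds):
        model, medium, _ = toy_system
        bounds = detect_phases(toy_curve_notox, model, medium)
        assert [pytest.approx(b.xi, rel=1e-4) for b in bounds] == \
            [thresholds.xi_0, thresholds.xi_sec]

    def test_single_phase_region_has_no_boundary(self):
        fx = generate_fixture(FixtureSpec(topology="chain", seed=3))
        xi_lim = fx.params["c"] / fx.params["V"]  # substrate limits beyond
        curve = scan(fx.model, fx.medium, fx.toxicity,
                     np.linspace(0.0, 0.8 * xi_lim, 6), phi=1.0)
        assert detect_phases(curve, fx.model, fx.medium) == []


class TestUnitConversions:
    @pytest.mark.parametrize("value, src, dst, expected", [
        (100.0 / 3.0, "gDW*h/L", "Mcells*day/mL", 1.5432),
        (0.0489583333, "1/h", "1/day", 1.175),
        (0.9, "gDW/L", "Mcells/mL", 1.0),
    ])
    def test_examples(self, value, src, dst, expected):
        assert convert(value, src, dst, 0.9e-9) == pytest.approx(
            expected, rel=1e-3)

    @given(st.floats(1e-6, 1e6), st.sampled_from(
        [("gDW*h/L", "Mcells*day/mL"), ("1/h", "1/day"),
         ("gDW/L", "Mcells/mL")]))
    @settings(max_examples=30, deadline=None)
    def test_round_trip(self, value, pair):
        src, dst = pair
        back = convert(convert(value, src, dst, 0.9e-9), dst, src, 0.9e-9)
        assert back == pytest.approx(value, rel=1e-12)

    def test_unsupported_pair_rejected(self):
        with pytest.raises(ValueError):
            convert(1.0, "gDW/L", "1/day", 0.9e-9)
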