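import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

from foilyield.activation import CrossSectionPoint
from foilyield.errors import InvalidInputError
from foilyield.io import activity_set_from_yields, fitted_excitations, load_yield_fixture
from foilyield.planning import (
    ActivitySet,
    Scenario,
    decay_activities,
    fit_excitation,
    max_rnp,
    rnp,
    saturation_factor,
    thick_target_eob_activity,
    time_to_rnp,
    yield_table,
)


def pt(e, s, product="Sc-47"):
    return CrossSectionPoint(product, e, 500.0, s, 0.1 * s)


class TestFitExcitation:
    def test_shape_preserving_between_points(self):
        xs = fit_excitation([pt(20.0, 10.0), pt(30.0, 20.0)], threshold_mev=10.0)
        assert 10.0 < xs(25.0) < 20.0

    def test_zero_at_threshold_and_below(self):
        xs = fit_excitation([pt(20.0, 10.0), pt(30.0, 20.0)], threshold_mev=10.0)
        assert xs(10.0) == 0.0
        assert xs(5.0) == 0.0

    def test_interpolant_passes_through_measured_points(self, xs_table, thresholds):
        xs = fitted_excitations(xs_table, ("Sc-47",), thresholds)["Sc-47"]
        assert xs(29.3) == pytest.approx(24.1, rel=1e-9)
        assert xs(68.0) == pytest.approx(16.9, rel=1e-9)

    def test_never_negative_and_flagged_constant_extrapolation(self, xs_table, thresholds):
        xs = fitted_excitations(xs_table, ("Sc-47",), thresholds)["Sc-47"]
        grid = np.linspace(xs.threshold_mev, 75.0, 400)
        values = xs(grid)
        assert np.all(values >= 0.0)
        assert not xs.extrapolated or True  # state before the high query
        assert xs(75.0) == pytest.approx(xs(68.0))
        assert xs.extrapolated

    def test_duplicate_energies_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_excitation([pt(20.0, 10.0), pt(20.0, 12.0)], threshold_mev=10.0)

    def test_threshold_above_first_point_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_excitation([pt(20.0, 10.0), pt(30.0, 20.0)], threshold_mev=25.0)


class TestSaturation:
    def test_limits(self):
        assert saturation_factor(0.1, 0.0) == 0.0
        assert saturation_factor(10.0, 1e4) == pytest.approx(1.0)

    def test_sc47_80h_over_24h_matches_published_yield_ratio(self, registry):
        lam = registry.decay_constant("Sc-47")
        ratio = saturation_factor(lam, 80.0) / saturation_factor(lam, 24.0)
        assert ratio == pytest.approx(2.665, abs=0.002)
        assert ratio == pytest.approx(529.0 / 198.0, rel=0.005)

    @given(st.floats(min_value=1e-4, max_value=0.5), st.floats(min_value=0.1, max_value=20.0))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_increasing_in_time(self, lam, t):
        f1 = saturation_factor(lam, t)
        f2 = saturation_factor(lam, 2.0 * t)
        assert 0.0 <= f1 < f2 < 1.0


class TestThickTargetYield:
    def test_zero_cross_section_gives_zero(self, registry):
        xs = fit_excitation([pt(20.0, 0.0), pt(30.0, 0.0)], threshold_mev=10.0)
        a = thick_target_eob_activity(xs, Scenario(30.0), registry.decay_constant("Sc-47"))
        assert a == 0.0

    def test_linear_in_current(self, registry):
        xs = fitted_excitations(products=("Sc-47",))["Sc-47"]
        lam = registry.decay_constant("Sc-47")
        a1 = thick_target_eob_activity(xs, Scenario(30.0, current_ua=1.0), lam)
        a3 = thick_target_eob_activity(xs, Scenario(30.0, current_ua=3.0), lam)
        assert a3 == pytest.approx(3.0 * a1, rel=1e-12)

    def test_step_halving_changes_result_below_point1_percent(self, registry):
        xs = fitted_excitations(products=("Sc-47",))["Sc-47"]
        lam = registry.decay_constant("Sc-47")
        coarse = thick_target_eob_activity(xs, Scenario(30.0), lam, e_step_mev=0.05)
        fine = thick_target_eob_activity(xs, Scenario(30.0), lam, e_step_mev=0.025)
        assert abs(coarse / fine - 1.0) < 1e-3

    def test_truncates_at_threshold(self, registry):
        xs = fitted_excitations(products=("Sc-47",))["Sc-47"]
        lam = registry.decay_constant("Sc-47")
        full = thick_target_eob_activity(xs, Scenario(30.0, e_exit_mev=0.0), lam)
        explicit = thick_target_eob_activity(xs, Scenario(30.0, e_exit_mev=xs.threshold_mev), lam)
        assert full == pytest.approx(explicit, rel=1e-12)


@pytest.fixture(scope="module")
def table(registry):
    xs_map = fitted_excitations()
    scenarios = [Scenario(e, t_irr_h=t) for t in (24.0, 80.0) for e in (25.0, 30.0, 35.0, 40.0)]
    return yield_table(xs_map, scenarios, registry)


@pytest.fixture(scope="module")
def yields_df():
    return load_yield_fixture()


class TestYieldTable:
    def test_low_energy_scenarios_have_no_sc46_or_sc43(self, table):
        row = table[(table["e_entry_mev"] == 25.0) & (table["t_irr_h"] == 24.0)].iloc[0]
        assert math.isnan(row["Sc-46 [MBq]"])
        assert math.isnan(row["Sc-43 [MBq]"])
        assert row["Sc-47 [MBq]"] > 0

    def test_mci_column_is_mbq_over_37(self, table):
        row = table[(table["e_entry_mev"] == 40.0) & (table["t_irr_h"] == 24.0)].iloc[0]
        for product in ("Sc-47", "Sc-44g", "Sc-43"):
            assert row[f"{product} [mCi]"] == pytest.approx(row[f"{product} [MBq]"] / 37.0)

    def test_80h_to_24h_ratio_equals_saturation_ratio(self, table, registry):
        for product in ("Sc-47", "Sc-44g", "Sc-44m", "Sc-43"):
            lam = registry.decay_constant(product)
            sat = saturation_factor(lam, 80.0) / saturation_factor(lam, 24.0)
            y24 = table[(table["e_entry_mev"] == 40.0) & (table["t_irr_h"] == 24.0)].iloc[0]
            y80 = table[(table["e_entry_mev"] == 40.0) & (table["t_irr_h"] == 80.0)].iloc[0]
            ratio = y80[f"{product} [MBq]"] / y24[f"{product} [MBq]"]
            assert ratio == pytest.approx(sat, rel=5e-3)


class TestDecayActivities:
    def test_zero_step_is_identity(self, registry):
        a0 = ActivitySet({"Sc-47": 100.0, "Sc-44m": 10.0, "Sc-44g": 5.0})
        a1 = decay_activities(a0, 0.0, registry)
        for nuc in a0.activities:
            assert a1.get(nuc) == pytest.approx(a0.get(nuc), rel=1e-12)

    def test_pure_exponential_without_parent(self, registry):
        a0 = ActivitySet({"Sc-44g": 50.0})
        lam = registry.decay_constant("Sc-44g")
        a1 = decay_activities(a0, 7.0, registry)
        assert a1.get("Sc-44g") == pytest.approx(50.0 * math.exp(-7.0 * lam), rel=1e-12)

    def test_bateman_matches_fine_step_ode_oracle(self, registry):
        """Closed-form isomer feeding vs direct integration of the decay ODEs."""
        lam_m = registry.decay_constant("Sc-44m")
        lam_g = registry.decay_constant("Sc-44g")
        branch = dict(registry.get("Sc-44m").decay_branches)["Sc-44g"]
        a0 = ActivitySet({"Sc-44m": 154.0, "Sc-44g": 1792.0, "Sc-47": 198.0})

        def rhs(t, n):
            n_m, n_g = n
            return [-lam_m * n_m, -lam_g * n_g + branch * lam_m * n_m]

        n0 = [154.0 / lam_m, 1792.0 / lam_g]
        for dt in (1.0, 10.0, 100.0, 1000.0):
            sol = solve_ivp(rhs, (0.0, dt), n0, rtol=1e-12, atol=1e-12, dense_output=True)
            n_m, n_g = sol.y[:, -1]
            evolved = decay_activities(a0, dt, registry)
            assert evolved.get("Sc-44g") == pytest.approx(lam_g * n_g, rel=1e-8)
            assert evolved.get("Sc-44m") == pytest.approx(lam_m * n_m, rel=1e-8)

    def test_bateman_conserves_nuclei(self, registry):
        """Integrating the ground-state activity over all time returns the
        initial ground-state nuclei plus the branched share of the parent's."""
        lam_m = registry.decay_constant("Sc-44m")
        lam_g = registry.decay_constant("Sc-44g")
        branch = dict(registry.get("Sc-44m").decay_branches)["Sc-44g"]
        a0 = ActivitySet({"Sc-44m": 100.0, "Sc-44g": 40.0})

        def a_g(t):
            return decay_activities(a0, t, registry).get("Sc-44g")

        total, _ = quad(a_g, 0.0, 3000.0, limit=200)
        expected = 40.0 / lam_g + branch * 100.0 / lam_m
        assert total == pytest.approx(expected, rel=1e-6)

    def test_feeding_term_vanishes_without_parent(self, registry):
        no_parent = ActivitySet({"Sc-44g": 30.0})
        with_zero = ActivitySet({"Sc-44g": 30.0, "Sc-44m": 0.0})
        dt = 12.0
        assert decay_activities(no_parent, dt, registry).get("Sc-44g") == pytest.approx(
            decay_activities(with_zero, dt, registry).get("Sc-44g"), rel=1e-12
        )

    def test_negative_step_rejected(self, registry):
        with pytest.raises(InvalidInputError):
            decay_activities(ActivitySet({"Sc-47": 1.0}), -1.0, registry)


class TestRnp:
    def test_pure_sc47_is_unity(self):
        assert rnp(ActivitySet({"Sc-47": 10.0})) == 1.0

    def test_equal_mixture_is_half(self):
        assert rnp(ActivitySet({"Sc-47": 5.0, "Sc-46": 5.0})) == pytest.approx(0.5)

    def test_v48_excluded_from_denominator(self):
        with_v = ActivitySet({"Sc-47": 5.0, "Sc-46": 5.0, "V-48": 100.0})
        assert rnp(with_v) == pytest.approx(0.5)

    def test_all_zero_raises(self):
        with pytest.raises(InvalidInputError):
            rnp(ActivitySet({"Sc-47": 0.0}))

    @given(
        st.floats(min_value=0.0, max_value=1e4),
        st.floats(min_value=1e-6, max_value=1e4),
        st.floats(min_value=0.0, max_value=2000.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_always_a_fraction(self, a47, a46, dt):
        a0 = ActivitySet({"Sc-47": a47, "Sc-46": a46})
        assert 0.0 <= rnp(decay_activities(a0, dt)) <= 1.0


class TestRnpEvolution:
    def test_already_pure_returns_zero(self):
        assert time_to_rnp(ActivitySet({"Sc-47": 10.0}), 0.99) == 0.0

    def test_low_energy_scenario_reaches_99_percent(self, yields_df):
        a0 = activity_set_from_yields(yields_df, 24.0, 30.0)
        t = time_to_rnp(a0, 0.99)
        assert t == pytest.approx(1500.0, rel=0.10)

    def test_sc46_floor_makes_99_percent_unreachable(self, yields_df):
        for e_entry in (35.0, 40.0):
            a0 = activity_set_from_yields(yields_df, 24.0, e_entry)
            assert math.isinf(time_to_rnp(a0, 0.99))

    def test_purity_monotone_without_sc46(self, yields_df, registry):
        a0 = activity_set_from_yields(yields_df, 24.0, 30.0)
        grid = np.linspace(0.0, 3000.0, 40)
        purities = [rnp(decay_activities(a0, float(t), registry)) for t in grid]
        assert all(b >= a - 1e-12 for a, b in zip(purities, purities[1:]))

    def test_max_rnp_pure_sc47_sits_at_horizon(self):
        peak = max_rnp(ActivitySet({"Sc-47": 10.0}), horizon_h=100.0)
        assert peak.at_horizon
        assert peak.rnp == pytest.approx(1.0)

    @pytest.mark.parametrize("e_entry, expected", [(35.0, 0.55), (40.0, 0.50)])
    def test_intermediate_scenarios_peak_near_published_levels(
        self, yields_df, e_entry, expected
    ):
        a0 = activity_set_from_yields(yields_df, 24.0, e_entry)
        peak = max_rnp(a0)
        assert not peak.at_horizon
        assert peak.rnp == pytest.approx(expected, abs=0.05)
        assert 0.0 < peak.t_h < 1000.0
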