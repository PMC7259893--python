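"""Hourly controller behavior and day/annual aggregation."""

import numpy as np
import pytest

from paleotherm.config import build_physiology, build_scenario
from paleotherm.microclimate import chamber_environment
from paleotherm.morphometry import build_animal
from paleotherm.thermoregulation import (daily_target_me, simulate_day,
                                         simulate_year, solve_hour)


class TestDailyTarget:
    @pytest.mark.parametrize("rmr,expected", [
        (301.1, 52.03), (3.4, 0.59), (12.3, 2.13), (52.7, 9.11),
    ])
    def test_published_rows(self, rmr, expected):
        assert round(daily_target_me(rmr, 2.0), 2) == expected

    def test_vanishes_with_rmr(self):
        assert daily_target_me(1e-9, 2.0) == pytest.approx(0.0, abs=1e-9)


class TestSolveHour:
    def test_thermoneutral_hour_hits_target(self, plateosaurus, plateo_ratite_narrow):
        env = chamber_environment(20.0)
        hr = solve_hour(plateosaurus, plateo_ratite_narrow, env, env,
                        behaviors_enabled=frozenset())
        assert hr.stress == "none"
        assert hr.achieved_met == pytest.approx(hr.target_met)
        assert hr.active

    def test_deep_cold_exceeds_target(self, coelophysis_bare):
        phys = build_physiology("ratite", "narrow", 21, taxon="coelophysis")
        env = chamber_environment(phys.ctr_min - 20.0)
        hr = solve_hour(coelophysis_bare, phys, env, env,
                        behaviors_enabled=frozenset())
        assert hr.stress == "cold"
        assert hr.achieved_met > hr.target_met
        assert hr.active  # cold-stressed animals stay active, burning more

    def test_heat_stress_reduces_activity(self, plateosaurus, plateo_ratite_narrow):
        env = chamber_environment(44.0)
        hr = solve_hour(plateosaurus, plateo_ratite_narrow, env, env,
                        behaviors_enabled=frozenset())
        assert hr.stress == "heat"
        assert hr.achieved_met < hr.target_met
        assert not hr.active

    def test_state_respects_bounds_everywhere(self, coelophysis_full):
        phys = build_physiology("ratite", "broad", 21, taxon="coelophysis")
        k_lo, k_hi = phys.flesh_conductivity_range
        o2_lo, o2_hi = phys.o2_extraction_range
        for t in np.arange(0, 51, 3.0):
            env = chamber_environment(float(t))
            st = solve_hour(coelophysis_full, phys, env, env,
                            behaviors_enabled=frozenset()).state
            assert 0.0 <= st.erect_fraction <= 1.0
            assert k_lo <= st.flesh_conductivity <= k_hi
            assert phys.ctr_min <= st.t_core <= phys.ctr_max
            assert o2_lo <= st.o2_extraction <= o2_hi
            # sweating disabled: wetness pinned at its baseline
            assert st.wet_fraction == pytest.approx(0.04)

    def test_achieved_non_increasing_below_tnz(self, plateosaurus,
                                               plateo_ratite_narrow):
        temps = np.arange(0, 30, 2.0)
        met = []
        for t in temps:
            env = chamber_environment(float(t))
            met.append(solve_hour(plateosaurus, plateo_ratite_narrow, env, env,
                                  behaviors_enabled=frozenset()).achieved_met)
        assert all(a >= b - 1e-6 for a, b in zip(met, met[1:]))

    def test_erection_engaged_before_vasoconstriction(self, coelophysis_full):
        # mildly cold insulated animal: ptiloerection is listed first and
        # must be the option engaged while conductivity stays mid-range
        phys = build_physiology("ratite", "narrow", 21, taxon="coelophysis")
        k_lo, k_hi = phys.flesh_conductivity_range
        for t in np.arange(30, 10, -1.0):
            env = chamber_environment(float(t))
            st = solve_hour(coelophysis_full, phys, env, env,
                            behaviors_enabled=frozenset()).state
            if 0 < st.erect_fraction < 1:
                assert st.flesh_conductivity == pytest.approx((k_lo + k_hi) / 2)
                break
        else:
            pytest.fail("no partially erected state found in the sweep")

    def test_options_only_help(self, coelophysis_bare):
        phys = build_physiology("ratite", "narrow", 21, taxon="coelophysis")
        scenario = build_scenario("cold_arid")
        from paleotherm.microclimate import day_environments
        sun, shade = day_environments(scenario, 0)[4]  # cold pre-dawn hour
        with_b = solve_hour(coelophysis_bare, phys, sun, shade)
        without = solve_hour(coelophysis_bare, phys, sun, shade,
                             behaviors_enabled=frozenset())
        assert (abs(with_b.achieved_met - with_b.target_met)
                <= abs(without.achieved_met - without.target_met) + 1e-6)


class TestAggregation:
    def test_day_integrates_hourly_rates(self, plateosaurus,
                                         plateo_ratite_narrow, hot_arid):
        day = simulate_day(plateosaurus, plateo_ratite_narrow, hot_arid, 6)
        assert len(day.hourly) == 24
        expected = sum(h.achieved_met for h in day.hourly) * 3600 / 1e6
        assert day.daily_me == pytest.approx(expected)

    def test_hot_midday_heat_stress(self, plateosaurus, plateo_ratite_narrow,
                                    hot_arid):
        day = simulate_day(plateosaurus, plateo_ratite_narrow, hot_arid, 6)
        assert any(h.stress == "heat" for h in day.hourly[10:17])

    def test_year_weights_months(self, coelophysis_bare):
        phys = build_physiology("ratite", "broad", 21, taxon="coelophysis")
        year = simulate_year(coelophysis_bare, phys, build_scenario("hot_arid"))
        assert len(year.days) == 12
        weights = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
        expected = sum(d.daily_me * w for d, w in zip(year.days, weights))
        assert year.annual_me == pytest.approx(expected)
        assert year.annual_target_me == pytest.approx(
            daily_target_me(phys.rmr, 2.0) * 365)
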