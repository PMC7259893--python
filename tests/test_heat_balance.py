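"""Convection, porous insulation and the segment/animal heat balance."""

import math

import pytest

from paleotherm import constants as k
from paleotherm.heat_balance import (SurfaceState, _internal_conductance,
                                     animal_balance, convection_coefficient,
                                     insulation_conductance, segment_balance)
from paleotherm.microclimate import chamber_environment
from paleotherm.morphometry import AnimalSpec, BodySegment, InsulationSpec


def _dry_state(**kw):
    defaults = dict(wet_fraction=0.0, flesh_conductivity=0.5)
    defaults.update(kw)
    return SurfaceState(**defaults)


class TestConvection:
    def test_free_convection_floor_in_still_air(self):
        h = convection_coefficient(0.1, 0.0, 25.0, 20.0)
        assert h > 0
        # at dT = 0 the Churchill-Chu correlation reduces to Nu = 0.6^2
        h0 = convection_coefficient(0.1, 0.0, 20.0, 20.0)
        _, k_air, _, _ = _air_props(20.0)
        assert h0 == pytest.approx(0.36 * k_air / 0.1, rel=1e-3)

    def test_hand_evaluated_churchill_bernstein(self):
        d, wind, t = 0.1, 1.0, 20.0
        h = convection_coefficient(d, wind, t, t)
        # independent evaluation at the same film conditions
        tk = t + 273.15
        p = 101325.0
        rho = p / (287.05 * tk)
        mu = 1.458e-6 * tk ** 1.5 / (tk + 110.4)
        k_air = 0.0241 * (tk / 273.15) ** 0.9
        re = wind * d * rho / mu
        pr = 0.71
        nu_f = (0.3 + 0.62 * math.sqrt(re) * pr ** (1 / 3)
                / (1 + (0.4 / pr) ** (2 / 3)) ** 0.25
                * (1 + (re / 282000) ** 0.625) ** 0.8)
        nu_n = 0.36  # Ra -> 0 at zero temperature difference
        expected = (nu_f ** 3 + nu_n ** 3) ** (1 / 3) * k_air / d
        assert h == pytest.approx(expected, rel=1e-6)

    def test_monotone_in_wind(self):
        hs = [convection_coefficient(0.1, w, 30.0, 20.0) for w in (1, 2, 3, 4)]
        assert all(a < b for a, b in zip(hs, hs[1:]))


def _air_props(t):
    from paleotherm.heat_balance import _air_props as ap
    return ap(t, 0.0)


class TestInsulation:
    def test_zero_depth_is_bare_skin(self):
        assert insulation_conductance(None, 0.0, 20.0) == (float("inf"), float("inf"))

    def test_hand_evaluated_parallel_path(self):
        spec = InsulationSpec()  # 30 mm length, 10 mm depth, 2000 /cm2, 100 um
        k_eff, u = insulation_conductance(spec, 0.0, 20.0)
        n = 2000e4
        d = 100e-6
        fill = n * math.pi * (d / 2) ** 2
        beta = n * d
        k_rad = 16 * 5.670374419e-8 * (293.15) ** 3 / (3 * beta)
        expected = 0.0257 * (1 - fill) + 0.2 * fill + k_rad
        assert k_eff == pytest.approx(expected, rel=1e-6)
        assert u == pytest.approx(expected / 0.010, rel=1e-6)

    def test_erection_deepens_and_insulates(self):
        spec = InsulationSpec()
        us = [insulation_conductance(spec, e, 20.0)[1] for e in (0.0, 0.5, 1.0)]
        assert us[0] > us[1] > us[2]

    def test_sparser_coat_leaks_more_radiation(self):
        dense = insulation_conductance(InsulationSpec(element_density=2000), 0, 20)[0]
        sparse = insulation_conductance(InsulationSpec(element_density=200), 0, 20)[0]
        assert sparse > dense


class TestSegmentBalance:
    def test_zero_gradient_limit(self):
        seg = BodySegment("torso", "cylinder", (0.1, 1.0))
        env = chamber_environment(38.0)
        fx = segment_balance(seg, 38.0, _dry_state(), env)
        assert abs(fx.q_met) < 0.05

    def test_insulation_reduces_cold_loss(self):
        bare = BodySegment("torso", "cylinder", (0.1, 1.0))
        ins = BodySegment("torso", "cylinder", (0.1, 1.0),
                          insulation_dorsal=InsulationSpec(),
                          insulation_ventral=InsulationSpec())
        env = chamber_environment(28.0)
        q_bare = segment_balance(bare, 38.0, _dry_state(), env).q_met
        q_ins = segment_balance(ins, 38.0, _dry_state(), env).q_met
        assert 0 < q_ins < q_bare

    def test_series_resistance_oracle_without_radiation(self, monkeypatch):
        # disable all radiative exchange; the solution must match an
        # independent conduction + convection series-resistance calculation
        monkeypatch.setattr(k, "EMISSIVITY_DEFAULT", 0.0)
        seg = BodySegment("torso", "cylinder", (0.1, 1.0), flesh_conductivity=0.5)
        t_core, t_air = 38.0, 18.0
        env = chamber_environment(t_air, wind=1.0)
        fx = segment_balance(seg, t_core, _dry_state(), env)
        g_int = _internal_conductance(seg, 0.5)
        area = 2 * math.pi * 0.1 * 1.0
        # self-consistent skin temperature via an independent fixed point
        t_s = 0.5 * (t_core + t_air)
        for _ in range(200):
            h = convection_coefficient(0.2, 1.0, t_s, t_air)
            t_new = (g_int * t_core + h * area * t_air) / (g_int + h * area)
            if abs(t_new - t_s) < 1e-8:
                break
            t_s = 0.5 * (t_s + t_new)
        expected = g_int * (t_core - t_s)
        assert fx.q_met == pytest.approx(expected, rel=0.01)
        assert fx.q_rad == pytest.approx(0.0, abs=1e-9)


class TestAnimalBalance:
    def _toy_animal(self):
        torso = BodySegment("torso", "cylinder", (0.1, 1.0))
        head = BodySegment("head", "sphere", (0.08,))
        from paleotherm.morphometry import segment_properties
        mass = sum(segment_properties(s)[2] for s in (torso, head))
        return AnimalSpec(taxon="toy", segments=(torso, head),
                          total_mass=mass, mean_height=0.5)

    def test_composition_of_segments(self):
        animal = self._toy_animal()
        env = chamber_environment(25.0)
        state = _dry_state()
        total = animal_balance(animal, 38.0, state, env)
        parts = sum(segment_balance(s, 38.0, state, env, z_height=0.5).q_met
                    for s in animal.segments)
        assert total.q_met - total.q_resp == pytest.approx(parts, rel=1e-6)

    def test_appendage_runs_cooler(self, coelophysis_bare):
        env = chamber_environment(18.0)
        state = _dry_state()
        legs = coelophysis_bare.segment("hind_legs")
        t_air, _ = env.at_height(coelophysis_bare.mean_height)
        q_at_core = segment_balance(legs, 38.0, state, env, z_height=0.45).q_met
        q_effective = segment_balance(legs, 38.0 - 0.5 * (38.0 - t_air), state,
                                      env, z_height=0.45).q_met
        assert q_effective == pytest.approx(q_at_core / 2, rel=0.05)

    def test_energy_closure_across_environments(self, plateosaurus, hot_arid):
        from paleotherm.microclimate import day_environments
        state = SurfaceState(flesh_conductivity=1.0)
        for sun, shade in day_environments(hot_arid, 6)[::4]:
            for env in (sun, shade):
                fx = animal_balance(plateosaurus, 38.0, state, env)
                tol = max(0.001 * abs(fx.q_met), 0.05)
                assert fx.closure_residual < tol
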