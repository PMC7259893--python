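"""Diurnal curves, solar geometry, sky longwave, soil solver, profiles."""

import math

import numpy as np
import pytest

from paleotherm import constants as k
from paleotherm.config import SoilProperties, build_scenario
from paleotherm.microclimate import (_monthly_envelope, day_environments,
                                     diurnal_curve, env_at_height, longwave_sky,
                                     solar_flux, solve_soil, sunrise_hour)


class TestDiurnalCurve:
    def test_anchors_and_midpoint(self):
        assert diurnal_curve(26, 40, 6, 12, 6) == pytest.approx(26)
        assert diurnal_curve(26, 40, 6, 12, 13) == pytest.approx(40)
        # half-phase of the rising sine sits at the midpoint
        assert diurnal_curve(26, 40, 6, 12, 9.5) == pytest.approx(33)

    def test_periodic_and_continuous(self):
        hours = np.linspace(0, 24, 481)
        vals = [diurnal_curve(10, 20, 6.2, 12, h) for h in hours]
        assert vals[0] == pytest.approx(vals[-1], abs=1e-9)
        assert max(abs(a - b) for a, b in zip(vals, vals[1:])) < 0.5
        assert min(vals) >= 10 and max(vals) <= 20

    def test_inverted_phase_peaks_at_sunrise(self):
        assert diurnal_curve(40, 90, 6, 12, 6, "inverted") == pytest.approx(90)
        assert diurnal_curve(40, 90, 6, 12, 13, "inverted") == pytest.approx(40)

    def test_reversed_extremes_rejected(self):
        with pytest.raises(ValueError):
            diurnal_curve(20, 10, 6, 12, 9)


class TestSolar:
    def test_night_is_dark(self):
        assert solar_flux(12, 80, 0.0, 0.0) == (0.0, 0.0)

    def test_equinox_noon_matches_hand_formula(self):
        # zenith = |latitude - declination|; near the equinox declination ~ 0
        lat, doy, elev = 12.0, 80, 0.0
        direct, diffuse = solar_flux(lat, doy, 12.0, 0.0, elev)
        dec = math.radians(23.45) * math.sin(2 * math.pi * (284 + doy) / 365)
        cosz = math.cos(math.radians(lat) - dec)
        expected = k.SOLAR_CONSTANT * k.ATM_TRANSMITTANCE ** (1 / cosz) * cosz
        assert direct == pytest.approx(expected, rel=1e-6)
        assert diffuse == pytest.approx(expected * 0.15 / 0.85, rel=1e-6)

    def test_cloud_attenuates_monotonically(self):
        fluxes = [sum(solar_flux(12, 172, 12.0, c)) for c in (0, 50, 100)]
        assert fluxes[0] > fluxes[1] > fluxes[2] > 0


class TestLongwaveSky:
    def test_overcast_sky_near_air_temperature(self):
        assert longwave_sky(20, 50, 100) == pytest.approx(20, abs=2)

    def test_clear_sky_colder_than_air(self):
        assert longwave_sky(20, 50, 0) < 20

    def test_matches_hand_evaluated_brunt(self):
        t_air, rh = 30.0, 80.0
        e_hpa = 610.78 * math.exp(17.27 * 30 / (30 + 237.3)) * 0.80 / 100.0
        eps = 0.52 + 0.065 * math.sqrt(e_hpa)
        expected = (30 + 273.15) * eps ** 0.25 - 273.15
        assert longwave_sky(t_air, rh, 0) == pytest.approx(expected, abs=1e-9)


class TestSoil:
    def test_isothermal_equilibrium(self, hot_arid):
        const = np.full(24, 20.0)
        grid = solve_soil(hot_arid, dict(t_air=const, t_sky=const,
                                         wind=np.full(24, 1.0), solar=np.zeros(24)))
        assert np.allclose(grid.temperatures, 20.0, atol=0.05)

    def test_sinusoidal_damping_matches_analytic(self, hot_arid):
        # conduction-only, prescribed surface temperature, fine grid
        depths = tuple(np.concatenate([np.linspace(0, 0.3, 25), [0.5, 1.0, 2.0]]))
        sc = build_scenario("hot_arid", substrate=SoilProperties(node_depths=depths))
        hours = np.arange(24)
        amp = 10.0
        tsurf = 25.0 + amp * np.sin(2 * np.pi * hours / 24)
        grid = solve_soil(sc, dict(t_surface=tsurf), substeps=12)
        soil = sc.substrate
        omega = 2 * np.pi / 86400.0
        damping_depth = math.sqrt(2 * soil.thermal_conductivity
                                  / (soil.volumetric_heat_capacity * omega))
        for zi in (4, 8, 12):
            z = grid.node_depths[zi]
            got = (grid.temperatures[:, zi].max() - grid.temperatures[:, zi].min()) / 2
            expected = amp * math.exp(-z / damping_depth)
            assert got == pytest.approx(expected, rel=0.02)

    def test_hot_day_phase_and_deep_mean(self, hot_arid):
        envs = day_environments(hot_arid, 6)
        surface = np.array([e[0].t_ground_surface for e in envs])
        t_air = np.array([e[0].t_air_ref for e in envs])
        assert surface.argmax() >= 13  # lags solar noon
        deep = np.array([e[0].t_substrate_profile[-1] for e in envs])
        assert np.allclose(deep, t_air.mean(), atol=0.1)

    def test_grid_convergence(self, hot_arid):
        envs = day_environments(hot_arid, 6)
        forcing = dict(
            t_air=np.array([e[0].t_air_ref for e in envs]),
            t_sky=np.array([e[0].t_sky for e in envs]),
            wind=np.array([e[0].wind_ref for e in envs]),
            solar=np.array([e[0].solar_direct + e[0].solar_diffuse for e in envs]))
        coarse = solve_soil(hot_arid, forcing)
        base = np.asarray(hot_arid.substrate.node_depths)
        fine_depths = tuple(np.unique(np.concatenate([base, (base[1:] + base[:-1]) / 2])))
        sc_fine = build_scenario("hot_arid",
                                 substrate=SoilProperties(node_depths=fine_depths))
        fine = solve_soil(sc_fine, forcing)
        assert np.max(np.abs(coarse.temperatures[:, 0] - fine.temperatures[:, 0])) < 0.1


class TestHeightProfile:
    def test_reference_height_returns_reference_values(self):
        t, w = env_at_height(35.0, 25.0, 3.0, 2.0)
        assert (t, w) == (25.0, 3.0)

    def test_roughness_height_is_surface(self):
        t, w = env_at_height(35.0, 25.0, 3.0, 0.01)
        assert t == 35.0 and w == 0.0

    def test_log_midpoint_is_arithmetic_mean(self):
        z0, zref = 0.01, 2.0
        z_mid = math.sqrt(z0 * zref)
        t, w = env_at_height(35.0, 25.0, 3.0, z_mid, z0, zref)
        assert t == pytest.approx(30.0)
        assert w == pytest.approx(1.5)


class TestDayAssembly:
    def test_envelope_touched_exactly_at_anchor_hours(self, hot_arid):
        month = 6
        t_lo, t_hi = _monthly_envelope(hot_arid, month)
        sr = sunrise_hour(hot_arid.latitude, k.MID_MONTH_DOY[month])
        assert diurnal_curve(t_lo, t_hi, sr, 12.0, sr) == pytest.approx(t_lo, abs=0.01)
        assert diurnal_curve(t_lo, t_hi, sr, 12.0, 13.0) == pytest.approx(t_hi, abs=0.01)

    def test_annual_envelope_spans_scenario_range(self, hot_arid):
        mins = [_monthly_envelope(hot_arid, m)[0] for m in range(12)]
        maxs = [_monthly_envelope(hot_arid, m)[1] for m in range(12)]
        assert min(mins) == pytest.approx(hot_arid.air_temp_min, abs=0.01)
        assert max(maxs) == pytest.approx(hot_arid.air_temp_max, abs=0.01)

    def test_shade_site_darker_but_radiantly_warmer(self, hot_arid):
        for sun, shade in day_environments(hot_arid, 3):
            assert shade.solar_direct <= sun.solar_direct + 1e-9
            assert (shade.solar_direct + shade.solar_diffuse
                    <= (1 - hot_arid.shade_max / 100) * (sun.solar_direct + sun.solar_diffuse) + 1e-9)
            assert shade.t_sky >= sun.t_sky - 1e-9

    def test_solar_zero_at_night(self, hot_arid):
        for sun, _ in day_environments(hot_arid, 0):
            if not (6 <= sun.hour <= 18):
                assert sun.solar_direct == 0.0 and sun.solar_diffuse == 0.0
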