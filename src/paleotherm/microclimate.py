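"""Hourly microclimate generation.

From an annual :class:`~paleotherm.config.MicroclimateScenario` this module
produces, for each of 12 mid-month model days, the hourly operative
environment at a reference height of 2 m — air temperature, wind, humidity,
solar flux, radiant sky temperature and the soil temperature profile — for an
open-sun site and a deep-shade site.  Heat-balance code then maps air
temperature and wind down to animal height with a logarithmic profile.

Conventions: hours are local solar time 0-23, values are instantaneous on
the hour; solar noon is hour 12.  Daily minima of air temperature (and wind)
occur at sunrise and maxima one hour after solar noon; relative humidity and
cloud run inverted (maxima at sunrise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from . import constants as k
from .config import MicroclimateScenario

__all__ = [
    "HourlyEnvironment",
    "SoilGrid",
    "diurnal_curve",
    "solar_flux",
    "longwave_sky",
    "solve_soil",
    "env_at_height",
    "build_day",
    "chamber_environment",
    "saturation_vapor_pressure",
    "vapor_density",
]

REFERENCE_HEIGHT = 2.0   # m, height of the driving met variables
ROUGHNESS_DEFAULT = 0.01  # m, momentum roughness of the substrate
SPINUP_DAYS = 3
MAX_SPINUP_DAYS = 60
SOIL_PERIODIC_TOL = 0.05  # degC between successive days at convergence


# ---------------------------------------------------------------------------
# Psychrometrics
# ---------------------------------------------------------------------------

def saturation_vapor_pressure(t_c: float) -> float:
    """Saturation vapor pressure over water, Pa (Tetens formula)."""
    return 610.78 * math.exp(17.27 * t_c / (t_c + 237.3))


def vapor_density(t_c: float, rh: float) -> float:
    """Absolute humidity, kg/m^3, at air temperature t_c (degC) and RH %."""
    e = saturation_vapor_pressure(t_c) * rh / 100.0
    return e / (461.5 * (t_c + k.T_KELVIN))


# ---------------------------------------------------------------------------
# Solar geometry
# ---------------------------------------------------------------------------

def _declination(day_of_year: int) -> float:
    """Solar declination, radians."""
    return math.radians(23.45) * math.sin(2 * math.pi * (284 + day_of_year) / 365.0)


def _cos_zenith(latitude: float, day_of_year: int, hour: float) -> float:
    phi = math.radians(latitude)
    dec = _declination(day_of_year)
    hour_angle = math.radians(15.0 * (hour - 12.0))
    return math.sin(phi) * math.sin(dec) + math.cos(phi) * math.cos(dec) * math.cos(hour_angle)


def sunrise_hour(latitude: float, day_of_year: int) -> float:
    """Local solar time of sunrise; polar day/night clamp to 0/12."""
    phi = math.radians(latitude)
    dec = _declination(day_of_year)
    x = -math.tan(phi) * math.tan(dec)
    if x >= 1.0:
        return 12.0  # polar night
    if x <= -1.0:
        return 0.0   # midnight sun
    return 12.0 - math.degrees(math.acos(x)) / 15.0


def solar_flux(latitude: float, day_of_year: int, hour: float, cloud: float,
               elevation: float = 0.0) -> tuple[float, float]:
    """(direct, diffuse) solar flux on a horizontal surface, W/m^2.

    Single-transmittance clear-sky model: direct = S0 * tau**m * cos(z) with
    tau = 0.70 per optical air mass (pressure-corrected for elevation), plus
    a 15 % diffuse fraction of the global flux.  Cloud attenuates the global
    flux by (1 - 0.65 * cloud/100).  Zero below the horizon.
    """
    cosz = _cos_zenith(latitude, day_of_year, hour)
    if cosz <= 0.0:
        return 0.0, 0.0
    pressure_ratio = math.exp(-elevation / 8434.0)  # scale-height barometric form
    air_mass = pressure_ratio / max(cosz, 0.03)
    direct = k.SOLAR_CONSTANT * k.ATM_TRANSMITTANCE ** air_mass * cosz
    # diffuse is DIFFUSE_FRACTION of the clear-sky global flux
    diffuse = direct * k.DIFFUSE_FRACTION / (1.0 - k.DIFFUSE_FRACTION)
    atten = 1.0 - k.CLOUD_SOLAR_ATTENUATION * cloud / 100.0
    return direct * atten, diffuse * atten


def longwave_sky(t_air: float, rh: float, cloud: float) -> float:
    """Effective radiant sky temperature, degC.

    Clear-sky emissivity from the Brunt correlation
    eps = 0.52 + 0.065*sqrt(e_hPa); cloud blends emissivity toward 1:
    eps_sky = eps + (cloud/100)*(1 - eps).  T_sky = eps_sky**(1/4) * T_air.
    """
    e_hpa = saturation_vapor_pressure(t_air) * rh / 100.0 / 100.0
    eps_clear = min(1.0, k.BRUNT_A + k.BRUNT_B * math.sqrt(max(e_hpa, 0.0)))
    eps = eps_clear + cloud / 100.0 * (1.0 - eps_clear)
    t_k = (t_air + k.T_KELVIN) * eps ** 0.25
    return t_k - k.T_KELVIN


# ---------------------------------------------------------------------------
# Diurnal interpolation
# ---------------------------------------------------------------------------

def diurnal_curve(v_min: float, v_max: float, sunrise: float, solar_noon: float,
                  hour: float, phase: str = "min_at_sunrise_max_at_noon_plus1") -> float:
    """24-h periodic piecewise sinusoid between daily extremes.

    The standard phase anchors the minimum exactly at sunrise and the maximum
    exactly one hour after solar noon, rising on a half sine and relaxing on
    a half cosine until the next sunrise.  ``phase="inverted"`` swaps the
    extremes (used for humidity and cloud, which peak at sunrise).
    """
    if v_min > v_max:
        raise ValueError(f"v_min {v_min} exceeds v_max {v_max}")
    t_peak = solar_noon + 1.0
    h = hour % 24.0
    if h < sunrise:
        h += 24.0
    if h <= t_peak:
        # rising limb: half sine from sunrise to peak
        f = 0.5 * (1.0 - math.cos(math.pi * (h - sunrise) / (t_peak - sunrise)))
    else:
        # falling limb: half cosine from peak to next sunrise
        f = 0.5 * (1.0 + math.cos(math.pi * (h - t_peak) / (sunrise + 24.0 - t_peak)))
    if phase == "inverted":
        f = 1.0 - f
    return v_min + (v_max - v_min) * f


# ---------------------------------------------------------------------------
# Soil heat conduction
# ---------------------------------------------------------------------------

@dataclass
class SoilGrid:
    node_depths: np.ndarray          # m
    temperatures: np.ndarray         # degC, shape (24, n_nodes), converged day
    surface_flux_components: np.ndarray  # W/m^2, (24, 4): solar, IR net, convective, conductive
    residual: float                  # max |T(h) - T(h-24h)| on the reported day


def _surface_h(wind: float) -> float:
    """Bulk surface convection coefficient, W/m^2/K (empirical flat-ground form)."""
    return 5.7 + 3.8 * max(wind, 0.1)


def solve_soil(scenario: MicroclimateScenario, forcing: dict,
               substeps: int = 6) -> SoilGrid:
    """Periodic steady-state soil temperature profile for one model day.

    ``forcing`` supplies 24-element arrays ``t_air``, ``t_sky``, ``wind`` and
    ``solar`` (site-shaded global flux; soil reflectivity is applied here).
    Alternatively a ``t_surface`` array prescribes the surface temperature
    directly (conduction-only mode, used for verification against the
    analytic damping-depth solution).

    Backward-Euler finite differences on the scenario's node grid, with the
    surface radiation term linearized about the previous step, repeating the
    same forcing day until the profile is 24-h periodic.  The deep boundary
    is pinned at the running mean air (or surface) temperature.
    """
    from scipy.linalg import solve_banded

    soil = scenario.substrate
    z = np.asarray(soil.node_depths)
    n = len(z)
    kc, cv = soil.thermal_conductivity, soil.volumetric_heat_capacity
    dz = np.diff(z)
    thick = np.empty(n)
    thick[0] = dz[0] / 2
    thick[1:-1] = (dz[:-1] + dz[1:]) / 2
    thick[-1] = dz[-1] / 2

    prescribed = "t_surface" in forcing
    if prescribed:
        t_surf = np.asarray(forcing["t_surface"], float)
        deep_t = float(np.mean(t_surf))
        t_air = t_surf
        t_sky = t_surf
        wind = np.zeros(24)
        solar = np.zeros(24)
    else:
        t_air = np.asarray(forcing["t_air"], float)
        t_sky = np.asarray(forcing["t_sky"], float)
        wind = np.asarray(forcing["wind"], float)
        solar = np.asarray(forcing["solar"], float) * (1.0 - soil.solar_reflectivity)
        deep_t = float(np.mean(t_air))

    temps = np.full(n, deep_t, dtype=float)
    dt = 3600.0 / substeps
    eps = soil.ir_emissivity
    sigma = k.STEFAN_BOLTZMANN

    # time-invariant parts of the banded matrix (interior conduction)
    g = kc / dz  # conductance between node i and i+1, per unit area
    day_T = np.empty((24, n))
    flux = np.zeros((24, 4))
    prev_day = None
    residual = math.inf
    ab = np.zeros((3, n))
    rhs = np.zeros(n)
    for day in range(MAX_SPINUP_DAYS):
        for hour in range(24):
            ta, ts, w, s = t_air[hour], t_sky[hour], wind[hour], solar[hour]
            h = _surface_h(w)
            for _ in range(substeps):
                cap = cv * thick / dt
                # interior rows
                ab[0, 1:] = -g          # superdiagonal (node i+1 in row i)
                ab[2, :-1] = -g         # subdiagonal
                ab[1, :] = cap
                ab[1, 1:-1] += g[:-1] + g[1:]
                rhs[:] = cap * temps
                if prescribed:
                    ab[1, 0] = 1.0
                    ab[0, 1] = 0.0
                    rhs[0] = ts
                else:
                    t0k = temps[0] + k.T_KELVIN
                    hr_lin = 4.0 * eps * sigma * t0k ** 3
                    ab[1, 0] = cap[0] + g[0] + h + hr_lin
                    rhs[0] = (cap[0] * temps[0] + s + h * ta
                              + eps * sigma * ((ts + k.T_KELVIN) ** 4 - t0k ** 4)
                              + hr_lin * temps[0])
                # deep boundary pinned
                ab[1, -1] = 1.0
                ab[2, -2] = 0.0
                rhs[-1] = deep_t
                temps = solve_banded((1, 1), ab, rhs)
            day_T[hour] = temps
            if not prescribed:
                t0k = temps[0] + k.T_KELVIN
                flux[hour] = (s,
                              eps * sigma * ((ts + k.T_KELVIN) ** 4 - t0k ** 4),
                              h * (ta - temps[0]),
                              kc * (temps[1] - temps[0]) / dz[0])
        if prev_day is not None:
            residual = float(np.max(np.abs(day_T - prev_day)))
            if day + 1 >= SPINUP_DAYS and residual < SOIL_PERIODIC_TOL:
                break
        prev_day = day_T.copy()
    else:
        raise RuntimeError(
            f"soil solver failed to reach a periodic state after {MAX_SPINUP_DAYS} "
            f"spin-up days (residual {residual:.3f} degC)"
        )
    return SoilGrid(z, day_T.copy(), flux, residual)


# ---------------------------------------------------------------------------
# Height profiles
# ---------------------------------------------------------------------------

def env_at_height(t_surface: float, t_air_ref: float, wind_ref: float, z: float,
                  roughness: float = ROUGHNESS_DEFAULT,
                  z_ref: float = REFERENCE_HEIGHT) -> tuple[float, float]:
    """(air temperature, wind) at height ``z`` from a logarithmic profile.

    Wind vanishes at the roughness height; air temperature interpolates
    between the ground-surface temperature (at the roughness height) and the
    reference-height value on the same log coordinate.
    """
    if z <= roughness:
        return t_surface, 0.0
    z = min(z, z_ref)
    f = math.log(z / roughness) / math.log(z_ref / roughness)
    wind = wind_ref * f
    t_air = t_surface + (t_air_ref - t_surface) * f
    return t_air, wind


# ---------------------------------------------------------------------------
# Day assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HourlyEnvironment:
    """Operative environment for one hour at one site."""
    hour: int
    t_air_ref: float          # degC at reference height
    wind_ref: float           # m/s at reference height
    rh: float                 # %
    cloud: float              # %
    solar_direct: float       # W/m^2 horizontal
    solar_diffuse: float      # W/m^2 horizontal
    cos_zenith: float
    t_sky: float              # degC radiant
    t_ground_surface: float   # degC
    t_substrate_profile: tuple[float, ...]
    site: str                 # "open-sun" | "deep-shade"
    elevation: float = 0.0
    o2_fraction: float = 20.95
    roughness: float = ROUGHNESS_DEFAULT
    uniform: bool = False  # chamber conditions: no vertical profile

    def at_height(self, z: float) -> tuple[float, float]:
        """(t_air, wind) at animal height z."""
        if self.uniform:
            return self.t_air_ref, self.wind_ref
        return env_at_height(self.t_ground_surface, self.t_air_ref, self.wind_ref,
                             z, self.roughness)


DIURNAL_SHARE = 0.7  # fraction of the annual air-temperature span that is
                     # the day-night swing (semi-arid tropical analogues have
                     # diurnally dominated temperature ranges); the remainder
                     # is the seasonal drift of the daily envelope


def _monthly_envelope(scenario: MicroclimateScenario, month: int) -> tuple[float, float]:
    """Daily (t_min, t_max) for a mid-month model day.

    The daily swing is DIURNAL_SHARE of the annual span; the envelope drifts
    with an annual cosine peaking mid-July (mid-January south of the
    equator), so the union of the 12 daily envelopes spans exactly the
    scenario's annual extremes: the coldest sunrise touches air_temp_min in
    January and the hottest afternoon touches air_temp_max in July.
    """
    doy = k.MID_MONTH_DOY[month]
    s = math.cos(2 * math.pi * (doy - 196) / 365.0)  # +1 mid-July, -1 mid-Jan
    if scenario.latitude < 0:
        s = -s
    span = scenario.air_temp_max - scenario.air_temp_min
    diurnal = DIURNAL_SHARE * span
    t_min = scenario.air_temp_min + (1.0 + s) / 2.0 * (span - diurnal)
    return t_min, t_min + diurnal


def build_day(scenario: MicroclimateScenario, month: int) -> list[tuple[HourlyEnvironment, HourlyEnvironment]]:
    """24 hourly (open-sun, deep-shade) environment pairs for a mid-month day."""
    doy = k.MID_MONTH_DOY[month]
    sr = sunrise_hour(scenario.latitude, doy)
    t_lo, t_hi = _monthly_envelope(scenario, month)
    hours = np.arange(24)

    t_air = np.array([diurnal_curve(t_lo, t_hi, sr, 12.0, h) for h in hours])
    wind = np.array([diurnal_curve(scenario.wind_min, scenario.wind_max, sr, 12.0, h)
                     for h in hours])
    rh = np.array([diurnal_curve(scenario.rh_min, scenario.rh_max, sr, 12.0, h, "inverted")
                   for h in hours])
    cloud = np.array([diurnal_curve(scenario.cloud_min, scenario.cloud_max, sr, 12.0, h,
                                    "inverted") for h in hours])
    sol = [solar_flux(scenario.latitude, doy, h, cloud[i], scenario.elevation)
           for i, h in enumerate(hours)]
    direct = np.array([s[0] for s in sol])
    diffuse = np.array([s[1] for s in sol])
    cosz = np.array([max(0.0, _cos_zenith(scenario.latitude, doy, h)) for h in hours])
    t_sky = np.array([longwave_sky(t_air[i], rh[i], cloud[i]) for i in range(24)])

    shade_frac = 1.0 - scenario.shade_max / 100.0
    sun_soil = solve_soil(scenario, dict(t_air=t_air, t_sky=t_sky, wind=wind,
                                         solar=direct + diffuse))
    # shade site: solar reduced, sky radiant temperature replaced by air temp
    shade_soil = solve_soil(scenario, dict(t_air=t_air, t_sky=t_air, wind=wind,
                                           solar=(direct + diffuse) * shade_frac))

    out = []
    for i in range(24):
        common = dict(hour=int(i), t_air_ref=float(t_air[i]), wind_ref=float(wind[i]),
                      rh=float(rh[i]), cloud=float(cloud[i]), cos_zenith=float(cosz[i]),
                      elevation=scenario.elevation, o2_fraction=scenario.o2_fraction)
        sun = HourlyEnvironment(
            solar_direct=float(direct[i]), solar_diffuse=float(diffuse[i]),
            t_sky=float(t_sky[i]),
            t_ground_surface=float(sun_soil.temperatures[i, 0]),
            t_substrate_profile=tuple(sun_soil.temperatures[i]),
            site="open-sun", **common)
        shade = HourlyEnvironment(
            solar_direct=float(direct[i] * shade_frac),
            solar_diffuse=float(diffuse[i] * shade_frac),
            t_sky=float(t_air[i]),  # canopy radiates near air temperature
            t_ground_surface=float(shade_soil.temperatures[i, 0]),
            t_substrate_profile=tuple(shade_soil.temperatures[i]),
            site="deep-shade", **common)
        out.append((sun, shade))
    return out


@lru_cache(maxsize=256)
def _build_day_cached(scenario: MicroclimateScenario, month: int):
    return build_day(scenario, month)


def day_environments(scenario: MicroclimateScenario, month: int):
    """Memoized :func:`build_day` (scenarios are frozen dataclasses)."""
    return _build_day_cached(scenario, month)


def chamber_environment(t_air: float, wind: float = 0.1, rh: float = 5.0,
                        o2_fraction: float = 20.95) -> HourlyEnvironment:
    """Metabolic-chamber environment: all radiant temperatures equal air
    temperature, no solar, constant low wind and humidity."""
    return HourlyEnvironment(
        hour=12, t_air_ref=t_air, wind_ref=wind, rh=rh, cloud=0.0,
        solar_direct=0.0, solar_diffuse=0.0, cos_zenith=0.0,
        t_sky=t_air, t_ground_surface=t_air,
        t_substrate_profile=(t_air,) * 10, site="open-sun",
        o2_fraction=o2_fraction, uniform=True)
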