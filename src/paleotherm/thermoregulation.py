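"""Hourly thermoregulatory controller and day/annual aggregation.

Each hour the animal starts from a neutral state (flat insulation,
mid-range flesh conductivity, target core temperature, baseline skin
wetness, maximal oxygen extraction, open site, standing posture) and engages
options in a fixed order — physiological first, then behavioral — until the
heat it must generate to hold its core temperature matches the target
metabolic heat within tolerance, or options run out:

  too cold: ptiloerection -> vasoconstriction -> core-temperature drop
            (bounded heat storage) -> night shade -> wind shelter ->
            curled posture
  too hot:  vasodilation -> core-temperature rise -> skin wetting (only if
            sweating is enabled; it never is for the study taxa) ->
            panting (reduced O2 extraction) -> shade seeking

Each engaged option is resolved continuously within its bounds (a bisection
replaces discrete increments), so an option that can balance the budget
lands exactly on target; later options are only touched if earlier ones
saturate, preserving the stated engagement order.

Energy bookkeeping: the target *heat* the balance must match is
RMR * (1 + (multiplier - 1) * (1 - muscle_efficiency)) because a fraction of
activity energy leaves as mechanical work; the reported metabolic *energy*
is RMR * multiplier on target, grows 1:1 with extra thermogenic heat when
cold-stressed, and shrinks by (heat deficit)/(1 - efficiency) when heat
stress forces activity below the multiplier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from . import constants as k
from . import mass_budget
from .config import DietSpec, MicroclimateScenario, PhysiologySpec, build_diet
from .heat_balance import BASELINE_WET_FRACTION, SurfaceState, animal_balance, HeatFluxes
from .microclimate import HourlyEnvironment, day_environments
from .morphometry import AnimalSpec, apply_posture

__all__ = [
    "ThermoregState",
    "HourResult",
    "DayResult",
    "AnnualResult",
    "daily_target_me",
    "solve_hour",
    "simulate_day",
    "simulate_year",
    "DEFAULT_BEHAVIORS",
]

DEFAULT_BEHAVIORS = frozenset({"shade", "night_shade", "wind_shelter", "posture"})


@dataclass
class ThermoregState:
    erect_fraction: float = 0.0
    flesh_conductivity: float = 0.5
    t_core: float = 38.0
    wet_fraction: float = BASELINE_WET_FRACTION
    o2_extraction: float = 0.20
    in_shade: bool = False
    night_shade: bool = False
    wind_sheltered: bool = False
    posture: str = "standing"


@dataclass
class HourResult:
    hour: int
    fluxes: HeatFluxes
    state: ThermoregState
    target_met: float     # W, metabolic energy target (RMR x multiplier)
    achieved_met: float   # W, metabolic energy actually spent
    stress: str           # none | cold | heat
    active: bool


@dataclass
class DayResult:
    month: int
    hourly: list[HourResult]
    daily_me: float       # MJ
    food_kg: float
    water_budget: mass_budget.MassBudget
    shade_hours: int
    hours_at_target_tcore: int


@dataclass
class AnnualResult:
    days: list[DayResult]
    annual_me: float      # MJ
    annual_target_me: float
    food_kg: float        # per year
    drinking_water_kg: float  # per year (only hours in deficit)
    shade_hours: int
    hours_at_target_tcore: int

    @property
    def ratio_to_target(self) -> float:
        return self.annual_me / self.annual_target_me


def daily_target_me(rmr: float, activity_multiplier: float) -> float:
    """Daily target metabolic energy, MJ/day = RMR * multiplier * 86400 / 1e6."""
    return rmr * activity_multiplier * 86400.0 / 1.0e6


def _target_heat(phys: PhysiologySpec, multiplier: float) -> float:
    """Heat-production target, W: activity energy above resting loses a
    muscle-efficiency share as mechanical work."""
    return phys.rmr * (1.0 + (multiplier - 1.0) * (1.0 - phys.muscle_efficiency))


def _achieved_energy(q_needed: float, phys: PhysiologySpec, multiplier: float) -> float:
    """Map required heat production to metabolic energy spent (W)."""
    target_heat = _target_heat(phys, multiplier)
    target_energy = phys.rmr * multiplier
    if q_needed >= target_heat:
        return target_energy + (q_needed - target_heat)  # thermogenesis is all heat
    if q_needed >= phys.rmr:
        # scale activity down: each W of activity energy sheds (1-eff) W heat
        return phys.rmr + (q_needed - phys.rmr) / (1.0 - phys.muscle_efficiency)
    return max(q_needed, 0.0)  # cannot even dissipate resting heat


class _HourSolver:
    """One hour's controller run; owns the (cached) balance evaluation."""

    def __init__(self, animal, phys, env_sun, env_shade, behaviors, multiplier):
        self.animal = animal
        self.lying = None  # built lazily
        self.phys = phys
        self.env_sun = env_sun
        self.env_shade = env_shade
        self.behaviors = behaviors
        self.multiplier = multiplier
        self.target_heat = _target_heat(phys, multiplier)
        self.tol = k.MET_TOLERANCE * self.target_heat
        self.is_night = env_sun.solar_direct + env_sun.solar_diffuse <= 0.0

    def _env(self, state: ThermoregState) -> HourlyEnvironment:
        env = self.env_shade if (state.in_shade or state.night_shade) else self.env_sun
        if state.night_shade and not state.in_shade:
            # night shade substitutes the radiant sky only
            env = replace(self.env_sun, t_sky=self.env_sun.t_air_ref)
        if state.wind_sheltered:
            env = replace(env, wind_ref=max(0.1, 0.3 * env.wind_ref))
        return env

    def balance(self, state: ThermoregState) -> HeatFluxes:
        body = self.animal
        if state.posture == "posture_3":
            if self.lying is None:
                self.lying = apply_posture(self.animal, "posture_3")
            body = self.lying
        surf = SurfaceState(erect_fraction=state.erect_fraction,
                            flesh_conductivity=state.flesh_conductivity,
                            wet_fraction=state.wet_fraction,
                            o2_extraction=state.o2_extraction)
        return animal_balance(body, state.t_core, surf, self._env(state))

    def err(self, state: ThermoregState) -> float:
        """required heat - target heat (positive = too cold)."""
        return self.balance(state).q_met - self.target_heat

    def solve(self) -> tuple[ThermoregState, HeatFluxes, float]:
        phys = self.phys
        k_lo, k_hi = phys.flesh_conductivity_range
        k_mid = 0.5 * (k_lo + k_hi)
        o2_lo, o2_hi = phys.o2_extraction_range
        state = ThermoregState(
            erect_fraction=0.0, flesh_conductivity=k_mid,
            t_core=phys.ctr_target,
            wet_fraction=BASELINE_WET_FRACTION,
            o2_extraction=o2_hi)

        e0 = self.err(state)
        if abs(e0) <= self.tol:
            return self._finish(state)

        if e0 > 0:   # too cold: reduce heat loss
            options = [
                ("erect_fraction", 0.0, 1.0, self._has_erectable()),
                ("flesh_conductivity", k_mid, k_lo, True),
                ("t_core", phys.ctr_target, phys.ctr_min, True),
                ("night_shade", None, None,
                 "night_shade" in self.behaviors and self.is_night),
                ("wind_shelter", None, None, "wind_shelter" in self.behaviors),
                ("posture", None, None, "posture" in self.behaviors),
            ]
        else:        # too hot: increase heat loss
            options = [
                ("flesh_conductivity", k_mid, k_hi, True),
                ("t_core", phys.ctr_target, phys.ctr_max, True),
                ("wet_fraction", BASELINE_WET_FRACTION, 1.0, phys.sweating_enabled),
                ("o2_extraction", o2_hi, o2_lo, True),
                ("shade", None, None, "shade" in self.behaviors),
            ]
        for name, lo, hi, enabled in options:
            if not enabled:
                continue
            state, err, done = self._engage(state, name, lo, hi, e0)
            if done:
                return self._finish(state)
            e0 = err
        return self._finish(state)

    def _has_erectable(self) -> bool:
        return any(
            (s.insulation_dorsal is not None and s.insulation_dorsal.erectable)
            or (s.insulation_ventral is not None and s.insulation_ventral.erectable)
            for s in self.animal.segments)

    def _set(self, state: ThermoregState, name: str, value) -> ThermoregState:
        if name == "night_shade":
            return replace(state, night_shade=bool(value))
        if name == "wind_shelter":
            return replace(state, wind_sheltered=bool(value))
        if name == "shade":
            return replace(state, in_shade=bool(value))
        if name == "posture":
            return replace(state, posture="posture_3" if value else "standing")
        return replace(state, **{name: value})

    def _engage(self, state, name, lo, hi, err_before):
        """Engage one option; returns (state, err, on_target)."""
        if lo is None:  # binary behavioral option
            trial = self._set(state, name, True)
            err = self.err(trial)
            if abs(err) <= self.tol:
                return trial, err, True
            # keep it only if it helped (moved toward target without crossing
            # to a worse deficit on the other side)
            if abs(err) < abs(err_before):
                return trial, err, False
            return state, err_before, False
        full = self._set(state, name, hi)
        err_full = self.err(full)
        if abs(err_full) <= self.tol:
            return full, err_full, True
        if (err_full > 0) == (err_before > 0):
            # option saturates without crossing the target: keep it fully on
            return full, err_full, False
        # target bracketed inside this option's range: bisect the setting
        x_lo, x_hi = 0.0, 1.0
        state_mid = full
        err_mid = err_full
        for _ in range(25):
            x = 0.5 * (x_lo + x_hi)
            state_mid = self._set(state, name, lo + (hi - lo) * x)
            err_mid = self.err(state_mid)
            if abs(err_mid) <= self.tol:
                return state_mid, err_mid, True
            if (err_mid > 0) == (err_before > 0):
                x_lo = x
            else:
                x_hi = x
        return state_mid, err_mid, True  # within bisection resolution

    def _finish(self, state: ThermoregState) -> tuple[ThermoregState, HeatFluxes, float]:
        fluxes = self.balance(state)
        return state, fluxes, fluxes.q_met


def solve_hour(animal: AnimalSpec, phys: PhysiologySpec,
               env_sun: HourlyEnvironment, env_shade: HourlyEnvironment,
               behaviors_enabled: frozenset = DEFAULT_BEHAVIORS,
               multiplier: float | None = None) -> HourResult:
    """Run the hourly controller; see the module docstring for the order."""
    mult = phys.activity_multiplier if multiplier is None else multiplier
    solver = _HourSolver(animal, phys, env_sun, env_shade, behaviors_enabled, mult)
    state, fluxes, q_needed = solver.solve()
    target_energy = phys.rmr * mult
    achieved = _achieved_energy(q_needed, phys, mult)
    err_heat = q_needed - solver.target_heat
    if abs(err_heat) <= solver.tol:
        stress = "none"
        achieved = target_energy
    elif err_heat > 0:
        stress = "cold"
    else:
        stress = "heat"
    return HourResult(hour=env_sun.hour, fluxes=fluxes, state=state,
                      target_met=target_energy, achieved_met=achieved,
                      stress=stress, active=stress != "heat")


def simulate_day(animal: AnimalSpec, phys: PhysiologySpec,
                 scenario: MicroclimateScenario, model_day: int,
                 diet: DietSpec | None = None,
                 behaviors_enabled: frozenset = DEFAULT_BEHAVIORS) -> DayResult:
    """24 controller hours on the mid-month model day ``model_day`` (0-11)."""
    if diet is None:
        diet = build_diet("carnivore" if animal.taxon == "coelophysis"
                          else "high_browser")
    env_pairs = day_environments(scenario, model_day)
    hourly = [solve_hour(animal, phys, sun, shade, behaviors_enabled)
              for sun, shade in env_pairs]
    daily_me = sum(h.achieved_met for h in hourly) * 3600.0 / 1.0e6
    m_in, _, _ = mass_budget.food_requirement(daily_me, diet)
    resp_water = sum(
        mass_budget.respiratory_exchange(
            metabolic_rate=max(h.achieved_met, 1e-6),
            o2_fraction=env_pairs[i][0].o2_fraction,
            extraction=h.state.o2_extraction, t_lung=h.state.t_core,
            inhaled_rh=env_pairs[i][0].rh,
            t_air=env_pairs[i][0].at_height(animal.mean_height)[0])[2] / 24.0
        for i, h in enumerate(hourly))
    budget = mass_budget.water_budget(m_in, diet, resp_water, daily_me)
    return DayResult(
        month=model_day, hourly=hourly, daily_me=daily_me, food_kg=m_in,
        water_budget=budget,
        shade_hours=sum(1 for h in hourly if h.state.in_shade),
        hours_at_target_tcore=sum(
            1 for h in hourly
            if abs(h.state.t_core - phys.ctr_target) < 0.5))


def simulate_year(animal: AnimalSpec, phys: PhysiologySpec,
                  scenario: MicroclimateScenario,
                  diet: DietSpec | None = None,
                  behaviors_enabled: frozenset = DEFAULT_BEHAVIORS) -> AnnualResult:
    """12 mid-month model days weighted by month length (365-day year)."""
    days = [simulate_day(animal, phys, scenario, m, diet, behaviors_enabled)
            for m in range(12)]
    weights = k.DAYS_PER_MONTH
    annual_me = sum(d.daily_me * w for d, w in zip(days, weights))
    annual_target = daily_target_me(phys.rmr, phys.activity_multiplier) * sum(weights)
    food = sum(d.food_kg * w for d, w in zip(days, weights))
    drink = sum(max(0.0, -d.water_budget.discretionary_water) / 1000.0 * w
                for d, w in zip(days, weights))
    return AnnualResult(
        days=days, annual_me=annual_me, annual_target_me=annual_target,
        food_kg=food, drinking_water_kg=drink,
        shade_hours=sum(d.shade_hours * w for d, w in zip(days, weights)),
        hours_at_target_tcore=sum(d.hours_at_target_tcore * w
                                  for d, w in zip(days, weights)))
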