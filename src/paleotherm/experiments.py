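"""Experiment drivers: metabolic-chamber sweeps, viability matrices,
factorial climate analysis and single-parameter sensitivity sweeps."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import constants as k
from .config import (CTR_LABELS, ConfigurationError, MicroclimateScenario,
                     PhysiologySpec, build_diet, build_physiology, build_scenario,
                     rmr_from_mass)
from .microclimate import chamber_environment
from .morphometry import AnimalSpec, InsulationSpec, build_animal
from .thermoregulation import (DEFAULT_BEHAVIORS, daily_target_me, simulate_year,
                               solve_hour)

__all__ = [
    "TNZResult",
    "ViabilityMatrix",
    "EffectsTable",
    "metabolic_chamber",
    "classify_viability",
    "run_matrix",
    "yates_effects",
    "inverse_yates",
    "sweep",
    "annual_target_me",
]

CHAMBER_WIND = 0.1   # m/s
CHAMBER_RH = 5.0     # %
CRITICAL_TEMP_RESOLUTION = 0.1  # degC bisection refinement of TNZ bounds


def annual_target_me(phys: PhysiologySpec) -> float:
    """Annual target metabolic energy, MJ (365-day year)."""
    return daily_target_me(phys.rmr, phys.activity_multiplier) * sum(k.DAYS_PER_MONTH)


# ---------------------------------------------------------------------------
# Metabolic chamber
# ---------------------------------------------------------------------------

@dataclass
class TNZResult:
    grid: pd.DataFrame          # columns: t_air_C, q_met_W, t_core_C, stress
    lower_critical: float | None
    upper_critical: float | None

    @property
    def width(self) -> float | None:
        if self.lower_critical is None or self.upper_critical is None:
            return None
        return self.upper_critical - self.lower_critical


def _chamber_hour(animal, phys, t_air, mode, o2):
    mult = 1.0 if mode == "resting" else phys.activity_multiplier
    env = chamber_environment(t_air, wind=CHAMBER_WIND, rh=CHAMBER_RH, o2_fraction=o2)
    return solve_hour(animal, phys, env, env,
                      behaviors_enabled=frozenset(), multiplier=mult)


def metabolic_chamber(animal: AnimalSpec, phys: PhysiologySpec,
                      t_min: float = 0.0, t_max: float = 51.0, step: float = 0.5,
                      mode: str = "resting", o2_fraction: float = 20.95) -> TNZResult:
    """Sweep chamber air temperature and locate the thermoneutral zone.

    Chamber conditions: ground, sky and air temperatures all equal, no solar
    input, 0.1 m/s wind, 5 % relative humidity, standing posture, behaviors
    disabled.  ``mode="resting"`` uses no activity multiplier; ``"active"``
    applies the physiology's multiplier, giving the active thermoneutral
    zone.  Critical temperatures (the TNZ interval bounds, where the
    achieved metabolic rate departs from target) are refined by bisection to
    0.1 degC.
    """
    if t_min >= t_max:
        raise ValueError("t_min must be below t_max")
    temps = np.arange(t_min, t_max + step / 2, step)
    rows = []
    on_target = []
    for t in temps:
        hr = _chamber_hour(animal, phys, float(t), mode, o2_fraction)
        rows.append((float(t), hr.achieved_met, hr.state.t_core, hr.stress))
        on_target.append(hr.stress == "none")
    grid = pd.DataFrame(rows, columns=["t_air_C", "q_met_W", "t_core_C", "stress"])

    if not any(on_target):
        return TNZResult(grid=grid, lower_critical=None, upper_critical=None)

    # longest contiguous on-target run = the TNZ interval
    best_len, best_start = 0, 0
    i = 0
    while i < len(on_target):
        if on_target[i]:
            j = i
            while j < len(on_target) and on_target[j]:
                j += 1
            if j - i > best_len:
                best_len, best_start = j - i, i
            i = j
        else:
            i += 1
    lo_idx, hi_idx = best_start, best_start + best_len - 1

    def refine(t_out, t_in):
        """Bisect between an off-target and an on-target temperature."""
        for _ in range(30):
            if abs(t_in - t_out) <= CRITICAL_TEMP_RESOLUTION:
                break
            mid = 0.5 * (t_in + t_out)
            if _chamber_hour(animal, phys, mid, mode, o2_fraction).stress == "none":
                t_in = mid
            else:
                t_out = mid
        return t_in

    lower = float(temps[lo_idx])
    if lo_idx > 0:
        lower = refine(float(temps[lo_idx - 1]), lower)
    upper = float(temps[hi_idx])
    if hi_idx < len(temps) - 1:
        upper = refine(float(temps[hi_idx + 1]), upper)
    return TNZResult(grid=grid, lower_critical=lower, upper_critical=upper)


def compare_tnz(bounds_a: tuple[float, float], bounds_b: tuple[float, float]) -> dict:
    """Width and bound shifts going from TNZ ``bounds_a`` to ``bounds_b``.

    Returns width_increase = width(b) - width(a), and the (positive
    downward) shifts of the upper and lower critical temperatures.
    """
    (lo_a, hi_a), (lo_b, hi_b) = bounds_a, bounds_b
    return dict(width_increase=(hi_b - lo_b) - (hi_a - lo_a),
                upper_shift=hi_a - hi_b, lower_shift=lo_a - lo_b)


# ---------------------------------------------------------------------------
# Viability classification and matrices
# ---------------------------------------------------------------------------

VIABILITY_CLASSES = ("far_below", "below", "target", "above", "far_above")


def classify_viability(annual_me: float, annual_target: float) -> str:
    """Five-class ratio thresholding of annual ME against target.

    far_above (>10 % above target: cold-stressed), above (5-10 % above),
    target (+/- 5 %), below (5-10 % below), far_below (>10 % below:
    heat-stressed).  Boundary ratios join the milder class.
    """
    if annual_target <= 0:
        raise ValueError("annual_target must be positive")
    r = annual_me / annual_target
    if r > 1.10:
        return "far_above"
    if r > 1.05:
        return "above"
    if r >= 0.95:
        return "target"
    if r >= 0.90:
        return "below"
    return "far_below"


@dataclass
class ViabilityMatrix:
    table: pd.DataFrame  # scenario, rmr, ctr, annual_me_MJ, target_MJ, ratio, class

    def count(self, cls: str) -> int:
        return int((self.table["class"] == cls).sum())


def run_matrix(taxon: str, insulation_mode: str = "none",
               scenarios: tuple[str, ...] = ("hot_arid", "moderate_arid", "cold_arid"),
               grades: tuple[str, ...] = ("squamate", "monotreme", "ratite"),
               ctrs: tuple[str, ...] = ("broad", "moderate", "narrow"),
               mass: float | None = None) -> ViabilityMatrix:
    """Annual simulations over scenario x RMR grade x CTR (27 cells default)."""
    animal = build_animal(taxon, insulation=insulation_mode, mass=mass)
    rows = []
    for sc_name, grade, ctr in itertools.product(scenarios, grades, ctrs):
        scenario = build_scenario(sc_name)
        phys = build_physiology(grade, ctr, animal.total_mass, taxon=taxon)
        year = simulate_year(animal, phys, scenario)
        target = annual_target_me(phys)
        rows.append(dict(scenario=sc_name, rmr=grade, ctr=ctr,
                         annual_me_MJ=year.annual_me, target_MJ=target,
                         ratio=year.annual_me / target,
                         **{"class": classify_viability(year.annual_me, target)}))
    return ViabilityMatrix(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Yates 2^4 factorial
# ---------------------------------------------------------------------------

@dataclass
class EffectsTable:
    factors: tuple[str, ...]
    responses: np.ndarray          # 2^k, standard (Yates) order
    mean: float
    effects: dict[str, float]      # label like "temperature" or "temperature:wind"


def _yates_labels(factors):
    labels = []
    n = len(factors)
    for i in range(1, 2 ** n):
        parts = [factors[j] for j in range(n) if i >> j & 1]
        labels.append(":".join(parts))
    return labels


def yates_effects(responses, factors=("temperature", "wind", "humidity", "cloud")
                  ) -> EffectsTable:
    """Classical Yates forward pass on a 2^k response vector.

    ``responses`` must be in standard order (first factor alternating
    fastest).  Effects are the fold-and-difference column divided by
    2^(k-1); the grand mean divides by 2^k.
    """
    y = np.asarray(responses, dtype=float)
    n = len(factors)
    if y.shape != (2 ** n,):
        raise ValueError(f"need {2 ** n} responses in standard order, got {y.shape}")
    col = y.copy()
    for _ in range(n):
        sums = col[0::2] + col[1::2]
        diffs = col[1::2] - col[0::2]
        col = np.concatenate([sums, diffs])
    mean = col[0] / 2 ** n
    effects = dict(zip(_yates_labels(factors), col[1:] / 2 ** (n - 1)))
    return EffectsTable(factors=tuple(factors), responses=y, mean=mean,
                        effects=effects)


def inverse_yates(table: EffectsTable) -> np.ndarray:
    """Reconstruct the response vector from mean + effects (exact inverse)."""
    n = len(table.factors)
    runs = 2 ** n
    y = np.empty(runs)
    labels = _yates_labels(table.factors)
    for run in range(runs):
        total = table.mean
        for idx, label in enumerate(labels, start=1):
            sign = 1.0
            for j in range(n):
                if idx >> j & 1:
                    sign *= 1.0 if run >> j & 1 else -1.0
            total += sign * table.effects[label] / 2.0
        y[run] = total
    return y


# Factor levels for the climate factorial: temperature uses the cold/hot
# scenario envelopes (both ends move together); wind, humidity and cloud pin
# their daily range at the envelope's low or high end.
_CLIMATE_LEVELS = {
    "temperature": ({"air_temp_min": 16.0, "air_temp_max": 30.0},
                    {"air_temp_min": 26.0, "air_temp_max": 40.0}),
    "wind": ({"wind_min": 1.0, "wind_max": 1.0}, {"wind_min": 4.0, "wind_max": 4.0}),
    "humidity": ({"rh_min": 13.0, "rh_max": 65.0}, {"rh_min": 48.0, "rh_max": 96.0}),
    "cloud": ({"cloud_min": 50.0, "cloud_max": 50.0},
              {"cloud_min": 90.0, "cloud_max": 90.0}),
}


def climate_factorial(taxon: str, insulation_mode: str = "none",
                      grade: str = "ratite", ctr: str = "narrow") -> EffectsTable:
    """Run the 2^4 climate factorial (annual ME response) and analyze it."""
    animal = build_animal(taxon, insulation=insulation_mode)
    phys = build_physiology(grade, ctr, animal.total_mass, taxon=taxon)
    factors = ("temperature", "wind", "humidity", "cloud")
    responses = []
    for run in range(16):
        overrides = {}
        for j, f in enumerate(factors):
            overrides.update(_CLIMATE_LEVELS[f][run >> j & 1])
        scenario = build_scenario("moderate_arid", **overrides)
        year = simulate_year(animal, phys, scenario)
        responses.append(year.annual_me)
    return yates_effects(responses, factors)


# ---------------------------------------------------------------------------
# Single-parameter sweeps
# ---------------------------------------------------------------------------

SWEEP_PARAMETERS = ("mass", "wind", "reflectivity", "muscle_efficiency",
                    "respiratory_extraction", "digestive_efficiency",
                    "latitude", "insulation_mode")


def sweep(parameter: str, values, taxon: str = "plateosaurus",
          scenario_name: str = "hot_arid", grade: str = "ratite",
          ctr: str = "narrow", insulation_mode: str = "none",
          diet_name: str | None = None) -> pd.DataFrame:
    """One annual simulation per value, all else fixed.

    Returns a table with annual ME (MJ), annual food (kg), drinking water
    (kg) and viability class per value.
    """
    if parameter not in SWEEP_PARAMETERS:
        raise ConfigurationError(
            f"unsupported sweep parameter {parameter!r}; valid: {SWEEP_PARAMETERS}")
    if diet_name is None:
        diet_name = "carnivore" if taxon == "coelophysis" else "high_browser"
    rows = []
    for v in values:
        scenario = build_scenario(scenario_name)
        animal = build_animal(taxon, insulation=insulation_mode)
        diet = build_diet(diet_name)
        phys_over = {}
        if parameter == "mass":
            animal = build_animal(taxon, insulation=insulation_mode, mass=float(v))
        elif parameter == "wind":
            scenario = build_scenario(scenario_name, wind_min=float(v), wind_max=float(v))
        elif parameter == "reflectivity":
            spec = InsulationSpec(surface_reflectivity=float(v))
            animal = build_animal(taxon, insulation=insulation_mode,
                                  insulation_spec=spec)
            animal = replace(animal, segments=tuple(
                replace(s, skin_reflectivity=float(v)) for s in animal.segments))
        elif parameter == "muscle_efficiency":
            phys_over["muscle_efficiency"] = float(v)
        elif parameter == "respiratory_extraction":
            phys_over["o2_extraction_range"] = (float(v), float(v))
        elif parameter == "digestive_efficiency":
            diet = build_diet(diet_name, digestive_efficiency=float(v))
        elif parameter == "latitude":
            scenario = build_scenario(scenario_name, latitude=float(v))
        elif parameter == "insulation_mode":
            animal = build_animal(taxon, insulation=str(v))
        phys = build_physiology(grade, ctr, animal.total_mass, taxon=taxon,
                                **phys_over)
        year = simulate_year(animal, phys, scenario, diet=diet)
        target = annual_target_me(phys)
        rows.append(dict(value=v, annual_me_MJ=year.annual_me,
                         annual_target_MJ=target,
                         food_kg_y=year.food_kg,
                         drinking_water_kg_y=year.drinking_water_kg,
                         **{"class": classify_viability(year.annual_me, target)}))
    return pd.DataFrame(rows)
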