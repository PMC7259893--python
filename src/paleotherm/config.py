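"""Study configuration: microclimate scenarios, physiology grades and diets.

This module is the package's synthetic-scenario generator.  It encodes the
six Late Triassic microclimate parameter sets (hot/moderate/cold crossed with
arid/humid), the resting-metabolic-rate (RMR) grades spanning squamate to
eutherian physiology, the three core-temperature-range (CTR) labels, and the
three diets, all as validated dataclasses that round-trip through YAML.

The RMR table encodes published annual energy budgets for the two study taxa
(a 21 kg theropod, *Coelophysis*, and an 850 kg prosauropod, *Plateosaurus*)
at six mass estimates each; off-table masses are served by a log-log power
law fitted through the tabulated pairs.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import constants as k

__all__ = [
    "SoilProperties",
    "MicroclimateScenario",
    "PhysiologySpec",
    "DietSpec",
    "build_scenario",
    "build_physiology",
    "build_diet",
    "fmr_allometric",
    "rmr_from_mass",
    "SCENARIO_NAMES",
    "RMR_GRADES",
    "CTR_LABELS",
    "RMR_TABLE",
]


class ConfigurationError(ValueError):
    """Raised for invalid scenario / physiology / diet requests."""


# ---------------------------------------------------------------------------
# Soil
# ---------------------------------------------------------------------------

def _default_node_depths() -> tuple[float, ...]:
    # 10 nodes, surface to 2 m deep boundary, quasi-log spacing
    return (0.0, 0.025, 0.05, 0.1, 0.2, 0.35, 0.55, 0.8, 1.2, 2.0)


@dataclass(frozen=True)
class SoilProperties:
    """Homogeneous substrate column for the 1-D soil heat solver.

    Defaults describe a generic dry loam; the study's substance is not
    sensitive to substrate choice, but the values are overridable.
    """

    thermal_conductivity: float = 0.9       # W/m/K
    volumetric_heat_capacity: float = 1.5e6  # J/m^3/K
    solar_reflectivity: float = 0.3
    ir_emissivity: float = 0.95
    node_depths: tuple[float, ...] = field(default_factory=_default_node_depths)

    def __post_init__(self) -> None:
        if self.thermal_conductivity <= 0 or self.volumetric_heat_capacity <= 0:
            raise ConfigurationError("soil conductivity and heat capacity must be positive")
        if not (0 <= self.solar_reflectivity <= 1 and 0 <= self.ir_emissivity <= 1):
            raise ConfigurationError("soil reflectivity/emissivity must lie in [0, 1]")
        d = np.asarray(self.node_depths)
        if d[0] != 0 or np.any(np.diff(d) <= 0):
            raise ConfigurationError("node_depths must increase strictly from 0")


# ---------------------------------------------------------------------------
# Microclimate scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicroclimateScenario:
    """Annual envelope of one named microclimate.

    Air-temperature, wind, humidity and cloud envelopes are annual ranges;
    the microclimate module expands them into 12 mid-month model days with
    diurnal sinusoids and a seasonal cycle (warmest month July at 12 N).
    """

    name: str
    latitude: float = 12.0       # degrees N
    elevation: float = 150.0     # m
    air_temp_min: float = 20.0   # degC, annual envelope
    air_temp_max: float = 34.0
    wind_min: float = 1.0        # m/s
    wind_max: float = 4.0
    rh_min: float = 13.0         # %
    rh_max: float = 65.0
    cloud_min: float = 50.0      # %
    cloud_max: float = 90.0
    substrate: SoilProperties = field(default_factory=SoilProperties)
    o2_fraction: float = 18.0    # % of atmosphere (Late Triassic)
    co2_fraction: float = 0.13   # %
    shade_max: float = 90.0      # % of solar blocked at the deepest-shade site

    def __post_init__(self) -> None:
        for lo, hi, what in (
            (self.air_temp_min, self.air_temp_max, "air_temp"),
            (self.wind_min, self.wind_max, "wind"),
            (self.rh_min, self.rh_max, "rh"),
            (self.cloud_min, self.cloud_max, "cloud"),
        ):
            if lo > hi:
                raise ConfigurationError(f"{what}: min {lo} exceeds max {hi}")
        if not (0 <= self.rh_min and self.rh_max <= 100):
            raise ConfigurationError("relative humidity must lie in [0, 100] %")
        if not (0 <= self.cloud_min and self.cloud_max <= 100):
            raise ConfigurationError("cloud cover must lie in [0, 100] %")
        if self.o2_fraction <= 0:
            raise ConfigurationError("o2_fraction must be positive")
        if not -90 <= self.latitude <= 90:
            raise ConfigurationError("latitude must lie in [-90, 90]")
        if not 0 <= self.shade_max <= 100:
            raise ConfigurationError("shade_max must lie in [0, 100] %")


# Annual air-temperature envelopes (degC) and humidity regimes.
_TEMPERATURE_RANGES = {"hot": (26.0, 40.0), "moderate": (20.0, 34.0), "cold": (16.0, 30.0)}
_HUMIDITY_RANGES = {"arid": (13.0, 65.0), "humid": (48.0, 96.0)}

SCENARIO_NAMES = tuple(
    f"{t}_{h}" for t in ("hot", "moderate", "cold") for h in ("arid", "humid")
)


def build_scenario(name: str, **overrides) -> MicroclimateScenario:
    """Build one of the six named microclimates, e.g. ``"hot_arid"``.

    Keyword overrides replace any scenario field (used by sensitivity sweeps,
    e.g. ``build_scenario("cold_arid", latitude=45.0)``).
    """
    if name not in SCENARIO_NAMES:
        raise ConfigurationError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        )
    temp_label, hum_label = name.split("_")
    t_lo, t_hi = _TEMPERATURE_RANGES[temp_label]
    rh_lo, rh_hi = _HUMIDITY_RANGES[hum_label]
    params = dict(
        name=name,
        air_temp_min=t_lo,
        air_temp_max=t_hi,
        rh_min=rh_lo,
        rh_max=rh_hi,
    )
    params.update(overrides)
    return MicroclimateScenario(**params)


# ---------------------------------------------------------------------------
# Physiology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhysiologySpec:
    rmr: float                      # W, resting metabolic rate
    ctr_min: float                  # degC, lower bound of core-temperature range
    ctr_target: float
    ctr_max: float
    activity_multiplier: float = 2.0
    muscle_efficiency: float = k.MUSCLE_EFFICIENCY_DEFAULT
    o2_extraction_range: tuple[float, float] = (0.15, 0.20)  # panting lowers it
    flesh_conductivity_range: tuple[float, float] = (k.FLESH_K_MIN, k.FLESH_K_MAX)
    sweating_enabled: bool = False
    fat_fraction: float = 5.0       # % of body mass as subcutaneous fat

    def __post_init__(self) -> None:
        if not self.ctr_min <= self.ctr_target <= self.ctr_max:
            raise ConfigurationError("require ctr_min <= ctr_target <= ctr_max")
        if self.rmr <= 0:
            raise ConfigurationError("rmr must be positive")
        if self.activity_multiplier < 1:
            raise ConfigurationError("activity_multiplier must be >= 1")
        lo, hi = self.o2_extraction_range
        if not 0 < lo <= hi <= 1:
            raise ConfigurationError("o2_extraction_range must satisfy 0 < lo <= hi <= 1")


# Published RMR table (W) at six mass estimates per taxon; columns are
# the three tabulated grades.  Masses in kg.
RMR_TABLE: dict[str, dict[str, tuple[tuple[float, ...], tuple[float, ...]]]] = {
    "coelophysis": {
        "squamate": ((15, 21, 30, 40, 50, 60), (2.6, 3.4, 4.5, 5.7, 6.9, 8.0)),
        "monotreme": ((15, 21, 30, 40, 50, 60), (9.7, 12.3, 16.0, 19.7, 23.1, 26.4)),
        "ratite": ((15, 21, 30, 40, 50, 60), (17.5, 22.2, 28.5, 34.9, 40.9, 46.5)),
    },
    "plateosaurus": {
        "squamate": ((600, 850, 1150, 1600, 2000, 3000),
                     (52.7, 70.1, 89.9, 117.8, 141.5, 197.2)),
        "monotreme": ((600, 850, 1150, 1600, 2000, 3000),
                      (139.8, 179.9, 224.0, 284.4, 334.3, 448.4)),
        "ratite": ((600, 850, 1150, 1600, 2000, 3000),
                   (235.5, 301.1, 372.6, 470.3, 550.4, 732.5)),
    },
}

RMR_GRADES = ("squamate", "monotreme", "marsupial", "ratite", "eutherian")

CTR_LABELS = {
    # label -> (ctr_min, ctr_target, ctr_max); all share the 40 C ceiling
    # and the 38 C target.
    "broad": (26.0, 38.0, 40.0),
    "moderate": (32.0, 38.0, 40.0),
    "narrow": (36.0, 38.0, 40.0),
}


def _power_law_fit(masses, rmrs) -> tuple[float, float]:
    """Least-squares log-log fit, returning (a, b) of rmr = a * mass**b."""
    logm = np.log(np.asarray(masses, dtype=float))
    logr = np.log(np.asarray(rmrs, dtype=float))
    b, loga = np.polyfit(logm, logr, 1)
    return float(np.exp(loga)), float(b)


def rmr_from_mass(grade: str, taxon: str, mass: float) -> float:
    """RMR (W) for a grade/taxon at an arbitrary mass.

    Tabulated masses return the printed value exactly; other masses evaluate
    the power law fitted through the taxon's tabulated column.  The two
    untabulated grades are synthesized: eutherian from the classic
    3.4*M^0.75 W mammalian allometry, marsupial as the geometric mean of the
    monotreme and ratite fits.
    """
    if mass <= 0:
        raise ConfigurationError("mass must be positive")
    if grade not in RMR_GRADES:
        raise ConfigurationError(f"unknown RMR grade {grade!r}; valid: {RMR_GRADES}")
    taxon = taxon.lower()
    if taxon not in RMR_TABLE:
        raise ConfigurationError(f"unknown taxon {taxon!r}; valid: {tuple(RMR_TABLE)}")

    if grade == "eutherian":
        return 3.4 * mass ** 0.75
    if grade == "marsupial":
        return math.sqrt(
            rmr_from_mass("monotreme", taxon, mass) * rmr_from_mass("ratite", taxon, mass)
        )

    masses, rmrs = RMR_TABLE[taxon][grade]
    for m, r in zip(masses, rmrs):
        if math.isclose(mass, m, rel_tol=1e-9):
            return r
    if not masses[0] / 1.5 <= mass <= masses[-1] * 1.5:
        warnings.warn(
            f"mass {mass} kg is outside 1.5x the tabulated span for {taxon}; "
            "power-law extrapolation",
            stacklevel=2,
        )
    a, b = _power_law_fit(masses, rmrs)
    return a * mass ** b


def build_physiology(grade: str, ctr: str, taxon_mass: float, taxon: str = None,
                     **overrides) -> PhysiologySpec:
    """Physiology for an RMR grade and CTR label at a given body mass.

    ``taxon`` defaults to whichever taxon's tabulated mass span contains the
    requested mass (the two spans do not overlap).
    """
    if ctr not in CTR_LABELS:
        raise ConfigurationError(f"unknown CTR label {ctr!r}; valid: {tuple(CTR_LABELS)}")
    if taxon is None:
        taxon = "coelophysis" if taxon_mass <= 300 else "plateosaurus"
    rmr = rmr_from_mass(grade, taxon, taxon_mass)
    lo, target, hi = CTR_LABELS[ctr]
    params = dict(rmr=rmr, ctr_min=lo, ctr_target=target, ctr_max=hi)
    params.update(overrides)
    return PhysiologySpec(**params)


def fmr_allometric(mass: float) -> float:
    """Field metabolic rate diagnostic, FMR = 4.82 * mass**0.734.

    The source formula's units are not stated; this is exposed purely as a
    diagnostic and is never used inside the heat balance.
    """
    if mass <= 0:
        raise ConfigurationError("mass must be positive")
    return 4.82 * mass ** 0.734


# ---------------------------------------------------------------------------
# Diets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DietSpec:
    name: str
    protein_pct: float           # % of dry mass
    fat_pct: float
    carb_pct: float
    dry_matter_pct: float        # % of wet mass
    digestive_efficiency: float  # fraction of ingested energy absorbed
    fecal_water_pct: float       # % water in feces
    urinary_nitrogen_water_pct: float = 0.0  # "uric acid" water parameter
    energy_density_protein: float = k.ENERGY_DENSITY_PROTEIN  # MJ/kg
    energy_density_fat: float = k.ENERGY_DENSITY_FAT
    energy_density_carb: float = k.ENERGY_DENSITY_CARB

    def __post_init__(self) -> None:
        if self.protein_pct + self.fat_pct + self.carb_pct > 100 + 1e-9:
            raise ConfigurationError("protein + fat + carb cannot exceed 100 % of dry mass")
        for v in (self.protein_pct, self.fat_pct, self.carb_pct,
                  self.dry_matter_pct, self.fecal_water_pct,
                  self.urinary_nitrogen_water_pct):
            if not 0 <= v <= 100:
                raise ConfigurationError("diet percentages must lie in [0, 100]")
        if not 0 < self.digestive_efficiency <= 1:
            raise ConfigurationError("digestive_efficiency must lie in (0, 1]")

    @property
    def dry_energy_density(self) -> float:
        """Gross energy of the dry matter, MJ/kg."""
        return (self.protein_pct * self.energy_density_protein
                + self.fat_pct * self.energy_density_fat
                + self.carb_pct * self.energy_density_carb) / 100.0

    @property
    def wet_energy_density(self) -> float:
        """Gross energy per kg of food as eaten, MJ/kg wet."""
        return self.dry_energy_density * self.dry_matter_pct / 100.0


_DIETS = {
    # High browse (conifer/ginkgo-like): drier, same macronutrients.
    "high_browser": dict(protein_pct=10, fat_pct=0, carb_pct=88,
                         dry_matter_pct=44, digestive_efficiency=0.60,
                         fecal_water_pct=60, urinary_nitrogen_water_pct=60),
    # Low browse (fern/horsetail-like): high water content.
    "low_browser": dict(protein_pct=10, fat_pct=0, carb_pct=88,
                        dry_matter_pct=25, digestive_efficiency=0.60,
                        fecal_water_pct=60, urinary_nitrogen_water_pct=60),
    "carnivore": dict(protein_pct=60, fat_pct=38, carb_pct=0,
                      dry_matter_pct=66.7, digestive_efficiency=0.85,
                      fecal_water_pct=46, urinary_nitrogen_water_pct=27),
}


def build_diet(name: str, **overrides) -> DietSpec:
    if name not in _DIETS:
        raise ConfigurationError(f"unknown diet {name!r}; valid: {tuple(_DIETS)}")
    params = dict(name=name, **_DIETS[name])
    params.update(overrides)
    return DietSpec(**params)


def wet_energy_density(dry_energy_mj_per_kg: float, dry_fraction: float) -> float:
    """Energy per kg wet mass of a food given its dry-matter energy density.

    E.g. horsetail at 11.6 MJ/kg dry and 30 % dry matter -> 3.5 MJ/kg wet.
    """
    if not 0 < dry_fraction <= 1:
        raise ConfigurationError("dry_fraction must lie in (0, 1]")
    return dry_energy_mj_per_kg * dry_fraction


# ---------------------------------------------------------------------------
# Serialization helpers (YAML round-trip is exercised by paleotherm.io)
# ---------------------------------------------------------------------------

def to_dict(obj) -> dict:
    """Dataclass -> plain dict (tuples become lists for YAML)."""
    def convert(v):
        if dataclasses.is_dataclass(v):
            return {f.name: convert(getattr(v, f.name)) for f in dataclasses.fields(v)}
        if isinstance(v, tuple):
            return [convert(x) for x in v]
        return v
    return convert(obj)


def scenario_from_dict(d: dict) -> MicroclimateScenario:
    d = dict(d)
    soil = d.pop("substrate", None)
    if soil is not None:
        soil = dict(soil)
        if "node_depths" in soil:
            soil["node_depths"] = tuple(soil["node_depths"])
        soil = SoilProperties(**soil)
        d["substrate"] = soil
    return MicroclimateScenario(**d)


def physiology_from_dict(d: dict) -> PhysiologySpec:
    d = dict(d)
    for key in ("o2_extraction_range", "flesh_conductivity_range"):
        if key in d:
            d[key] = tuple(d[key])
    return PhysiologySpec(**d)


def diet_from_dict(d: dict) -> DietSpec:
    return DietSpec(**d)
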