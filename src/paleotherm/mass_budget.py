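"""Daily food, oxygen and water budgets driven by metabolic energy.

The metabolic rate is a 'biological fire': the day's energy expenditure sets
how much dry matter must be absorbed from the gut, digestive efficiency sets
how much food must be ingested, and the oxygen demand (through the oxyjoule
equivalent) sets the ventilation volume and hence respiratory water loss.
Discretionary water is the credit (or debt, requiring drinking) left after
food water and metabolic water cover respiratory, fecal and urinary losses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import constants as k
from .config import DietSpec
from .microclimate import vapor_density

__all__ = ["MassBudget", "food_requirement", "respiratory_exchange", "water_budget"]

# Rough dry mass of nitrogenous waste produced per gram of protein oxidized.
NITROGEN_WASTE_PER_G_PROTEIN = 0.35


@dataclass
class MassBudget:
    m_in: float                 # kg wet food / day
    m_abs: float                # kg / day absorbed (dry)
    m_out: float                # kg / day excreted (everything not absorbed)
    vo2: float = 0.0            # L O2 / day
    vair: float = 0.0           # L air / day
    resp_water_loss: float = 0.0    # g / day
    metabolic_water: float = 0.0    # g / day
    food_water: float = 0.0         # g / day
    fecal_water: float = 0.0        # g / day
    urinary_water: float = 0.0      # g / day
    discretionary_water: float = 0.0  # g / day; negative = must drink


def food_requirement(daily_me: float, diet: DietSpec) -> tuple[float, float, float]:
    """(m_in, m_abs, m_out) in kg/day for a daily metabolic energy in MJ.

    The dry matter's energy density is the macronutrient-weighted sum;
    m_abs is the dry mass whose oxidation covers daily_me, the digestive
    efficiency divides into it to give the dry intake, and the dry-matter
    fraction converts to wet food as eaten.
    """
    if daily_me < 0:
        raise ValueError("daily_me must be >= 0")
    e_dry = diet.dry_energy_density
    if e_dry <= 0 or diet.dry_matter_pct <= 0:
        raise ValueError("diet has no usable dry matter")
    m_abs = daily_me / e_dry                      # kg dry oxidized
    dry_intake = m_abs / diet.digestive_efficiency
    m_in = dry_intake / (diet.dry_matter_pct / 100.0)
    m_out = m_in - m_abs
    return m_in, m_abs, m_out


def respiratory_exchange(metabolic_rate: float, o2_fraction: float,
                         extraction: float, t_lung: float, inhaled_rh: float,
                         t_air: float, nostril_recovery: float = k.NOSTRIL_RECOVERY_DEFAULT
                         ) -> tuple[float, float, float, float]:
    """(vo2 L/day, vair L/day, respiratory water loss g/day, sensible W).

    Oxygen demand is metabolic power over the oxyjoule equivalent; dividing
    by the extraction coefficient and the atmospheric O2 fraction gives the
    ventilation volume.  Inhaled air is saturated at lung (core) temperature;
    exhaled air leaves at a temperature pulled back toward ambient by the
    nostril counter-current recovery fraction, and the vapor-density
    difference over the ventilation volume is the water loss.
    """
    if extraction <= 0 or extraction > 1:
        raise ValueError("extraction must lie in (0, 1]")
    if o2_fraction <= 0:
        raise ValueError("o2_fraction must be positive")
    vo2_per_s = metabolic_rate / k.OXYJOULE_EQUIVALENT     # L/s
    vair_per_s = vo2_per_s / (o2_fraction / 100.0 * extraction)
    t_exhale = t_lung - nostril_recovery * (t_lung - t_air)
    rho_out = vapor_density(t_exhale, 100.0)               # kg/m^3, saturated
    rho_in = vapor_density(t_air, inhaled_rh)
    water_per_s = vair_per_s * 1e-3 * max(0.0, rho_out - rho_in)  # kg/s
    # sensible warming of the ventilated air mass
    rho_air = k.P_SEA_LEVEL / (k.R_AIR * (t_air + k.T_KELVIN))
    sensible = vair_per_s * 1e-3 * rho_air * k.CP_AIR * max(0.0, t_exhale - t_air)
    return (vo2_per_s * 86400.0, vair_per_s * 86400.0,
            water_per_s * 86400.0 * 1000.0, sensible)


def water_budget(m_in: float, diet: DietSpec, resp_water_loss: float,
                 daily_me: float) -> MassBudget:
    """Complete the daily mass/water budget for a given intake and energy.

    Metabolic water applies per-gram oxidation coefficients to the
    macronutrient mix actually oxidized; fecal water is the stated percent of
    wet fecal mass applied to the unabsorbed dry residue; urinary water is
    modeled only when the diet's uric-acid parameter is set, as that percent
    of the wet nitrogenous excretion estimated from protein turnover.
    """
    _, m_abs, m_out = food_requirement(daily_me, diet)
    food_water = m_in * (1.0 - diet.dry_matter_pct / 100.0) * 1000.0  # g

    g_abs = m_abs * 1000.0
    g_protein = g_abs * diet.protein_pct / 100.0
    g_fat = g_abs * diet.fat_pct / 100.0
    g_carb = g_abs * diet.carb_pct / 100.0
    metabolic_water = (g_protein * k.METABOLIC_WATER_PROTEIN
                       + g_fat * k.METABOLIC_WATER_FAT
                       + g_carb * k.METABOLIC_WATER_CARB)

    dry_feces = max(0.0, (m_in * diet.dry_matter_pct / 100.0 - m_abs)) * 1000.0
    fw = diet.fecal_water_pct
    fecal_water = dry_feces * fw / (100.0 - fw) if fw < 100 else dry_feces

    urinary_water = 0.0
    uw = diet.urinary_nitrogen_water_pct
    if uw > 0:
        waste_dry = NITROGEN_WASTE_PER_G_PROTEIN * g_protein
        urinary_water = waste_dry * uw / (100.0 - uw) if uw < 100 else waste_dry

    discretionary = (food_water + metabolic_water
                     - resp_water_loss - fecal_water - urinary_water)
    return MassBudget(
        m_in=m_in, m_abs=m_abs, m_out=m_out,
        resp_water_loss=resp_water_loss, metabolic_water=metabolic_water,
        food_water=food_water, fecal_water=fecal_water,
        urinary_water=urinary_water, discretionary_water=discretionary)
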