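"""Physical constants and documented model defaults.

Everything here is a plain module-level constant so that values are easy to
audit and (where scientifically negotiable) to override through configuration
objects that take them as defaults.
"""

# --- universal / atmospheric ------------------------------------------------
STEFAN_BOLTZMANN = 5.670374419e-8  # W/m^2/K^4
SOLAR_CONSTANT = 1361.0            # W/m^2, top of atmosphere
T_KELVIN = 273.15
P_SEA_LEVEL = 101325.0             # Pa
GRAVITY = 9.80665                  # m/s^2
R_AIR = 287.05                     # J/kg/K, dry air gas constant
CP_AIR = 1006.0                    # J/kg/K
LATENT_HEAT_VAP = 2.43e6           # J/kg, water at ~30 C

# --- clear-sky solar / longwave --------------------------------------------
ATM_TRANSMITTANCE = 0.70           # broadband transmittance per optical air mass
DIFFUSE_FRACTION = 0.15            # diffuse share of global clear-sky flux
CLOUD_SOLAR_ATTENUATION = 0.65     # global flux reduced by (1 - 0.65*cloud_frac)
# Brunt clear-sky emissivity: eps = BRUNT_A + BRUNT_B * sqrt(e_hPa)
BRUNT_A = 0.52
BRUNT_B = 0.065

# --- tissue / insulation ---------------------------------------------------
FLESH_DENSITY = 0.97               # kg/L, whole-body average used for both taxa
FLESH_SPECIFIC_HEAT = 3470.0       # J/kg/K (lumped capacitance)
FLESH_K_MIN = 0.4                  # W/m/K, fully vasoconstricted
FLESH_K_MAX = 2.8                  # W/m/K, fully vasodilated
FAT_CONDUCTIVITY = 0.2             # W/m/K
FAT_DENSITY = 0.9                  # kg/L
KERATIN_CONDUCTIVITY = 0.2         # W/m/K, feather/hair element material
AIR_CONDUCTIVITY_20C = 0.0257      # W/m/K
EMISSIVITY_DEFAULT = 0.95          # skin, insulation and ground IR emissivity
PTILOERECTION_DEPTH_GAIN = 2.0     # full erection triples depth (1 + f*gain),
                                   # i.e. 10 mm flat layer erects to the 30 mm
                                   # element length of the default plumage
GROUND_CONTACT_CONDUCTANCE = 20.0  # W/m^2/K, ventral surface to substrate

# --- metabolism / mass budget ----------------------------------------------
OXYJOULE_EQUIVALENT = 20.1e3       # J per L O2
ENERGY_DENSITY_PROTEIN = 17.8      # MJ/kg (combustion)
ENERGY_DENSITY_FAT = 39.3          # MJ/kg
ENERGY_DENSITY_CARB = 17.5         # MJ/kg
METABOLIC_WATER_PROTEIN = 0.396    # g water per g oxidized
METABOLIC_WATER_FAT = 1.07
METABOLIC_WATER_CARB = 0.556
NOSTRIL_RECOVERY_DEFAULT = 0.5     # fraction of lung-air warming recovered on exhale
MUSCLE_EFFICIENCY_DEFAULT = 0.20   # fraction of activity energy NOT appearing as heat

# --- numerics ---------------------------------------------------------------
MET_TOLERANCE = 0.01               # |achieved - target| / target for "on target"
SKIN_SOLVE_TOL = 1e-3              # degC, surface-temperature iteration
DAYS_PER_MONTH = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
MID_MONTH_DOY = (15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349)
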