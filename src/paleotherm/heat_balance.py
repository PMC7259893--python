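"""Steady-state heat balance of body segments and whole animals.

For each hour the flesh of every segment must generate exactly the metabolic
heat that leaves through its surfaces while the core is held at the
controller's chosen temperature.  Heat leaves the core through the flesh
(distributed-generation conduction), an optional fat shell, an optional
porous fur/feather layer, and finally by convection and net infrared
exchange at the exposed surface, offset by absorbed solar radiation and
augmented by cutaneous evaporation on bare skin.  The required generation
solves

    q_met - q_resp - q_st - q_evap = q_rad + q_conv - q_sol

with q_st = 0 at steady state; the porous-layer flux q_fur carries the same
energy where insulation is present.  Respiratory loss is a whole-animal term
evaluated once per hour and iterated to consistency with the metabolic rate.

Appendages (legs, tail) are mostly muscle and tendon and are solved with an
effective core temperature halfway between the torso core and ambient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import constants as k
from . import mass_budget
from .microclimate import HourlyEnvironment, vapor_density
from .morphometry import AnimalSpec, BodySegment, InsulationSpec, segment_properties

__all__ = [
    "HeatFluxes",
    "SurfaceState",
    "convection_coefficient",
    "insulation_conductance",
    "segment_balance",
    "animal_balance",
]

_SIGMA = k.STEFAN_BOLTZMANN
_TK = k.T_KELVIN
BASELINE_WET_FRACTION = 0.04   # fraction of bare skin effectively wet (non-sweating)
INSULATION_COMPRESSION = 0.3   # lying compresses ventral insulation to 30 % depth


@dataclass
class HeatFluxes:
    """Per-hour flux decomposition, W (positive = loss from the animal,
    except q_sol and q_met which are gains/generation)."""
    q_met: float = 0.0
    q_resp: float = 0.0
    q_evap: float = 0.0
    q_st: float = 0.0
    q_fur: float = 0.0
    q_rad: float = 0.0
    q_conv: float = 0.0
    q_sol: float = 0.0
    q_cond_ground: float = 0.0

    def __add__(self, other: "HeatFluxes") -> "HeatFluxes":
        return HeatFluxes(*(getattr(self, f) + getattr(other, f)
                            for f in self.__dataclass_fields__))

    @property
    def closure_residual(self) -> float:
        """|q_met - q_resp - q_st - q_evap - (q_rad + q_conv + q_cond_ground - q_sol)|."""
        return abs(self.q_met - self.q_resp - self.q_st - self.q_evap
                   - (self.q_rad + self.q_conv + self.q_cond_ground - self.q_sol))


@dataclass
class SurfaceState:
    """Controller-set surface/physiology state used by the balance."""
    erect_fraction: float = 0.0
    flesh_conductivity: float = 0.5       # W/m/K
    wet_fraction: float = BASELINE_WET_FRACTION
    o2_extraction: float = 0.20
    t_skin: float = float("nan")          # filled by the solver (area-mean)
    t_insulation_surface: float = float("nan")


# ---------------------------------------------------------------------------
# Air properties and convection
# ---------------------------------------------------------------------------

def _air_props(t_film_c: float, elevation: float):
    """(rho, k_air, kinematic viscosity, Pr) at film temperature/elevation."""
    t = t_film_c + _TK
    p = k.P_SEA_LEVEL * math.exp(-elevation / 8434.0)
    rho = p / (k.R_AIR * t)
    mu = 1.458e-6 * t ** 1.5 / (t + 110.4)  # Sutherland
    k_air = 0.0241 * (t / 273.15) ** 0.9
    return rho, k_air, mu / rho, 0.71


def convection_coefficient(characteristic_dimension: float, wind: float,
                           t_surface: float, t_air: float,
                           elevation: float = 0.0) -> float:
    """Combined free + forced convection coefficient, W/m^2/K.

    Forced: Churchill-Bernstein cylinder-in-crossflow Nusselt correlation.
    Free: Churchill-Chu horizontal-cylinder correlation.  The two are blended
    as Nu = (Nu_forced^3 + Nu_free^3)^(1/3); air properties at the film
    temperature, density corrected for elevation.
    """
    if characteristic_dimension <= 0:
        raise ValueError("characteristic dimension must be positive")
    d = characteristic_dimension
    t_film = 0.5 * (t_surface + t_air)
    rho, k_air, nu, pr = _air_props(t_film, elevation)

    nu_f = 0.0
    if wind > 0:
        re = wind * d / nu
        nu_f = (0.3 + 0.62 * math.sqrt(re) * pr ** (1 / 3)
                / (1 + (0.4 / pr) ** (2 / 3)) ** 0.25
                * (1 + (re / 282000.0) ** 0.625) ** 0.8)

    dt = abs(t_surface - t_air)
    ra = k.GRAVITY * dt * d ** 3 / ((t_film + _TK) * nu * (nu / pr))
    nu_n = (0.60 + 0.387 * ra ** (1 / 6)
            / (1 + (0.559 / pr) ** (9 / 16)) ** (8 / 27)) ** 2

    nu_comb = (nu_f ** 3 + nu_n ** 3) ** (1 / 3)
    return nu_comb * k_air / d


# ---------------------------------------------------------------------------
# Porous insulation
# ---------------------------------------------------------------------------

def insulation_conductance(spec: InsulationSpec | None, erect_fraction: float,
                           t_mean: float) -> tuple[float, float]:
    """(effective conductivity W/m/K, layer conductance W/m^2/K).

    The layer conducts along three parallel paths: still air between the
    elements, the keratin elements themselves (area-weighted by their fill
    fraction), and thermal radiation through the inter-element space with a
    radiative conductivity 16*sigma*T^3 / (3*beta), where the extinction
    coefficient beta = N*d grows with element areal density N and diameter d
    (denser coats block radiation better).  Erection deepens the layer by
    (1 + erect_fraction * depth_gain), capped at the element length.

    A missing or zero-depth layer returns infinite conductance (bare skin).
    """
    if spec is None or spec.layer_depth <= 0:
        return float("inf"), float("inf")
    depth = spec.layer_depth * 1e-3
    if spec.erectable:
        depth *= 1.0 + erect_fraction * k.PTILOERECTION_DEPTH_GAIN
    depth = min(depth, spec.element_length * 1e-3)

    n_per_m2 = spec.element_density * 1e4
    d_m = spec.element_diameter * 1e-6
    fill = min(0.95, n_per_m2 * math.pi * (d_m / 2) ** 2)

    t_k3 = (t_mean + _TK) ** 3
    beta = max(n_per_m2 * d_m, 1e-6)  # optical extinction, 1/m
    k_rad = 16.0 * _SIGMA * t_k3 / (3.0 * beta)
    k_eff = (k.AIR_CONDUCTIVITY_20C * (1.0 - fill)
             + spec.element_conductivity * fill
             + k_rad)
    return k_eff, k_eff / depth


# ---------------------------------------------------------------------------
# Segment balance
# ---------------------------------------------------------------------------

def _internal_conductance(segment: BodySegment, k_flesh: float) -> float:
    """Whole-segment conductance from core to skin, W/K (flesh + fat in series).

    Flesh uses the distributed-generation closed forms (core = hottest point):
    4*pi*k*L per cylinder-like element, 8*pi*k*r_eq for sphere/ellipsoid.
    The fat shell is treated as a slab of its thickness over the skin area.
    """
    dims = segment.dimensions
    if segment.shape == "cylinder":
        g = 4 * math.pi * k_flesh * dims[1]
    elif segment.shape == "elliptical_cylinder":
        g = 4 * math.pi * k_flesh * dims[2]
    elif segment.shape == "truncated_cone":
        g = 4 * math.pi * k_flesh * dims[2]
    elif segment.shape == "sphere":
        g = 8 * math.pi * k_flesh * dims[0]
    else:  # ellipsoid
        r_eq = (dims[0] * dims[1] * dims[2]) ** (1 / 3)
        g = 8 * math.pi * k_flesh * r_eq
    g *= segment.count
    if segment.fat_layer_thickness > 0:
        area = segment_properties(segment)[0]
        g_fat = k.FAT_CONDUCTIVITY * area / segment.fat_layer_thickness
        g = 1.0 / (1.0 / g + 1.0 / g_fat)
    return g


def _path_solve(t_core: float, g_int: float, area: float, u_ins: float,
                d_char: float, wind: float, t_air: float, t_rad: float,
                q_sol: float, wet_fraction: float, rh: float,
                elevation: float, emissivity: float) -> tuple[float, dict]:
    """Solve one surface path (bare or insulated half) for its exterior
    surface temperature; returns (q_from_core, flux components).

    The surface balance is linearized (radiation via h_r = 4*eps*sigma*T^3)
    and iterated with updated film properties until the surface temperature
    moves < SKIN_SOLVE_TOL between passes.
    """
    insulated = math.isfinite(u_ins)
    g_core_surface = g_int if not insulated else 1.0 / (1.0 / g_int + 1.0 / (u_ins * area))
    t_s = 0.5 * (t_core + t_air)
    rho_v_air = vapor_density(t_air, rh)
    h = h_r = q_evap = 0.0
    for _ in range(80):
        h = convection_coefficient(d_char, wind, t_s, t_air, elevation)
        dt_rad = t_s - t_rad
        if abs(dt_rad) > 1e-6:
            # secant radiative coefficient: exact T^4 flux at convergence
            h_r = (emissivity * _SIGMA
                   * ((t_s + _TK) ** 4 - (t_rad + _TK) ** 4) / dt_rad)
        else:
            h_r = 4.0 * emissivity * _SIGMA * (0.5 * (t_s + t_rad) + _TK) ** 3
        if wet_fraction > 0 and not insulated:
            rho, _, _, _ = _air_props(0.5 * (t_s + t_air), elevation)
            h_m = h / (rho * k.CP_AIR)  # Lewis relation
            q_evap = (wet_fraction * area * h_m
                      * max(0.0, vapor_density(t_s, 100.0) - rho_v_air)
                      * k.LATENT_HEAT_VAP)
        else:
            q_evap = 0.0
        t_new = ((g_core_surface * t_core + area * (h * t_air + h_r * t_rad)
                  + q_sol - q_evap)
                 / (g_core_surface + area * (h + h_r)))
        if abs(t_new - t_s) < 0.2 * k.SKIN_SOLVE_TOL:
            t_s = t_new
            break
        t_s = 0.7 * t_new + 0.3 * t_s
    q_conv = h * area * (t_s - t_air)
    q_rad = emissivity * _SIGMA * area * ((t_s + _TK) ** 4 - (t_rad + _TK) ** 4)
    q_core = g_core_surface * (t_core - t_s)
    comp = dict(q_conv=q_conv, q_rad=q_rad, q_evap=q_evap, q_sol=q_sol,
                t_surface=t_s, insulated=insulated)
    return q_core, comp


def segment_balance(segment: BodySegment, t_core: float, state: SurfaceState,
                    env: HourlyEnvironment, z_height: float | None = None) -> HeatFluxes:
    """Metabolic heat the segment's flesh must generate to hold ``t_core``.

    The exposed surface is split into a dorsal half (sees the sky, receives
    all solar) and a ventral half (sees the ground); each half carries its
    own insulation layer.  A posture-defined ground-contact area conducts
    directly to the substrate surface.
    """
    area, _, _, d_char = segment_properties(segment)
    if z_height is None:
        z_height = 0.5
    t_air, wind = env.at_height(z_height)

    g_int = _internal_conductance(segment, state.flesh_conductivity)

    contact = min(segment.ground_contact_area, 0.45 * area)
    exposed = area - contact
    a_half = exposed / 2.0

    # solar load: beam on projected area (1/4 of total for a convex body)
    # plus diffuse on the upward-facing half
    s_beam_h = env.solar_direct
    s_diff = env.solar_diffuse
    beam_normal = s_beam_h / max(env.cos_zenith, 0.08) if s_beam_h > 0 else 0.0
    refl = (segment.insulation_dorsal.surface_reflectivity
            if segment.insulation_dorsal else segment.skin_reflectivity)
    alpha = 1.0 - refl / 100.0
    q_sol_total = alpha * (0.25 * exposed * beam_normal + 0.5 * exposed * s_diff)

    t_mean_layer = 0.5 * (t_core + t_air)
    _, u_dorsal = insulation_conductance(segment.insulation_dorsal,
                                         state.erect_fraction, t_mean_layer)
    _, u_ventral = insulation_conductance(segment.insulation_ventral,
                                          state.erect_fraction, t_mean_layer)

    fluxes = HeatFluxes()
    t_surfaces = []
    for (a_i, u_i, t_rad, q_sol) in (
        (a_half, u_dorsal, env.t_sky, q_sol_total),
        (a_half, u_ventral, env.t_ground_surface, 0.0),
    ):
        if a_i <= 0:
            continue
        g_share = g_int * a_i / area
        q_core, comp = _path_solve(
            t_core, g_share, a_i, u_i, d_char, wind, t_air, t_rad, q_sol,
            state.wet_fraction, env.rh, env.elevation, k.EMISSIVITY_DEFAULT)
        fluxes.q_conv += comp["q_conv"]
        fluxes.q_rad += comp["q_rad"]
        fluxes.q_evap += comp["q_evap"]
        fluxes.q_sol += comp["q_sol"]
        if comp["insulated"]:
            fluxes.q_fur += q_core
        fluxes.q_met += q_core
        t_surfaces.append(comp["t_surface"])

    if contact > 0:
        # core -> flesh/fat -> (compressed ventral insulation) -> substrate
        g_share = g_int * contact / area
        g = g_share
        if segment.insulation_ventral is not None:
            k_eff, _ = insulation_conductance(segment.insulation_ventral, 0.0,
                                              t_mean_layer)
            depth = segment.insulation_ventral.layer_depth * 1e-3 * INSULATION_COMPRESSION
            g = 1.0 / (1.0 / g + depth / (k_eff * contact))
        g = 1.0 / (1.0 / g + 1.0 / (k.GROUND_CONTACT_CONDUCTANCE * contact))
        q_gc = g * (t_core - env.t_ground_surface)
        fluxes.q_cond_ground += q_gc
        fluxes.q_met += q_gc

    return fluxes


def animal_balance(animal: AnimalSpec, t_core: float, state: SurfaceState,
                   env: HourlyEnvironment,
                   nostril_recovery: float = k.NOSTRIL_RECOVERY_DEFAULT) -> HeatFluxes:
    """Whole-animal required heat generation at ``t_core`` in ``env``.

    Segment balances are summed; appendages (legs, tail) run at an effective
    core temperature halfway between the torso core and local air.  The
    respiratory loss is a single whole-animal term assigned to the torso and
    iterated to consistency: q_met = surface losses + q_resp(q_met).
    """
    z = animal.mean_height
    t_air, _ = env.at_height(z)
    total = HeatFluxes()
    for seg in animal.segments:
        t_eff = t_core if not seg.is_appendage else t_core - 0.5 * (t_core - t_air)
        total = total + segment_balance(seg, t_eff, state, env, z_height=z)

    # respiratory loss: fixed-point on the gross metabolic rate
    q_surface = total.q_met
    q_met = max(q_surface, 1e-6)
    q_resp = 0.0
    for _ in range(4):
        _, _, water_g, sensible_w = mass_budget.respiratory_exchange(
            metabolic_rate=max(q_met, 1e-6), o2_fraction=env.o2_fraction,
            extraction=state.o2_extraction, t_lung=t_core,
            inhaled_rh=env.rh, t_air=t_air, nostril_recovery=nostril_recovery)
        q_resp_new = water_g / 86400.0 / 1000.0 * k.LATENT_HEAT_VAP + sensible_w
        if abs(q_resp_new - q_resp) < 1e-3:
            q_resp = q_resp_new
            break
        q_resp = q_resp_new
        q_met = max(q_surface + q_resp, 1e-6)
    total.q_resp = q_resp
    total.q_met = q_surface + q_resp
    return total
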