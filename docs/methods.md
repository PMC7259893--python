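# Methods

`paleotherm` couples a one-dimensional microclimate model to a steady-state
animal heat- and mass-balance model, and asks whether an animal of a given
geometry, insulation, resting metabolic rate (RMR) and core-temperature
range (CTR) can hold its energy budget hour by hour across a year.  The
package ships two reference morphologies — a 21 kg bipedal theropod
(*Coelophysis*-like) and an 850 kg prosauropod (*Plateosaurus*-like) — and
six Late Triassic microclimates (hot/moderate/cold × arid/humid at 12° N,
150 m elevation, 18 % atmospheric O₂), but every piece is configurable.

## Microclimate model

**Annual structure.** Each scenario gives annual envelopes for air
temperature, wind (1–4 m s⁻¹), relative humidity and cloud (50–90 %).  The
year is represented by 12 mid-month model days.  The daily air-temperature
swing is 70 % of the annual span, and the daily envelope drifts on an
annual cosine peaking in mid-July, so the coldest January sunrise touches
the annual minimum and the hottest July afternoon the annual maximum.  The
70 % diurnal share reflects the semi-arid tropical regimes the scenarios
describe, whose temperature ranges are dominated by the day–night cycle
rather than seasonality; it is a package constant
(`microclimate.DIURNAL_SHARE`).  Users needing a more seasonal climate can
widen the envelope or lower the share.

**Diurnal interpolation.** Hourly values follow a piecewise sinusoid with
the minimum anchored exactly at sunrise and the maximum one hour after
solar noon (humidity and cloud run inverted, peaking at sunrise): a half
sine on the rising limb, a half cosine relaxing to the next sunrise.

**Solar.** A single-transmittance clear-sky model: direct horizontal flux
S₀ τ^m cos z with S₀ = 1361 W m⁻², τ = 0.70 per optical air mass
(pressure-corrected for elevation), a 15 % diffuse fraction of the global
flux, and cloud attenuation 1 − 0.65·(cloud/100).  Sunrise and solar noon
come from standard solar geometry in local solar time; no spectral
resolution is attempted because the animal balance consumes broadband flux.

**Longwave sky.** Clear-sky emissivity from the Brunt correlation
ε = 0.52 + 0.065 √e (e in hPa), blended toward 1 by cloud fraction;
T_sky = ε^¼ T_air.  The deep-shade site replaces the radiant sky with air
temperature (canopy at air temperature) and blocks `shade_max` (default
90 %) of solar flux.

**Soil.** A 10-node, 0–2 m quasi-log grid solved by backward-Euler finite
differences (six substeps per hour; the surface radiation term is advanced
with a secant-linearized coefficient).  The surface node balances absorbed
solar, net infrared against the sky, bulk convection (h = 5.7 + 3.8·u) and
conduction; the deep boundary is pinned at the day's mean air temperature.
The same forcing day is repeated (minimum 3, maximum 60 spin-up days) until
the profile is 24-h periodic to 0.05 °C; non-convergence raises an error
with the residual.  Against the analytic sinusoidal solution the damped
amplitude is reproduced within 2 % on a refined grid, and doubling the node
count moves the reported surface temperature by less than 0.1 °C.

**Height profiles.** Air temperature and wind at animal height follow a
logarithmic profile between the ground surface (at the roughness height,
default 0.01 m) and the 2 m reference height; wind vanishes at the
roughness height.

## Animal model

**Geometry.** Animals are assemblies of closed-form segments (cylinder,
elliptical cylinder, truncated cone, sphere, ellipsoid) at 0.97 kg L⁻¹
flesh density, with up to three concentric layers: heat-generating flesh, a
subcutaneous fat shell (5 % of body mass on the torso, conductivity
0.2 W m⁻¹ K⁻¹), and porous insulation.  Mass scaling keeps lengths fixed
and multiplies radial dimensions by √(target/current).  The cold resting
posture merges leg volume into the torso (volume conserved to 0.1 %),
drops head and neck to the ground, and opens a ventral conduction
interface equal to the enlarged torso's footprint (contact conductance
20 W m⁻² K⁻¹, ventral insulation compressed to 30 % depth).

**Flesh conduction.** Core-to-skin conductance uses the
distributed-generation closed forms with core = hottest tissue: 4πkL for
cylinder-like segments, 8πk r for spheres/ellipsoids, in series with the
fat shell treated as a slab.  Flesh conductivity ranges 0.4–2.8 W m⁻¹ K⁻¹
for full vasoconstriction to full vasodilation.

**Porous insulation.** The default plumage is 30 mm elements, 10 mm flat
layer depth, 2000 elements cm⁻², 100 µm diameter, 15 % surface
reflectivity.  Effective conductivity is the parallel sum of still air,
keratin (area-weighted by the element fill fraction) and a radiative term
16σT³/(3β) with extinction coefficient β = N·d, so sparse coats leak
radiation.  Erection deepens the layer by (1 + erect·2), capped at the
element length (a flat 10 mm layer erects to the full 30 mm).

**Surface balance.** Each segment's exposed area splits into a dorsal half
(sees the sky, receives all solar: absorbed = (1 − reflectivity)·(beam on
a convex body's A/4 silhouette + diffuse on A/2)) and a ventral half (sees
the ground).  Convection combines a Churchill–Bernstein forced term and a
Churchill–Chu free term as (Nu_f³ + Nu_n³)^⅓ at film-temperature air
properties.  Surface temperatures are solved by damped fixed-point
iteration with a secant radiative coefficient, so the converged balance
satisfies the exact T⁴ exchange; closure residuals are below 0.1 % of the
metabolic term (tested).  Bare skin carries a baseline 4 % effective wet
fraction — non-sweating cutaneous water loss through imperfectly watertight
skin — without which no upper critical temperature above core temperature
exists for low-RMR configurations; sweating (controller-driven wetting) is
disabled for the study taxa.

**Appendages and respiration.** Legs and tail run at an effective core
temperature halfway between torso core and local air.  Respiratory loss is
one whole-animal term: O₂ demand = power / 20.1 kJ L⁻¹, ventilation =
VO₂/(O₂ fraction × extraction), inhaled air saturates at core temperature
and exhales at a temperature pulled halfway back to ambient (nostril
recovery 0.5); the term is iterated to consistency with the metabolic rate.

## Thermoregulatory controller

Each hour starts from a neutral state and engages options in a fixed
order — physiological, then behavioral.  Too cold: ptiloerection,
vasoconstriction, core-temperature drop within the CTR, night shade, wind
shelter, curled posture.  Too hot: vasodilation, core-temperature rise,
skin wetting (if sweating were enabled), panting (O₂ extraction drops from
0.20 toward 0.15, inflating ventilation and respiratory evaporation), shade
seeking.  An option that saturates without reaching target is locked at
full and the next option engages; an option whose range brackets the target
is resolved by bisection to a 1 % metabolic tolerance, so the thermoneutral
plateau is exactly flat.  The controller is fully deterministic.

Energy bookkeeping separates heat from energy: the heat target is
RMR·(1 + (multiplier − 1)·(1 − muscle efficiency)) with a mammal-like 20 %
muscle efficiency (that share of activity energy leaves as work, not heat),
while the reported metabolic energy is RMR·multiplier on target, rises 1:1
with thermogenesis when cold, and falls by (heat deficit)/(1 − efficiency)
when heat stress forces activity down.  Hours are integrated to daily
(MJ/day) and month-length-weighted annual (MJ over 365 days) budgets; cold
hours stay "active", heat-stressed hours do not.

## Experiments

The metabolic chamber sets ground, sky and air temperature equal, no solar,
0.1 m s⁻¹ wind, 5 % humidity, behaviors disabled, and sweeps 0–51 °C in
0.5 °C steps (critical temperatures refined by bisection to 0.1 °C);
"resting" mode uses multiplier 1, "active" mode the physiology's
multiplier.  Viability matrices run scenario × RMR grade × CTR annual
simulations and classify each cell by its ratio to target: > 1.10
cold-stressed, 1.05–1.10 above, ±5 % on target, 0.90–0.95 below, < 0.90
heat-stressed, with boundaries joining the milder class.  The 2⁴ climate
factorial varies temperature (cold vs hot envelope), wind, humidity (arid
vs humid) and cloud between their envelope extremes and analyzes annual
metabolic energy with the classical Yates fold-and-difference pass (the
inverse transform reconstructs responses exactly).  Single-parameter sweeps
cover mass, wind, reflectivity, muscle efficiency, respiratory extraction,
digestive efficiency, latitude and insulation mode.

## RMR grades and diets

The tabulated squamate, monotreme and ratite RMR columns (six masses per
taxon) are ground truth: tabulated masses return the printed value, other
masses evaluate a least-squares log-log power law through the column.  The
two untabulated grades used only by the chamber experiment are synthesized:
eutherian from the classic 3.4·M^0.75 W mammalian allometry, marsupial as
the geometric mean of the monotreme and ratite fits.  Diets (high browser
44 % dry matter, low browser 25 %, carnivore 66.7 %) convert energy to
food through macronutrient energy densities (protein 17.8, fat 39.3,
carbohydrate 17.5 MJ kg⁻¹) and digestive efficiency; metabolic water uses
0.396/1.07/0.556 g per g of protein/fat/carbohydrate oxidized.  Diet
parameters never feed back into the heat balance, so annual metabolic
energy is bit-identical across digestive efficiencies (tested).

## What the generator does and does not emulate

The scenario generator reproduces the stated study conditions: envelope
ranges, sinusoidal diurnal structure, cloudy-sky radiation, soil heat
storage, sun/shade sites.  It does not emulate weather variability (every
July 15th is identical), rainfall, topographic shelter, vegetation
structure beyond a single shade fraction, or paleo-orbital insolation
(modern solar geometry is used).  Passing tests therefore demonstrate the
model's internal physics and its response to mean climate structure, not
robustness to real-weather extremes.

## Numerical choices

Surface-temperature iteration tolerance 2 × 10⁻⁴ °C with 0.7 damping;
controller tolerance 1 % of target heat; chamber critical-temperature
resolution 0.1 °C; soil periodicity 0.05 °C; 365-day year with month
lengths (31, 28, …).  Simulation sizes — 12 model days × 24 h per year,
27 cells per matrix, 16 factorial runs — complete in under two minutes per
matrix on one CPU.

## Known limitations

Absolute thermoneutral-zone bounds and cell-by-cell viability counts depend
on closed-source details of the original study's engine (spectral solar,
fur radiative transfer, convection correlations) and are reproduced here
directionally rather than exactly: thermoneutral zones widen and shift to
lower temperatures with RMR grade and with insulation, the upper bound
drops less than the lower, the large prosauropod is heat-stressed in the
hot microclimate and viable in the moderate one, and the bare theropod is
cold-biased with its best cells in the hot climate.  The steady-state
hourly balance carries no explicit thermal inertia: bounded core-
temperature drift stands in for heat storage, which understates the damping
a multi-tonne body enjoys on sub-daily timescales.  Urinary water is a
coarse nitrogenous-waste estimate.  Juvenile/ontogenetic series and aquatic
or fossorial behaviors are out of scope.
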