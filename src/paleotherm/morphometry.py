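"""Animal geometry: body segments, insulation layers, scaling and posture.

Animals are assemblies of simple closed-form shapes (cylinder, elliptical
cylinder, truncated cone, sphere, ellipsoid), each with flesh density and
conductivity, an optional subcutaneous fat shell, and optional dorsal and/or
ventral porous insulation.  Mass scaling follows the diameter rule: axial
lengths fixed, every radial dimension multiplied by sqrt(target/current), so
mass scales exactly with diameter squared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from . import constants as k

__all__ = [
    "InsulationSpec",
    "BodySegment",
    "AnimalSpec",
    "segment_properties",
    "scale_mass_by_diameter",
    "apply_posture",
    "build_animal",
    "TAXA",
]

SHAPES = ("cylinder", "elliptical_cylinder", "truncated_cone", "sphere", "ellipsoid")


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class InsulationSpec:
    """Porous fur/feather layer on one face of a segment."""
    element_length: float = 30.0     # mm
    layer_depth: float = 10.0        # mm, flat (unerected)
    element_density: float = 2000.0  # elements/cm^2
    element_diameter: float = 100.0  # um
    element_conductivity: float = k.KERATIN_CONDUCTIVITY  # W/m/K
    surface_reflectivity: float = 15.0  # % solar
    erectable: bool = True

    def __post_init__(self) -> None:
        if self.layer_depth > self.element_length:
            raise GeometryError("layer depth cannot exceed element length")
        if self.element_density < 0:
            raise GeometryError("element density must be >= 0")
        if not 0 <= self.surface_reflectivity <= 100:
            raise GeometryError("reflectivity must lie in [0, 100] %")


@dataclass(frozen=True)
class BodySegment:
    """One geometric body part.

    ``dimensions`` are shape specific (all metres):
      cylinder:            (radius, length)
      elliptical_cylinder: (semi_axis_a, semi_axis_b, length)
      truncated_cone:      (radius_base, radius_tip, length)
      sphere:              (radius,)
      ellipsoid:           (semi_a, semi_b, semi_c)
    """
    name: str
    shape: str
    dimensions: tuple[float, ...]
    flesh_density: float = k.FLESH_DENSITY      # kg/L
    flesh_conductivity: float = 0.5             # W/m/K (controller overrides)
    fat_layer_thickness: float = 0.0            # m
    insulation_dorsal: InsulationSpec | None = None
    insulation_ventral: InsulationSpec | None = None
    count: int = 1
    skin_reflectivity: float = 15.0             # % solar, bare skin
    ground_contact_area: float = 0.0            # m^2, set by posture
    is_appendage: bool = False                  # limbs/tail use the 50 % rule

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise GeometryError(f"unsupported shape {self.shape!r}; valid: {SHAPES}")
        if any(d <= 0 for d in self.dimensions):
            raise GeometryError(f"{self.name}: all dimensions must be positive")


def _shape_geometry(shape: str, dims: tuple[float, ...]) -> tuple[float, float, float]:
    """(lateral/total surface area m^2, volume m^3, characteristic dimension m).

    Cylinders and cones expose lateral area only (their ends abut neighbouring
    segments); spheres and ellipsoids are fully exposed.  The characteristic
    dimension is the (mean) diameter for cylinders/cones and the
    equal-volume-sphere diameter for ellipsoids.
    """
    if shape == "cylinder":
        r, L = dims
        return 2 * math.pi * r * L, math.pi * r * r * L, 2 * r
    if shape == "elliptical_cylinder":
        a, b, L = dims
        # Ramanujan perimeter approximation
        h = ((a - b) / (a + b)) ** 2
        per = math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
        return per * L, math.pi * a * b * L, 2 * math.sqrt(a * b)
    if shape == "truncated_cone":
        r1, r2, L = dims
        slant = math.sqrt((r1 - r2) ** 2 + L * L)
        area = math.pi * (r1 + r2) * slant
        vol = math.pi * L / 3.0 * (r1 * r1 + r1 * r2 + r2 * r2)
        return area, vol, r1 + r2  # mean diameter
    if shape == "sphere":
        (r,) = dims
        return 4 * math.pi * r * r, 4.0 / 3.0 * math.pi * r ** 3, 2 * r
    if shape == "ellipsoid":
        a, b, c = dims
        p = 1.6075  # Thomsen approximation
        area = 4 * math.pi * ((a ** p * b ** p + a ** p * c ** p + b ** p * c ** p) / 3) ** (1 / p)
        vol = 4.0 / 3.0 * math.pi * a * b * c
        return area, vol, 2 * (a * b * c) ** (1.0 / 3.0)
    raise GeometryError(shape)


def segment_properties(segment: BodySegment) -> tuple[float, float, float, float]:
    """(surface_area m^2, volume m^3, mass kg, characteristic_dimension m).

    Values are per segment multiplied by ``count``; the characteristic
    dimension is per element.  Mass = density x closed-form volume (flesh
    density applied; the fat shell adds volume at fat density).
    """
    area, vol, d = _shape_geometry(segment.shape, segment.dimensions)
    mass = vol * segment.flesh_density * 1000.0
    if segment.fat_layer_thickness > 0:
        fat_vol = area * segment.fat_layer_thickness
        mass += fat_vol * k.FAT_DENSITY * 1000.0
        vol += fat_vol
    n = segment.count
    return area * n, vol * n, mass * n, d


@dataclass(frozen=True)
class AnimalSpec:
    taxon: str
    segments: tuple[BodySegment, ...]
    total_mass: float        # kg
    mean_height: float       # m, torso axis midline in current posture
    posture: str = "standing"

    def __post_init__(self) -> None:
        mass = sum(segment_properties(s)[2] for s in self.segments)
        if abs(mass - self.total_mass) > 0.005 * self.total_mass:
            raise GeometryError(
                f"segment masses sum to {mass:.2f} kg but total_mass is "
                f"{self.total_mass} kg (> 0.5 % apart)")

    @property
    def surface_area(self) -> float:
        return sum(segment_properties(s)[0] for s in self.segments)

    def segment(self, name: str) -> BodySegment:
        for s in self.segments:
            if s.name == name:
                return s
        raise GeometryError(f"no segment named {name!r}")


def _scale_segment(seg: BodySegment, f: float) -> BodySegment:
    """Multiply radial dimensions by f, leave axial lengths unchanged."""
    d = seg.dimensions
    if seg.shape == "cylinder":
        nd = (d[0] * f, d[1])
    elif seg.shape == "elliptical_cylinder":
        nd = (d[0] * f, d[1] * f, d[2])
    elif seg.shape == "truncated_cone":
        nd = (d[0] * f, d[1] * f, d[2])
    elif seg.shape == "sphere":
        nd = (d[0] * f ** (2.0 / 3.0),)  # keep mass ~ f^2 for closed shapes
    else:  # ellipsoid: scale the two minor axes, keep the long axis
        nd = (d[0], d[1] * f, d[2] * f)
    return replace(seg, dimensions=nd)


def scale_mass_by_diameter(animal: AnimalSpec, target_mass: float) -> AnimalSpec:
    """Rescale to ``target_mass`` by inflating/deflating segment diameters.

    Axial lengths are conserved and densities unchanged, so mass scales with
    diameter squared: f = sqrt(target/current).  The fat shell is rebuilt to
    keep its share of body mass.
    """
    if target_mass <= 0:
        raise GeometryError("target mass must be positive")
    f = math.sqrt(target_mass / animal.total_mass)
    segs = tuple(_scale_segment(s, f) for s in animal.segments)
    # fat shells scale imperfectly (area x thickness); renormalize thickness
    segs = _adjust_fat(segs, animal, target_mass)
    return replace(animal, segments=segs, total_mass=target_mass,
                   mean_height=animal.mean_height * math.sqrt(f))


def _adjust_fat(segs: tuple[BodySegment, ...], animal: AnimalSpec,
                target_mass: float) -> tuple[BodySegment, ...]:
    """Trim the torso fat shell so the assembly hits target_mass exactly."""
    torso_idx = next((i for i, s in enumerate(segs) if s.name == "torso"), None)
    mass_wo_fat = sum(
        segment_properties(replace(s, fat_layer_thickness=0.0))[2] for s in segs)
    if torso_idx is None:
        return segs
    torso = segs[torso_idx]
    area, _, _, _ = segment_properties(replace(torso, fat_layer_thickness=0.0))
    deficit = target_mass - mass_wo_fat
    thickness = max(0.0, deficit / (area * k.FAT_DENSITY * 1000.0))
    segs = list(segs)
    segs[torso_idx] = replace(torso, fat_layer_thickness=thickness)
    return tuple(segs)


# ---------------------------------------------------------------------------
# Postures
# ---------------------------------------------------------------------------

def apply_posture(animal: AnimalSpec, posture: str) -> AnimalSpec:
    """Apply a named posture.

    ``standing`` restores the as-built geometry.  ``posture_3`` (the cold /
    resting posture) merges the legs' volume into the torso — the torso's
    radial dimensions grow to conserve total volume — drops head and neck to
    ground contact, and opens a ventral conduction interface equal to the
    enlarged torso's projected ventral area.
    """
    if posture == "standing":
        return animal if animal.posture == "standing" else replace(
            animal, posture="standing")
    if posture != "posture_3":
        raise GeometryError(f"unknown posture {posture!r}; valid: standing, posture_3")

    legs = [s for s in animal.segments if "leg" in s.name]
    others = [s for s in animal.segments if "leg" not in s.name]
    leg_volume = sum(segment_properties(s)[1] for s in legs)
    leg_mass = sum(segment_properties(s)[2] for s in legs)

    new_segments = []
    for seg in others:
        if seg.name == "torso":
            bare = replace(seg, fat_layer_thickness=0.0)
            _, vol, flesh_mass, _ = segment_properties(bare)
            fat_mass = segment_properties(seg)[2] - flesh_mass
            extra_flesh = leg_mass / (seg.flesh_density * 1000.0)
            f = math.sqrt((vol + extra_flesh) / vol)
            seg = _scale_segment(seg, f)
            if fat_mass > 0:  # conserve the fat shell's mass on the larger torso
                area_new = segment_properties(replace(seg, fat_layer_thickness=0.0))[0]
                seg = replace(seg, fat_layer_thickness=fat_mass / (area_new * k.FAT_DENSITY * 1000.0))
            # ventral contact: projected footprint of the enlarged torso
            d = seg.dimensions
            if seg.shape == "cylinder":
                contact = 2 * d[0] * d[1]
            elif seg.shape == "elliptical_cylinder":
                contact = 2 * d[0] * d[2]
            else:
                contact = segment_properties(seg)[0] / math.pi
            seg = replace(seg, ground_contact_area=contact)
        elif seg.name in ("head", "neck"):
            area = segment_properties(seg)[0]
            seg = replace(seg, ground_contact_area=0.25 * area)
        new_segments.append(seg)
    lying = replace(animal, segments=tuple(new_segments),
                    mean_height=max(0.05, animal.mean_height * 0.35),
                    posture="posture_3")
    return lying


# ---------------------------------------------------------------------------
# Taxon fixtures
# ---------------------------------------------------------------------------

# Nominal segment dimension sets (m); built geometry is rescaled by
# scale_mass_by_diameter so the assembly hits the target mass exactly at
# 0.97 kg/L flesh density.
_COELOPHYSIS_SEGMENTS = (
    ("torso", "elliptical_cylinder", (0.085, 0.065, 0.75), 1, False),
    ("neck", "truncated_cone", (0.040, 0.030, 0.45), 1, False),
    ("head", "ellipsoid", (0.11, 0.045, 0.045), 1, False),
    ("tail", "truncated_cone", (0.046, 0.012, 1.20), 1, True),
    ("hind_legs", "cylinder", (0.024, 0.55), 2, True),
    ("front_legs", "cylinder", (0.018, 0.30), 2, True),
)

_PLATEOSAURUS_SEGMENTS = (
    ("torso", "elliptical_cylinder", (0.34, 0.28, 1.80), 1, False),
    ("neck", "truncated_cone", (0.13, 0.10, 1.40), 1, False),
    ("head", "ellipsoid", (0.18, 0.08, 0.08), 1, False),
    ("tail", "truncated_cone", (0.22, 0.04, 2.40), 1, True),
    ("hind_legs", "cylinder", (0.114, 1.10), 2, True),
    ("front_legs", "cylinder", (0.080, 0.80), 2, True),
)

TAXA = {
    "coelophysis": dict(segments=_COELOPHYSIS_SEGMENTS, mass=21.0, height=0.45),
    "plateosaurus": dict(segments=_PLATEOSAURUS_SEGMENTS, mass=850.0, height=1.10),
}

_INSULATED_SEGMENTS = ("head", "neck", "torso", "tail")


def build_animal(taxon: str, insulation: str = "none", mass: float | None = None,
                 fat_fraction: float = 5.0,
                 insulation_spec: InsulationSpec | None = None) -> AnimalSpec:
    """Construct a study animal.

    ``insulation`` is ``"none"``, ``"top"`` (dorsal only on head, neck, torso
    and tail) or ``"full"`` (dorsal + ventral).  ``mass`` defaults to the
    taxon's reference mass (21 kg / 850 kg); other values reuse the same
    skeleton with the diameter mass-scaling rule.
    """
    taxon = taxon.lower()
    if taxon not in TAXA:
        raise GeometryError(f"unknown taxon {taxon!r}; valid: {tuple(TAXA)}")
    if insulation not in ("none", "top", "full"):
        raise GeometryError("insulation must be one of: none, top, full")
    spec = insulation_spec or InsulationSpec()
    cfg = TAXA[taxon]
    target = mass if mass is not None else cfg["mass"]

    segments = []
    for name, shape, dims, count, appendage in cfg["segments"]:
        dorsal = ventral = None
        if insulation != "none" and name in _INSULATED_SEGMENTS:
            dorsal = spec
            if insulation == "full":
                ventral = spec
        segments.append(BodySegment(
            name=name, shape=shape, dimensions=dims, count=count,
            insulation_dorsal=dorsal, insulation_ventral=ventral,
            is_appendage=appendage))

    nominal_mass = sum(segment_properties(s)[2] for s in segments)
    animal = AnimalSpec(taxon=taxon, segments=tuple(segments),
                        total_mass=nominal_mass, mean_height=cfg["height"])
    animal = scale_mass_by_diameter(animal, target)
    if fat_fraction > 0:
        animal = _with_fat(animal, fat_fraction)
    return animal


def _with_fat(animal: AnimalSpec, fat_fraction: float) -> AnimalSpec:
    """Carry ``fat_fraction`` % of body mass as a uniform torso fat shell,
    shrinking torso flesh so total mass is conserved."""
    torso = animal.segment("torso")
    fat_mass = animal.total_mass * fat_fraction / 100.0
    _, t_vol, t_mass, _ = segment_properties(replace(torso, fat_layer_thickness=0.0))
    flesh_target = t_mass - fat_mass
    f = math.sqrt(flesh_target / t_mass)
    new_torso = _scale_segment(torso, f)
    area, _, _, _ = segment_properties(replace(new_torso, fat_layer_thickness=0.0))
    thickness = fat_mass / (area * k.FAT_DENSITY * 1000.0)
    new_torso = replace(new_torso, fat_layer_thickness=thickness)
    segs = tuple(new_torso if s.name == "torso" else s for s in animal.segments)
    total = sum(segment_properties(s)[2] for s in segs)
    return replace(animal, segments=segs, total_mass=total)
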