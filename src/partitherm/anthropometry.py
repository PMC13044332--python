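"""Multi-part body geometry: sizing, assembly, heights, silhouette areas.

The body is modelled as four part classes — an ellipsoidal (prolate spheroid)
head and cylindrical trunk, arms, and legs — each sized from its mass, density
and a shape ratio ``shape_b`` (length:diameter for cylinders, semi-major to
semi-minor axis for the head).  :func:`assemble_body` breaks the body into
parts from proportion tables, works out their shapes, then rescales the shape
ratios and sets joined fractions so the summed exposed skin areas close on the
specified whole-body surface area while the stacked part lengths approximate
the target stature.  Joined (fused) surfaces are removed from all exchange
with the environment and treated as a zero-net-flux boundary at core
temperature.

Silhouette areas — the projection of each shape toward the sun — are computed
geometrically as a function of solar zenith angle, with an optional whole-body
correction factor: geometric projections of assembled primitives typically
overestimate the radiant heat load on a standing human, so the ratio of an
empirical standing-human projected-area function to the geometric value is
fitted as an 8th-order polynomial in zenith angle (coefficients shipped in
``data/silhouette_correction.json``) and applied multiplicatively.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Literal, Sequence

__all__ = [
    "BodyPartSpec",
    "PartGeometry",
    "size_part",
    "assemble_body",
    "part_heights",
    "stature",
    "silhouette_area",
    "body_silhouette_area",
    "silhouette_correction",
    "underwood_ward_projected_area",
    "DEFAULT_PART_SPECS",
    "dubois_area",
    "FAT_DENSITY",
]

ShapeClass = Literal["cylinder", "prolate_spheroid"]

FAT_DENSITY = 900.0  # kg/m^3, adipose tissue


def _positive(name: str, value: float) -> None:
    if not value > 0.0:
        raise ValueError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class BodyPartSpec:
    """Proportions and shape of one body part class.

    ``mass_fraction``/``area_fraction`` are per individual part; ``count``
    (2 for arms and legs) multiplies them when closing whole-body sums.
    """

    part_id: str  # head | trunk | arm | leg
    shape_class: ShapeClass
    mass_fraction: float
    area_fraction: float
    shape_b: float
    density: float = 1050.0  # kg/m^3
    fat_fraction: float = 0.15
    joined_fraction: float = 0.0
    count: int = 1

    def __post_init__(self) -> None:
        _positive("mass_fraction", self.mass_fraction)
        _positive("area_fraction", self.area_fraction)
        _positive("shape_b", self.shape_b)
        _positive("density", self.density)
        if not 0.0 <= self.joined_fraction < 1.0:
            raise ValueError(f"joined_fraction {self.joined_fraction} outside [0, 1)")
        if not 0.0 <= self.fat_fraction < 1.0:
            raise ValueError(f"fat_fraction {self.fat_fraction} outside [0, 1)")


# Stand-in proportion table (editable; supply your own for a specific subject
# population).  Mass fractions per part follow segment-mass conventions, area
# fractions standard regional surface-area tables.
DEFAULT_PART_SPECS: tuple[BodyPartSpec, ...] = (
    BodyPartSpec("head", "prolate_spheroid", 0.07, 0.07, 1.6, density=1070.0, fat_fraction=0.10),
    BodyPartSpec("trunk", "cylinder", 0.50, 0.36, 2.1, density=1050.0, fat_fraction=0.20),
    BodyPartSpec("arm", "cylinder", 0.055, 0.09, 8.0, density=1050.0, fat_fraction=0.12, count=2),
    BodyPartSpec("leg", "cylinder", 0.16, 0.195, 6.5, density=1050.0, fat_fraction=0.15, count=2),
)


def validate_part_specs(specs: Sequence[BodyPartSpec]) -> None:
    m = sum(s.count * s.mass_fraction for s in specs)
    a = sum(s.count * s.area_fraction for s in specs)
    if abs(m - 1.0) > 1e-9:
        raise ValueError(f"count-weighted mass fractions sum to {m}, expected 1")
    if abs(a - 1.0) > 1e-9:
        raise ValueError(f"count-weighted area fractions sum to {a}, expected 1")


def dubois_area(mass: float, height: float) -> float:
    """DuBois & DuBois body surface area, m^2, from mass (kg) and height (m)."""
    return 0.202 * mass**0.425 * height**0.725


@dataclass(frozen=True)
class PartGeometry:
    """Solved absolute geometry of one body part (SI units)."""

    part_id: str
    shape_class: ShapeClass
    shape_b: float
    mass: float  # kg
    density: float  # kg/m^3
    length: float  # m (cylinder length; head: 2a)
    diameter: float  # m (2r; head: 2b equatorial)
    volume: float  # m^3
    area_total: float  # m^2, closed surface
    area_joined: float = 0.0  # m^2 fused to adjacent parts
    fat_mass: float = 0.0  # kg
    fat_thickness: float = 0.0  # m, subcutaneous shell
    config_factor_sky: float = 0.5
    config_factor_ground: float = 0.5
    height_midpoint: float = 0.0  # m above ground, standing
    count: int = 1
    insulation_depth: float = 0.0  # m, mean clothing/hair depth (set by the solver layer)

    def __post_init__(self) -> None:
        if abs(self.config_factor_sky + self.config_factor_ground - 1.0) > 1e-9:
            raise ValueError("configuration factors to sky and ground must sum to 1")

    @property
    def area_skin(self) -> float:
        """Exposed skin area, m^2 (total minus joined)."""
        return self.area_total - self.area_joined

    @property
    def area_evaporative(self) -> float:
        """Area available for cutaneous evaporation (exposed skin)."""
        return self.area_skin

    @property
    def radius_to_skin(self) -> float:
        return self.diameter / 2.0

    @property
    def radius_to_insulation_surface(self) -> float:
        return self.radius_to_skin + self.insulation_depth

    @property
    def characteristic_dimension(self) -> float:
        """Dimension governing the convective boundary layer (diameter)."""
        return self.diameter

    @property
    def radius_flesh(self) -> float:
        """Radius of the lean-tissue region (inside the fat shell)."""
        return self.radius_to_skin - self.fat_thickness

    @property
    def sphere_equivalent_radius(self) -> float:
        """Equal-volume sphere radius (used for spheroid conduction shells)."""
        return (3.0 * self.volume / (4.0 * math.pi)) ** (1.0 / 3.0)

    def silhouette_geometric(self, zenith: float) -> float:
        return silhouette_area(self, zenith)

    def with_(self, **kwargs) -> "PartGeometry":
        return replace(self, **kwargs)


def _cylinder_dims(volume: float, shape_b: float) -> tuple[float, float]:
    # V = pi r^2 L, L = 2 r shape_b  ->  r = (V / (2 pi b))^(1/3)
    r = (volume / (2.0 * math.pi * shape_b)) ** (1.0 / 3.0)
    return r, 2.0 * r * shape_b


def _cylinder_area(r: float, L: float) -> float:
    return 2.0 * math.pi * r * r + 2.0 * math.pi * r * L


def prolate_spheroid_area(a: float, b: float) -> float:
    """Closed-form surface area of a prolate spheroid, semi-axes a >= b."""
    if abs(a - b) < 1e-12 * max(a, b):
        return 4.0 * math.pi * b * b
    e = math.sqrt(1.0 - (b / a) ** 2)
    return 2.0 * math.pi * b * b * (1.0 + (a / (b * e)) * math.asin(e))


def _spheroid_dims(volume: float, shape_b: float) -> tuple[float, float]:
    # V = (4/3) pi a b^2, a = shape_b * b
    b = (3.0 * volume / (4.0 * math.pi * shape_b)) ** (1.0 / 3.0)
    return b, shape_b * b


def size_part(mass: float, density: float, shape_class: ShapeClass, shape_b: float,
              part_id: str = "part", fat_fraction: float = 0.0, count: int = 1) -> PartGeometry:
    """Size one part from mass, density and shape ratio (closed form).

    Cylinders: V = pi r^2 L with L/diameter = shape_b.  Prolate spheroid:
    V = (4/3) pi a b^2 with a/b = shape_b, surface area by the exact
    eccentricity formula.  The subcutaneous fat shell (``fat_fraction`` of
    part mass at adipose density) is carved from just under the skin.
    """
    _positive("mass", mass)
    _positive("density", density)
    _positive("shape_b", shape_b)
    volume = mass / density
    if shape_class == "cylinder":
        r, L = _cylinder_dims(volume, shape_b)
        area = _cylinder_area(r, L)
        length, diameter = L, 2.0 * r
    elif shape_class == "prolate_spheroid":
        if shape_b < 1.0:
            raise ValueError(f"shape_b for a prolate spheroid must be >= 1, got {shape_b}")
        b, a = _spheroid_dims(volume, shape_b)
        area = prolate_spheroid_area(a, b)
        length, diameter = 2.0 * a, 2.0 * b
    else:
        raise ValueError(f"unknown shape_class {shape_class!r}")

    fat_mass = fat_fraction * mass
    fat_volume = fat_mass / FAT_DENSITY
    fat_thickness = _fat_shell_thickness(shape_class, length, diameter, volume, fat_volume)
    return PartGeometry(
        part_id=part_id, shape_class=shape_class, shape_b=shape_b, mass=mass,
        density=density, length=length, diameter=diameter, volume=volume,
        area_total=area, fat_mass=fat_mass, fat_thickness=fat_thickness, count=count,
    )


def _fat_shell_thickness(shape_class: ShapeClass, length: float, diameter: float,
                         volume: float, fat_volume: float) -> float:
    if fat_volume <= 0.0:
        return 0.0
    if shape_class == "cylinder":
        R = diameter / 2.0
        inner_sq = R * R - fat_volume / (math.pi * length)
        if inner_sq <= 0.0:
            raise ValueError("fat volume exceeds part volume; reduce fat_fraction")
        return R - math.sqrt(inner_sq)
    # spheroid: equal-volume sphere shells
    R = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    inner_cubed = R**3 - 3.0 * fat_volume / (4.0 * math.pi)
    if inner_cubed <= 0.0:
        raise ValueError("fat volume exceeds part volume; reduce fat_fraction")
    return R - inner_cubed ** (1.0 / 3.0)


# Default joined fractions: attachment footprints where head, arms and legs
# meet the trunk, as a fraction of each part's own surface.  The trunk's
# joined fraction is derived by bookkeeping (it absorbs the matching area).
_DEFAULT_JOIN = {"head": 0.10, "arm": 0.07, "leg": 0.10, "trunk": 0.0}

_HEIGHT_CHAIN = ("leg", "trunk", "head")  # stacked to form stature


def _sized_parts(total_mass: float, specs: Sequence[BodyPartSpec],
                 scale: float) -> list[PartGeometry]:
    parts = []
    for s in specs:
        b = s.shape_b * scale
        if s.shape_class == "prolate_spheroid":
            b = max(b, 1.0)  # head stays prolate; rescaling saturates at a sphere
        g = size_part(total_mass * s.mass_fraction, s.density, s.shape_class,
                      b, part_id=s.part_id,
                      fat_fraction=s.fat_fraction, count=s.count)
        parts.append(g)
    return parts


def _joined(parts: list[PartGeometry], join: dict[str, float], t: float = 1.0) -> dict[str, float]:
    """Per-part joined fractions (scaled by ``t``) with trunk bookkeeping.

    Each attachment footprint removes equal area from the attaching part and
    from the trunk (the two fused surfaces)."""
    out = {}
    attached = 0.0
    trunk_area = None
    for g in parts:
        if g.part_id == "trunk":
            trunk_area = g.area_total
            continue
        j = join.get(g.part_id, 0.0) * t
        out[g.part_id] = j
        attached += g.count * g.area_total * j
    if trunk_area is not None:
        j_trunk = attached / trunk_area
        if j_trunk >= 1.0:
            raise ValueError("attachment areas exceed trunk surface; adjust joined fractions")
        out["trunk"] = j_trunk
    return out


def _skin_sum(parts: list[PartGeometry], j: dict[str, float]) -> float:
    return sum(p.count * p.area_total * (1.0 - j.get(p.part_id, 0.0)) for p in parts)


def assemble_body(total_mass: float, total_area: float, height_target: float,
                  part_specs: Sequence[BodyPartSpec] | None = None,
                  join_fractions: dict[str, float] | None = None,
                  area_tol: float = 1e-3) -> list[PartGeometry]:
    """Assemble the multi-part body to match whole-body area and stature.

    Part masses follow the proportion table exactly.  A closed-form common
    rescaling of the stacked parts' shape ratios matches the target stature
    (lengths scale as shape_b^(2/3) at fixed volume), then a second common
    shape multiplier is root-found so that the count-weighted exposed skin
    areas (after joining) close on ``total_area`` to 0.1%.  The stature
    residual after the area stage is reported via the returned geometries'
    lengths (see :func:`stature`); area closure is the hard constraint.
    """
    from scipy.optimize import brentq

    specs = list(part_specs) if part_specs is not None else list(DEFAULT_PART_SPECS)
    validate_part_specs(specs)
    _positive("total_mass", total_mass)
    _positive("total_area", total_area)
    _positive("height_target", height_target)
    join = dict(_DEFAULT_JOIN if join_fractions is None else join_fractions)
    if len(specs) == 1:
        join = {specs[0].part_id: 0.0}

    # Stage 1 - stature: stacked lengths scale as s^(2/3) at fixed volume.
    base = _sized_parts(total_mass, specs, 1.0)
    h0 = _stacked_height(base)
    s_height = (height_target / h0) ** 1.5 if h0 > 0 else 1.0
    specs = [replace(s, shape_b=s.shape_b * s_height) for s in specs]

    # Stage 2 - area closure.  Primary knob: scale the joined fractions
    # (preserves the stature hit in stage 1 exactly).  Fallback when joining
    # alone cannot close: a common multiplier g on all shape ratios (its
    # stature effect is the reported residual).
    _JOIN_CAP = 6.0  # at most 6x the default footprints; keeps every j < ~0.6

    def closure_at(g: float) -> tuple[list[PartGeometry], dict[str, float], float]:
        parts = _sized_parts(total_mass, specs, g)
        raw = sum(p.count * p.area_total for p in parts)
        half_denom = sum(p.count * p.area_total * join.get(p.part_id, 0.0)
                         for p in parts if p.part_id != "trunk")
        trunk_area = next((p.area_total for p in parts if p.part_id == "trunk"), None)
        if half_denom > 0.0:
            t = (raw - total_area) / (2.0 * half_denom)
            t_cap = _JOIN_CAP
            if trunk_area is not None:
                t_cap = min(t_cap, 0.9 * trunk_area / half_denom)
            t = min(max(t, 0.0), t_cap)
        else:
            t = 0.0
        j = _joined(parts, join, t)
        return parts, j, _skin_sum(parts, j) - total_area

    parts, j, resid = closure_at(1.0)
    if abs(resid) > area_tol * total_area:
        # Joining saturated (or none possible): rescale shapes.  Skin area
        # grows with elongation at fixed volume for shape ratios above ~1.
        def f(g: float) -> float:
            return closure_at(g)[2]

        # scan a geometric grid for a sign change, skipping shape scalings
        # that are geometrically infeasible (e.g. fat shell thicker than the
        # part radius at extreme elongations)
        grid = [0.1, 0.2, 0.35, 0.5, 0.7, 1.0, 1.5, 2.0, 3.0, 5.0, 8.0, 15.0, 30.0]
        samples = []
        for g in grid:
            try:
                samples.append((g, f(g)))
            except ValueError:
                continue
        tol_abs = 0.5 * area_tol * total_area
        bracket = next(
            ((g0, g1) for (g0, f0), (g1, f1) in zip(samples, samples[1:])
             if f0 * f1 < 0.0 and abs(f0) > tol_abs and abs(f1) > tol_abs), None)
        if bracket is not None:
            g = brentq(f, *bracket, xtol=1e-12, rtol=1e-14)
        else:
            # the join-scaling clamp makes f plateau at exactly zero once
            # joining can absorb the excess; walk to the edge of the plateau
            # (smallest shape distortion that closes the area)
            zero_idx = [i for i, (_, fv) in enumerate(samples) if abs(fv) <= tol_abs]
            if not zero_idx:
                raise ValueError(
                    "no positive shape rescaling or joining closes the surface "
                    f"area (residual {resid:.4f} m^2 at unit scale) — the "
                    "mass/area/proportion combination is infeasible"
                )
            i0 = zero_idx[0]
            g = samples[i0][0]
            if i0 > 0:
                lo = samples[i0 - 1][0]
                for _ in range(60):
                    mid = 0.5 * (lo + g)
                    if abs(f(mid)) <= tol_abs:
                        g = mid
                    else:
                        lo = mid
                    if g - lo < 1e-10:
                        break
        parts, j, resid = closure_at(g)

    parts = [p.with_(area_joined=p.area_total * j.get(p.part_id, 0.0)) for p in parts]
    closure_err = abs(sum(p.count * p.area_skin for p in parts) - total_area) / total_area
    if closure_err > area_tol:  # pragma: no cover - brentq guarantees closure
        raise ValueError(f"area closure failed: relative error {closure_err:.2e}")
    return _with_heights(parts)


def _stacked_height(parts: Sequence[PartGeometry]) -> float:
    by_id = {p.part_id: p for p in parts}
    return sum(by_id[pid].length for pid in _HEIGHT_CHAIN if pid in by_id)


def _with_heights(parts: list[PartGeometry]) -> list[PartGeometry]:
    heights = part_heights(parts)
    return [p.with_(height_midpoint=heights[p.part_id]) for p in parts]


def part_heights(parts: Sequence[PartGeometry]) -> dict[str, float]:
    """Height above ground of each part's midpoint, standing posture.

    Legs stand on the ground, the trunk stacks on the legs, the head on the
    trunk; arms hang from the shoulder line (top of the trunk).
    """
    by_id = {p.part_id: p for p in parts}
    leg_len = by_id["leg"].length if "leg" in by_id else 0.0
    trunk_len = by_id["trunk"].length if "trunk" in by_id else 0.0
    out: dict[str, float] = {}
    for p in parts:
        if p.part_id == "leg":
            out[p.part_id] = leg_len / 2.0
        elif p.part_id == "trunk":
            out[p.part_id] = leg_len + trunk_len / 2.0
        elif p.part_id == "head":
            out[p.part_id] = leg_len + trunk_len + p.length / 2.0
        elif p.part_id == "arm":
            out[p.part_id] = max(leg_len + trunk_len - p.length / 2.0, p.length / 2.0)
        else:
            out[p.part_id] = p.length / 2.0
    return out


def stature(parts: Sequence[PartGeometry]) -> float:
    """Achieved stacked stature (legs + trunk + head lengths), m."""
    return _stacked_height(parts)


def silhouette_area(geometry: PartGeometry, zenith: float) -> float:
    """Geometric silhouette of one part at a solar zenith angle (degrees).

    Vertical cylinder: end disc plus side rectangle projection,
    ``pi r^2 cos(z) + 2 r L sin(z)``.  Vertical prolate spheroid:
    ``pi b sqrt(a^2 sin^2 z + b^2 cos^2 z)``.
    """
    if not 0.0 <= zenith <= 90.0:
        raise ValueError(f"zenith {zenith} deg outside [0, 90]")
    z = math.radians(zenith)
    if geometry.shape_class == "cylinder":
        r = geometry.diameter / 2.0
        return math.pi * r * r * math.cos(z) + 2.0 * r * geometry.length * math.sin(z)
    b = geometry.diameter / 2.0
    a = geometry.length / 2.0
    return math.pi * b * math.sqrt(a * a * math.sin(z) ** 2 + b * b * math.cos(z) ** 2)


def underwood_ward_projected_area(zenith: float, n_azimuth: int = 91) -> float:
    """Empirical projected area of a standing human, m^2, azimuth-averaged.

    ``A_p = 0.043 sin(alt) + 2.997 cos(alt) sqrt(0.02133 + 0.0091 sin^2(az))``
    with altitude = 90 - zenith, averaged over azimuth 0-90 deg (the function
    has quarter-turn symmetry).  Values are for a reference adult of about
    1.8 m^2 surface area; callers rescale by body area.
    """
    alt = math.radians(90.0 - zenith)
    total = 0.0
    for i in range(n_azimuth):
        az = math.radians(90.0 * i / (n_azimuth - 1))
        total += math.sqrt(0.02133 + 0.0091 * math.sin(az) ** 2)
    mean_az = total / n_azimuth
    return 0.043 * math.sin(alt) + 2.997 * math.cos(alt) * mean_az


_UW_REFERENCE_AREA = 1.8  # m^2, surface area scale of the empirical function

_correction_cache: list[float] | None = None


def _load_correction_coeffs() -> list[float]:
    global _correction_cache
    if _correction_cache is None:
        with resources.files("partitherm.data").joinpath("silhouette_correction.json").open() as fh:
            payload = json.load(fh)
        _correction_cache = payload["coefficients"]
    return _correction_cache


def silhouette_correction(zenith: float) -> float:
    """Whole-body silhouette correction ratio, clamped to (0, 1.5].

    8th-order polynomial in normalised zenith (z/90), least-squares fitted at
    build time to the ratio of the empirical standing-human projection to the
    geometric whole-body silhouette of the default body over 0-90 deg.
    """
    if not 0.0 <= zenith <= 90.0:
        raise ValueError(f"zenith {zenith} deg outside [0, 90]")
    coeffs = _load_correction_coeffs()
    x = zenith / 90.0
    val = 0.0
    for c in coeffs:  # Horner, highest degree first
        val = val * x + c
    return min(max(val, 1e-6), 1.5)


def body_silhouette_area(parts: Sequence[PartGeometry], zenith: float,
                         corrected: bool = True) -> float:
    """Whole-body silhouette, m^2: count-weighted geometric sum, optionally
    multiplied by the empirical correction ratio."""
    geom = sum(p.count * silhouette_area(p, zenith) for p in parts)
    if corrected:
        geom *= silhouette_correction(zenith)
    return geom
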