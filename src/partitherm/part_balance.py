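"""Single-part steady-state heat budget.

For one body part with a prescribed core temperature, flesh conductivity and
skin wetness, :func:`solve_part` finds the skin temperature, the dorsal and
ventral insulation-surface temperatures, and the metabolic heat generation
that make three things simultaneously consistent:

(i)   radial conduction of metabolic heat through the lean tissue (with
      distributed generation) and the subcutaneous fat shell to the skin;
(ii)  conduction from the skin through each side's insulation layer
      (clothing/hair) to its outer surface; and
(iii) exchange at the exposed surfaces: mixed free/forced convection,
      full Stefan-Boltzmann longwave radiation (dorsal side to the sky,
      ventral side to the ground, split by configuration factors), absorbed
      solar at the exposed surface, and cutaneous evaporation taking its
      latent heat at the skin.

The solver is a nested, bracketed, deterministic scalar root-find: outer on
skin temperature, inner (per clothed side) on the insulation surface
temperature.  Joined surfaces are a zero-net-flux boundary at core
temperature: they are removed from every exchange pathway, which is
represented by confining conduction to the exposed sector of each shell.

Temperatures are deg C at the interface, K internally for radiation; all
fluxes W (whole part, not per area).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from scipy.optimize import brentq

from .anthropometry import PartGeometry, silhouette_correction
from .environment import (
    Environment,
    air_properties,
    latent_heat_vaporisation,
    saturation_vapour_pressure,
    vapour_density,
)

__all__ = [
    "InsulationLayer",
    "PartState",
    "PartSolution",
    "solve_part",
    "convective_coefficient",
    "evaporative_flux",
    "temperature_profile",
    "conduction_resistance",
    "K_FAT",
]

SIGMA = 5.670374419e-8  # W m^-2 K^-4
K_FAT = 0.16  # W m^-1 K^-1, adipose tissue


@dataclass(frozen=True)
class InsulationLayer:
    """One side's clothing/hair layer: direct-conductivity description."""

    depth: float = 0.0  # m
    conductivity: float = 0.042  # W m^-1 K^-1 (typical clothing batting)
    solar_reflectance: float = 0.3
    emissivity: float = 0.98

    def __post_init__(self) -> None:
        if self.depth < 0.0:
            raise ValueError(f"insulation depth must be >= 0, got {self.depth}")
        if self.depth > 0.0 and self.conductivity <= 0.0:
            raise ValueError("insulation conductivity must be positive")


@dataclass(frozen=True)
class PartState:
    """Physiological and covering state of one part for a single solve."""

    T_core_target: float = 36.5  # degC
    k_flesh: float = 0.412  # W m^-1 K^-1 (vasoconstricted lean tissue)
    pct_wet: float = 0.01  # skin wetness fraction w, 0-1
    fat_factor: float = 1.0  # 0-1 multiplier on the fat shell (vasodilation ramp)
    dorsal: InsulationLayer = field(default_factory=InsulationLayer)
    ventral: InsulationLayer = field(default_factory=InsulationLayer)
    pct_bare_evap: float = 0.3  # fraction of covered-skin evaporation transmitted
    k_fat: float = K_FAT

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_wet <= 1.0:
            raise ValueError(f"pct_wet {self.pct_wet} outside [0, 1]")
        if not 0.0 <= self.fat_factor <= 1.0:
            raise ValueError(f"fat_factor {self.fat_factor} outside [0, 1]")
        if self.k_flesh <= 0.0:
            raise ValueError("k_flesh must be positive")

    @property
    def nude(self) -> bool:
        return self.dorsal.depth == 0.0 and self.ventral.depth == 0.0

    def with_(self, **kwargs) -> "PartState":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PartSolution:
    """Converged (or flagged) steady state of one part."""

    part_id: str
    Q_gen: float  # W, metabolic heat generated in the part
    T_skin: float  # degC
    T_ins_dorsal: float  # degC (equals T_skin when bare)
    T_ins_ventral: float  # degC
    Q_sol: float  # W absorbed shortwave
    Q_rad: float  # W net longwave loss
    Q_conv: float  # W convective loss
    Q_cond: float  # W conduction to substrate (always 0: standing, no contact)
    Q_evap_cut: float  # W cutaneous evaporation
    Q_evap_ins: float  # W evaporation from the insulation surface
    residual: float  # W, energy-balance closure
    iterations: int
    converged: bool
    T_core: float  # degC, prescribed core
    T_fat_boundary: float  # degC at the lean/fat interface

    @property
    def Q_ins(self) -> float:
        """Heat through the insulation: Qrad + Qconv + Qcond + Qevap,ins - Qsol."""
        return self.Q_rad + self.Q_conv + self.Q_cond + self.Q_evap_ins - self.Q_sol


def conduction_resistance(shape: str, r_in: float, r_out: float, k: float,
                          length: float = 1.0) -> float:
    """Steady conduction resistance of a shell, K/W.

    Cylindrical shell: ln(r_out/r_in) / (2 pi L k).  Spherical shell:
    (1/r_in - 1/r_out) / (4 pi k).
    """
    if r_out < r_in or r_in <= 0.0 or k <= 0.0:
        raise ValueError("need r_out >= r_in > 0 and k > 0")
    if r_out == r_in:
        return 0.0
    if shape == "cylinder":
        return math.log(r_out / r_in) / (2.0 * math.pi * length * k)
    if shape == "sphere":
        return (1.0 / r_in - 1.0 / r_out) / (4.0 * math.pi * k)
    raise ValueError(f"unknown shell shape {shape!r}")


def _generation_resistance(geometry: PartGeometry, k_flesh: float, r_flesh: float) -> float:
    """Core-to-flesh-boundary resistance with uniform volumetric generation.

    Cylinder: dT = Q / (4 pi k L); sphere (head, equal-volume shells):
    dT = Q / (8 pi k r).
    """
    if geometry.shape_class == "cylinder":
        return 1.0 / (4.0 * math.pi * k_flesh * geometry.length)
    return 1.0 / (8.0 * math.pi * k_flesh * r_flesh)


def _core_to_skin_resistance(geometry: PartGeometry, state: PartState) -> float:
    """Series resistance from the core (tissue center) to the skin surface,
    confined to the exposed sector of the shells."""
    fat_t = geometry.fat_thickness * state.fat_factor
    f_exposed = geometry.area_skin / geometry.area_total
    if geometry.shape_class == "cylinder":
        r_skin = geometry.radius_to_skin
        shape = "cylinder"
        length = geometry.length
    else:
        r_skin = geometry.sphere_equivalent_radius
        shape = "sphere"
        length = 1.0
    r_flesh = max(r_skin - fat_t, 1e-6)
    R = _generation_resistance(geometry, state.k_flesh, r_flesh)
    if fat_t > 0.0:
        R += conduction_resistance(shape, r_flesh, r_skin, state.k_fat, length)
    return R / f_exposed


def _insulation_resistance(geometry: PartGeometry, layer: InsulationLayer,
                           side_fraction: float) -> float:
    """Skin-to-insulation-surface resistance for one side, K/W."""
    if layer.depth <= 0.0:
        return 0.0
    f_exposed = geometry.area_skin / geometry.area_total
    if geometry.shape_class == "cylinder":
        r_skin = geometry.radius_to_skin
        R = conduction_resistance("cylinder", r_skin, r_skin + layer.depth,
                                  layer.conductivity, geometry.length)
    else:
        r_skin = geometry.sphere_equivalent_radius
        R = conduction_resistance("sphere", r_skin, r_skin + layer.depth,
                                  layer.conductivity)
    return R / (f_exposed * side_fraction)


def convective_coefficient(geometry: PartGeometry, env: Environment,
                           T_surface: float | None = None) -> float:
    """Mixed free/forced convective coefficient h, W m^-2 K^-1.

    Forced: Churchill-Bernstein (cylinder in crossflow) or Whitaker (sphere,
    for the head).  Free: Churchill-Chu (horizontal cylinder) or Churchill
    (sphere), driven by the surface-air temperature difference.  Combined as
    Nu = (Nu_free^3 + Nu_forced^3)^(1/3); h = Nu k_air / D.
    """
    if T_surface is None:
        T_surface = env.TA
    T_film = 0.5 * (T_surface + env.TA)
    props = air_properties(min(max(T_film, -40.0), 100.0), env.pressure)
    D = geometry.characteristic_dimension
    nu, pr, k = props.kinematic_viscosity, props.prandtl, props.conductivity
    re = env.VEL * D / nu
    dT = abs(T_surface - env.TA)
    gr = 9.80665 * dT * D**3 / ((T_film + 273.15) * nu * nu)
    ra = gr * pr
    sphere = geometry.shape_class == "prolate_spheroid"
    if sphere:
        nu_forced = 2.0 + (0.4 * math.sqrt(re) + 0.06 * re ** (2.0 / 3.0)) * pr**0.4
        nu_free = 2.0 + 0.589 * ra**0.25 / (1.0 + (0.469 / pr) ** (9.0 / 16.0)) ** (4.0 / 9.0)
    else:
        if re > 0.0:
            nu_forced = 0.3 + (0.62 * math.sqrt(re) * pr ** (1.0 / 3.0)
                               / (1.0 + (0.4 / pr) ** (2.0 / 3.0)) ** 0.25
                               * (1.0 + (re / 282000.0) ** 0.625) ** 0.8)
        else:
            nu_forced = 0.0
        nu_free = (0.60 + 0.387 * ra ** (1.0 / 6.0)
                   / (1.0 + (0.559 / pr) ** (9.0 / 16.0)) ** (8.0 / 27.0)) ** 2
    nu_mixed = (nu_free**3 + nu_forced**3) ** (1.0 / 3.0)
    return nu_mixed * k / D


def evaporative_flux(T_surface: float, w: float, area: float, h: float,
                     env: Environment) -> float:
    """Evaporative heat flux from a partially wet surface, W.

    Mass-transfer coefficient from the heat-transfer analogy (Lewis
    relation, Chilton-Colburn): h_m = h / (rho cp Le^(2/3)); flux =
    lambda h_m w A drho_v, with the vapour-density difference formed from
    the vapour-pressure difference at the film temperature — equivalent to
    a mole-fraction driving force, and consistent with the thermodynamic
    wet bulb (a fully wet surface equilibrates near the ambient wet-bulb
    temperature).
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"wetness {w} outside [0, 1]")
    if w == 0.0 or area == 0.0:
        return 0.0
    T_film = 0.5 * (T_surface + env.TA)
    T_film = min(max(T_film, -40.0), 100.0)
    props = air_properties(T_film, env.pressure)
    lewis = props.thermal_diffusivity / props.diffusivity_water
    h_m = h / (props.density * props.cp * lewis ** (2.0 / 3.0))
    de = saturation_vapour_pressure(min(max(T_surface, -40.0), 105.0)) \
        - env.vapour_pressure_air
    drho = vapour_density(de, T_film)
    return latent_heat_vaporisation(T_surface) * h_m * w * area * drho


def _outer_area_factor(geometry: PartGeometry, depth: float) -> float:
    """Area magnification from skin to the insulation outer surface."""
    if depth <= 0.0:
        return 1.0
    if geometry.shape_class == "cylinder":
        return (geometry.radius_to_skin + depth) / geometry.radius_to_skin
    r = geometry.sphere_equivalent_radius
    return ((r + depth) / r) ** 2


def _solar_load(geometry: PartGeometry, layer: InsulationLayer, env: Environment,
                dorsal: bool, area_side: float) -> float:
    """Shortwave absorbed at one side's exposed surface, W."""
    alpha = 1.0 - layer.solar_reflectance
    if dorsal:
        beam = env.solar_direct * geometry.silhouette_geometric(env.zenith) \
            * silhouette_correction(env.zenith)
        diffuse = env.solar_diffuse * area_side
        return alpha * (beam + diffuse)
    global_horizontal = env.solar_direct * math.cos(math.radians(env.zenith)) + env.solar_diffuse
    return alpha * env.ground_reflectance * global_horizontal * area_side


def _side_external_flux(T_s: float, geometry: PartGeometry, layer: InsulationLayer,
                        env: Environment, T_radiant: float, area_side: float,
                        q_sol: float, h_override: float | None) -> tuple[float, float, float]:
    """(net flux leaving the side surface, Q_conv, Q_rad) at surface temp T_s."""
    h = h_override if h_override is not None else convective_coefficient(geometry, env, T_s)
    q_conv = h * area_side * (T_s - env.TA)
    TK, TRK = T_s + 273.15, T_radiant + 273.15
    q_rad = layer.emissivity * SIGMA * area_side * (TK**4 - TRK**4)
    return q_conv + q_rad - q_sol, q_conv, q_rad


_DEFAULT_BRACKET_PAD = (10.0, 15.0)


def solve_part(geometry: PartGeometry, state: PartState, env: Environment,
               h_override: float | None = None, tol: float = 1e-7,
               t_skin_override: float | None = None) -> PartSolution:
    """Solve one part's steady-state balance.

    ``h_override`` injects a fixed convective coefficient (bypassing the
    correlations); ``t_skin_override`` bypasses the outer root-find and
    evaluates the budget at a prescribed skin temperature (the returned
    ``Q_gen`` is then the conduction-implied generation and the residual
    reports the imbalance).  Both exist for verification against closed-form
    references.
    """
    T_core = state.T_core_target
    R_core = _core_to_skin_resistance(geometry, state)
    f_sky = geometry.config_factor_sky
    f_ground = geometry.config_factor_ground
    area_skin = geometry.area_skin

    sides = []
    for layer, dorsal, f_side, T_rad in (
        (state.dorsal, True, f_sky, env.t_sky),
        (state.ventral, False, f_ground, env.t_ground),
    ):
        if f_side <= 0.0:
            continue
        area_side = area_skin * f_side * _outer_area_factor(geometry, layer.depth)
        q_sol = _solar_load(geometry, layer, env, dorsal, area_side)
        R_ins = _insulation_resistance(geometry, layer, f_side)
        sides.append((layer, dorsal, f_side, T_rad, area_side, q_sol, R_ins))

    t_lo = min(env.TA, env.t_sky, env.t_ground, T_core) - _DEFAULT_BRACKET_PAD[0]
    t_hi = max(env.TA, env.t_sky, env.t_ground, T_core) + _DEFAULT_BRACKET_PAD[1]
    evals = [0]

    def side_solution(T_skin: float, layer, dorsal, f_side, T_rad, area_side, q_sol, R_ins):
        """Surface temperature and fluxes of one side at a given skin temp."""
        if R_ins == 0.0:
            flux, q_conv, q_rad = _side_external_flux(
                T_skin, geometry, layer, env, T_rad, area_side, q_sol, h_override)
            return T_skin, flux, q_conv, q_rad

        def g(T_s: float) -> float:
            ext, _, _ = _side_external_flux(T_s, geometry, layer, env, T_rad,
                                            area_side, q_sol, h_override)
            return (T_skin - T_s) / R_ins - ext

        lo, hi = t_lo - 30.0, max(t_hi, T_skin) + 60.0
        T_s = brentq(g, lo, hi, xtol=1e-8)
        ext, q_conv, q_rad = _side_external_flux(T_s, geometry, layer, env, T_rad,
                                                 area_side, q_sol, h_override)
        return T_s, ext, q_conv, q_rad

    def budget(T_skin: float):
        evals[0] += 1
        q_core = (T_core - T_skin) / R_core
        h_skin = h_override if h_override is not None else \
            convective_coefficient(geometry, env, T_skin)
        q_evap = 0.0
        side_out = []
        total_ext = 0.0
        for layer, dorsal, f_side, T_rad, area_side, q_sol, R_ins in sides:
            T_s, ext, q_conv, q_rad = side_solution(
                T_skin, layer, dorsal, f_side, T_rad, area_side, q_sol, R_ins)
            eta = 1.0 if layer.depth == 0.0 else state.pct_bare_evap
            q_evap += evaporative_flux(T_skin, state.pct_wet,
                                       area_skin * f_side * eta, h_skin, env)
            side_out.append((dorsal, T_s, q_conv, q_rad, q_sol))
            total_ext += ext
        residual = q_core - (q_evap + total_ext)
        return residual, q_core, q_evap, side_out

    if t_skin_override is not None:
        T_skin = t_skin_override
    else:
        f = lambda t: budget(t)[0]
        f_lo, f_hi = f(t_lo), f(t_hi)
        expand = 0
        while f_lo * f_hi > 0.0 and expand < 3:
            # strong solar loads can push the skin equilibrium past the
            # nominal bracket; widen it (within the property formulations'
            # validity) before giving up
            t_lo = max(t_lo - 20.0, -39.0)
            t_hi = min(t_hi + 30.0, 100.0)
            f_lo, f_hi = f(t_lo), f(t_hi)
            expand += 1
        if f_lo * f_hi > 0.0:
            raise RuntimeError(
                f"part {geometry.part_id}: no steady skin temperature in "
                f"[{t_lo:.1f}, {t_hi:.1f}] degC (residuals {f_lo:.2f}, {f_hi:.2f} W); "
                "environment outside solver bounds"
            )
        T_skin = brentq(f, t_lo, t_hi, xtol=1e-6, rtol=1e-14)

    residual, q_core, q_evap, side_out = budget(T_skin)
    q_conv = sum(s[2] for s in side_out)
    q_rad = sum(s[3] for s in side_out)
    q_sol = sum(s[4] for s in side_out)
    T_d = next((s[1] for s in side_out if s[0]), T_skin)
    T_v = next((s[1] for s in side_out if not s[0]), T_skin)
    q_gen = q_core
    fat_t = geometry.fat_thickness * state.fat_factor
    if geometry.shape_class == "cylinder":
        r_skin = geometry.radius_to_skin
    else:
        r_skin = geometry.sphere_equivalent_radius
    r_flesh = max(r_skin - fat_t, 1e-6)
    f_exposed = area_skin / geometry.area_total
    R_gen = _generation_resistance(geometry, state.k_flesh, r_flesh) / f_exposed
    T_fat_boundary = T_core - q_gen * R_gen
    converged = t_skin_override is None and abs(residual) <= max(tol, 1e-4)
    return PartSolution(
        part_id=geometry.part_id, Q_gen=q_gen, T_skin=T_skin,
        T_ins_dorsal=T_d, T_ins_ventral=T_v, Q_sol=q_sol, Q_rad=q_rad,
        Q_conv=q_conv, Q_cond=0.0, Q_evap_cut=q_evap, Q_evap_ins=0.0,
        residual=residual, iterations=evals[0], converged=converged,
        T_core=T_core, T_fat_boundary=T_fat_boundary,
    )


def temperature_profile(geometry: PartGeometry, state: PartState,
                        solution: PartSolution) -> list[tuple[str, float]]:
    """Ordered radial temperature nodes: core, lean/fat boundary, skin,
    insulation surface (dorsal/ventral area-weighted mean).

    Requires a converged solution; each step satisfies its layer's Fourier
    law with the solved fluxes.
    """
    if not solution.converged:
        raise ValueError("temperature_profile requires a converged part solution")
    t_ins = (geometry.config_factor_sky * solution.T_ins_dorsal
             + geometry.config_factor_ground * solution.T_ins_ventral)
    return [
        ("core", solution.T_core),
        ("fat_boundary", solution.T_fat_boundary),
        ("skin", solution.T_skin),
        ("insulation_surface", t_ins),
    ]
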