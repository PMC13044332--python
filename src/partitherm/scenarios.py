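"""Scenario analyses built on the whole-body solver.

* :func:`thermoneutral_zone` — sweep air temperature at fixed wind/humidity
  and locate the lower critical temperature (LCT: metabolic elevation above
  the minimum) and the upper critical temperature (UCT: skin wetness
  exceeding 2%, the conventional sweating-onset marker).

* :func:`hhb_steady_core` — a minimal single-node fixed-skin heat-balance
  reference model: skin temperature is an input (not solved), there is no
  Q10 effect, and the inferred steady core temperature follows from the
  uncompensable surplus.  It represents the class of simple human
  heat-balance models whose survivability limit collapses onto the 35 degC
  wet-bulb isopleth when sweating is non-limiting.

* :func:`survivability_grid` — air-temperature x relative-humidity grids of
  steady-state core temperature for either model, with a survivability
  frontier (lowest non-survivable RH per TA), the wet-bulb temperature along
  it, and the limiting mechanism (environmental evaporative capacity versus
  sweat production capacity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import Environment, air_properties, latent_heat_vaporisation, \
    saturation_vapour_pressure, vapour_density, wet_bulb
from .part_balance import convective_coefficient
from .thermoregulation import BodySolution, HumanSpec, SolveOptions, solve_human

__all__ = [
    "TNZResult",
    "SurvivalGrid",
    "thermoneutral_zone",
    "hhb_steady_core",
    "survivability_grid",
    "feed_skin_temperature",
    "HHBParams",
]

LETHAL_CORE = 43.0  # degC
SKIN_EXCLUDE = 40.0  # degC: full-model cells with hotter skin are excluded


@dataclass(frozen=True)
class TNZResult:
    """Thermoneutral-zone bounds and the per-TA sweep behind them."""

    LCT: float | None  # degC air; None when not bracketed by the sweep
    UCT: float | None  # degC air
    table: pd.DataFrame  # per-TA: Q_gen_net, Q_min_eff, T_core, T_skin, wetness, status

    @property
    def found(self) -> bool:
        return self.LCT is not None and self.UCT is not None


def thermoneutral_zone(human: HumanSpec, VEL: float = 0.1, RH: float = 50.0,
                       TA_range: tuple[float, float] = (0.0, 55.0),
                       TA_step: float = 1.0,
                       wetness_threshold: float = 0.02) -> TNZResult:
    """Locate the TNZ by sweeping air temperature.

    LCT: highest TA at which Q_gen_net exceeds the (Q10-adjusted) minimum
    metabolic rate beyond tolerance, linearly interpolated to the crossing.
    UCT: lowest TA at which aggregate skin wetness exceeds the threshold
    (default 2%), linearly interpolated.
    """
    tas = np.arange(TA_range[0], TA_range[1] + 0.5 * TA_step, TA_step)
    rows = []
    for ta in tas:
        sol = solve_human(human, Environment(TA=float(ta), VEL=VEL, RH=RH))
        rows.append({
            "TA": float(ta), "Q_gen_net": sol.Q_gen_net,
            "Q_min_eff": sol.Q_min_effective, "T_core": sol.T_core_trunk,
            "T_skin": sol.T_skin, "wetness": sol.pct_wet, "status": sol.status,
        })
    df = pd.DataFrame(rows)
    band = 0.5  # W, matches the solver's balance band

    excess = df["Q_gen_net"].to_numpy() - df["Q_min_eff"].to_numpy()
    lct = None
    status = df["status"].to_numpy()
    cold_block = 0
    while cold_block < len(df) and status[cold_block] == "cold_compensating":
        cold_block += 1
    if 0 < cold_block < len(df):
        i = cold_block - 1  # last cold cell before the zone
        x0, x1 = excess[i], max(excess[i + 1], 0.0)
        frac = (x0 - band) / (x0 - x1) if x0 != x1 else 0.0
        lct = float(df["TA"][i] + frac * (df["TA"][i + 1] - df["TA"][i]))

    uct = None
    wet = df["wetness"].to_numpy()
    hot = np.where(wet > wetness_threshold)[0]
    if hot.size and hot[0] > 0:
        i = hot[0]
        w0, w1 = wet[i - 1], wet[i]
        frac = (wetness_threshold - w0) / (w1 - w0) if w1 != w0 else 1.0
        uct = float(df["TA"][i - 1] + frac * (df["TA"][i] - df["TA"][i - 1]))

    return TNZResult(LCT=lct, UCT=uct, table=df)


@dataclass(frozen=True)
class HHBParams:
    """Parameters of the minimal fixed-skin heat-balance model.

    The model has one tissue node: the core-to-skin gradient is the normal
    resting 2 degC, inflated by any uncompensable heat surplus divided by
    the tissue conductance.  Skin temperature never responds to the
    environment — the defining simplification.
    """

    T_skin: float = 35.0  # degC, fixed
    lethal_core: float = LETHAL_CORE
    conductance: float = 10.0  # W/K applied to the uncompensable surplus
    normal_gradient: float = 2.0  # degC core-skin at rest
    M_net: float = 87.0  # W net metabolic heat
    area: float = 1.844  # m^2 (matches the default body)
    radiant_offset_W: float = 0.0  # additive radiant load; 0 when MRT = TA
    sweat_capacity_W: float | None = None  # None: sweating non-limiting


def _hhb_fluxes(env: Environment, p: HHBParams, human: HumanSpec | None = None,
                geoms=None) -> tuple[float, float]:
    """(dry loss, E_max) from the fixed skin, W (positive = loss).

    Dry exchange is convective, with any radiant load entering as an
    additive offset — the minimal model does not resolve longwave exchange
    (that is the defining 'radiant offset' simplification of its class)."""
    if geoms is None:
        geoms = (human or HumanSpec.nude()).geometry()
    h = 0.0
    area = 0.0
    for g in geoms:
        hg = convective_coefficient(g, env, p.T_skin)
        h += hg * g.count * g.area_skin
        area += g.count * g.area_skin
    h /= area  # area-weighted mean film coefficient over the real geometry
    area = p.area
    dry = h * area * (p.T_skin - env.TA) - p.radiant_offset_W
    t_film = 0.5 * (p.T_skin + env.TA)
    props = air_properties(t_film, env.pressure)
    lewis = props.thermal_diffusivity / props.diffusivity_water
    h_m = h / (props.density * props.cp * lewis ** (2.0 / 3.0))
    de = saturation_vapour_pressure(p.T_skin) - env.vapour_pressure_air
    e_max = latent_heat_vaporisation(p.T_skin) * h_m * area * vapour_density(de, t_film)
    return dry, max(e_max, 0.0)


def hhb_steady_core(env: Environment, params: HHBParams | None = None,
                    human: HumanSpec | None = None, geoms=None) -> dict[str, float]:
    """Steady core temperature inferred by the fixed-skin model.

    Required evaporation E_req = M_net - dry loss.  The achievable
    evaporation is capped by the environmental maximum from fully wet skin
    (and optionally by sweat capacity).  When the requirement is met, the
    core sits the normal gradient above the skin; any uncompensable surplus
    adds surplus/conductance on top.  A cell is non-survivable when the
    inferred core reaches the lethal threshold.
    """
    p = params or HHBParams()
    if p.conductance <= 0.0:
        raise ValueError("tissue conductance must be positive")
    dry, e_max = _hhb_fluxes(env, p, human, geoms)
    e_req = p.M_net - dry
    e_cap = e_max if p.sweat_capacity_W is None else min(e_max, p.sweat_capacity_W)
    e_used = min(max(e_req, 0.0), e_cap)
    surplus = max(p.M_net - dry - e_used, 0.0)
    core = p.T_skin + p.normal_gradient + surplus / p.conductance
    return {
        "T_core": core, "dry_loss": dry, "E_req": e_req, "E_max": e_max,
        "E_used": e_used, "surplus": surplus,
        "survivable": core < p.lethal_core,
        "sweat_limited": (p.sweat_capacity_W is not None
                          and e_req > 0.0 and e_cap < min(e_req, e_max)),
    }


def feed_skin_temperature(body: BodySolution, params: HHBParams | None = None) -> HHBParams:
    """Use the full model's solved aggregate skin temperature as the fixed
    skin input of the minimal model (cell-wise coupling)."""
    if not body.converged and body.status != "storage_implied":
        raise ValueError("feed_skin_temperature requires a solved body state")
    p = params or HHBParams()
    from dataclasses import replace
    return replace(p, T_skin=body.T_skin)


@dataclass(frozen=True)
class SurvivalGrid:
    """TA x RH survivability grid and its frontier."""

    model: str  # "homotherm-like full cascade" -> "full" | "hhb"
    TA: np.ndarray  # grid axis, degC
    RH: np.ndarray  # grid axis, %
    T_core: np.ndarray  # (nTA, nRH) steady core, NaN where unsolved/excluded
    T_skin: np.ndarray  # (nTA, nRH)
    survivable: np.ndarray  # bool (nTA, nRH)
    excluded: np.ndarray  # bool (nTA, nRH), skin above the exclusion limit
    frontier: pd.DataFrame  # per TA: RH*, wet_bulb, mechanism

    def frontier_wet_bulbs(self) -> np.ndarray:
        return self.frontier["wet_bulb"].to_numpy()


def _frontier_row(ta: float, rh: float, mechanism: str, pressure: float) -> dict:
    return {"TA": ta, "RH": rh, "wet_bulb": wet_bulb(ta, rh, pressure),
            "mechanism": mechanism}


def _hhb_cell(ta: float, rh: float, env_proto: Environment, p: HHBParams,
              human: HumanSpec | None, geoms=None) -> dict[str, float]:
    env = env_proto.with_(TA=ta, RH=rh, T_sky=ta, T_ground=ta)
    return hhb_steady_core(env, p, human, geoms)


def _full_cell(ta: float, rh: float, env_proto: Environment, human: HumanSpec,
               opts: SolveOptions) -> BodySolution:
    env = env_proto.with_(TA=ta, RH=rh, T_sky=ta, T_ground=ta)
    return solve_human(human, env, opts)


def survivability_grid(model: str, human: HumanSpec | None = None,
                       VEL: float = 1.0,
                       TA_range: tuple[float, float, float] = (35.0, 60.0, 0.5),
                       RH_range: tuple[float, float, float] = (1.0, 100.0, 1.0),
                       hhb_params: HHBParams | None = None,
                       env_proto: Environment | None = None,
                       frontier_only: bool = False) -> SurvivalGrid:
    """Survivability over a TA x RH grid for either model.

    ``model`` is ``"hhb"`` (fixed-skin minimal model; every cell evaluated —
    it is closed-form) or ``"full"`` (the thermoregulatory cascade with
    EXCEED_TCMAX on; non-survivable when the steady core reaches 43 degC,
    excluded when skin exceeds 40 degC).  For the full model
    ``frontier_only=True`` finds the lowest non-survivable RH per TA by
    bisection over the RH grid — the survivable region is contiguous
    downward in RH (a property-tested invariant), so the result matches the
    exhaustive scan at a fraction of the solves; grid cells not visited are
    NaN.
    """
    if model not in ("hhb", "full"):
        raise ValueError(f"model must be 'hhb' or 'full', got {model!r}")
    human = human or HumanSpec.nude()
    env_proto = env_proto or Environment(TA=40.0, VEL=VEL, RH=50.0)
    env_proto = env_proto.with_(VEL=VEL)
    tas = np.arange(TA_range[0], TA_range[1] + 0.5 * TA_range[2], TA_range[2])
    rhs = np.arange(RH_range[0], RH_range[1] + 0.5 * RH_range[2], RH_range[2])
    n_ta, n_rh = len(tas), len(rhs)
    t_core = np.full((n_ta, n_rh), np.nan)
    t_skin = np.full((n_ta, n_rh), np.nan)
    surv = np.ones((n_ta, n_rh), dtype=bool)
    excl = np.zeros((n_ta, n_rh), dtype=bool)
    rows = []

    p = hhb_params or HHBParams()

    if model == "hhb":
        hhb_geoms = human.geometry()
        for i, ta in enumerate(tas):
            frontier_j = None
            mech = "environment"
            for j, rh in enumerate(rhs):
                out = _hhb_cell(float(ta), float(rh), env_proto, p, human, hhb_geoms)
                t_core[i, j] = out["T_core"]
                t_skin[i, j] = p.T_skin
                surv[i, j] = out["survivable"]
                if not out["survivable"] and frontier_j is None:
                    frontier_j = j
                    mech = "sweat" if out["sweat_limited"] else "environment"
            if frontier_j is not None:
                rows.append(_frontier_row(float(tas[i]), float(rhs[frontier_j]),
                                          mech, env_proto.pressure))
        frontier = pd.DataFrame(rows, columns=["TA", "RH", "wet_bulb", "mechanism"])
        return SurvivalGrid("hhb", tas, rhs, t_core, t_skin, surv, excl, frontier)

    opts = SolveOptions(stop_at_core=LETHAL_CORE + 0.5)

    def eval_cell(i: int, j: int) -> tuple[bool, bool, BodySolution]:
        """A cell is certified survivable only when the cascade converges
        with core below the lethal threshold AND skin at or below the
        exclusion limit (hotter-skin solutions are outside the model's
        certified domain, per the exclusion rule)."""
        sol = _full_cell(float(tas[i]), float(rhs[j]), env_proto, human, opts)
        t_core[i, j] = sol.T_core_trunk
        t_skin[i, j] = sol.T_skin
        lethal = sol.T_core_trunk >= LETHAL_CORE or not sol.converged
        excluded = sol.T_skin > SKIN_EXCLUDE
        dead = lethal or excluded
        surv[i, j] = not dead
        excl[i, j] = excluded and not lethal
        return dead, excluded, sol

    for i in range(n_ta):
        if frontier_only:
            lo, hi = 0, n_rh - 1
            dead_hi, _, sol_hi = eval_cell(i, hi)
            if not dead_hi:
                continue  # survivable even at the most humid cell: no frontier
            dead_lo, _, _ = eval_cell(i, lo)
            if dead_lo:
                hi = lo  # non-survivable across the whole row
            while hi - lo > 1:
                mid = (lo + hi) // 2
                dead_mid, _, _ = eval_cell(i, mid)
                if dead_mid:
                    hi = mid
                else:
                    lo = mid
            j_front = hi
        else:
            j_front = None
            for j in range(n_rh):
                dead, _, _ = eval_cell(i, j)
                if dead and j_front is None:
                    j_front = j
            if j_front is None:
                continue
        sol = _full_cell(float(tas[i]), float(rhs[j_front]), env_proto, human, opts)
        mech = "sweat" if sol.sweat_limited else "environment"
        row = _frontier_row(float(tas[i]), float(rhs[j_front]), mech, env_proto.pressure)
        row["criterion"] = "hot_skin" if excl[i, j_front] else "lethal_core"
        rows.append(row)

    frontier = pd.DataFrame(
        rows, columns=["TA", "RH", "wet_bulb", "mechanism", "criterion"])
    return SurvivalGrid("full", tas, rhs, t_core, t_skin, surv, excl, frontier)
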