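"""Whole-body steady-state solve with the human thermoregulatory cascade.

The body is iterated part by part (head, trunk, and one of each limb pair,
limb results doubled) at the current physiological state.  The summed part
generations give the net heat that must leave through the skin, Q_gen_net;
respiration is then coupled by a root-find so that total generation minus
respiratory loss equals that net.  If Q_gen_net exceeds the minimum
allowable metabolic rate Q_min the subject is compensating for cold (the
model reports the required metabolic elevation).  Otherwise a cascade of
effectors is engaged, in series with a parallel sweating channel, until a
steady state is found or every effector is exhausted:

1. vasodilation — flesh conductivity k_flesh always steps up under strain,
   with the step size driven by the solved skin temperature (a 3k step while
   the skin is below the 35 degC control point, a gentle 0.5k step once near
   or above it, so skin approaches the control point softly), capped at
   k_max and backed off by log-space bisection when a step overshoots the
   balance band; beyond 0.5 W/m/K the subcutaneous fat shell's influence is
   ramped linearly to zero at k_max (vasodilated blood bypasses the fat);
2. core-temperature rise — once k_flesh saturates, every part's core
   target steps up together (default 0.1 degC per iteration) toward TC_MAX,
   with the minimum metabolic rate inflated by Q10^(dT/10);
3. sweating (parallel, every iteration) — when a part's skin temperature
   comes within 2 degC of its core target its wetness steps up; above
   35 degC skin the step is 10x and the core target is nudged up as well.
   Wetness is capped by its maximum and by the maximum sweat rate through
   the evaporation efficiency r = 1 - w^2/2 (dripped sweat does not cool);
4. beyond TC_MAX — with EXCEED_TCMAX the core continues to climb to find
   the theoretical steady state (up to MAXITER); otherwise the solve
   returns with heat storage implied (Q_gen_net below minimum).

Everything is deterministic: repeated solves are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .anthropometry import (
    BodyPartSpec,
    DEFAULT_PART_SPECS,
    PartGeometry,
    assemble_body,
    dubois_area,
)
from .environment import Environment, EnvironmentProfile, latent_heat_vaporisation
from .part_balance import InsulationLayer, PartSolution, PartState, solve_part
from .respiration import RespirationResult, solve_qgen_total

__all__ = [
    "HumanSpec",
    "BodySolution",
    "solve_human",
    "initial_state",
    "aggregate",
    "run_vector",
    "SolveOptions",
]

_BAND = 0.5  # W: Q_gen_net within [Q_min_eff, Q_min_eff + band] counts as balanced
_SKIN_CONTROL = 35.0  # degC: skin-temperature control point of the vasomotor servo
_CORE_CEILING = 60.0  # degC: hard cap on the theoretical core-temperature climb


_LIGHT_CLOTHING: dict[str, InsulationLayer] = {
    "head": InsulationLayer(depth=0.003, conductivity=0.05),  # hair
    "trunk": InsulationLayer(depth=0.003, conductivity=0.042),
    "arm": InsulationLayer(depth=0.002, conductivity=0.042),
    "leg": InsulationLayer(depth=0.002, conductivity=0.042),
}

_TC_REF_DEFAULT = {"head": 36.5, "trunk": 36.5, "arm": 35.0, "leg": 36.7}


@dataclass(frozen=True)
class HumanSpec:
    """The modelled human: size, proportions, coverings, physiology.

    Defaults describe a 70 kg, 1.75 m lightly clothed adult with a resting
    metabolic rate of 87 W.  ``insulation`` maps part id to a layer applied
    to both sides (use ``insulation_dorsal``/``insulation_ventral`` for
    asymmetric coverings).  Resting core targets are part-specific (arms
    rest cooler than the trunk); the cascade shifts all of them together.
    """

    mass: float = 70.0  # kg
    height: float = 1.75  # m
    area: float | None = None  # m^2; DuBois from mass/height when omitted
    part_specs: tuple[BodyPartSpec, ...] = DEFAULT_PART_SPECS
    Q_min: float = 87.0  # W, minimum allowable (resting/active) metabolic rate
    TC_REF: dict[str, float] = field(default_factory=lambda: dict(_TC_REF_DEFAULT))
    TC_MAX: float = 38.0  # degC
    TC_step: float = 0.1  # degC per cascade iteration
    Q10: float = 2.0
    k_flesh_min: float = 0.412  # W/m/K, fully vasoconstricted
    k_flesh_max: float = 5.0  # W/m/K, fully vasodilated
    pct_wet_baseline: float = 0.01  # insensible skin wetness fraction
    pct_wet_step: float = 0.01  # fraction per cascade iteration
    pct_wet_max: float = 1.0
    sweat_max: float = 1.5  # L/h whole body
    exceed_tcmax: bool = True
    maxiter: int = 500
    insulation_dorsal: dict[str, InsulationLayer] = field(
        default_factory=lambda: dict(_LIGHT_CLOTHING))
    insulation_ventral: dict[str, InsulationLayer] = field(
        default_factory=lambda: dict(_LIGHT_CLOTHING))
    pct_bare_evap: float = 0.3
    rq: float = 0.85
    extraction_efficiency: float = 0.20

    def __post_init__(self) -> None:
        if self.Q_min <= 0.0:
            raise ValueError("Q_min must be positive")
        if self.TC_step <= 0.0 or self.pct_wet_step <= 0.0:
            raise ValueError("cascade step sizes must be positive")
        for pid, tc in self.TC_REF.items():
            if tc > self.TC_MAX:
                raise ValueError(f"TC_REF[{pid}]={tc} exceeds TC_MAX={self.TC_MAX}")

    @property
    def total_area(self) -> float:
        return self.area if self.area is not None else dubois_area(self.mass, self.height)

    @classmethod
    def nude(cls, **kwargs) -> "HumanSpec":
        """A nude configuration (no clothing or hair layers anywhere)."""
        bare: dict[str, InsulationLayer] = {}
        return cls(insulation_dorsal=bare, insulation_ventral=bare, **kwargs)

    def geometry(self) -> list[PartGeometry]:
        parts = assemble_body(self.mass, self.total_area, self.height, self.part_specs)
        out = []
        for p in parts:
            d = self.insulation_dorsal.get(p.part_id, InsulationLayer())
            v = self.insulation_ventral.get(p.part_id, InsulationLayer())
            out.append(p.with_(insulation_depth=0.5 * (d.depth + v.depth)))
        return out


@dataclass(frozen=True)
class SolveOptions:
    """Solver controls for one whole-body solve."""

    stop_at_core: float | None = None  # degC; truncate the cascade's core climb
    band: float = _BAND  # W, balance acceptance band on Q_gen_net


def initial_state(human: HumanSpec, mode: str = "vasoconstricted",
                  custom: dict[str, PartState] | None = None) -> dict[str, PartState]:
    """Per-part starting states.

    ``vasoconstricted``: k_flesh at its minimum with the fat layer fully
    active and baseline wetness — the maximum capacity to defend against
    cold.  ``custom`` passes user states through untouched.
    """
    if mode == "custom":
        if custom is None:
            raise ValueError("custom mode requires explicit per-part states")
        return dict(custom)
    if mode != "vasoconstricted":
        raise ValueError(f"unknown initial-state mode {mode!r}")
    states = {}
    for spec in human.part_specs:
        pid = spec.part_id
        states[pid] = PartState(
            T_core_target=human.TC_REF.get(pid, 36.5),
            k_flesh=human.k_flesh_min,
            pct_wet=human.pct_wet_baseline,
            fat_factor=1.0,
            dorsal=human.insulation_dorsal.get(pid, InsulationLayer()),
            ventral=human.insulation_ventral.get(pid, InsulationLayer()),
            pct_bare_evap=human.pct_bare_evap,
        )
    return states


def _fat_factor(k: float, k_max: float) -> float:
    """Linear removal of the fat shell's influence from k=0.5 to k_max."""
    if k <= 0.5:
        return 1.0
    return max(0.0, (k_max - k) / (k_max - 0.5))


@dataclass(frozen=True)
class BodySolution:
    """Whole-body steady state: aggregates, budgets, per-part tables."""

    status: str  # cold_compensating | thermoneutral | regulating_heat | storage_implied | max_iter
    T_core: float  # degC, skin-area-weighted mean of part core targets
    T_core_trunk: float  # degC, the trunk's core target (cascade reference)
    T_lung: float  # degC, respiratory tract
    T_skin: float  # degC, area-weighted mean
    T_ins_dorsal: float
    T_ins_ventral: float
    pct_wet: float  # aggregate wetness fraction
    k_flesh: float  # W/m/K
    Q_gen: float  # W total metabolic heat production
    Q_gen_net: float  # W delivered past respiration (= sum of part budgets)
    Q_min: float  # W, configured minimum metabolic rate
    Q_min_effective: float  # W, Q10-inflated minimum
    Q_sol: float
    Q_rad: float
    Q_conv: float
    Q_cond: float
    Q_evap_cut: float
    Q_evap_ins: float
    Q_resp_conv: float
    Q_resp_evap: float
    water_cutaneous_L_h: float
    water_respiratory_L_h: float
    sweat_rate_L_h: float
    evaporation_efficiency: float  # r = 1 - w^2/2
    sweat_limited: bool
    iterations: int
    parts: dict[str, PartSolution]
    states: dict[str, PartState]
    geometries: dict[str, PartGeometry]
    respiration: RespirationResult
    environment: Environment

    @property
    def Q_resp(self) -> float:
        return self.Q_resp_conv + self.Q_resp_evap

    @property
    def balance_residual(self) -> float:
        """Whole-body closure: Qgen - Qresp - Qevap,cut - sum(Qins), W."""
        q_ins = sum(
            self.geometries[pid].count * s.Q_ins for pid, s in self.parts.items())
        q_evap = sum(
            self.geometries[pid].count * s.Q_evap_cut for pid, s in self.parts.items())
        return self.Q_gen - self.Q_resp - q_evap - q_ins

    @property
    def converged(self) -> bool:
        return self.status in ("cold_compensating", "thermoneutral", "regulating_heat")

    def summary(self) -> str:
        lines = [
            f"status: {self.status}   iterations: {self.iterations}",
            f"T_core {self.T_core:6.2f} C   T_skin {self.T_skin:6.2f} C   "
            f"T_ins {self.T_ins_dorsal:6.2f}/{self.T_ins_ventral:6.2f} C",
            f"Q_gen {self.Q_gen:7.2f} W   Q_gen_net {self.Q_gen_net:7.2f} W   "
            f"Q_min_eff {self.Q_min_effective:6.2f} W",
            f"wetness {100 * self.pct_wet:5.1f} %   k_flesh {self.k_flesh:5.2f} W/m/K   "
            f"sweat {self.sweat_rate_L_h:5.3f} L/h",
        ]
        return "\n".join(lines)


def aggregate(solutions: dict[str, PartSolution],
              geometries: dict[str, PartGeometry]) -> dict[str, float]:
    """Area-weighted temperature means and count-weighted flux sums."""
    weights = {}
    total_area = sum(g.count * g.area_skin for g in geometries.values())
    for pid, g in geometries.items():
        weights[pid] = g.count * g.area_skin / total_area
    out = {
        "T_skin": sum(weights[p] * s.T_skin for p, s in solutions.items()),
        "T_ins_dorsal": sum(weights[p] * s.T_ins_dorsal for p, s in solutions.items()),
        "T_ins_ventral": sum(weights[p] * s.T_ins_ventral for p, s in solutions.items()),
        "T_core": sum(weights[p] * s.T_core for p, s in solutions.items()),
    }
    for term in ("Q_gen", "Q_sol", "Q_rad", "Q_conv", "Q_cond", "Q_evap_cut", "Q_evap_ins"):
        out[term] = sum(geometries[p].count * getattr(s, term) for p, s in solutions.items())
    out["weights_sum"] = sum(weights.values())
    return out


def _solve_all(geoms: dict[str, PartGeometry], states: dict[str, PartState],
               profile: EnvironmentProfile) -> dict[str, PartSolution]:
    return {pid: solve_part(geoms[pid], states[pid], profile[pid]) for pid in geoms}


def _sweat_rate(q_evap_cut: float, w: float, T_skin: float) -> tuple[float, float]:
    """(sweat L/h, efficiency r): secreted sweat needed to sustain the
    evaporative flux given that dripping wastes 1 - r of it."""
    r = 1.0 - w * w / 2.0
    lam = latent_heat_vaporisation(T_skin)
    if q_evap_cut <= 0.0:
        return 0.0, r
    return q_evap_cut / (lam * r) * 3600.0, r


def solve_human(human: HumanSpec, env: Environment | EnvironmentProfile,
                options: SolveOptions | None = None,
                init: dict[str, PartState] | None = None) -> BodySolution:
    """Run the whole-body loop and thermoregulatory cascade to steady state."""
    opts = options or SolveOptions()
    geoms = {g.part_id: g for g in human.geometry()}
    if isinstance(env, Environment):
        profile = EnvironmentProfile.broadcast(env, list(geoms))
        env_ref = env
    else:
        profile = env
        env_ref = profile.environments[0]
    states = dict(init) if init is not None else initial_state(human)

    k = min(s.k_flesh for s in states.values())
    k_lo, k_hi = k, None  # log-bisection bracket for vasodilation
    delta_core = 0.0
    sweat_limited = False
    effectors_used = False
    tc_ref_trunk = human.TC_REF.get("trunk", 36.5)
    status = "max_iter"
    sols: dict[str, PartSolution] = {}
    iterations = 0

    def apply_states(k_val: float, dc: float, wet: dict[str, float]) -> None:
        ff = _fat_factor(k_val, human.k_flesh_max)
        for pid in states:
            states[pid] = states[pid].with_(
                k_flesh=k_val, fat_factor=ff,
                T_core_target=human.TC_REF.get(pid, 36.5) + dc,
                pct_wet=wet[pid],
            )

    wet = {pid: states[pid].pct_wet for pid in states}
    apply_states(k, delta_core, wet)

    for iterations in range(1, human.maxiter + 1):
        sols = _solve_all(geoms, states, profile)
        agg = aggregate(sols, geoms)
        net = agg["Q_gen"]
        tc_trunk = states["trunk"].T_core_target if "trunk" in states else \
            next(iter(states.values())).T_core_target
        qmin_eff = human.Q_min * human.Q10 ** ((tc_trunk - tc_ref_trunk) / 10.0)

        sweat_L_h, r_eff = _sweat_rate(agg["Q_evap_cut"], _aggregate_wetness(sols, geoms, states),
                                       agg["T_skin"])

        skin_agg = agg["T_skin"]

        if net >= qmin_eff:
            if net <= qmin_eff + opts.band:
                # vasomotor adjustment alone still counts as thermoneutral;
                # active sweating or an elevated core means heat regulation
                baseline = delta_core == 0.0 and all(
                    wet[pid] <= human.pct_wet_baseline + 1e-12 for pid in wet)
                status = "thermoneutral" if baseline else "regulating_heat"
                break
            if not effectors_used:
                status = "cold_compensating"
                break
            # a vasodilation step overshot the balance band: bisect k back
            # down in log space (the x0.5 back-off)
            if k <= human.k_flesh_min * (1.0 + 1e-9):
                status = "regulating_heat"  # cannot constrict further; accept
                break
            if k_hi is None or k < k_hi:
                k_hi = k
            k_lo = min(k_lo, k_hi)
            if k_hi / max(k_lo, 1e-12) < 1.0 + 1e-9:
                status = "regulating_heat"  # bracket collapsed; accept
                break
            k = max(math.sqrt(k_lo * k_hi), human.k_flesh_min)
            apply_states(k, delta_core, wet)
            effectors_used = True
            continue

        # --- heat strain: Q_gen_net below the allowable minimum ---
        if opts.stop_at_core is not None and tc_trunk >= opts.stop_at_core:
            status = "storage_implied"
            break

        if sweat_L_h >= human.sweat_max:
            sweat_limited = True

        stepped = False

        # (1) vasodilation: under strain the flesh conductivity always steps
        # up while room remains; the step size is driven by the skin
        # temperature — a 3k step (k -> 4k) while the skin is below the
        # 35 degC control point, a gentle 0.5k step (k -> 1.5k) once it is
        # near or above it, so the skin approaches the control point softly.
        if k < human.k_flesh_max - 1e-12:
            k_lo = k
            if k_hi is not None and k_hi / k_lo > 1.0 + 1e-9:
                k = min(math.sqrt(k_lo * k_hi), human.k_flesh_max)
            elif skin_agg < _SKIN_CONTROL:
                k = min(k * 4.0, human.k_flesh_max)
            else:
                k = min(k * 1.5, human.k_flesh_max)
            stepped = True

        dilation_exhausted = k >= human.k_flesh_max - 1e-12
        wet_capped = sweat_limited or all(
            wet[pid] >= human.pct_wet_max - 1e-12 for pid in wet)
        allow_beyond_tcmax = human.exceed_tcmax and dilation_exhausted and wet_capped
        # even with EXCEED_TCMAX the theoretical climb stops at a hard
        # physical ceiling: no meaningful steady state exists above it
        max_delta = (_CORE_CEILING - tc_ref_trunk) if allow_beyond_tcmax \
            else human.TC_MAX - tc_ref_trunk

        def bump_core() -> bool:
            nonlocal delta_core
            if delta_core + human.TC_step <= max_delta + 1e-12:
                delta_core += human.TC_step
                return True
            return False

        # (2) serial core-temperature rise once conductivity is saturated
        if k >= human.k_flesh_max - 1e-12:
            stepped = bump_core() or stepped

        # (3) sweating channel, in parallel every iteration
        hot_skin = False
        if not sweat_limited:
            for pid, s in sols.items():
                step = 0.0
                if s.T_skin >= states[pid].T_core_target - 2.0:
                    step += human.pct_wet_step
                if s.T_skin > _SKIN_CONTROL:
                    step += 10.0 * human.pct_wet_step
                    hot_skin = True
                if step > 0.0:
                    new_w = min(wet[pid] + step, human.pct_wet_max)
                    if new_w > wet[pid]:
                        wet[pid] = new_w
                        stepped = True
        else:
            hot_skin = any(s.T_skin > _SKIN_CONTROL for s in sols.values())
        if hot_skin:
            stepped = bump_core() or stepped  # hot skin: core additionally incremented

        if not stepped and dilation_exhausted and wet_capped:
            # every faster channel is idle; the core is the only effector left
            stepped = bump_core()
        if not stepped:
            status = "storage_implied"
            break
        effectors_used = True
        apply_states(k, delta_core, wet)

    # --- final bookkeeping at the last solved state ---
    agg = aggregate(sols, geoms)
    net = agg["Q_gen"]
    tc_trunk = states["trunk"].T_core_target if "trunk" in states else \
        next(iter(states.values())).T_core_target
    qmin_eff = human.Q_min * human.Q10 ** ((tc_trunk - tc_ref_trunk) / 10.0)
    trunk_sol = sols.get("trunk", next(iter(sols.values())))
    q_total, resp = solve_qgen_total(
        max(net, qmin_eff), env_ref, trunk_sol.T_core, trunk_sol.T_fat_boundary,
        human.rq, human.extraction_efficiency)
    w_mean = _aggregate_wetness(sols, geoms, states)
    sweat_L_h, r_eff = _sweat_rate(agg["Q_evap_cut"], w_mean, agg["T_skin"])
    lam = latent_heat_vaporisation(agg["T_skin"])
    return BodySolution(
        status=status,
        T_core=agg["T_core"], T_core_trunk=tc_trunk, T_lung=resp.T_tract,
        T_skin=agg["T_skin"], T_ins_dorsal=agg["T_ins_dorsal"],
        T_ins_ventral=agg["T_ins_ventral"], pct_wet=w_mean,
        k_flesh=next(iter(states.values())).k_flesh,
        Q_gen=q_total, Q_gen_net=net, Q_min=human.Q_min, Q_min_effective=qmin_eff,
        Q_sol=agg["Q_sol"], Q_rad=agg["Q_rad"], Q_conv=agg["Q_conv"],
        Q_cond=agg["Q_cond"], Q_evap_cut=agg["Q_evap_cut"],
        Q_evap_ins=agg["Q_evap_ins"], Q_resp_conv=resp.Q_resp_conv,
        Q_resp_evap=resp.Q_resp_evap,
        water_cutaneous_L_h=max(agg["Q_evap_cut"], 0.0) / lam * 3600.0,
        water_respiratory_L_h=resp.water_loss_L_h,
        sweat_rate_L_h=min(sweat_L_h, human.sweat_max),
        evaporation_efficiency=r_eff, sweat_limited=sweat_limited,
        iterations=iterations, parts=sols, states=dict(states),
        geometries=geoms, respiration=resp, environment=env_ref,
    )


def _mean_wet(wet: dict[str, float], geoms: dict[str, PartGeometry]) -> float:
    total = sum(g.count * g.area_skin for g in geoms.values())
    return sum(geoms[p].count * geoms[p].area_skin * w for p, w in wet.items()) / total


def _aggregate_wetness(sols: dict[str, PartSolution], geoms: dict[str, PartGeometry],
                       states: dict[str, PartState]) -> float:
    total = sum(g.count * g.area_skin for g in geoms.values())
    return sum(geoms[p].count * geoms[p].area_skin * states[p].pct_wet
               for p in sols) / total


def run_vector(human: HumanSpec, TAs: Sequence[float], VELs: Sequence[float],
               RHs: Sequence[float], envs: Sequence[Environment] | None = None,
               options: SolveOptions | None = None, **env_kwargs) -> list[BodySolution]:
    """Element-wise independent steady-state solves over condition vectors.

    Either provide TAs/VELs/RHs (plus shared keyword overrides such as
    ``T_sky``) or a prebuilt list of environments via ``envs``.
    """
    if envs is None:
        if not (len(TAs) == len(VELs) == len(RHs)):
            raise ValueError(
                f"environment vectors must have equal length: "
                f"{len(TAs)}, {len(VELs)}, {len(RHs)}")
        envs = [Environment(TA=ta, VEL=v, RH=rh, **env_kwargs)
                for ta, v, rh in zip(TAs, VELs, RHs)]
    return [solve_human(human, e, options) for e in envs]
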