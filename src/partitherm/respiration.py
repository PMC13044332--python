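"""Respiratory heat and water exchange from a molar ventilation balance.

Ventilation is driven by the metabolic oxygen demand implied by the total
heat generation: an oxyjoule equivalent converts watts to O2 consumption,
the ambient O2 fraction and the extraction efficiency set the inspired air
flow, the respiratory exchange ratio (RQ) sets CO2 production, and expired
air leaves saturated at the expired-air temperature.  The upper respiratory
tract sits halfway between the core and the start of the trunk's fat layer;
expired air is the cooler of the tract temperature and the air/tract mean.

Because ventilation depends on total heat generation while the net heat that
must leave through the skin is fixed by the part solutions, a scalar
root-find couples the two: Q_gen - Q_resp(Q_gen) - Q_gen_net = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

from .environment import (
    CP_AIR_MOLAR,
    Environment,
    latent_heat_vaporisation,
    saturation_vapour_pressure,
    vapour_pressure,
)

__all__ = [
    "RespirationResult",
    "tract_temperature",
    "ventilation",
    "respiratory_exchange",
    "respire",
    "solve_qgen_total",
    "oxyjoule_equivalent",
    "M_WATER_MOLAR",
]

R_GAS = 8.314462618
M_WATER_MOLAR = 0.018015  # kg/mol
STP_MOLAR_VOLUME_ML = 22414.0  # mL/mol at 0 degC, 101.325 kPa (STPD)


def oxyjoule_equivalent(rq: float) -> float:
    """Heat yield per mL O2 (STPD), J/mL: 19.6 at RQ 0.7 to 21.1 at RQ 1.0,
    linear in between (standard respirometry constants)."""
    if not 0.7 <= rq <= 1.0:
        raise ValueError(f"respiratory quotient {rq} outside [0.7, 1.0]")
    return 19.6 + (21.1 - 19.6) * (rq - 0.7) / 0.3


def tract_temperature(T_core: float, T_fat_boundary: float, TA: float) -> tuple[float, float]:
    """(tract temperature, expired-air temperature), deg C.

    Tract: midway between core and the start of the fat layer.  Expired:
    mean of air and tract temperature, or the tract temperature, whichever
    is lower.
    """
    t_tract = 0.5 * (T_core + T_fat_boundary)
    t_exp = min(0.5 * (TA + t_tract), t_tract)
    return t_tract, t_exp


@dataclass(frozen=True)
class RespirationResult:
    """Molar/volumetric flows and the respiratory heat terms."""

    Q_resp_conv: float  # W, sensible (warming inspired air)
    Q_resp_evap: float  # W, latent (humidifying expired air)
    air_flow_L_h: float  # L/h of moist air at ambient T, P
    O2_flow_L_h: float  # L/h O2 consumed, STPD
    mol_air_in: float  # mol/s moist air inspired
    mol_air_out: float  # mol/s moist air expired
    mol_O2_in: float  # mol/s O2 inspired
    mol_O2_out: float  # mol/s O2 expired
    T_tract: float  # degC
    T_exp: float  # degC

    @property
    def Q_resp(self) -> float:
        return self.Q_resp_conv + self.Q_resp_evap

    @property
    def water_loss_L_h(self) -> float:
        """Respiratory water loss, litres per hour (liquid equivalent)."""
        t_mean = self.T_exp
        lam = latent_heat_vaporisation(t_mean)
        kg_s = self.Q_resp_evap / lam
        return kg_s * 3600.0


def ventilation(Q_gen: float, env: Environment, rq: float = 0.85,
                extraction_efficiency: float = 0.20) -> dict[str, float]:
    """Molar and volumetric flows from metabolic oxygen demand.

    O2 consumption follows the oxyjoule chain; inspired dry-gas flow is the
    O2 flow divided by (ambient dry O2 fraction x extraction efficiency);
    CO2 production is RQ x O2 consumption; vapour is carried on top of the
    dry-gas flows (dry fractions applied after removing vapour).
    """
    if Q_gen <= 0.0:
        raise ValueError(f"ventilation requires Q_gen > 0, got {Q_gen}")
    if not 0.0 < extraction_efficiency <= 1.0:
        raise ValueError("extraction efficiency must be in (0, 1]")
    if env.f_O2 <= 0.0:
        raise ValueError("ambient O2 fraction must be positive")
    vo2_mL_s = Q_gen / oxyjoule_equivalent(rq)  # mL O2 (STPD) per second
    n_O2_used = vo2_mL_s / STP_MOLAR_VOLUME_ML  # mol/s
    n_dry_in = n_O2_used / (env.f_O2 * extraction_efficiency)
    n_O2_in = n_dry_in * env.f_O2
    n_O2_out = n_O2_in - n_O2_used
    n_CO2_prod = rq * n_O2_used
    n_dry_out = n_dry_in - n_O2_used + n_CO2_prod
    e_a = env.vapour_pressure_air
    n_w_in = n_dry_in * e_a / (env.pressure - e_a)
    n_air_in = n_dry_in + n_w_in
    return {
        "n_O2_used": n_O2_used, "n_dry_in": n_dry_in, "n_dry_out": n_dry_out,
        "n_O2_in": n_O2_in, "n_O2_out": n_O2_out, "n_CO2_prod": n_CO2_prod,
        "n_w_in": n_w_in, "n_air_in": n_air_in, "vo2_mL_s": vo2_mL_s,
    }


def respiratory_exchange(flows: dict[str, float], TA: float, RH: float,
                         T_exp: float, pressure: float) -> tuple[float, float, float]:
    """(Q_resp_conv, Q_resp_evap, n_w_out) from the molar flows.

    Sensible: warming the inspired moist air from TA to T_exp.  Latent:
    vapour added between inspiration (ambient TA, RH) and expiration
    (saturated at T_exp).
    """
    e_exp = saturation_vapour_pressure(T_exp)
    if e_exp >= pressure:
        raise ValueError("expired air temperature implies boiling; check inputs")
    e_in = vapour_pressure(TA, RH)
    n_w_in = flows["n_dry_in"] * e_in / (pressure - e_in)
    n_w_out = flows["n_dry_out"] * e_exp / (pressure - e_exp)
    q_conv = (flows["n_dry_in"] + n_w_in) * CP_AIR_MOLAR * (T_exp - TA)
    lam_molar = latent_heat_vaporisation(T_exp) * M_WATER_MOLAR
    q_evap = (n_w_out - n_w_in) * lam_molar
    return q_conv, q_evap, n_w_out


def respire(Q_gen: float, env: Environment, T_core: float, T_fat_boundary: float,
            rq: float = 0.85, extraction_efficiency: float = 0.20) -> RespirationResult:
    """Full respiration bundle for a given total heat generation."""
    t_tract, t_exp = tract_temperature(T_core, T_fat_boundary, env.TA)
    flows = ventilation(Q_gen, env, rq, extraction_efficiency)
    q_conv, q_evap, n_w_out = respiratory_exchange(flows, env.TA, env.RH, t_exp, env.pressure)
    n_air_out = flows["n_dry_out"] + n_w_out
    TK = env.TA + 273.15
    air_L_h = flows["n_air_in"] * R_GAS * TK / env.pressure * 1000.0 * 3600.0
    o2_L_h = flows["vo2_mL_s"] * 3.6
    return RespirationResult(
        Q_resp_conv=q_conv, Q_resp_evap=q_evap, air_flow_L_h=air_L_h,
        O2_flow_L_h=o2_L_h, mol_air_in=flows["n_air_in"], mol_air_out=n_air_out,
        mol_O2_in=flows["n_O2_in"], mol_O2_out=flows["n_O2_out"],
        T_tract=t_tract, T_exp=t_exp,
    )


def solve_qgen_total(Q_gen_net: float, env: Environment, T_core: float,
                     T_fat_boundary: float, rq: float = 0.85,
                     extraction_efficiency: float = 0.20,
                     tol: float = 1e-6) -> tuple[float, RespirationResult]:
    """Total generation Q_gen such that Q_gen - Q_resp(Q_gen) = Q_gen_net.

    Q_resp is monotone (linear) in Q_gen through the ventilation chain, so
    the root is bracketed and unique; solved to ``tol`` watts.
    """
    def f(q: float) -> float:
        r = respire(q, env, T_core, T_fat_boundary, rq, extraction_efficiency)
        return q - r.Q_resp - Q_gen_net

    lo = max(Q_gen_net * 0.5, 1e-3)
    hi = max(Q_gen_net * 2.0 + 50.0, 10.0)
    for _ in range(60):
        if f(lo) <= 0.0:
            break
        lo *= 0.5
        if lo < 1e-9:
            raise RuntimeError("respiration coupling: no positive bracket")
    if f(hi) < 0.0:
        for _ in range(60):
            hi *= 2.0
            if f(hi) >= 0.0:
                break
        else:
            raise RuntimeError("respiration coupling did not bracket a root")
    q_gen = brentq(f, lo, hi, xtol=tol)
    return q_gen, respire(q_gen, env, T_core, T_fat_boundary, rq, extraction_efficiency)
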