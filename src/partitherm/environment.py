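"""Microclimate representation, psychrometrics, and air thermophysical properties.

One :class:`Environment` holds a single microclimate condition: air temperature,
wind, humidity, the dorsal (sky) and ventral (ground) radiant temperatures,
direct and diffuse solar components with the solar zenith angle, barometric
pressure, and the gas composition of the air breathed.  Psychrometric
primitives (saturation vapour pressure, thermodynamic wet bulb, dew point) and
smooth correlations for the thermophysical properties of air live here because
every exchange pathway in the heat budget — convection, cutaneous and
respiratory evaporation — consumes them, and a single consistent formulation
must be used throughout.

Units at the boundary: temperatures in deg C, pressures in Pa, wind in m/s,
relative humidity in percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

__all__ = [
    "Environment",
    "EnvironmentProfile",
    "saturation_vapour_pressure",
    "vapour_pressure",
    "vapour_density",
    "dew_point",
    "wet_bulb",
    "air_properties",
    "latent_heat_vaporisation",
    "read_environment_csv",
    "AirProperties",
]

P_STANDARD = 101325.0  # Pa
R_GAS = 8.314462618  # J / (mol K)
M_AIR = 0.0289647  # kg / mol, dry air
M_WATER = 0.018015  # kg / mol
CP_AIR = 1006.0  # J / (kg K), dry air
CP_VAPOUR = 1860.0  # J / (kg K)
CP_AIR_MOLAR = 29.1  # J / (mol K)

_T_MIN, _T_MAX = -40.0, 110.0


def saturation_vapour_pressure(T: float) -> float:
    """Saturation vapour pressure over liquid water, Pa (Buck 1996).

    Valid for ``-40 <= T <= 110`` deg C; monotone increasing.  The same
    formulation is used for skin, clothing, and respiratory evaporation so
    that vapour-pressure differences are internally consistent.
    """
    if not (_T_MIN <= T <= _T_MAX):
        raise ValueError(f"temperature {T} degC outside [{_T_MIN}, {_T_MAX}] for saturation_vapour_pressure")
    return 611.21 * math.exp((18.678 - T / 234.5) * T / (257.14 + T))


def vapour_pressure(T: float, RH: float) -> float:
    """Ambient vapour pressure, Pa, from air temperature and RH (%)."""
    if not 0.0 <= RH <= 100.0:
        raise ValueError(f"relative humidity {RH}% outside [0, 100]")
    return saturation_vapour_pressure(T) * RH / 100.0


def vapour_density(e: float, T: float) -> float:
    """Water-vapour density, kg/m^3, from vapour pressure (Pa) and T (degC)."""
    return e * M_WATER / (R_GAS * (T + 273.15))


def latent_heat_vaporisation(T: float) -> float:
    """Latent heat of vaporisation of water, J/kg, linear in T (degC)."""
    return 2.501e6 - 2361.0 * T


def _humidity_ratio(e: float, pressure: float) -> float:
    return 0.622 * e / (pressure - e)


def dew_point(TA: float, RH: float) -> float:
    """Dew-point temperature, deg C (inverse of the saturation curve)."""
    from scipy.optimize import brentq

    e = vapour_pressure(TA, RH)
    if e <= saturation_vapour_pressure(_T_MIN):
        return _T_MIN
    return brentq(lambda t: saturation_vapour_pressure(t) - e, _T_MIN, TA + 1e-9, xtol=1e-8)


def wet_bulb(TA: float, RH: float, pressure: float = P_STANDARD) -> float:
    """Thermodynamic wet-bulb temperature, deg C.

    Solves the adiabatic-saturation (psychrometer) equation

        (w_s(Twb) - w) * lambda(Twb) = cp_moist * (TA - Twb)

    by bracketed root finding.  ``Twb = TA`` at saturation; ``Twb <= TA``
    always.
    """
    if not 0.0 <= RH <= 100.0:
        raise ValueError(f"relative humidity {RH}% outside [0, 100]")
    e_a = vapour_pressure(TA, RH)
    w_a = _humidity_ratio(e_a, pressure)
    cp_m = CP_AIR + CP_VAPOUR * w_a

    def f(t: float) -> float:
        w_s = _humidity_ratio(saturation_vapour_pressure(t), pressure)
        return (w_s - w_a) * latent_heat_vaporisation(t) - cp_m * (TA - t)

    if RH >= 100.0:
        return TA
    from scipy.optimize import brentq

    lo = max(_T_MIN, TA - 60.0)
    if f(lo) > 0.0:  # extremely cold/dry corner: wet bulb pinned to bracket edge
        return lo
    try:
        return brentq(f, lo, TA, xtol=1e-6)
    except ValueError as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"wet-bulb solve failed for TA={TA}, RH={RH}: {exc}") from exc


@dataclass(frozen=True)
class AirProperties:
    """Thermophysical properties of moist air at a film temperature."""

    conductivity: float  # W / (m K)
    kinematic_viscosity: float  # m^2 / s
    dynamic_viscosity: float  # Pa s
    prandtl: float
    density: float  # kg / m^3
    diffusivity_water: float  # m^2 / s
    thermal_diffusivity: float  # m^2 / s
    cp: float  # J / (kg K)


def air_properties(T_film: float, pressure: float = P_STANDARD) -> AirProperties:
    """Air properties at a film temperature (deg C): smooth, all positive.

    Conductivity is a linear fit to tabulated dry air, viscosity is
    Sutherland's law, density the ideal-gas law, and the water-vapour
    diffusivity a power law in absolute temperature scaled inversely with
    pressure.
    """
    if not (-40.0 <= T_film <= 100.0):
        raise ValueError(f"film temperature {T_film} degC outside [-40, 100]")
    TK = T_film + 273.15
    k = 0.0241 + 7.7e-5 * T_film
    mu = 1.458e-6 * TK**1.5 / (TK + 110.4)
    rho = pressure * M_AIR / (R_GAS * TK)
    nu = mu / rho
    alpha = k / (rho * CP_AIR)
    pr = CP_AIR * mu / k
    d_wv = 2.26e-5 * (TK / 273.15) ** 1.81 * (P_STANDARD / pressure)
    return AirProperties(
        conductivity=k,
        kinematic_viscosity=nu,
        dynamic_viscosity=mu,
        prandtl=pr,
        density=rho,
        diffusivity_water=d_wv,
        thermal_diffusivity=alpha,
        cp=CP_AIR,
    )


@dataclass(frozen=True)
class Environment:
    """One microclimate condition.

    ``T_sky``/``T_ground`` default to the air temperature (indoor setting:
    radiant temperature equals air temperature).  Gas fractions are of dry
    air and must sum to 1.
    """

    TA: float  # air temperature, degC
    VEL: float = 0.1  # wind speed, m/s
    RH: float = 50.0  # relative humidity, %
    T_sky: float | None = None  # degC
    T_ground: float | None = None  # degC
    solar_direct: float = 0.0  # W/m^2, beam normal
    solar_diffuse: float = 0.0  # W/m^2
    zenith: float = 0.0  # degrees from vertical
    ground_reflectance: float = 0.2
    pressure: float = P_STANDARD  # Pa
    f_O2: float = 0.2095
    f_CO2: float = 0.0004
    f_N2: float = 0.7901

    def __post_init__(self) -> None:
        if not 0.0 <= self.RH <= 100.0:
            raise ValueError(f"RH {self.RH}% outside [0, 100]")
        if self.VEL < 0.0:
            raise ValueError(f"wind speed {self.VEL} m/s must be >= 0")
        if self.solar_direct < 0.0 or self.solar_diffuse < 0.0:
            raise ValueError("solar components must be >= 0")
        gas_sum = self.f_O2 + self.f_CO2 + self.f_N2
        if abs(gas_sum - 1.0) > 1e-6:
            raise ValueError(f"gas fractions sum to {gas_sum}, expected 1")

    @property
    def t_sky(self) -> float:
        return self.TA if self.T_sky is None else self.T_sky

    @property
    def t_ground(self) -> float:
        return self.TA if self.T_ground is None else self.T_ground

    @property
    def vapour_pressure_air(self) -> float:
        return vapour_pressure(self.TA, self.RH)

    def with_(self, **kwargs) -> "Environment":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class EnvironmentProfile:
    """Per-part microclimate: one Environment per body part.

    Built either from user-supplied per-part values or by broadcasting one
    scalar condition to every part (no internal boundary-layer model).
    """

    parts: tuple[str, ...]
    environments: tuple[Environment, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.parts) != len(self.environments):
            raise ValueError(
                f"profile needs one environment per part: {len(self.parts)} parts, "
                f"{len(self.environments)} environments"
            )

    @classmethod
    def broadcast(cls, env: Environment, parts: Sequence[str]) -> "EnvironmentProfile":
        return cls(parts=tuple(parts), environments=tuple(env for _ in parts))

    def __getitem__(self, part_id: str) -> Environment:
        return self.environments[self.parts.index(part_id)]


_ENV_CSV_OPTIONAL = {
    "T_sky": None,
    "T_ground": None,
    "solar_direct": 0.0,
    "solar_diffuse": 0.0,
    "zenith": 0.0,
    "ground_reflectance": 0.2,
    "pressure": P_STANDARD,
}


def read_environment_csv(path) -> list[Environment]:
    """Read a vector of conditions from CSV (columns TA, VEL, RH, optional
    T_sky, T_ground, solar_direct, solar_diffuse, zenith, ground_reflectance,
    pressure).  Missing optional columns take their documented defaults."""
    df = pd.read_csv(path)
    required = {"TA", "VEL", "RH"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"environment CSV missing required columns: {sorted(missing)}")
    envs = []
    for _, row in df.iterrows():
        kwargs = {"TA": float(row["TA"]), "VEL": float(row["VEL"]), "RH": float(row["RH"])}
        for col, default in _ENV_CSV_OPTIONAL.items():
            if col in df.columns and not pd.isna(row[col]):
                kwargs[col] = float(row[col])
            elif default is not None:
                kwargs[col] = default
        envs.append(Environment(**kwargs))
    return envs
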