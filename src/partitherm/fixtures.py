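"""Named, deterministic scenario fixtures used by the test suite and docs.

Each fixture is a (HumanSpec, environment set) pair describing a standard
study condition: the indoor reference condition, the thermoneutral-zone
sweep, a cold sweep, and the nude humid-heat configurations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .environment import Environment
from .thermoregulation import HumanSpec

__all__ = ["make_fixture", "FIXTURES", "Fixture"]


@dataclass(frozen=True)
class Fixture:
    name: str
    human: HumanSpec
    environments: tuple[Environment, ...]
    description: str


def _indoor_21C() -> Fixture:
    return Fixture(
        "indoor_21C", HumanSpec(),
        (Environment(TA=21.0, VEL=0.1, RH=50.0),),
        "Default lightly clothed adult indoors at 21 degC, 0.1 m/s, 50% RH.",
    )


def _tnz_sweep() -> Fixture:
    envs = tuple(Environment(TA=float(ta), VEL=0.1, RH=50.0) for ta in range(0, 56))
    return Fixture(
        "tnz_sweep", HumanSpec(), envs,
        "Air temperatures 0-55 degC at 0.1 m/s, 50% RH (thermoneutral zone sweep).",
    )


def _cold_sweep() -> Fixture:
    envs = tuple(Environment(TA=float(ta), VEL=0.1, RH=50.0) for ta in range(0, 21, 2))
    return Fixture(
        "cold_sweep", HumanSpec.nude(), envs,
        "Nude cold exposure, 0-20 degC at 0.1 m/s (metabolic elevation range).",
    )


def _humid_heat_grid() -> Fixture:
    envs = tuple(
        Environment(TA=float(ta), VEL=1.0, RH=float(rh), T_sky=float(ta), T_ground=float(ta))
        for ta in (38, 42, 46) for rh in (20, 50, 80)
    )
    return Fixture(
        "humid_heat_grid", HumanSpec.nude(), envs,
        "Nude human at 1 m/s over a small humid-heat TA x RH grid "
        "(the full survivability analysis runs its own fine grid).",
    )


def _nude_1ms() -> Fixture:
    return Fixture(
        "nude_1ms", HumanSpec.nude(),
        (Environment(TA=40.0, VEL=1.0, RH=50.0, T_sky=40.0, T_ground=40.0),),
        "Nude human at 1 m/s wind, 40 degC, 50% RH.",
    )


FIXTURES: dict[str, Callable[[], Fixture]] = {
    "indoor_21C": _indoor_21C,
    "tnz_sweep": _tnz_sweep,
    "cold_sweep": _cold_sweep,
    "humid_heat_grid": _humid_heat_grid,
    "nude_1ms": _nude_1ms,
}


def make_fixture(scenario: str) -> Fixture:
    """Build a named scenario fixture; unknown names list the registry."""
    try:
        builder = FIXTURES[scenario]
    except KeyError:
        raise ValueError(
            f"unknown scenario {scenario!r}; available: {sorted(FIXTURES)}") from None
    return builder()
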