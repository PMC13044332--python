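"""Run configuration: YAML schema, validation, defaults, provenance logging.

A run config has up to four sections — ``human``, ``environment``,
``options`` and ``output``.  Unknown keys are rejected with their location;
all defaults are resolved at load time and the fully resolved parameter set
is logged (and can be re-serialized), so every run carries the complete
provenance of the many stand-in physiological defaults.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path
from typing import Any

import yaml

from .anthropometry import BodyPartSpec
from .environment import Environment
from .part_balance import InsulationLayer
from .thermoregulation import HumanSpec, SolveOptions

__all__ = ["RunConfig", "load_config", "dump_config", "human_from_dict"]

log = logging.getLogger("partitherm")

_HUMAN_SIMPLE_KEYS = {
    "mass", "height", "area", "Q_min", "TC_MAX", "TC_step", "Q10",
    "k_flesh_min", "k_flesh_max", "pct_wet_baseline", "pct_wet_step",
    "pct_wet_max", "sweat_max", "exceed_tcmax", "maxiter", "pct_bare_evap",
    "rq", "extraction_efficiency",
}
_HUMAN_KEYS = _HUMAN_SIMPLE_KEYS | {"TC_REF", "nude", "insulation", "part_specs"}
_ENV_KEYS = {f.name for f in fields(Environment)} | {"csv"}
_OPTION_KEYS = {"stop_at_core", "band"}
_OUTPUT_KEYS = {"path", "format"}
_INS_KEYS = {"depth", "conductivity", "solar_reflectance", "emissivity"}
_PART_KEYS = {f.name for f in fields(BodyPartSpec)}


def _reject_unknown(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section '{section}' "
            f"(allowed: {sorted(allowed)})")


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully resolved configuration for one run."""

    human: HumanSpec
    environment: Environment | None  # None when a CSV vector is used
    environment_csv: str | None
    options: SolveOptions
    output_path: str | None
    output_format: str


def human_from_dict(section: dict[str, Any]) -> HumanSpec:
    _reject_unknown("human", section, _HUMAN_KEYS)
    section = dict(section)
    nude = bool(section.pop("nude", False))
    ins_cfg = section.pop("insulation", None)
    tc_ref = section.pop("TC_REF", None)
    parts_cfg = section.pop("part_specs", None)
    kwargs: dict[str, Any] = {k: v for k, v in section.items()}
    if parts_cfg is not None:
        parts = []
        for p in parts_cfg:
            _reject_unknown("human.part_specs[]", p, _PART_KEYS)
            parts.append(BodyPartSpec(**p))
        kwargs["part_specs"] = tuple(parts)
    if tc_ref is not None:
        kwargs["TC_REF"] = {str(k): float(v) for k, v in tc_ref.items()}
    if nude:
        human = HumanSpec.nude(**kwargs)
    else:
        human = HumanSpec(**kwargs)
    if ins_cfg is not None:
        layers = {}
        for pid, layer in ins_cfg.items():
            _reject_unknown(f"human.insulation.{pid}", layer, _INS_KEYS)
            layers[pid] = InsulationLayer(**layer)
        human = replace(human, insulation_dorsal=layers, insulation_ventral=dict(layers))
    return human


def load_config(path: str | Path) -> RunConfig:
    """Load, validate, and resolve a YAML run config.

    Raises ``ValueError`` naming the offending key and section on any
    schema violation; logs the complete resolved parameter set.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _reject_unknown("<root>", raw, {"human", "environment", "options", "output"})

    human = human_from_dict(raw.get("human", {}) or {})

    env_section = dict(raw.get("environment", {}) or {})
    _reject_unknown("environment", env_section, _ENV_KEYS)
    env_csv = env_section.pop("csv", None)
    env = None if env_csv else Environment(**env_section) if env_section else None
    if env is None and env_csv is None:
        env = Environment(TA=21.0, VEL=0.1, RH=50.0)

    opt_section = dict(raw.get("options", {}) or {})
    _reject_unknown("options", opt_section, _OPTION_KEYS)
    options = SolveOptions(**opt_section)

    out_section = dict(raw.get("output", {}) or {})
    _reject_unknown("output", out_section, _OUTPUT_KEYS)
    fmt = out_section.get("format", "csv")
    if fmt not in ("csv", "json"):
        raise ValueError(f"output.format must be 'csv' or 'json', got {fmt!r}")

    cfg = RunConfig(
        human=human, environment=env, environment_csv=env_csv, options=options,
        output_path=out_section.get("path"), output_format=fmt,
    )
    log.info("resolved configuration:\n%s", dump_config(cfg))
    return cfg


def _human_to_dict(h: HumanSpec) -> dict[str, Any]:
    d: dict[str, Any] = {k: getattr(h, k) for k in sorted(_HUMAN_SIMPLE_KEYS)}
    d["TC_REF"] = dict(h.TC_REF)
    d["part_specs"] = [asdict(p) for p in h.part_specs]
    d["insulation"] = {pid: asdict(l) for pid, l in h.insulation_dorsal.items()}
    return d


def dump_config(cfg: RunConfig) -> str:
    """Serialize a resolved config back to YAML (round-trips via load)."""
    doc: dict[str, Any] = {"human": _human_to_dict(cfg.human)}
    if cfg.environment_csv:
        doc["environment"] = {"csv": cfg.environment_csv}
    elif cfg.environment is not None:
        doc["environment"] = {
            k: v for k, v in asdict(cfg.environment).items() if v is not None}
    doc["options"] = {"stop_at_core": cfg.options.stop_at_core, "band": cfg.options.band}
    doc["output"] = {"path": cfg.output_path, "format": cfg.output_format}
    return yaml.safe_dump(doc, sort_keys=True)
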