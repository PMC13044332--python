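"""Result tables and serialization.

Mirrors the solver's reporting surface: a whole-body ``balance`` record, a
``respire`` record, and per-part ``treg`` (thermoregulatory state), ``enbal``
(energy budget) and ``morph`` (morphometry) tables, written as CSV (one file
per table) or as a single JSON bundle.  Column order is stable and floats are
serialized at full precision so repeated runs are bit-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .anthropometry import silhouette_correction
from .part_balance import temperature_profile
from .thermoregulation import BodySolution

__all__ = [
    "balance_table",
    "respire_table",
    "treg_table",
    "enbal_table",
    "morph_table",
    "solution_tables",
    "write_outputs",
    "trunk_profile",
]

_BALANCE_COLUMNS = [
    "status", "T_core", "T_lung", "T_skin", "T_ins_dorsal", "T_ins_ventral",
    "pct_wet", "k_flesh", "water_cutaneous_L_h", "water_respiratory_L_h",
    "sweat_rate_L_h", "Q_gen", "Q_gen_net", "Q_min_effective", "Q_sol",
    "Q_rad", "Q_conv", "Q_cond", "Q_evap_cut", "Q_evap_ins", "Q_resp_conv",
    "Q_resp_evap", "iterations",
]


def balance_table(sol: BodySolution) -> pd.DataFrame:
    """Whole-body record: temperatures, wetness, water losses, heat flows."""
    row = {c: getattr(sol, c) for c in _BALANCE_COLUMNS}
    return pd.DataFrame([row], columns=_BALANCE_COLUMNS)


def respire_table(sol: BodySolution) -> pd.DataFrame:
    r = sol.respiration
    return pd.DataFrame([{
        "air_flow_L_h": r.air_flow_L_h, "O2_flow_L_h": r.O2_flow_L_h,
        "mol_air_in_s": r.mol_air_in, "mol_air_out_s": r.mol_air_out,
        "mol_O2_in_s": r.mol_O2_in, "mol_O2_out_s": r.mol_O2_out,
        "T_tract": r.T_tract, "T_exp": r.T_exp,
        "Q_resp_conv": r.Q_resp_conv, "Q_resp_evap": r.Q_resp_evap,
    }])


def treg_table(sol: BodySolution, part_id: str) -> pd.DataFrame:
    s, st = sol.parts[part_id], sol.states[part_id]
    return pd.DataFrame([{
        "T_core": s.T_core, "T_skin": s.T_skin,
        "T_ins_dorsal": s.T_ins_dorsal, "T_ins_ventral": s.T_ins_ventral,
        "pct_wet": st.pct_wet, "k_flesh": st.k_flesh,
        "k_ins_dorsal": st.dorsal.conductivity if st.dorsal.depth > 0 else 0.0,
        "k_ins_ventral": st.ventral.conductivity if st.ventral.depth > 0 else 0.0,
        "fat_factor": st.fat_factor,
        "Q10_multiplier": sol.Q_min_effective / sol.Q_min,
    }])


def enbal_table(sol: BodySolution, part_id: str) -> pd.DataFrame:
    s = sol.parts[part_id]
    return pd.DataFrame([{
        "Q_gen": s.Q_gen, "Q_sol": s.Q_sol, "Q_rad": s.Q_rad,
        "Q_conv": s.Q_conv, "Q_cond": s.Q_cond, "Q_evap_cut": s.Q_evap_cut,
        "Q_evap_ins": s.Q_evap_ins, "balance_residual": s.residual,
        "iterations": s.iterations, "converged": s.converged,
    }])


def morph_table(sol: BodySolution, part_id: str) -> pd.DataFrame:
    g = sol.geometries[part_id]
    zen = sol.environment.zenith
    return pd.DataFrame([{
        "mass": g.mass, "area_total": g.area_total, "volume": g.volume,
        "characteristic_dimension": g.characteristic_dimension,
        "fat_mass": g.fat_mass, "fat_thickness": g.fat_thickness,
        "flesh_volume": g.volume - g.fat_mass / 900.0,
        "length": g.length, "width": g.diameter, "height_midpoint": g.height_midpoint,
        "radius_to_skin": g.radius_to_skin,
        "radius_to_insulation": g.radius_to_insulation_surface,
        "area_skin": g.area_skin,
        "area_silhouette": g.silhouette_geometric(zen) * silhouette_correction(zen),
        "area_evaporative": g.area_evaporative, "area_joined": g.area_joined,
        "config_factor_sky": g.config_factor_sky,
        "config_factor_ground": g.config_factor_ground,
    }])


def trunk_profile(sol: BodySolution) -> pd.DataFrame:
    """Core-to-insulation-surface radial temperature profile of the trunk."""
    nodes = temperature_profile(sol.geometries["trunk"], sol.states["trunk"],
                                sol.parts["trunk"])
    return pd.DataFrame(nodes, columns=["node", "temperature"])


def solution_tables(sol: BodySolution) -> dict[str, pd.DataFrame]:
    out = {"balance": balance_table(sol), "respire": respire_table(sol)}
    for pid in sol.parts:
        out[f"{pid}.treg"] = treg_table(sol, pid)
        out[f"{pid}.enbal"] = enbal_table(sol, pid)
        out[f"{pid}.morph"] = morph_table(sol, pid)
    return out


def write_outputs(solutions: BodySolution | Sequence[BodySolution], out: str | Path,
                  fmt: str = "csv") -> list[Path]:
    """Write one solution (or a vector of them) to CSV files or a JSON bundle.

    CSV: one file per table, named ``<stem>_<table>.csv``; vector runs
    produce one row per condition, order preserved.  JSON: a single bundle
    keyed by table name.  Returns the written paths.
    """
    sols = [solutions] if isinstance(solutions, BodySolution) else list(solutions)
    out = Path(out)
    tables: dict[str, pd.DataFrame] = {}
    for sol in sols:
        for name, df in solution_tables(sol).items():
            tables.setdefault(name, []).append(df)
    merged = {name: pd.concat(dfs, ignore_index=True) for name, dfs in tables.items()}

    written: list[Path] = []
    if fmt == "csv":
        out.parent.mkdir(parents=True, exist_ok=True)
        for name, df in merged.items():
            path = out.parent / f"{out.stem}_{name.replace('.', '_')}.csv"
            df.to_csv(path, index=False, float_format="%.17g")
            written.append(path)
    elif fmt == "json":
        out.parent.mkdir(parents=True, exist_ok=True)
        bundle = {name: json.loads(df.to_json(orient="records", double_precision=15))
                  for name, df in merged.items()}
        out.write_text(json.dumps(bundle, indent=1, sort_keys=True))
        written.append(out)
    else:
        raise ValueError(f"unknown output format {fmt!r} (use 'csv' or 'json')")
    return written
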