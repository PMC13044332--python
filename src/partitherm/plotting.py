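"""Optional static plots: radial temperature profile, thermoneutral zone,
survivability maps.  Requires matplotlib (not a core dependency); every
function writes a file and returns the path."""

from __future__ import annotations

from pathlib import Path

from .io import trunk_profile
from .scenarios import SurvivalGrid, TNZResult
from .thermoregulation import BodySolution


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_temperature_profile(sol: BodySolution, out: str | Path) -> Path:
    """Core-to-clothing radial temperature profile of the trunk."""
    plt = _pyplot()
    prof = trunk_profile(sol)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(range(len(prof)), prof["temperature"], "o-", color="firebrick")
    ax.axhline(sol.T_core_trunk, ls="--", lw=0.8, color="grey")
    ax.set_xticks(range(len(prof)), prof["node"], rotation=20)
    ax.set_ylabel("temperature (°C)")
    ax.set_title("Radial temperature profile, trunk")
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def plot_thermoneutral_zone(res: TNZResult, out: str | Path) -> Path:
    """Metabolic demand, body temperatures, and wetness against air
    temperature, with the zone bounds marked."""
    plt = _pyplot()
    t = res.table
    fig, axes = plt.subplots(3, 1, figsize=(6, 7), sharex=True)
    axes[0].plot(t.TA, t.Q_gen_net, color="black", label="Q_gen,net")
    axes[0].plot(t.TA, t.Q_min_eff, ls="--", color="grey", label="Q_min,eff")
    axes[0].set_ylabel("W")
    axes[0].legend(frameon=False)
    axes[1].plot(t.TA, t.T_core, color="firebrick", label="core")
    axes[1].plot(t.TA, t.T_skin, color="steelblue", label="skin")
    axes[1].set_ylabel("°C")
    axes[1].legend(frameon=False)
    axes[2].plot(t.TA, 100 * t.wetness, color="seagreen")
    axes[2].axhline(2.0, ls=":", color="grey")
    axes[2].set_ylabel("skin wetness (%)")
    axes[2].set_xlabel("air temperature (°C)")
    for ax in axes:
        if res.LCT is not None:
            ax.axvline(res.LCT, ls="--", lw=0.8, color="navy")
        if res.UCT is not None:
            ax.axvline(res.UCT, ls="--", lw=0.8, color="darkred")
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def plot_survivability(grid: SurvivalGrid, out: str | Path,
                       wet_bulb_contours: tuple[float, ...] = (35.0, 37.0, 39.0)) -> Path:
    """Survivability map over TA x RH with the frontier and wet-bulb
    contours."""
    import numpy as np

    from .environment import wet_bulb

    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 4.5))
    with np.errstate(invalid="ignore"):
        core = np.ma.masked_invalid(grid.T_core)
    if core.count():
        pcm = ax.pcolormesh(grid.TA, grid.RH, core.T, cmap="inferno", shading="auto")
        fig.colorbar(pcm, ax=ax, label="steady core temperature (°C)")
    if len(grid.frontier):
        ax.plot(grid.frontier.TA, grid.frontier.RH, "c-", lw=2, label="frontier")
    wb_grid = np.array([[wet_bulb(float(ta), float(rh)) for ta in grid.TA]
                        for rh in grid.RH])
    cs = ax.contour(grid.TA, grid.RH, wb_grid, levels=wet_bulb_contours,
                    colors="lightblue", linestyles="dashed", linewidths=0.8)
    ax.clabel(cs, fmt="%.0f °C wb", fontsize=7)
    ax.set_xlabel("air temperature (°C)")
    ax.set_ylabel("relative humidity (%)")
    ax.set_title(f"Survivability ({grid.model} model)")
    if len(grid.frontier):
        ax.legend(frameon=False, loc="upper right")
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
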