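# partitherm

Steady-state heat-budget modelling of humans (and other hominins) as a
multi-part body: an ellipsoidal head and cylindrical trunk, arms, and legs,
each with lean tissue, a subcutaneous fat shell, and an optional clothing or
hair layer. Given a body specification and a microclimate, the solver finds
the metabolic rate, skin and clothing temperatures, sweating rate, and water
loss required for thermal homeostasis.

It is written for researchers in thermal physiology, climate–health, and
human evolution who need a physically explicit but fast model: one that
*solves for* metabolic rate, skin temperature, and clothing temperature
rather than requiring them as inputs, and that therefore behaves sensibly
in extreme or unusual environments where empirical shortcut models break
down.

## The model

For each body part, steady state requires

```
Q_gen − Q_resp,conv − Q_resp,evap − Q_evap,cut
      = Q_ins
      = Q_rad + Q_conv + Q_cond + Q_evap,ins − Q_sol
```

i.e. metabolic heat generation net of respiratory and cutaneous evaporative
loss must pass through the insulation layer and leave by longwave radiation
(dorsal surfaces exchange with the sky, ventral with the ground), mixed
free/forced convection, and any insulation-surface evaporation, less the
absorbed solar load on the silhouette area A_sil(zenith). Skin and clothing
temperatures are unknowns, found by nested bracketed root-finding; the
respiratory terms come from a molar ventilation balance driven by the
oxygen demand implied by Q_gen (oxyjoule equivalent, respiratory quotient,
extraction efficiency), closed by the root-find
`Q_gen − Q_resp(Q_gen) − Q_gen,net = 0`.

If the net generation required for balance falls below the minimum
allowable metabolic rate Q_min (heat strain), a thermoregulatory cascade is
engaged: peripheral vasodilation (flesh conductivity k_flesh rises toward
5 W m⁻¹ K⁻¹, controlling skin temperature near 35 °C), then a rising core
temperature with Q10 effects on the metabolic floor
(`Q_min,eff = Q_min · Q10^(ΔT/10)`), with sweating in parallel (skin
wetness w rising, evaporation efficiency `r = 1 − w²/2`, capped by a
maximum sweat rate). Above the core target ceiling the solver can continue
climbing to find the theoretical steady-state core temperature — the basis
of the humid-heat survivability analysis.

A minimal single-node fixed-skin reference model (skin pinned at 35 °C,
lethal core 43 °C, no Q10 effect) is included for comparison: it is the
model class whose survivability limit collapses onto the 35 °C wet-bulb
isopleth when sweating is non-limiting.

## Worked example

```python
from partitherm import HumanSpec, Environment, solve_human, trunk_profile

sol = solve_human(HumanSpec(), Environment(TA=21, VEL=0.1, RH=50))
print(sol.summary())
```

```
status: cold_compensating   iterations: 1
T_core  36.27 C   T_skin  28.73 C   T_ins  25.91/ 25.91 C
Q_gen   97.32 W   Q_gen_net   90.90 W   Q_min_eff  87.00 W
wetness   1.0 %   k_flesh  0.41 W/m/K   sweat 0.001 L/h
```

At 21 °C in near-still air the default lightly clothed 70 kg adult sits
just below its lower critical temperature: holding a 36.5 °C trunk core in
the fully vasoconstricted state requires 90.9 W of net heat production,
about 4 W above the 87 W resting minimum, with a mean skin temperature of
28.7 °C and clothing surface at 25.9 °C. The radial temperature profile of
the trunk (`trunk_profile(sol)`) reads core 36.50 → fat boundary 30.72 →
skin 26.77 → clothing surface 24.28 °C.

The thermoneutral zone for the same person
(`thermoneutral_zone(HumanSpec(), VEL=0.1, RH=50, TA_range=(0, 55))`)
spans LCT ≈ 21.9 °C (below which metabolism must rise; the rise is linear
in air temperature) to UCT ≈ 27.1 °C (above which skin wetness exceeds the
2% sweating-onset criterion).

The same things are available from the shell:

```
partitherm run --ta 21 --vel 0.1 --rh 50 --out run.json --fmt json
partitherm tnz --ta-min 0 --ta-max 55
partitherm survive --model hhb --vel 1.0
partitherm geometry
```

## Layout

- `anthropometry` — part sizing, body assembly, heights, silhouette areas
- `environment` — microclimate container, psychrometrics, air properties
- `part_balance` — the single-part steady-state solver
- `respiration` — ventilation molar balance and respiratory heat loss
- `thermoregulation` — whole-body loop and the effector cascade
- `scenarios` — thermoneutral zone, survivability grids, fixed-skin model
- `config` / `io` / `fixtures` / `cli` — YAML configs, result tables, named
  scenarios, command-line entry points
- `plotting` — optional static figures (requires the `plots` extra)

See `docs/methods.md` for the full account of the model, its defaults, and
its limitations.
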