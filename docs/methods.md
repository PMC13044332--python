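# Methods

This note documents the model implemented by `partitherm`: its physical
assumptions, the numerical choices, the default parameter set and why each
value was chosen, and what the synthetic test scenarios do and do not
demonstrate about real human data.

## Body geometry

The body is four part classes: a prolate-spheroid head and cylindrical
trunk, arms (×2), and legs (×2). Each part is sized in closed form from its
mass, tissue density, and a shape ratio `shape_b` (length:diameter for
cylinders; semi-major:semi-minor axis for the head): `V = πr²L` with
`L = 2r·shape_b`, or `V = (4/3)πab²` with `a = shape_b·b`, with the exact
eccentricity formula for the spheroid surface.

`assemble_body` distributes total mass by a proportion table, then closes
two global constraints:

1. **Stature.** The stacked lengths (legs + trunk + head) scale as
   `shape_b^(2/3)` at fixed volume, so a single closed-form rescaling of
   the stacked parts' shape ratios hits the target height exactly.
2. **Surface area.** Joining is the primary knob: each limb/head attachment
   removes equal area from the attaching part and from the trunk, and a
   common multiplier on the default attachment footprints is solved so the
   count-weighted exposed skin areas sum to the specified whole-body area
   (default: DuBois from mass and height) to 0.1%. Only when joining alone
   cannot close the area (unusual proportion tables) is a common shape-ratio
   multiplier root-found as a fallback, in which case the stature residual
   is the price paid; area closure is always the hard constraint.

Joined surfaces are treated as a zero-net-flux boundary at core
temperature: they are removed from convection, radiation, and evaporation,
implemented by confining radial conduction to the exposed sector of each
shell (resistances divided by the exposed-area fraction).

The default proportion table (head 7%/7%, trunk 50%/36%, per-arm 5.5%/9%,
per-leg 16%/19.5% of mass/area; shape ratios 1.6 / 2.1 / 8 / 6.5; densities
1050–1070 kg m⁻³; fat fractions 10–20%) is an editable stand-in assembled
from standard segment-mass and regional surface-area conventions; users
modelling a specific population should supply their own via
`BodyPartSpec`/YAML.

**Silhouette.** The geometric projection of each primitive toward the sun
(vertical cylinder: `πr²cos z + 2rL sin z`; vertical spheroid:
`πb√(a²sin²z + b²cos²z)`) overestimates the radiant load on a real
standing human. The ratio of the empirical standing-human projected area
(the classical azimuth-averaged function
`0.043 sin(alt) + 2.997 cos(alt)·√(0.02133 + 0.0091 sin²az)`, rescaled to
the body's surface area) to the geometric whole-body silhouette of the
default body is least-squares fitted as an 8th-order polynomial in
normalised zenith over 91 integer angles (max fit residual 0.0015; ratio
range 0.38–0.93) and shipped as versioned JSON. The correction is clamped
to (0, 1.5] and applied multiplicatively; it is strictly valid for bodies
of roughly default proportions — a documented approximation for others.

## Microclimate and psychrometrics

One `Environment` holds air temperature, wind, relative humidity, sky and
ground radiant temperatures (defaulting to air temperature — the indoor
setting), direct/diffuse solar with zenith angle, ground reflectance,
pressure (default 101325 Pa; altitude via user-supplied pressure only), and
the breathed gas composition. A single saturation-vapour-pressure
formulation (Buck 1996, valid −40…110 °C) is used everywhere — skin,
clothing, respiration, wet bulb — because internal consistency of vapour
gradients matters more than the third decimal of any one formulation.
The thermodynamic wet bulb solves the adiabatic-saturation equation
`(w_s(Twb) − w)·λ(Twb) = cp_moist·(TA − Twb)` by bracketed root-finding.
Air properties are smooth correlations: Sutherland viscosity, linear-in-T
conductivity fit, ideal-gas density, power-law water-vapour diffusivity.

Per-part microclimates (`EnvironmentProfile`) are either user-supplied or
one condition broadcast to all parts; no internal boundary-layer profile is
generated.

## The single-part solver

Unknowns: skin temperature (one per part) and, for each clothed side, the
insulation surface temperature. Structure: an outer bracketed scalar
root-find on skin temperature (bracket `[min(env temps, T_core) − 10,
max(env temps, T_core) + 15]` °C, widened up to three times under strong
solar loads, tolerance 10⁻⁶ °C) with, per clothed side, an inner root-find
for the surface temperature balancing conduction through the clothing
against convection, longwave radiation, and absorbed solar. Design
choices:

- **Tissue conduction.** Metabolic heat is generated uniformly in the lean
  tissue: centre-to-surface resistance `1/(4πkL)` for cylinders and
  `1/(8πkr)` for the sphere-equivalent head (equal-volume shells; the
  error of the sphere mapping is second-order for head shape ratios near
  1.6). The subcutaneous fat shell (adipose conductivity 0.16 W m⁻¹ K⁻¹)
  is a series shell resistance.
- **Radiation.** Full Stefan–Boltzmann, no linearisation; emissivity 0.98
  for skin and clothing. The exposed area splits dorsal/ventral by the
  configuration factors (default 0.5/0.5): dorsal exchanges with the sky
  temperature, ventral with the ground.
- **Solar.** Absorbed at the exposed surface (beam on the corrected
  silhouette plus diffuse on the dorsal area; ground-reflected global on
  the ventral area), with solar reflectance 0.3 by default.
- **Convection.** Mixed free/forced: Churchill–Bernstein (cylinder
  crossflow) or Whitaker (sphere) for the forced branch, Churchill–Chu
  (cylinder) or Churchill (sphere) for the free branch, combined as
  `Nu = (Nu_free³ + Nu_forced³)^(1/3)`, diameter as the characteristic
  dimension. The correlations sit behind `convective_coefficient` and are
  swappable; a constant-h injection hook exists for verification.
- **Evaporation.** Lewis-relation mass transfer,
  `h_m = h/(ρ cp Le^(2/3))`, with the vapour-density driving force formed
  from the vapour-pressure difference at the film temperature. This is
  equivalent to a mole-fraction driving force and keeps the model
  consistent with the thermodynamic wet bulb (a fully wet surface
  equilibrates near the ambient wet-bulb temperature) and with the
  respiratory molar balance; evaluating each vapour density at its own
  temperature instead would systematically weaken evaporation in very hot
  air. Covered skin evaporates at `pct_bare_evap` (default 0.3) of the
  free rate — the clothing vapour path collapsed into one factor.
  Insulation-surface evaporation (soaked clothing) defaults to zero.
- **No substrate conduction** (standing posture; `Q_cond` is reported but
  always zero) and no panting.

Every converged part balances to ≤ 0.01 W (property-tested over 500 random
environment/state draws); the solver is deterministic.

## Respiration

Ventilation is driven by oxygen demand: `V̇O₂ = Q_gen / oxyjoule(RQ)` with
the oxyjoule equivalent 19.6–21.1 J mL⁻¹ linear in RQ (default RQ 0.85 →
20.35 J mL⁻¹), inspired dry-gas flow `= n_O₂ / (f_O₂ · extraction)`
(default extraction 0.20), CO₂ production `RQ·n_O₂`, expired air saturated
at the expired-air temperature. Dry-gas fractions are applied after
removing vapour; vapour rides on top of the dry flows. The respiratory
tract sits halfway between the core and the trunk's fat boundary; expired
air is the cooler of the tract temperature and the air/tract mean. The
sensible term warms inspired moist air to the expired temperature; the
latent term is the molar vapour difference times the molar latent heat.
`Q_gen − Q_resp(Q_gen) = Q_gen,net` is closed by a bracketed root-find to
10⁻⁶ W (the dependence is linear, so the root is unique).

## The whole-body cascade

Each iteration solves all four parts (limbs once, doubled), sums the net
generation, and compares it with the Q10-inflated minimum metabolic rate.
`Q_gen,net > Q_min,eff`: cold compensation (the reported elevation is the
model's cold-stress estimate). Within `[Q_min,eff, Q_min,eff + 0.5 W]`:
balanced. Below: heat strain, and the effectors step, states persisting
across iterations:

1. **Vasomotor.** The flesh conductivity always steps up under strain
   (from the vasoconstricted floor 0.412 W m⁻¹ K⁻¹ toward the ceiling
   5 W m⁻¹ K⁻¹), with the step driven by the solved skin temperature: a
   3k step (k→4k) while aggregate skin is below the 35 °C control point,
   a gentle 0.5k step (k→1.5k) once near or above it — so the skin
   approaches 35 °C softly and, under sustained heat strain, is held in
   the 34–36 °C band (property-tested). When a step overshoots the balance
   band the solver bisects back in log space, making the vasomotor
   equilibrium deterministic and exact to the band. Above 0.5 W m⁻¹ K⁻¹
   (the constriction/dilation transition) the fat shell's influence ramps
   linearly to zero at the ceiling: dilated blood flow bypasses the fat.
2. **Core rise.** Once conductivity saturates, every part's core target
   steps up together (default 0.1 °C per iteration) toward TC_MAX
   (default 38 °C), with `Q_min,eff = Q_min · Q10^(ΔT/10)` (Q10 = 2) using
   the trunk target as reference. Resting targets are part-specific
   (head/trunk 36.5, arms 35.0, legs 36.7 °C).
3. **Sweating (parallel).** Whenever a part's skin is within 2 °C of its
   core target its wetness steps up (default 1 percentage point per
   iteration, baseline 1%); above 35 °C skin the step is 10× and the core
   target is additionally incremented. Wetness is capped at 100% and by
   the maximum sweat rate (default 1.5 L h⁻¹) through the evaporation
   efficiency `r = 1 − w²/2` (dripped sweat does not cool). When the
   sweat cap binds, wetness freezes and the solution is flagged
   sweat-limited.
4. **Beyond TC_MAX.** With `EXCEED_TCMAX` (default on) and the faster
   effectors exhausted, the core continues climbing to find the
   theoretical steady state, up to MAXITER (500) and a hard 60 °C ceiling
   (beyond which no physically meaningful steady state exists and the
   psychrometric formulations leave their validity range). With the flag
   off, the solve returns with heat storage implied.

Statuses: `cold_compensating`, `thermoneutral` (balanced by vasomotor tone
alone), `regulating_heat` (balanced with active sweating or an elevated
core), `storage_implied`, `max_iter`. The discrete cascade is
path-dependent: along a rising-temperature sweep the steady core is
monotone only to within about two core steps, because the 10× wetness ramp
above 35 °C skin can balance a hotter cell at a marginally lower core.
Whole-body budgets close to ≤ 0.05 W.

The default minimum metabolic rate is 87 W — the classic resting heat
production of a ~1.8 m² adult; raise it for activity. Default light
clothing is 2–3 mm at 0.042 W m⁻¹ K⁻¹ (≈0.5 clo overall) with 3 mm of
hair (0.05 W m⁻¹ K⁻¹) on the head; `HumanSpec.nude()` strips all layers.
The baseline skin wetness is 1% (insensible diffusion): it must lie below
the 2% sweating-onset criterion that defines the upper critical
temperature, which is why a larger "standard" 6% baseline is not usable
here.

## Scenarios

**Thermoneutral zone.** A sweep of air temperature at fixed wind and
humidity. LCT: the highest air temperature at which net generation exceeds
the minimum beyond tolerance (linearly interpolated at the crossing);
UCT: the lowest at which aggregate wetness exceeds 2%. Inside the zone the
metabolic rate is pinned at the minimum by vasomotor adjustment. For the
default person at 50% RH and 0.1 m/s: LCT ≈ 21.9 °C, UCT ≈ 27.1 °C.

**Fixed-skin reference model.** One tissue node, skin pinned at 35 °C.
Dry exchange is convective (area-weighted film coefficient over the real
assembled geometry), with radiation entering only as an additive offset —
zero when the mean radiant temperature equals air temperature. That is the
defining simplification of this model class; resolving full T⁴ exchange
with 50–60 °C surroundings would not be faithful to it and drags its
frontier about 2 °C of wet bulb below the 35 °C isopleth. The inferred
steady core is the fixed skin plus the normal resting gradient (2 °C) plus
any uncompensable surplus divided by the tissue conductance (10 W K⁻¹);
the cell is non-survivable when that core reaches 43 °C. With sweating
non-limiting the frontier tracks the 35 °C wet-bulb isopleth (mean 35.07,
SD 0.17 °C over the standard grid). `feed_skin_temperature` replaces the
fixed skin with the full model's solved aggregate skin, cell-wise.

**Survivability grids.** Nude human, 1 m/s wind, air temperature 35–60 °C
(0.5 °C steps) × RH 1–100% (1% steps), radiant temperatures equal to air.
Full model: `EXCEED_TCMAX` on with the climb truncated at 43.5 °C (only
the lethal crossing matters); a cell is certified survivable only when the
cascade converges with core < 43 °C *and* skin ≤ 40 °C — hotter-skin
solutions are outside the model's certified domain, and at lethal-core
cells the fully dilated skin always sits within ~1 °C of the core, so the
certified boundary is the only coherent frontier (each frontier row
records which criterion bound it, and whether the evaporative limitation
was environmental capacity or sweat production). Because the certified
region is contiguous downward in humidity (a property-tested invariant),
the frontier is located by per-temperature bisection over the humidity
grid — identical to the exhaustive scan (also tested) at ~8 solves per
temperature instead of 100. On the standard grid the full model's
frontier spans 40–60 °C air temperature with wet bulbs 37.1–39.2 °C
(sweat-limited at the hot-dry end), against the fixed-skin model's ≈35 °C.

## What the synthetic scenarios do not show

All tests run on synthetic environments and the stand-in default body; no
empirical human data ships with the package. Passing tests therefore
demonstrate internal correctness — energy closure, oracle agreement,
cascade behaviour, the structural contrast between the two model classes —
not quantitative fidelity to any measured subject. Real validation
requires measured microclimates and subject-specific parameters
(proportions, clothing conductivities, sweat capacities), all of which are
inputs. Other known limitations: strictly steady-state (exposures of order
1–8 h; no transient storage dynamics), standing posture only, no substrate
conduction, fibre-based insulation theory out of scope (clothing/hair
conductivity is a direct input), the silhouette correction is fitted to
the default proportions, and behavioural thermoregulation is not
modelled.

## Problem sizes used in the shipped analyses

The acceptance script runs both survivability analyses at the full
0.5 °C × 1% resolution (the fixed-skin model over all ~5,100 cells; the
full cascade via the bisected frontier, ~400 whole-body solves). The test
suite exercises 500 random part-level closures, a 60-condition whole-body
closure sweep, coarse thermoneutral-zone and survivability grids, and the
full-resolution frontier checks; the complete suite runs in well under a
minute on one CPU.
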