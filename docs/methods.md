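# Methods

This note documents the model equations, numerical choices, default
parameters and known limitations of `beachox`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Domain and grid

The cross-section spans 240 m horizontally (x from −50 m landward of the
mean high-water line, mHWL, to +190 m seaward; 300 columns × 0.8 m in the
full configuration) and 2.4 to −40 m asl vertically (90 layers). Vertical
spacing grows geometrically from 0.05 m at the surface, capped at 1.7 m;
the growth ratio is solved so the layers tile the extent exactly. Cells
whose centre lies above the local sediment surface are inactive; each
column's top active cell carries the surface boundary face. All volumes
are per metre of shoreline (m³ m⁻¹).

Topography is planar at the seasonal mean slope (1.9 % summer, 1.7 %
winter, mHWL at 1.37 m asl), with a cosine-tapered depression (default
0.1 m deep, 50–65 m seaward of the mHWL) on the summer berm — smooth, so
the flow solver sees a differentiable surface. Arbitrary profiles can be
supplied as two-column CSV.

Three geological layers: beach sands over tidal-flat deposits (K = 6.25
m d⁻¹) over glacial sands (K = 46 m d⁻¹), with planar interfaces at −4
and −12 m asl (the field geometry is known only graphically; planar
interfaces at these elevations preserve the layer ordering and
thicknesses). Within the beach sand, K decays with depth over the upper
metre, `K(d) = K₀ e^(−d/z*)`, reflecting grain-size (d10, Hazen
`K[cm/s] = 100·d10[cm]²`) profiles; defaults K₀ = 35 m d⁻¹, z* = 1.2 m,
held at K(1 m) ≈ 15 m d⁻¹ below. Retention: van Genuchten–Mualem with
α = 3.5 m⁻¹, n = 3, S_r = 0.05, φ = 0.35 — a standard medium-sand set
(the source retention table is not public); all configurable.

## Flow solver

Mixed-form Richards equation, cell-centred finite volumes, two-point
flux with harmonic saturated conductivity and upstream-weighted relative
permeability, modified-Picard (Celia-type) implicit stepping with a
specific storage of 10⁻⁴ m⁻¹ keeping saturated regions well-posed.
Convergence: max |Δψ| < 5·10⁻⁴ m; the update is damped by 0.5 whenever
it grows, which settles boundary-face flips; time steps halve on
failure (bounded retries).

Boundary conditions:

* **Beach face** (per column, re-evaluated every Picard iteration):
  prescribed head = sea level where submerged; where emerged, a one-way
  drain with flux `conductance · max(h − z_surf, 0)` — the continuous
  form of a seepage face (ψ = 0, outflow only). The continuous drain
  was chosen over discrete face switching with a hysteresis counter
  because the latter produced Picard limit cycles.
* **Landward**: freshwater influx Q_in = 0.51 m³ m⁻¹ d⁻¹ distributed
  over the saturated part of the boundary column.
* **Bottom and seaward wall**: no-flow.

Forcing: `sea(t) = A·sin(2πt/T) + s·H_s` with A = 1.37 m, H_s = 0.59 m,
setup factor s = 0.2. The default period is the semidiurnal M2
(12.42 h), the physically correct regime for a Wadden Sea beach;
configurable. Initial condition: hydrostatic, saturated below the high
water line. Cycles are iterated until the end-of-cycle head field
changes by < 10⁻³ of the tidal range (floored at 0.1 m so the
vanishing-tide limit remains defined); typically 25–45 cycles. The flow
product is one cycle of interval-mean face fluxes (50 intervals) plus
water contents at the interval edges, so the transport stage sees a
discretely water-conservative field; the cycle water balance closes to
a few 10⁻⁴ of the gross flux.

## O₂ transport

O₂ (µmol L⁻¹ ≡ mmol m⁻³) is advected, dispersed, consumed and
re-aerated on the replayed flow cycle:

* **Advection** — explicit first-order upwind on water masses,
  sub-stepped to CFL ≤ 0.9; inflowing beach-face water carries the
  seasonal air-saturated concentration C_sat (225 µmol L⁻¹ summer, 310
  winter), landward freshwater enters O₂-free (configurable). Water
  volumes evolve linearly between the flow field's interval edges, so
  advection is exactly mass-conservative.
* **Dispersion** — implicit, with the diagonal part of the
  velocity-dependent tensor (α_L = 0.1 m, α_T = 0.01 m) plus molecular
  diffusion D_m = 1.5·10⁻⁴ m² d⁻¹ with Millington–Quirk tortuosity
  θ^(7/3)/φ². Off-diagonal tensor terms and boundary dispersive flux
  are neglected (advection dominates at the face). Because the flow
  cycle repeats, each snapshot's operator is LU-factorised once and
  reused across cycles.
* **Consumption** — `R(z)·C/(C+K_O2)` with z the depth below the local
  sediment surface (rates were measured as sediment profiles).
  Seasonal defaults: summer R₀ = 50, winter R₀ = 12 µmol L⁻¹ h⁻¹, both
  z_R = 0.15 m, floors R_∞ = 0.19/0.1 µmol L⁻¹ h⁻¹, K_O2 = 1 µmol L⁻¹.
  The floors are the published seasonal deep rates; R₀ and z_R are set
  so the depth-integrated upper-layer demand matches the reported
  upper-layer OC remineralization (an integral constraint, chosen once).
* **Aeration** — `k_aer(C_sat − C)` wherever the interval-mean
  saturation is below 0.97, k_aer = 10 h⁻¹ ("rapid equilibration"; the
  e-folding is 6 min against a 12.4 h cycle, so results are insensitive
  to the exact rate). Consumption proceeds simultaneously.
* **Reactions** are integrated semi-analytically per cell (exact for
  the linearised aeration–consumption ODE), which is stiff-safe at the
  default k_aer; the budget uses the same closed form, so the cycle O₂
  budget (supply − consumption − outflow − storage) closes to numerical
  precision and the test suite asserts < 2 %.

Quasi-steady termination follows the 0.1 % oxic-volume criterion, but
applied to the *tide-averaged* oxic volume and required for 3
consecutive cycles: the raw end-of-cycle volume is quantised in units of
whole cells and can trigger the criterion spuriously during slow deep
growth (observed as a 40 % oxic-volume spread between time-step choices
before the change). Convergence takes ~100 cycles (summer) to ~260
(winter, finer grids) from a zero-O₂ start; warm starts are supported.

## Diagnostics

* Oxic zone: cells with C > 1 µmol L⁻¹ (strict), bulk volume, excluding
  sand that is unsaturated at every snapshot (permanently unsaturated,
  above the HWL). Pore-volume convention available via a flag.
* Penetration depth: per column, surface to the bottom face of the
  deepest oxic cell; reported at its maximising column.
* Infiltration partition: per-column cycle-mean boundary flux;
  "intertidal" means surface between low- and high-water levels; the
  fraction is weighted by sloping face length.
* Desaturated layer: low-tide snapshot, intertidal cells with S < 0.97.
* Station comparison: bilinear sampling at (x, depth), R² of the
  model = measurement line (1 − SS_res/SS_tot, not clipped).

## Carbon budget

Respiration quotient 106 C : 138 O₂ (106 for C oxidation + 32 for
nitrification of the OM nitrogen, C:N = 106:16); molar mass of C
12.011 g mol⁻¹. OC = supply·(106/138)·12.011; DIC = OC/12.011. The
nitrate estimate is exposed under both conventions — 1 NO₃ per
nitrification-O₂ (32/138 of supply; consistent with the published
seasonal range) and the textbook 2 O₂ per NO₃ (half of it). Reactive
DOC uses seasonal seawater DOC (180/140 µmol L⁻¹) minus the 80 µmol L⁻¹
refractory background; POC closes the balance, floored at zero. TOC
sustenance uses a dry bulk density of 1600 kg m⁻³ (not stated in the
source; typical beach sand). The per-area rate divides by a 61 m USP
footprint width (the width implied by the published per-metre and
per-area rates); it is logged, not asserted.

## Synthetic data

Generators are pure functions of (parameters, seed): seasonal
topography; d10 profiles inverting the Hazen relation from a K(z) decay
(lognormal noise); rate profiles sampled at a microprofile design
(centimetre spacing near the surface — this placement, together with a
log-space fit, is what makes the decay length identifiable at 10 %
noise); station observations from a model field with range-scaled
normal noise. The rate-profile floor R_∞ is structurally
unidentifiable from 0–70 cm samples (the exponential term still exceeds
the floor at 70 cm), so recovery checks cover R₀ and z_R; fits report a
`capped` flag for depth-flat profiles.

What the generators do **not** emulate: measured (non-planar) beach
profiles, spring–neap modulation, storms, within-layer heterogeneity,
salinity. Passing tests therefore demonstrate correct mechanics and
realistic seasonal contrasts, not agreement with any particular survey.

## Problem sizes

Three packaged grid scales: `paper` (90 × 300, the full configuration;
a complete seasonal pair takes hours on one CPU), `mid` (45 × 150, full
40 m depth; ~3 min per scenario) and `desk` (30 × 100, 30 m depth;
~1 min per scenario). The test suite runs the desk scale for the
seasonal-physics checks and the mid scale for the budget-reproduction
checks; `scripts/acceptance.py` uses the desk scale. Flow uses 50
snapshot intervals per cycle with one implicit step each (results agree
with 3 steps per interval to ~0.3 % in oxic volume).

## Known limitations

* No density coupling or salinity; single-phase Richards flow (no air
  phase), no vapour or temperature transport.
* Planar topography under-represents the measured seasonal profile
  difference: the winter/summer infiltration contrast comes out ~7 %
  rather than the reported ~35 %, and total O₂ supply is correspondingly
  high; deep-oxycline depths overshoot at the reduced scales the suite
  runs (penetration is the quantity most sensitive to the supply
  excess). The aeration-off contrasts and seasonal directions are
  robust to this.
* First-order upwind advection is diffusive; oxic-volume magnitudes at
  the desk scale carry O(10 %) discretisation effects (the mid scale
  shifts summer oxic volume by ~+20 %).
* The aeration threshold (S < 0.97) combined with the retention curve
  sets the aerated fringe thickness; with the default α = 3.5 m⁻¹ the
  fringe above the water table is ~10 cm.
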