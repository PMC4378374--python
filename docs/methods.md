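# Model description and methods

## Overview

`evoplankton` simulates the assembly and evolution of a phytoplankton
community in a seasonally forced 1-D water column.  Three layers make up
the model:

1. an **ecological food web** — a size-structured
   nutrient–phytoplankton–zooplankton (NPZ) system with variable internal
   stores (Droop) phytoplankton physiology, allometric trait scaling, and
   size-selective grazing;
2. a **physical column** — vertical diffusion, sinking and light
   attenuation under an idealized high-latitude seasonal cycle;
3. an **adaptive-dynamics engine** — trait evolution of phytoplankton
   cell volume by repeated rare-mutant invasion trials.

## Ecological model

### State vector

Per depth level the model integrates 4 dissolved nitrogen pools (NO3,
NO2, NH4, DON), 4 dead-organic pools (small and large detritus, each in
C and N), and 3 tracers per plankton species (carbon biomass, nitrogen
biomass, chlorophyll — the chlorophyll equation has no sources for
grazers and stays at zero).  The per-level system therefore has
`3 n_phyto + 3 n_zoo + 8` coupled equations: 59 at 8 phytoplankton and
9 zooplankton species, 275 at 80 phytoplankton.

### Phytoplankton physiology

Growth is decoupled from the external nutrient concentration through the
cell quota Q = N-biomass / C-biomass (mol N per mol C):

    uptake = V_max · (Q_max − Q)/(Q_max − Q_min) · N/(N + K_N)
    growth = µ_max · γ_T(T) · γ_I(I) · (Q − Q_min)/(Q_max − Q_min)

γ_T is an Eppley exponential, `exp(k (T − T_ref))` with k = 0.0639 /°C
(Q10 ≈ 1.9), equal to 1 at T_ref = 10 °C; γ_I is the saturating form
`1 − exp(−I/I_k)` with I_k = 25 W m⁻².  Nitrate is withheld from
Prochlorococcus; the three dissolved inorganic forms otherwise share one
Michaelis–Menten saturation on their sum, apportioned by concentration.
Chlorophyll is synthesized in proportion to nitrogen uptake
(1.6 mg Chl per mmol N) and lost with the same specific rates as
biomass; it feeds back on the light field through self-shading.

Every trait is a power law of cell volume, `log10 x = a + b log10 V`.
The constants are configuration data
(`evoplankton/data/default_params.yaml`), chosen from the standard
trait-allometry literature (Litchman-type uptake kinetics,
Menden-Deuer & Lessard carbon content): uptake capacity per unit carbon
falls with volume, the half-saturation constant and sinking speed rise,
and the maximum growth rate falls with a per-functional-type intercept
(diatoms fastest, Prochlorococcus slowest).  Under these choices the
critical nutrient concentration N* — the concentration at which growth
balances the mortality m, the analogue of Tilman's R* —

    Q* = (Q_max − Q_min) m / µ_max + Q_min
    N* = K_N µ_max (Q* − Q_min) Q* / [V_max (Q_max − Q*) − µ_max (Q* − Q_min) Q*]

increases monotonically with cell volume within every functional type,
so nutrient competition alone always favours the smallest cells.  N* is
evaluated at γ_T = γ_I = 1; the realized threshold under light or
temperature limitation is higher.  The closed form is verified in the
test suite against long integrations of the 0-D grazer-free Droop system
(relative agreement ≤ 1e-6 over randomized parameter sets).

### Grazing

Nine zooplankton species with fixed, log-spaced body volumes graze both
phytoplankton and strictly smaller grazers (intra-guild predation).
Prey selectivity is log-normal in the predator:prey volume ratio,
centred on ρ_opt = 1000 with width σ = 0.6 (ln-units), normalized to
peak 1.  Ingestion follows a Holling type-3 response on the
palatability-weighted prey biomass A:

    I = I_max · Z · A² / (A² + k_A²)

apportioned across prey by weighted biomass share.  A fraction β = 0.3
is assimilated; the rest becomes detritus.  The default grazer volumes
(10² … 10¹⁰ µm³ in decade steps) put the optimal prey volumes at
0.1 … 10⁷ µm³, covering the whole phytoplankton size range and creating
a log-periodic grazing background with refuges (local minima) between
the peaks — the central top-down structure of the model.

### Closure and recycling

Phytoplankton die at a size-independent background rate m = 0.05 d⁻¹.
Zooplankton carry a quadratic closure mortality by default.  This is a
deliberate design choice: with a linear closure this parameterization
produces multi-annual predator–prey cycles, while the invasion-trial
machinery requires the ecological attractor to be annually periodic
(fitness integrates exactly one seasonal cycle).  Quadratic closure
entrains the community to the annual forcing within 10–20 years; the
linear form remains available (`foodweb.zoo_mortality: linear`).

Dead organic nitrogen is remineralized along
PON → DON → NH4 → NO2 → NO3 (solubilization, remineralization,
two-step nitrification), all first-order.  Losses from organisms larger
than 10⁵ µm³ enter the fast-sinking large-detritus pool (10 m d⁻¹), all
others the slow pool (1 m d⁻¹).  Nitrogen is transferred strictly
pool-to-pool, so the biological tendencies conserve total nitrogen to
machine precision; carbon is not closed (respiration and detrital carbon
decay leave the system, there is no inorganic carbon pool).

## Physical column

The default grid covers 3275 m with 35 geometrically stretched levels
(5 m at the surface), resolving the euphotic zone.  The seasonal forcing
is an idealized Norwegian-Sea-like cycle on a 365-day year: surface
irradiance 5–250 W m⁻², surface temperature 3–10 °C over a 2 °C deep
ocean, and a mixed-layer depth moving smoothly (log-cosine) between
25 m in summer and 500 m in late winter.  Diffusivity is
10⁴ m² d⁻¹ inside the mixed layer and 0.5 m² d⁻¹ below.  Forcing is
tabulated per calendar day and strictly annual-periodic.

Time stepping is operator-split at dt = 0.05 d (0.1 d in the reduced
preset): explicit biology, backward-Euler flux-form vertical diffusion
(unconditionally stable; conserves every column integral to solver
precision), then upwind sinking with automatic CFL sub-stepping.  The
bottom boundary is closed; phytoplankton sinking through it is routed to
the deepest large-detritus cell so the budget stays closed.  Gross
consumption fluxes are limited per source pool so one explicit step
cannot overdraw a pool; residual negative values are clipped and every
clip or quasi-extinction floor addition is logged in nitrogen units, so
the audit `total N − injected` is conserved (≤1e-8 relative per decade
in the acceptance tests).  The floor (1e-15 mmol C m⁻³ per level, with
nitrogen topped up to the minimum quota) mimics immigration from
surrounding waters and keeps every species invasible.

## Evolutionary model

Cell volume is the single evolving trait; all physiological traits
follow it through the allometric rules.  Every cycle (1 evaluation year
+ 2 relaxation years):

1. each resident spawns two rare mutants at V·(1 ± 0.1), clamped to the
   functional-type volume range;
2. mutants are introduced on the first day of the model year with
   biomass/quota depth profiles cloned from the resident (scaled by
   1e-6; the scale cancels in the fitness and the passive-tracer design
   makes it irrelevant) and integrated for exactly one annual cycle as
   **passive tracers**: they experience the residents' nutrient fields,
   light and grazer saturation through identical formulas — including
   the flux limiters — but contribute nothing back;
3. invasion fitness is s = log(B(t+1)/B(t)) with B the column-integrated
   carbon biomass; the resident's own annual log-growth (close to, but
   not exactly, zero) is the reference;
4. if exactly one mutant beats the resident, the resident inherits the
   winning trait in place (attractor inheritance), its depth profiles
   untouched; if both beat it (disruptive selection) the fitter mutant
   wins and the event is flagged — lineage branching is outside the
   scope of this algorithm; ties and double losses leave the trait
   unchanged.

Because a clone of the resident follows bit-compatible per-capita
dynamics, its fitness equals the resident's annual growth rate to
rounding error; on the attractor both are numerically zero (≤1e-6 in
the acceptance test, ~1e-14 in practice).  Singularities are classified
by one extra probe trial per side: stabilizing → continuously stable
strategy (CSS), disruptive → evolutionary branching point (EBP).  On a
CSS whose optimum falls between two 10 % steps, the resident flip-flops
between the adjacent volumes — an evolutionary oscillation with a
period of two cycles (6 years) that is an artefact of the fixed step
size, and the probe classification at either endpoint reads
"directional" toward the other.

## Simulation protocol

A run seeds n ∈ {8, 20, 40, 80} phytoplankton species round-robin over
the four functional types, volumes log-uniform within each type range,
all plankton at 6e-9 mmol C m⁻³ uniformly in depth, starting in January
(day 0).  Phase 1 (100 years, fixed traits) sorts the community onto an
ecological attractor; phase 2 (250 years) runs the evolution engine.
Ensembles (default K = 24 seeds) are summarized by species richness
(threshold 1e-3 mmol C m⁻² column-integrated), Pielou evenness over 100
log-spaced size classes, and the intra-group mean square Canberra
distance to the ensemble-mean size distribution.  The Shannon indicator
is implemented with the conventional minus sign (entropy), normalized
by ln 100, so values lie in [0, 1] and larger means more even.
Canberra distances default to normalized biomass shares so runs of
different total biomass are comparable; a raw-biomass mode is available.

### Problem sizes used in the shipped tests and acceptance script

The full protocol (35 levels, 3275 m, 100 + 250 years, K = 24) is hours
of compute per ensemble; it is exposed through the CLI
(`evoplankton run --preset paper`, `evoplankton ensemble`).  The test
suite and `scripts/acceptance.py` run the same model at reduced sizes,
chosen as the smallest configurations that still exhibit the phenomena:
a fully ventilated 400-m, 10-level column (winter mixing reaches the
bottom, so the attractor is approached in a few years) for the
conservation, self-invasion and directional-selection checks, and a
desk preset (12 levels, 600 m, 15 + 75 years, 8 species) for the
two-phase protocol.  At this scale the runs reproduce the qualitative
results — fast ecological convergence (~5 years), an evolved community
of ~4 species in distinct grazing refuges, no branching points, and the
6-year trait oscillation — but not the full-size ensemble statistics,
which require the `paper` preset and hours of compute.

## What the idealized forcing does and does not emulate

The forcing generator reproduces the phenomenology that drives the
dynamics — strong annual cycles of light and temperature, deep winter
convection, summer stratification — not any particular reanalysis; real
Norwegian Sea profiles differ in detail (storm events, interannual
variability, lateral advection are absent).  Consequences: the model
attractor is exactly annually periodic (by construction), blooms are
smoother than observed, and the grazer seasonal peak follows the
phytoplankton peak with a short lag rather than the broader observed
phase structure.  Passing tests therefore demonstrate internal
consistency of the method and the qualitative top-down/bottom-up
selection structure, not quantitative fidelity to the Norwegian Sea.

## Numerical choices and degenerate inputs

* Pool-limiter: all outfluxes of an overdrawn source pool are scaled by
  a common factor, preserving the closed budget exactly; probes apply
  the identical factor so clones stay exact.
* Grazing with zero total palatability-weighted prey yields exactly
  zero flux (no division by zero); a prey with zero palatability
  receives zero flux regardless of biomass.
* Quota used in rate laws is clipped to [Q_min, Q_max]; mass bookkeeping
  always uses the actual N (no mass is created by clipping).
* An extinct mutant (B(t+1) ≤ 0) gets fitness −∞; exact fitness ties are
  treated as non-invading (replacement requires strict improvement).
* If both mutants are clamped away by the type range the event is
  logged and treated as stabilizing.
* Diffusion shares one tridiagonal factorization across all tracers;
  probes are solved separately so resident trajectories are
  bit-identical with and without probes present.

## Known limitations

* Single limiting element (N); no P, Fe or Si co-limitation.
* Zooplankton traits are fixed; no predator–prey coevolution.
* Disruptive selection cannot branch lineages; the engine flags it and
  continues monomorphically per lineage.
* The discrete grazer spectrum imposes the log-periodic grazing
  background; a continuous spectrum would smooth the refuges and likely
  change the evolved size structure.
* The chlorophyll tracer is a fixed-ratio bookkeeping of nitrogen
  uptake, not a photoacclimation model.
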