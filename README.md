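# evoplankton

Eco-evolutionary modelling of marine phytoplankton size structure: a
size-structured nutrient–phytoplankton–zooplankton (NPZ) food web in a
seasonally forced 1-D water column, coupled to an adaptive-dynamics
engine that evolves phytoplankton cell volume by repeated rare-mutant
invasion trials.

## The scientific problem

Why do phytoplankton communities sustain a wide range of coexisting cell
sizes when they compete for the same nutrients?  The classical
variable-internal-stores (Droop) model with allometric trait scaling
predicts that the critical nutrient concentration

    N* = K_N µ_max (Q* − Q_min) Q* / [V_max (Q_max − Q*) − µ_max (Q* − Q_min) Q*],
    Q* = (Q_max − Q_min) m / µ_max + Q_min

increases with cell volume, so bottom-up competition alone should select
the smallest cells (competitive exclusion, Tilman's R*).  Size-selective
grazing by a discrete spectrum of zooplankton adds a log-periodic
top-down pressure with *grazing refuges* — prey sizes between the
grazers' optima.  This package simulates how the interplay of the two
controls assembles a community, and — unlike "everything is everywhere,
the environment selects" species-sorting approaches — lets the surviving
species *evolve*: every 3 years each resident spawns mutants 10 % larger
and 10 % smaller in volume, integrated for one annual cycle as passive
tracers, and invasion fitness

    s = log(B(t + 1 yr) / B(t))

decides replacement.  Directional selection walks each lineage to a
continuously stable strategy (CSS); the evolved community sits in the
grazing refuges whose N* the ambient nutrient field can support.

It is intended for researchers in plankton ecology and trait-based ocean
modelling who want a transparent, fully testable 1-D implementation of
adaptive dynamics inside a seasonal water column.

## Worked example

Critical nutrient concentrations rise with cell volume (the bottom-up
pull toward small cells):

```text
$ evoplankton nstar --type Synechococcus --volumes 1,3,10
Synechococcus V=1 um^3: N* = 0.000853159 mmol N m^-3
Synechococcus V=3 um^3: N* = 0.00138834 mmol N m^-3
Synechococcus V=10 um^3: N* = 0.00237482 mmol N m^-3

$ evoplankton nstar --type diatom --volumes 1e3,1e5
diatom V=1000 um^3: N* = 0.0166349 mmol N m^-3
diatom V=100000 um^3: N* = 0.136468 mmol N m^-3
```

A reduced two-phase protocol (desk preset: 12 levels, 600 m, 15 years of
species sorting then 75 years of trait evolution, 8 seeded species):

```python
from evoplankton.params import load_params, deep_merge
from evoplankton.experiment import apply_preset, run_protocol

p = apply_preset(load_params(), "desk")
p = deep_merge(p, {"protocol": {"n_phyto_seed": 8, "phase2_years": 75}})
r = run_protocol(p, seed=3)
print(r.convergence_year)                   # 5
print(sorted(r.volumes_phase2[r.biomass_phase2 > 1e-3]))
# [0.24, 3.32, 3293.4, 283237.1]  (µm^3)
print(r.classification)
# {'p0-Prochlorococcus': 'directional', 'p3-diatom': 'directional',
#  'p5-Synechococcus': 'directional', 'p7-diatom': 'CSS'}
```

The ecological phase converges to its annual attractor in ~5 years.
After evolution, four species survive, one per grazing-refuge basin,
spanning all four functional types' size domain — a Prochlorococcus-
sized cell (0.24 µm³) up to a large diatom (2.8×10⁵ µm³).  Each lineage
is either exactly at a fitness maximum (`CSS`) or flip-flopping one
10 % mutation step around it (`directional` at the oscillation
endpoints — the 6-year evolutionary oscillation, two 3-year cycles).

The full-size protocol of the study design (35 levels, 3275 m,
100 + 250 years, 24-member ensembles) runs through the CLI:

```bash
evoplankton run --preset paper --seed 1 --out run1/
evoplankton ensemble --preset paper --k 24 --out ens/
evoplankton landscape --preset desk --out landscape.nc
```

## Layout

- `src/evoplankton/allometry.py` — functional types, trait power laws, Q*, N*
- `src/evoplankton/foodweb.py` — Droop growth, size-kernel Holling-III
  grazing, mortality, remineralization; nitrogen-conserving tendencies
- `src/evoplankton/column.py` — grid, seasonal forcing, diffusion,
  sinking, operator-split stepping
- `src/evoplankton/evolution.py` — mutant trials, invasion fitness,
  replacement, singularity classification
- `src/evoplankton/diagnostics.py` — richness, Pielou evenness, Canberra
  distance / MSD, grazing background, fitness landscapes
- `src/evoplankton/experiment.py` — seeding, two-phase protocol, ensembles
- `docs/methods.md` — full model description, parameter choices and
  numerical details
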