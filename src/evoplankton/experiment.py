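"""Simulation protocol: seeding, two-phase runs, ensembles.

A run seeds the column with n phytoplankton species (allocated
round-robin across the four functional types, cell volumes drawn
log-uniformly within each type's range) and nine fixed grazers, starting
from uniformly low plankton biomass (6e-9 mmol C m^-3) in winter
(calendar day 0, January) conditions.

Phase 1 ("ecological", default 100 years) lets species sorting play out
with fixed traits; phase 2 ("eco-evolutionary", default 250 years) runs
the adaptive-dynamics engine.  At the end of each phase the run records
snapshots, diagnostics and the year-over-year attractor distance, and at
the end of the run classifies every surviving resident as CSS, EBP or
directional.  Ensembles repeat the protocol over independent seeds and
summarize richness, evenness and the intra-group mean square Canberra
distance.

The reduced preset (``desk``) shrinks the column and phase lengths for
quick work; ``paper`` is the full-size protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diagnostics as dx
from .allometry import PhytoSpecies, build_species, functional_types_from_params, TYPE_ORDER
from .column import (ColumnSimulator, ColumnState, make_forcing, make_grid,
                     state_distance)
from .evolution import (EvolutionRecord, EvolutionSchedule, classify_community,
                        run_evolution)
from .foodweb import FoodWeb, ZooSpecies, zooplankton_from_params
from .params import deep_merge, load_params

__all__ = [
    "PRESETS", "apply_preset", "seed_community", "build_simulator",
    "RunResult", "run_protocol", "run_ensemble",
]

log = logging.getLogger(__name__)

PRESETS: dict[str, dict] = {
    "paper": {},
    "desk": {
        "column": {"n_levels": 12, "depth": 600.0, "dt": 0.1},
        "forcing": {"mld_winter": 600.0},
        "protocol": {"phase1_years": 15, "phase2_years": 30},
    },
}


def apply_preset(params: dict, preset: str | None) -> dict:
    if preset is None:
        return params
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return deep_merge(params, PRESETS[preset])


def seed_community(n: int, rng: np.random.Generator,
                   params: dict) -> list[PhytoSpecies]:
    """Draw the initial phytoplankton community.

    Species are allocated round-robin across the four functional types
    (n divisible by 4 gives n/4 per type) and volumes drawn log-uniform
    within each type's range.  Deterministic given the generator state.
    """
    fts = functional_types_from_params(params)
    out = []
    for i in range(n):
        ft = fts[TYPE_ORDER[i % 4]]
        lo, hi = ft.volume_range
        vol = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi))
        out.append(build_species(ft, vol, sid=f"p{i}-{ft.name}"))
    return out


def initial_state(params: dict, grid, n_phyto: int, n_zoo: int,
                  phyto_qmin: np.ndarray, q_zoo: float) -> ColumnState:
    """Winter initial conditions: nutrient-replete column, every plankton
    species at the uniformly low seed concentration."""
    ini = params["initial"]
    L = grid.n_levels
    nut = np.tile([float(ini["NO3"]), float(ini["NO2"]),
                   float(ini["NH4"]), float(ini["DON"])], (L, 1))
    det = np.zeros((L, 4))
    seed = float(ini["plankton_seed"])
    phy = np.zeros((L, n_phyto, 3))
    phy[:, :, 0] = seed
    phy[:, :, 1] = seed * phyto_qmin
    zoo = np.zeros((L, n_zoo, 3))
    zoo[:, :, 0] = seed
    zoo[:, :, 1] = seed * q_zoo
    return ColumnState(nut=nut, det=det, phy=phy, zoo=zoo, time=0.0)


def build_simulator(params: dict, species: list[PhytoSpecies],
                    zoo: list[ZooSpecies] | None = None,
                    freeze_zoo: bool = False) -> ColumnSimulator:
    """Assemble grid, forcing, food web and initial state into a simulator."""
    zoo = zoo if zoo is not None else zooplankton_from_params(params)
    grid = make_grid(int(params["column"]["n_levels"]),
                     float(params["column"]["depth"]),
                     float(params["column"]["stretch_min_dz"]))
    forcing = make_forcing(params, grid)
    web = FoodWeb(species, zoo, params)
    state = initial_state(params, grid, len(species), len(zoo),
                          web.p_Qmin, float(params["foodweb"]["q_zoo"]))
    return ColumnSimulator(web, grid, forcing, state, params,
                           freeze_zoo=freeze_zoo)


@dataclass
class RunResult:
    """Artifacts of one two-phase simulation."""

    seed: int
    params: dict
    species_initial: list[str]
    snapshot_phase1: ColumnState
    snapshot_phase2: ColumnState
    volumes_phase1: np.ndarray
    volumes_phase2: np.ndarray
    biomass_phase1: np.ndarray
    biomass_phase2: np.ndarray
    convergence_year: int | None          # first year with small YoY distance
    attractor_distance_phase1: float
    attractor_distance_phase2: float
    classification: dict[str, str]
    record: EvolutionRecord
    distribution_phase1: dx.SizeDistribution = None
    distribution_phase2: dx.SizeDistribution = None

    def diagnostics_frame(self) -> pd.DataFrame:
        rows = []
        thr = float(self.params["protocol"]["richness_threshold"])
        for phase, dist, biom in (("ecological", self.distribution_phase1,
                                   self.biomass_phase1),
                                  ("eco-evolutionary", self.distribution_phase2,
                                   self.biomass_phase2)):
            rows += [
                (self.seed, phase, "richness",
                 dx.species_richness(biom, thr)),
                (self.seed, phase, "shannon_evenness", dx.shannon_evenness(dist)),
                (self.seed, phase, "total_biomass", dist.total),
            ]
        return pd.DataFrame(rows, columns=["seed", "phase", "metric", "value"])


def _yearly_attractor_scan(sim: ColumnSimulator, years: int,
                           tol: float = 1e-3) -> tuple[int | None, float]:
    """Integrate ``years`` years, tracking year-over-year state distance.

    Returns (first year index at which the relative distance dropped
    below ``tol``, final year-over-year distance)."""
    conv_year = None
    prev = sim.snapshot()
    dist = np.inf
    for y in range(1, years + 1):
        sim.run_years(1)
        cur = sim.snapshot()
        dist = state_distance(prev, cur)
        if conv_year is None and dist < tol:
            conv_year = y
        prev = cur
    return conv_year, dist


def run_protocol(params: dict, seed: int, preset: str | None = None) -> RunResult:
    """Execute the full two-phase protocol for one random seed."""
    params = apply_preset(params, preset)
    proto = params["protocol"]
    rng = np.random.default_rng(seed)
    species = seed_community(int(proto["n_phyto_seed"]), rng, params)
    sim = build_simulator(params, species)
    edges = dx.make_size_edges(params)

    conv_year, dist1 = _yearly_attractor_scan(sim, int(proto["phase1_years"]))
    snap1 = sim.snapshot()
    biom1 = sim.resident_biomass()
    vols1 = sim.web.p_vol.copy()
    dist_p1 = dx.size_distribution(vols1, biom1, edges)

    schedule = EvolutionSchedule.from_params(params)
    record = run_evolution(sim, int(proto["phase2_years"]) * 1.0, schedule)
    # year-over-year distance across one final full evolutionary cycle
    pre = sim.snapshot()
    sim.run_years(schedule.cycle_years)
    dist2 = state_distance(pre, sim.snapshot())
    snap2 = sim.snapshot()
    biom2 = sim.resident_biomass()
    vols2 = sim.web.p_vol.copy()
    dist_p2 = dx.size_distribution(vols2, biom2, edges)

    thr = float(proto["richness_threshold"])
    classification = {
        sid: cls for sid, cls in classify_community(sim, schedule).items()
        if biom2[[s.id for s in sim.web.species].index(sid)] > thr}

    return RunResult(
        seed=seed, params=params,
        species_initial=[s.id for s in species],
        snapshot_phase1=snap1, snapshot_phase2=snap2,
        volumes_phase1=vols1, volumes_phase2=vols2,
        biomass_phase1=biom1, biomass_phase2=biom2,
        convergence_year=conv_year,
        attractor_distance_phase1=dist1, attractor_distance_phase2=dist2,
        classification=classification, record=record,
        distribution_phase1=dist_p1, distribution_phase2=dist_p2)


def run_ensemble(params: dict, k: int | None = None, base_seed: int = 0,
                 preset: str | None = None) -> dict:
    """Run K independent seeds and summarize the ensemble.

    Returns a dict with the per-run results, a tidy metric table (K rows
    per metric and phase) and the intra-group mean square Canberra
    distance of the size distributions at the end of each phase."""
    params = apply_preset(params, preset)
    k = k or int(params["protocol"]["ensemble_k"])
    if k < 1:
        raise ValueError("ensemble size must be >= 1")
    seeds = [base_seed + i for i in range(k)]
    runs = [run_protocol(params, s) for s in seeds]
    report = pd.concat([r.diagnostics_frame() for r in runs], ignore_index=True)
    msd = {
        "ecological": dx.mean_square_distance(
            [r.distribution_phase1 for r in runs]),
        "eco-evolutionary": dx.mean_square_distance(
            [r.distribution_phase2 for r in runs]),
    }
    return {"runs": runs, "report": report, "msd": msd, "seeds": seeds}
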