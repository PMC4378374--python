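"""Adaptive-dynamics engine: mutant trials, invasion fitness, replacement.

Evolution of phytoplankton cell volume proceeds by repeated
mutation-invasion-replacement-transient cycles.  Every cycle (3 years by
default) each resident species spawns two rare mutants, 10 % larger and
10 % smaller in cell volume (clamped to the functional-type range).
Mutants are passive tracers: their initial biomass and quota depth
profiles clone the resident's (scaled to a negligible amplitude), they
experience the residents' environment for exactly one annual cycle, and
invasion fitness is the log of their annual column-integrated biomass
ratio,

    s = log(B(t + 1 yr) / B(t)).

Because the community sits on an annual limit cycle, a mutant identical
to its resident has fitness zero; the resident's own annual log-growth is
used as the reference, so selection is directional only when exactly one
mutant beats the resident.  A winning mutant inherits the resident's
attractor: the trait is swapped in place, depth profiles untouched.  Two
relaxation years let the community settle before the next trial.
Disruptive outcomes cannot branch lineages here; the fitter mutant wins
and the event is flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allometry import PhytoSpecies, build_species
from .column import ColumnSimulator

__all__ = [
    "MutantTrial", "EvolutionEvent", "EvolutionSchedule", "EvolutionRecord",
    "spawn_mutants", "invasion_fitness", "selection_outcome",
    "replace_resident", "run_evolution", "classify_singularity",
    "classify_community", "clone_simulator",
]

log = logging.getLogger(__name__)

DIRECTIONAL_UP = "directional-up"
DIRECTIONAL_DOWN = "directional-down"
STABILIZING = "stabilizing"
DISRUPTIVE = "disruptive"


@dataclass
class MutantTrial:
    """One probe strategy attached to a resident."""

    parent_id: str
    species: PhytoSpecies
    side: int                   # -1 smaller, +1 larger, 0 clone
    B0: float = math.nan        # column-integrated C at introduction
    B1: float = math.nan        # one year later
    fitness: float = math.nan


@dataclass
class EvolutionEvent:
    cycle: int
    resident_id: str
    ftype: str
    outcome: str
    old_volume: float
    new_volume: float
    s_minus: float
    s_resident: float
    s_plus: float


@dataclass(frozen=True)
class EvolutionSchedule:
    """Timing of the mutation-invasion-replacement-transient cycle."""

    mutation_step: float = 0.10
    eval_years: int = 1
    relax_years: int = 2
    mutant_scale: float = 1e-6

    @property
    def cycle_years(self) -> int:
        return self.eval_years + self.relax_years

    @classmethod
    def from_params(cls, params: dict) -> "EvolutionSchedule":
        e = params["evolution"]
        return cls(mutation_step=float(e["mutation_step"]),
                   eval_years=int(e["eval_years"]),
                   relax_years=int(e["relax_years"]),
                   mutant_scale=float(e["mutant_scale"]))


class EvolutionRecord:
    """Accumulated evolutionary events, exportable as a tidy table."""

    def __init__(self):
        self.events: list[EvolutionEvent] = []
        self.trajectory: list[tuple[int, str, float]] = []  # (cycle, id, volume)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.cycle, e.resident_id, e.ftype, e.outcome, e.old_volume,
              e.new_volume, e.s_minus, e.s_resident, e.s_plus)
             for e in self.events],
            columns=["cycle", "species", "type", "outcome", "old_volume",
                     "new_volume", "s_minus", "s_res", "s_plus"])

    def trait_trajectory(self) -> pd.DataFrame:
        return pd.DataFrame(self.trajectory, columns=["cycle", "species", "volume"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def spawn_mutants(resident: PhytoSpecies, step: float = 0.10) -> list[MutantTrial]:
    """Generate up to two mutants at volume * (1 -/+ step).

    A mutant whose volume falls outside the parent's functional-type
    range is not generated (genetic constraint of the type)."""
    out = []
    for side in (-1, +1):
        vol = resident.volume * (1.0 + side * step)
        if resident.ftype.contains(vol):
            sp = build_species(resident.ftype, vol,
                               sid=f"{resident.id}|mut{'+' if side > 0 else '-'}")
            out.append(MutantTrial(parent_id=resident.id, species=sp, side=side))
    return out


def invasion_fitness(b_t: float, b_t1: float) -> float:
    """Annual invasion fitness log(B(t+1)/B(t)); -inf for an extinct mutant."""
    if b_t <= 0:
        raise ValueError("initial biomass must be positive")
    if b_t1 <= 0:
        return -math.inf
    return math.log(b_t1 / b_t)


def selection_outcome(s_minus: float | None, s_plus: float | None,
                      s_resident: float) -> str:
    """Classify a trial against the resident's own annual growth rate.

    The resident fitness is close to, but not exactly, zero off the
    attractor, so comparisons use it rather than literal zero.  Exact
    ties count as non-invading (replacement requires strict improvement).
    """
    if s_minus is None and s_plus is None:
        log.warning("both mutants clamped away; treating as stabilizing")
        return STABILIZING
    if s_minus is None:
        return DIRECTIONAL_UP if s_plus > s_resident else STABILIZING
    if s_plus is None:
        return DIRECTIONAL_DOWN if s_minus > s_resident else STABILIZING
    up, down = s_plus > s_resident, s_minus > s_resident
    if up and down:
        return DISRUPTIVE
    if up:
        return DIRECTIONAL_UP
    if down:
        return DIRECTIONAL_DOWN
    return STABILIZING


def replace_resident(sim: ColumnSimulator, index: int, new_volume: float) -> None:
    """Attractor inheritance: swap the resident's trait in place.

    All derived traits are rebuilt from (type, new volume); the biomass
    and quota depth profiles are left untouched."""
    old = sim.web.species[index]
    new = build_species(old.ftype, new_volume, sid=old.id)
    sim.web.replace_species(index, new)


def _install_trials(sim: ColumnSimulator, trials: list[list[MutantTrial]],
                    scale: float) -> None:
    flat = [t for group in trials for t in group]
    if not flat:
        return
    idx_of = {s.id: i for i, s in enumerate(sim.web.species)}
    L = sim.grid.n_levels
    init = np.empty((L, len(flat), 3))
    for k, t in enumerate(flat):
        init[:, k, :] = sim.state.phy[:, idx_of[t.parent_id], :] * scale
    sim.add_probes([t.species for t in flat], init)
    b0 = sim.probe_biomass()
    for k, t in enumerate(flat):
        t.B0 = float(b0[k])


def _harvest_trials(sim: ColumnSimulator, trials: list[list[MutantTrial]]) -> None:
    flat = [t for group in trials for t in group]
    b1 = sim.probe_biomass()
    for k, t in enumerate(flat):
        t.B1 = float(b1[k])
        t.fitness = invasion_fitness(t.B0, t.B1)
    sim.clear_probes()


def _evaluation_year(sim: ColumnSimulator, schedule: EvolutionSchedule,
                     trials: list[list[MutantTrial]]):
    """Run one shared evaluation year; returns resident fitnesses."""
    _install_trials(sim, trials, schedule.mutant_scale)
    b_res0 = sim.resident_biomass()
    sim.run_years(schedule.eval_years)
    b_res1 = sim.resident_biomass()
    _harvest_trials(sim, trials)
    return np.log(b_res1 / b_res0)


def run_evolution(sim: ColumnSimulator, years: float,
                  schedule: EvolutionSchedule | None = None,
                  record: EvolutionRecord | None = None) -> EvolutionRecord:
    """Advance the community through full evolutionary cycles.

    Each cycle: spawn mutants for every resident, co-integrate them for
    one shared year as passive tracers, evaluate fitness, apply the
    selection outcome (replacement on directional selection; on a
    disruptive outcome the fitter mutant wins and the event is flagged —
    lineage splitting is outside this algorithm), then relax for two
    years toward the new attractor."""
    schedule = schedule or EvolutionSchedule()
    record = record or EvolutionRecord()
    n_cycles = int(years // schedule.cycle_years)
    start_cycle = len({c for c, _, _ in record.trajectory})
    for cycle in range(start_cycle, start_cycle + n_cycles):
        residents = list(sim.web.species)
        trials = [spawn_mutants(r, schedule.mutation_step) for r in residents]
        s_res = _evaluation_year(sim, schedule, trials)
        for j, (resident, group) in enumerate(zip(residents, trials)):
            s_minus = next((t.fitness for t in group if t.side < 0), None)
            s_plus = next((t.fitness for t in group if t.side > 0), None)
            outcome = selection_outcome(s_minus, s_plus, float(s_res[j]))
            new_volume = resident.volume
            if outcome == DIRECTIONAL_UP:
                new_volume = resident.volume * (1.0 + schedule.mutation_step)
            elif outcome == DIRECTIONAL_DOWN:
                new_volume = resident.volume * (1.0 - schedule.mutation_step)
            elif outcome == DISRUPTIVE:
                log.warning("disruptive selection at %s (V=%.3g): winner takes "
                            "trait, branching not modelled",
                            resident.id, resident.volume)
                winner = -1 if s_minus > s_plus else 1
                new_volume = resident.volume * (1.0 + winner * schedule.mutation_step)
            if new_volume != resident.volume:
                replace_resident(sim, j, new_volume)
            record.events.append(EvolutionEvent(
                cycle=cycle, resident_id=resident.id,
                ftype=resident.ftype.name, outcome=outcome,
                old_volume=resident.volume, new_volume=new_volume,
                s_minus=math.nan if s_minus is None else s_minus,
                s_resident=float(s_res[j]),
                s_plus=math.nan if s_plus is None else s_plus))
            record.trajectory.append((cycle, resident.id, new_volume))
        sim.run_years(schedule.relax_years)
    return record


def clone_simulator(sim: ColumnSimulator) -> ColumnSimulator:
    """Independent copy for side trials: state and food web are copied
    (grid, forcing and parameters are shared read-only), so neither
    stepping nor trait replacement on the clone touches the original."""
    return ColumnSimulator(sim.web.copy(), sim.grid, sim.forcing,
                           sim.snapshot(), sim.params,
                           freeze_zoo=sim.freeze_zoo)


def classify_community(sim: ColumnSimulator,
                       schedule: EvolutionSchedule | None = None) -> dict[str, str]:
    """Singularity class of every resident from one shared probe year.

    Runs on a clone of the simulator (the live state is untouched).
    Stabilizing selection marks a continuously stable strategy (CSS),
    disruptive an evolutionary branching point (EBP), otherwise the
    resident is still mid-slope (directional)."""
    schedule = schedule or EvolutionSchedule()
    probe = clone_simulator(sim)
    residents = list(probe.web.species)
    trials = [spawn_mutants(r, schedule.mutation_step) for r in residents]
    s_res = _evaluation_year(probe, schedule, trials)
    out = {}
    for j, (resident, group) in enumerate(zip(residents, trials)):
        s_minus = next((t.fitness for t in group if t.side < 0), None)
        s_plus = next((t.fitness for t in group if t.side > 0), None)
        outcome = selection_outcome(s_minus, s_plus, float(s_res[j]))
        out[resident.id] = {STABILIZING: "CSS", DISRUPTIVE: "EBP"}.get(
            outcome, "directional")
    return out


def classify_singularity(sim: ColumnSimulator, resident_id: str,
                         schedule: EvolutionSchedule | None = None) -> str:
    """Singularity class of one resident (CSS | EBP | directional)."""
    return classify_community(sim, schedule)[resident_id]
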