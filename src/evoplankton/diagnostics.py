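"""Community indicators: richness, evenness, distribution distances,
grazing background, and fitness landscapes.

Biomass is binned into 100 log-spaced cell-volume classes spanning the
union of the functional-type size ranges; the class edges are part of
every result so that distances between runs are reproducible.  Evenness
is the Shannon entropy of the biomass shares normalized by log of the
class count (Pielou form, in [0, 1]).  Distances between two binned
distributions use the Canberra metric, whose per-bin contribution is
bounded by 1; ensemble spread is the mean square Canberra distance to
the group mean distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allometry import TYPE_ORDER
from .column import ColumnSimulator
from .evolution import EvolutionSchedule, clone_simulator

__all__ = [
    "SizeDistribution", "FitnessLandscape", "make_size_edges",
    "size_distribution", "species_richness", "shannon_evenness", "canberra",
    "mean_square_distance", "grazing_background", "grazing_refuges",
    "fitness_landscape",
]


@dataclass(frozen=True)
class SizeDistribution:
    """Biomass shares across fixed log-spaced cell-volume classes."""

    edges: np.ndarray        # (N+1,) bin edges, um^3
    p: np.ndarray            # (N,) biomass per class (shares if normalized)
    total: float             # total biomass before normalization

    @property
    def n_classes(self) -> int:
        return len(self.p)


@dataclass(frozen=True)
class FitnessLandscape:
    """Invasion fitness of probe volumes, per functional type."""

    volumes: dict[str, np.ndarray]
    fitness: dict[str, np.ndarray]
    residents: pd.DataFrame       # columns: species, ftype, volume, fitness


def make_size_edges(params: dict, n_classes: int | None = None) -> np.ndarray:
    """Log10-uniform class edges over the union of type volume ranges."""
    cfg = params["allometry"]["functional_types"]
    lo = min(float(cfg[t]["volume_range"][0]) for t in TYPE_ORDER)
    hi = max(float(cfg[t]["volume_range"][1]) for t in TYPE_ORDER)
    n = n_classes or int(params["protocol"]["n_size_classes"])
    return np.logspace(np.log10(lo), np.log10(hi), n + 1)


def size_distribution(volumes, biomass, edges, normalized: bool = True) -> SizeDistribution:
    """Bin species biomass by cell volume.

    With ``normalized`` (default) the classes hold biomass shares summing
    to one, so runs of different total biomass are comparable; the raw
    mode keeps absolute biomass per class."""
    v = np.asarray(volumes, float)
    b = np.asarray(biomass, float)
    hist, _ = np.histogram(v, bins=edges, weights=b)
    total = float(hist.sum())
    if normalized and total > 0:
        hist = hist / total
    return SizeDistribution(edges=np.asarray(edges, float), p=hist, total=total)


def species_richness(biomass, threshold: float = 1e-3) -> int:
    """Number of species whose column-integrated biomass (mmol C m^-2)
    exceeds the quasi-extinction threshold."""
    b = np.asarray(biomass, float)
    return int((b > threshold).sum())


def shannon_evenness(dist: SizeDistribution) -> float:
    """Pielou evenness S = -sum p_i ln p_i / ln N, in [0, 1].

    0 when all biomass sits in one class, 1 when spread uniformly over
    all classes; 0*ln 0 is taken as 0.  Undefined (NaN) for an empty
    community."""
    if dist.total <= 0:
        return float("nan")
    p = dist.p / dist.p.sum()
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(dist.n_classes))


def canberra(x: SizeDistribution, y: SizeDistribution) -> float:
    """Canberra distance sum |x_i - y_i| / (|x_i| + |y_i|).

    Bins empty in both distributions contribute 0; each bin contributes
    at most 1, so disjoint supports count one per occupied bin."""
    if x.edges.shape != y.edges.shape or not np.allclose(x.edges, y.edges):
        raise ValueError("distributions use different class edges")
    num = np.abs(x.p - y.p)
    den = np.abs(x.p) + np.abs(y.p)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(den > 0, num / den, 0.0)
    return float(terms.sum())


def mean_square_distance(dists: list[SizeDistribution]) -> float:
    """Mean square Canberra distance of group members to the group mean."""
    if not dists:
        raise ValueError("need at least one distribution")
    edges = dists[0].edges
    mean_p = np.mean([d.p for d in dists], axis=0)
    mean = SizeDistribution(edges=edges, p=mean_p, total=1.0)
    return float(np.mean([canberra(d, mean) ** 2 for d in dists]))


def grazing_background(web, zoo_biomass, volumes, weight_ingestion: bool = True):
    """Realized grazing pressure on prey of the given cell volumes.

    Sum over grazers of biomass-weighted palatability (times the
    grazer's maximum ingestion rate by default).  With a discrete
    spectrum of equally abundant grazers the curve is log-periodic, with
    local minima — grazing refuges — between the optimal-prey peaks."""
    v = np.asarray(volumes, float)
    bz = np.asarray(zoo_biomass, float)
    ratio = web.z_vol[:, None] / v[None, :]
    sigma = float(web.fw["sigma"])
    phi = np.exp(-(np.log(ratio / float(web.fw["rho_opt"])) ** 2)
                 / (2.0 * sigma ** 2))
    w = bz * (web.z_Imax if weight_ingestion else 1.0)
    return w @ phi


def grazing_refuges(volumes, pressure) -> np.ndarray:
    """Volumes of the local minima (refuges) of a grazing-pressure curve."""
    g = np.asarray(pressure, float)
    v = np.asarray(volumes, float)
    interior = (g[1:-1] < g[:-2]) & (g[1:-1] <= g[2:])
    return v[1:-1][interior]


def fitness_landscape(sim: ColumnSimulator, n_probes: int = 200,
                      schedule: EvolutionSchedule | None = None,
                      richness_threshold: float = 1e-3) -> FitnessLandscape:
    """Invasion-fitness landscape of the current community.

    For each functional type with a living resident, ``n_probes``
    log-spaced probe volumes span the type's range.  All probes run as
    passive tracers through one shared annual cycle on a clone of the
    simulator, initialized from the depth profile of the type's most
    abundant resident; residents evaluate to fitness ~ 0 when the system
    sits on its attractor."""
    from .allometry import build_species  # local to avoid cycle at import time
    from .evolution import _install_trials, _harvest_trials, MutantTrial

    schedule = schedule or EvolutionSchedule()
    probe = clone_simulator(sim)
    biomass = probe.resident_biomass()
    types_present: dict[str, list[int]] = {}
    for j, s in enumerate(probe.web.species):
        if biomass[j] > richness_threshold:
            types_present.setdefault(s.ftype.name, []).append(j)

    # each probe clones the depth profile of the same-type resident nearest
    # in log volume (the transient-shortcut assumption is most defensible
    # for the most similar resident)
    trials: list[list[MutantTrial]] = []
    for tname, members in types_present.items():
        ftype = probe.web.species[members[0]].ftype
        lo, hi = ftype.volume_range
        vols = np.geomspace(lo, hi, n_probes)
        logs = np.log(np.array([probe.web.species[j].volume for j in members]))
        group = []
        for k, v in enumerate(vols):
            j = members[int(np.argmin(np.abs(logs - np.log(v))))]
            group.append(MutantTrial(parent_id=probe.web.species[j].id,
                                     species=build_species(ftype, v,
                                                           sid=f"probe-{tname}-{k}"),
                                     side=0))
        trials.append(group)

    b0 = probe.resident_biomass()
    _install_trials(probe, trials, schedule.mutant_scale)
    probe.run_years(schedule.eval_years)
    b1 = probe.resident_biomass()
    _harvest_trials(probe, trials)

    with np.errstate(divide="ignore"):
        s_res = np.log(b1 / b0)
    volumes, fitness = {}, {}
    for group, tname in zip(trials, types_present):
        volumes[tname] = np.array([t.species.volume for t in group])
        fitness[tname] = np.array([t.fitness for t in group])
    residents = pd.DataFrame(
        [(s.id, s.ftype.name, s.volume, float(s_res[j]))
         for j, s in enumerate(probe.web.species) if biomass[j] > richness_threshold],
        columns=["species", "ftype", "volume", "fitness"])
    return FitnessLandscape(volumes=volumes, fitness=fitness, residents=residents)
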