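"""Functional types, allometric trait scaling, and Droop equilibrium theory.

Phytoplankton species are defined by a functional type (Prochlorococcus,
Synechococcus, small eukaryote, diatom) and a single evolving trait, the
cell volume V (um^3).  Every physiological trait x is the deterministic
image of V under a power law

    log10(x) = a + b * log10(V)

with per-trait constants (a, b).  The maximum growth-rate intercept ``a``
differs between functional types (hence four mu_max curves); all other
rules are shared by default.  Prochlorococcus cannot use nitrate.

From the variable-internal-stores (Droop) model the module derives the
equilibrium quota Q* and the critical nutrient concentration N* — the
external concentration at which growth exactly balances mortality, the
analogue of Tilman's R*.  Light and temperature limitation factors are
taken at their reference value 1 for this calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "FunctionalType", "TraitSet", "PhytoSpecies", "ModelParams",
    "NonViableSpecies", "allometric_param", "equilibrium_quota",
    "critical_nutrient", "build_species", "functional_types_from_params",
    "TYPE_ORDER",
]

TYPE_ORDER = ("Prochlorococcus", "Synechococcus", "small-eukaryote", "diatom")

# Trait names resolved through the allometric rules, in TraitSet field order.
_TRAITS = ("V_max", "K_N", "Q_min", "Q_max", "mu_max", "sinking", "carbon_per_cell")


class NonViableSpecies(ValueError):
    """Raised when a parameter set cannot sustain itself at any nutrient
    concentration (mortality exceeds the achievable growth rate)."""


@dataclass(frozen=True)
class FunctionalType:
    """One of the four phytoplankton functional groups."""

    name: str
    volume_range: tuple[float, float]          # [V_lo, V_hi], um^3
    allometric_rules: Mapping[str, tuple[float, float]]  # trait -> (a, b)
    can_use_nitrate: bool = True

    def __post_init__(self):
        lo, hi = self.volume_range
        if not (0 < lo < hi):
            raise ValueError(f"{self.name}: invalid volume range {self.volume_range}")
        if self.name == "Prochlorococcus" and self.can_use_nitrate:
            raise ValueError("Prochlorococcus cannot use nitrate")

    def contains(self, volume: float) -> bool:
        lo, hi = self.volume_range
        return lo <= volume <= hi


@dataclass(frozen=True)
class TraitSet:
    """Size-dependent eco-physiological traits of one phytoplankton species."""

    V_max: float            # max N uptake rate, mol N (mol C)^-1 d^-1
    K_N: float              # uptake half-saturation, mmol N m^-3
    Q_min: float            # minimum N:C quota, mol N (mol C)^-1
    Q_max: float            # maximum N:C quota
    mu_max: float           # max growth rate, d^-1
    sinking: float          # m d^-1
    carbon_per_cell: float  # mmol C cell^-1

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"trait {name} must be strictly positive")
        if not self.Q_min < self.Q_max:
            raise ValueError("Q_min must be < Q_max")


@dataclass(frozen=True)
class PhytoSpecies:
    """A resident phytoplankton strategy: functional type + cell volume."""

    id: str
    ftype: FunctionalType
    volume: float           # um^3, the evolving trait
    traits: TraitSet = field(compare=False)

    @property
    def can_use_nitrate(self) -> bool:
        return self.ftype.can_use_nitrate


@dataclass(frozen=True)
class ModelParams:
    """Scalar ecological constants shared by all species."""

    m: float = 0.05                 # background phytoplankton mortality, d^-1
    m_zoo: float = 0.05             # zooplankton closure mortality, d^-1
    assimilation: float = 0.30      # grazer assimilation efficiency
    rtol: float = 1e-10             # numerical tolerance for audits

    def __post_init__(self):
        if self.m <= 0:
            raise ValueError("mortality m must be > 0")


def allometric_param(rule: tuple[float, float], volume) -> float:
    """Evaluate the power law 10**(a + b*log10(V)) for a trait rule.

    Accepts scalar or array volumes; volumes must be strictly positive.
    """
    a, b = rule
    v = np.asarray(volume, dtype=float)
    if np.any(v <= 0):
        raise ValueError("cell volume must be strictly positive")
    out = 10.0 ** (a + b * np.log10(v))
    return float(out) if np.isscalar(volume) or out.ndim == 0 else out


def equilibrium_quota(traits: TraitSet, m: float) -> float:
    """Droop equilibrium quota Q* = (Q_max - Q_min) * m / mu_max + Q_min.

    Affine in the mortality m, with Q*(0) = Q_min and Q*(mu_max) = Q_max.
    A mortality above mu_max is not sustainable at any quota.
    """
    if m < 0:
        raise ValueError("mortality must be >= 0")
    if m > traits.mu_max:
        raise NonViableSpecies(
            f"mortality {m} exceeds mu_max {traits.mu_max}: no equilibrium quota")
    return (traits.Q_max - traits.Q_min) * m / traits.mu_max + traits.Q_min


def critical_nutrient(traits: TraitSet, m: float) -> float:
    """Critical nutrient concentration N* of the grazer-free Droop model.

        N* = K_N * mu_max * (Q*-Q_min) * Q*
             / [ V_max * (Q_max-Q*) - mu_max * (Q*-Q_min) * Q* ]

    N* is the external concentration at which per-capita growth balances
    the mortality m; below it the population declines.  Light/temperature
    limitation factors are taken as 1.  Raises :class:`NonViableSpecies`
    when the denominator is non-positive (uptake can never balance the
    growth requirement, so the species is non-viable at any N).
    """
    if not 0 <= m < traits.mu_max:
        raise NonViableSpecies(f"need 0 <= m < mu_max, got m={m}")
    q_star = equilibrium_quota(traits, m)
    num = traits.K_N * traits.mu_max * (q_star - traits.Q_min) * q_star
    den = (traits.V_max * (traits.Q_max - q_star)
           - traits.mu_max * (q_star - traits.Q_min) * q_star)
    if den <= 0:
        raise NonViableSpecies("uptake cannot sustain growth at any nutrient level")
    return num / den


def build_species(ftype: FunctionalType, volume: float, sid: str | None = None) -> PhytoSpecies:
    """Instantiate a species with all traits derived from (type, volume).

    Deterministic: identical inputs yield identical trait sets.
    """
    if not ftype.contains(volume):
        lo, hi = ftype.volume_range
        raise ValueError(
            f"volume {volume} um^3 outside the {ftype.name} range [{lo}, {hi}]")
    values = {t: allometric_param(ftype.allometric_rules[t], volume) for t in _TRAITS}
    traits = TraitSet(**values)
    if sid is None:
        sid = f"{ftype.name}-{volume:.6g}"
    return PhytoSpecies(id=sid, ftype=ftype, volume=volume, traits=traits)


def functional_types_from_params(params: Mapping) -> dict[str, FunctionalType]:
    """Build the four functional types from a parameter tree (see
    :func:`evoplankton.params.load_params`)."""
    cfg = params["allometry"]
    shared = {k: tuple(v) for k, v in cfg["rules"].items()}
    out: dict[str, FunctionalType] = {}
    for name in TYPE_ORDER:
        tcfg = cfg["functional_types"][name]
        rules = dict(shared)
        # per-type growth-rate intercept, shared slope
        rules["mu_max"] = (float(tcfg["mu_max_a"]), shared["mu_max"][1])
        for trait, pair in tcfg.get("rules", {}).items():
            rules[trait] = tuple(pair)
        out[name] = FunctionalType(
            name=name,
            volume_range=tuple(float(v) for v in tcfg["volume_range"]),
            allometric_rules=rules,
            can_use_nitrate=bool(tcfg["can_use_nitrate"]),
        )
    lows = [out[n].volume_range[0] for n in TYPE_ORDER]
    if lows != sorted(lows):
        raise ValueError("functional-type volume ranges must be ordered "
                         "Prochlorococcus < ... < diatom")
    return out
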