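"""Local ecological tendencies of the size-structured plankton food web.

Per spatial location the model integrates

* 4 dissolved pools: NO3, NO2, NH4 and DON (nitrification chain
  NH4 -> NO2 -> NO3, remineralization DON -> NH4),
* 4 dead-organic pools: small and large detritus, each in C and N
  (large detritus collects losses from big organisms and sinks faster),
* 3 tracers per phytoplankton species: carbon biomass, nitrogen biomass
  (= biomass times cell quota) and chlorophyll,
* 3 tracers per zooplankton species in the same unified-plankton layout
  (their chlorophyll has no sources and stays at zero),

i.e. ``3*n_phyto + 3*n_zoo + 8`` coupled equations per location.

Phytoplankton growth follows the variable-internal-stores (Droop) model:
uptake fills the cell quota Q as a saturating function of external
nitrogen, growth consumes the quota.  Grazing is a Holling type-3
functional response on palatability-weighted prey biomass, with a
log-normal prey-size kernel centred on an optimal predator:prey volume
ratio; grazers take both phytoplankton and smaller grazers (intra-guild
predation).  All nitrogen fluxes are explicit pool-to-pool transfers, so
the biological tendencies conserve total nitrogen to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .allometry import PhytoSpecies, allometric_param

__all__ = [
    "ZooSpecies", "LocalState", "Environment", "FoodWeb", "ProbeSet",
    "palatability", "grazing_flux", "droop_terms", "local_tendencies",
    "count_state_equations", "zooplankton_from_params",
    "NUT_NAMES", "DET_NAMES",
]

NUT_NAMES = ("NO3", "NO2", "NH4", "DON")
DET_NAMES = ("POC_small", "PON_small", "POC_large", "PON_large")
_TINY = 1e-300


@dataclass(frozen=True)
class ZooSpecies:
    """Fixed (non-evolving) grazer defined by its body volume."""

    id: str
    volume: float          # body volume, um^3
    I_max: float           # max ingestion rate, d^-1
    rho_opt: float         # optimal predator:prey volume ratio (> 1)
    sigma: float           # log-normal kernel width, ln-units
    assimilation: float    # fraction of ingestion assimilated

    def __post_init__(self):
        if self.rho_opt <= 1:
            raise ValueError("rho_opt must exceed 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class Environment:
    """Abiotic conditions at one depth level."""

    temperature: float     # deg C
    irradiance: float      # W m^-2

    def __post_init__(self):
        if self.irradiance < 0:
            raise ValueError("irradiance must be >= 0")


@dataclass
class LocalState:
    """State of every tracer at one depth level (concentrations >= 0)."""

    nut: np.ndarray        # (4,)  NO3, NO2, NH4, DON       mmol N m^-3
    det: np.ndarray        # (4,)  POC_s, PON_s, POC_l, PON_l
    phy: np.ndarray        # (P,3) C, N, Chl per phyto species
    zoo: np.ndarray        # (Z,3) C, N, Chl per zoo species

    def total_nitrogen(self) -> float:
        return float(self.nut.sum() + self.det[1] + self.det[3]
                     + self.phy[:, 1].sum() + self.zoo[:, 1].sum())


def count_state_equations(n_phyto: int, n_zoo: int = 9) -> int:
    """Number of coupled per-location state equations.

    Three tracers per plankton species (C, N, Chl) plus the 8 shared
    dissolved and detrital pools; affine in the species counts.
    """
    if n_phyto < 0 or n_zoo < 0:
        raise ValueError("species counts must be non-negative")
    return 3 * n_phyto + 3 * n_zoo + 8


def palatability(prey_volume, zoo: ZooSpecies):
    """Grazing efficiency of ``zoo`` on prey of the given volume.

    Log-normal in the predator:prey volume ratio, normalized to peak 1 at
    the optimal ratio and symmetric in log(ratio / rho_opt).
    """
    v = np.asarray(prey_volume, dtype=float)
    if np.any(v <= 0) or zoo.volume <= 0:
        raise ValueError("volumes must be strictly positive")
    x = np.log(zoo.volume / v / zoo.rho_opt)
    out = np.exp(-(x ** 2) / (2.0 * zoo.sigma ** 2))
    return float(out) if out.ndim == 0 else out


def grazing_flux(zoo: ZooSpecies, zoo_biomass: float,
                 prey_volumes: Sequence[float], prey_biomass: Sequence[float],
                 k_A: float) -> np.ndarray:
    """Per-prey ingestion fluxes of one grazer (mmol C m^-3 d^-1).

    Total ingestion follows a Holling type-3 response on the
    palatability-weighted prey availability A and is apportioned across
    prey by their weighted biomass share; a prey with zero palatability
    receives exactly zero flux, and zero availability yields zero flux.
    """
    pv = np.asarray(prey_volumes, dtype=float)
    pb = np.asarray(prey_biomass, dtype=float)
    if np.any(pb < 0) or zoo_biomass < 0:
        raise ValueError("biomasses must be >= 0")
    phi = palatability(pv, zoo)
    weighted = phi * pb
    A = weighted.sum()
    if A <= 0:
        return np.zeros_like(pb)
    total = zoo.I_max * zoo_biomass * A * A / (A * A + k_A * k_A)
    return total * weighted / A


def droop_terms(species: PhytoSpecies, N: float, Q: float,
                env: Environment, fw_params: dict | None = None) -> tuple[float, float]:
    """Droop uptake and growth rates of one species at one level.

    Returns ``(uptake, growth)`` where uptake is the specific N uptake
    rate (mol N (mol C)^-1 d^-1) at external concentration N and quota Q,
    and growth the specific C growth rate (d^-1) including the
    temperature and light limitation factors.  Nitrate is unavailable to
    Prochlorococcus, which is expressed here through ``N`` being the
    concentration of the forms the species can use.
    """
    t = species.traits
    if not t.Q_min <= Q <= t.Q_max:
        raise ValueError(f"quota {Q} outside [{t.Q_min}, {t.Q_max}]")
    if N < 0:
        raise ValueError("nutrient concentration must be >= 0")
    p = fw_params or {}
    gT = np.exp(p.get("eppley_k", 0.0639) * (env.temperature - p.get("T_ref", 10.0)))
    gI = 1.0 - np.exp(-env.irradiance / p.get("I_k", 25.0))
    span = t.Q_max - t.Q_min
    uptake = t.V_max * (t.Q_max - Q) / span * N / (N + t.K_N)
    growth = t.mu_max * gT * gI * (Q - t.Q_min) / span
    return float(uptake), float(growth)


def zooplankton_from_params(params: dict) -> list[ZooSpecies]:
    """Build the fixed grazer spectrum from a parameter tree.

    The default nine body volumes are log-spaced so that the optimal prey
    volumes (body volume / rho_opt) tile the whole phytoplankton size
    range; maximum ingestion scales allometrically with body volume.
    """
    fw = params["foodweb"]
    rule = tuple(fw["I_max_rule"])
    out = []
    for i, vol in enumerate(fw["zoo_volumes"]):
        out.append(ZooSpecies(
            id=f"zoo-{i}", volume=float(vol),
            I_max=allometric_param(rule, float(vol)),
            rho_opt=float(fw["rho_opt"]), sigma=float(fw["sigma"]),
            assimilation=float(fw["assimilation"]),
        ))
    return out


@dataclass
class ProbeSet:
    """Trait arrays for passive mutant/probe tracers (no feedback)."""

    species: list[PhytoSpecies]
    V_max: np.ndarray
    K_N: np.ndarray
    Q_min: np.ndarray
    Q_max: np.ndarray
    mu_max: np.ndarray
    sinking: np.ndarray
    no3_ok: np.ndarray     # bool (M,)
    phi: np.ndarray        # (Z, M) palatability of each probe to each grazer

    def __len__(self):
        return len(self.species)


class FoodWeb:
    """Vectorized ecological tendencies for a fixed community composition.

    Trait vectors are cached per species so the per-step cost is a fixed
    number of array operations regardless of community size.  Calling
    :meth:`replace_species` (trait evolution) refreshes the cache for one
    resident without touching the others.
    """

    def __init__(self, species: Sequence[PhytoSpecies],
                 zoo: Sequence[ZooSpecies], params: dict):
        self.params = params
        self.fw = params["foodweb"]
        self.species: list[PhytoSpecies] = list(species)
        self.zoo: list[ZooSpecies] = list(zoo)
        self._rebuild_phyto_arrays()
        self._rebuild_zoo_arrays()

    # -- cached trait arrays ------------------------------------------------
    def _rebuild_phyto_arrays(self):
        sp = self.species
        get = lambda attr: np.array([getattr(s.traits, attr) for s in sp], float)
        self.p_Vmax = get("V_max")
        self.p_K = get("K_N")
        self.p_Qmin = get("Q_min")
        self.p_Qmax = get("Q_max")
        self.p_span = self.p_Qmax - self.p_Qmin
        self.p_mumax = get("mu_max")
        self.p_sink = get("sinking")
        self.p_vol = np.array([s.volume for s in sp], float)
        self.p_no3 = np.array([s.can_use_nitrate for s in sp], bool)
        self._rebuild_kernel()

    def _rebuild_zoo_arrays(self):
        zs = self.zoo
        self.z_Imax = np.array([z.I_max for z in zs], float)
        self.z_vol = np.array([z.volume for z in zs], float)
        self.z_beta = np.array([z.assimilation for z in zs], float)
        self._rebuild_kernel()

    def _rebuild_kernel(self):
        if not hasattr(self, "z_vol") or not hasattr(self, "p_vol"):
            return
        # palatability matrix over prey = [phyto..., zoo...]
        prey_vol = np.concatenate([self.p_vol, self.z_vol])
        self.prey_vol = prey_vol
        ratio = self.z_vol[:, None] / prey_vol[None, :]
        sigma = float(self.fw["sigma"])
        phi = np.exp(-(np.log(ratio / float(self.fw["rho_opt"])) ** 2)
                     / (2.0 * sigma ** 2))
        P = len(self.p_vol)
        # intra-guild predation only on strictly smaller grazers
        zz = self.z_vol[None, :] <= self.z_vol[:, None] * (1 + 1e-12)
        phi[:, P:][zz] = 0.0
        self.phi = phi
        big = float(self.fw["large_detritus_volume"])
        self.p_large = self.p_vol > big
        self.z_large = self.z_vol > big

    def replace_species(self, index: int, new_species: PhytoSpecies):
        """Swap one resident's traits in place (attractor inheritance)."""
        self.species[index] = new_species
        self._rebuild_phyto_arrays()

    def copy(self) -> "FoodWeb":
        """Independent copy: trait replacements on the copy do not touch
        the original (species objects themselves are immutable)."""
        return FoodWeb(self.species, self.zoo, self.params)

    # -- probes -------------------------------------------------------------
    def make_probes(self, probe_species: Sequence[PhytoSpecies]) -> ProbeSet:
        sp = list(probe_species)
        get = lambda attr: np.array([getattr(s.traits, attr) for s in sp], float)
        vol = np.array([s.volume for s in sp], float)
        sigma = float(self.fw["sigma"])
        ratio = self.z_vol[:, None] / vol[None, :]
        phi = np.exp(-(np.log(ratio / float(self.fw["rho_opt"])) ** 2)
                     / (2.0 * sigma ** 2))
        return ProbeSet(
            species=sp, V_max=get("V_max"), K_N=get("K_N"),
            Q_min=get("Q_min"), Q_max=get("Q_max"), mu_max=get("mu_max"),
            sinking=get("sinking"),
            no3_ok=np.array([s.can_use_nitrate for s in sp], bool), phi=phi)

    # -- limitation factors -------------------------------------------------
    def gammas(self, T: np.ndarray, I: np.ndarray):
        gT = np.exp(float(self.fw["eppley_k"]) * (T - float(self.fw["T_ref"])))
        gI = 1.0 - np.exp(-I / float(self.fw["I_k"]))
        return gT, gI

    # -- core tendencies ----------------------------------------------------
    def tendencies(self, nut, det, phy, zoo, T, I, dt=None):
        """Biological time-derivatives of all tracers, vectorized over levels.

        Parameters are arrays: ``nut (L,4)``, ``det (L,4)``, ``phy (L,P,3)``,
        ``zoo (L,Z,3)``, ``T (L,)``, ``I (L,)``.  When ``dt`` is given,
        gross consumption fluxes are limited so no source pool can be
        driven below zero within one explicit step of that size (the
        limiter scales all outfluxes of an overdrawn pool by a common
        factor, which preserves the closed nitrogen budget exactly).

        Returns ``(dnut, ddet, dphy, dzoo, env)`` where ``env`` caches the
        fields a passive probe needs to experience — but not alter — the
        same environment (nutrients, limitation factors, per-grazer
        saturation and pool-limiter factors).
        """
        fw = self.fw
        L, P = phy.shape[0], phy.shape[1]
        Z = zoo.shape[1]
        NO3, NO2, NH4, DON = (nut[:, i] for i in range(4))
        POCs, PONs, POCl, PONl = (det[:, i] for i in range(4))
        C, N, Chl = phy[:, :, 0], phy[:, :, 1], phy[:, :, 2]
        Cz, Nz, Chlz = zoo[:, :, 0], zoo[:, :, 1], zoo[:, :, 2]

        gT, gI = self.gammas(T, I)
        gTc, gIc = gT[:, None], gI[:, None]

        # --- Droop uptake and growth (phyto) ---
        Q = N / np.maximum(C, _TINY)
        Qc = np.clip(Q, self.p_Qmin, self.p_Qmax)
        f_up = (self.p_Qmax - Qc) / self.p_span
        f_gr = (Qc - self.p_Qmin) / self.p_span
        din = (NO3[:, None] * self.p_no3) + NO2[:, None] + NH4[:, None]
        v_up = self.p_Vmax * f_up * din / (din + self.p_K)     # per C, d^-1
        share = v_up * C / np.maximum(din, _TINY)              # (L,P)
        U3 = share * (NO3[:, None] * self.p_no3)               # mmol N m^-3 d^-1
        U2 = share * NO2[:, None]
        U4 = share * NH4[:, None]

        # --- nutrient-pool limiters (uptake + linear chain sinks) ---
        r_n1 = float(fw["r_nitrif_nh4"])
        r_n2 = float(fw["r_nitrif_no2"])
        r_don = float(fw["r_don"])
        if dt is not None:
            f_no3 = _pool_factor(NO3, U3.sum(1), dt)
            f_no2 = _pool_factor(NO2, U2.sum(1) + r_n2 * NO2, dt)
            f_nh4 = _pool_factor(NH4, U4.sum(1) + r_n1 * NH4, dt)
        else:
            f_no3 = f_no2 = f_nh4 = np.ones(L)
        U3 *= f_no3[:, None]
        U2 *= f_no2[:, None]
        U4 *= f_nh4[:, None]
        uptakeN = U3 + U2 + U4                                  # (L,P)
        mu = self.p_mumax * gTc * gIc * f_gr                    # (L,P)

        # --- grazing (Holling III on palatability-weighted prey) ---
        preyC = np.concatenate([C, Cz], axis=1)                 # (L, P+Z)
        preyN = np.concatenate([N, Nz], axis=1)
        A = preyC @ self.phi.T                                  # (L, Z)
        kA = float(fw["k_A"])
        coef = self.z_Imax * Cz * A / (A * A + kA * kA)         # (L, Z)
        g_spec = coef @ self.phi                                # (L, P+Z) specific rate

        # --- mortality ---
        m_p = float(fw["m"])
        if fw.get("zoo_mortality", "linear") == "quadratic":
            m_z = float(fw["m_zoo"]) * Cz
        else:
            m_z = np.full_like(Cz, float(fw["m_zoo"]))
        mort_spec = np.concatenate([np.full_like(C, m_p), m_z], axis=1)

        # prey/biomass pool limiter: common factor on grazing + mortality
        loss_spec = g_spec + mort_spec
        if dt is not None:
            f_prey = np.minimum(1.0, 1.0 / np.maximum(loss_spec * dt, _TINY))
        else:
            f_prey = np.ones_like(loss_spec)
        g_spec = g_spec * f_prey
        mort_spec = mort_spec * f_prey

        # per-grazer ingestion, apportioned by palatability-weighted biomass
        wC = preyC * f_prey                                     # limiter-scaled
        wN = preyN * f_prey
        ingC = coef * (wC @ self.phi.T)                         # (L, Z)
        ingN = coef * (wN @ self.phi.T)
        beta = self.z_beta
        egC = (1.0 - beta) * ingC
        egN = (1.0 - beta) * ingN

        # --- phyto tendencies ---
        lossC_p = (g_spec[:, :P] + mort_spec[:, :P]) * C
        lossN_p = (g_spec[:, :P] + mort_spec[:, :P]) * N
        dC = mu * C - lossC_p
        theta = float(fw["theta_chl_n"])
        dN = uptakeN - lossN_p
        dChl = theta * uptakeN - (g_spec[:, :P] + mort_spec[:, :P]) * Chl

        # --- zoo tendencies ---
        q_zoo = float(fw["q_zoo"])
        r_ex = float(fw["zoo_excretion"])
        excr = r_ex * np.maximum(0.0, Nz - q_zoo * Cz)          # N -> NH4
        resp = r_ex * np.maximum(0.0, Cz - Nz / q_zoo)          # C -> implicit CO2
        lossC_z = (g_spec[:, P:] + mort_spec[:, P:]) * Cz
        lossN_z = (g_spec[:, P:] + mort_spec[:, P:]) * Nz
        dCz = beta * ingC - lossC_z - resp
        dNz = beta * ingN - lossN_z - excr
        dChlz = -(g_spec[:, P:] + mort_spec[:, P:]) * Chlz

        # --- detritus routing (small vs large by organism size) ---
        mortC = mort_spec * preyC
        mortN = mort_spec * preyN
        large = np.concatenate([self.p_large, self.z_large])
        small = ~large
        z_small, z_large = ~self.z_large, self.z_large
        dPOCs = (mortC[:, small].sum(1) + (egC * z_small).sum(1)
                 - float(fw["r_poc_small"]) * POCs)
        dPONs = (mortN[:, small].sum(1) + (egN * z_small).sum(1)
                 - float(fw["r_pon_small"]) * PONs)
        dPOCl = (mortC[:, large].sum(1) + (egC * z_large).sum(1)
                 - float(fw["r_poc_large"]) * POCl)
        dPONl = (mortN[:, large].sum(1) + (egN * z_large).sum(1)
                 - float(fw["r_pon_large"]) * PONl)

        # --- dissolved pools ---
        dNO3 = r_n2 * f_no2 * NO2 - U3.sum(1)
        dNO2 = r_n1 * f_nh4 * NH4 - r_n2 * f_no2 * NO2 - U2.sum(1)
        dNH4 = (r_don * DON + excr.sum(1)
                - r_n1 * f_nh4 * NH4 - U4.sum(1))
        dDON = (float(fw["r_pon_small"]) * PONs
                + float(fw["r_pon_large"]) * PONl - r_don * DON)

        dnut = np.stack([dNO3, dNO2, dNH4, dDON], axis=1)
        ddet = np.stack([dPOCs, dPONs, dPOCl, dPONl], axis=1)
        dphy = np.stack([dC, dN, dChl], axis=2)
        dzoo = np.stack([dCz, dNz, dChlz], axis=2)

        env = {
            "NO3": NO3, "NO2": NO2, "NH4": NH4,
            "f_no3": f_no3, "f_no2": f_no2, "f_nh4": f_nh4,
            "coef": coef, "gT": gT, "gI": gI,
        }
        return dnut, ddet, dphy, dzoo, env

    def probe_tendencies(self, probes: ProbeSet, pstate, env, dt=None):
        """Tendencies of passive probe tracers in the cached environment.

        Probes experience the residents' nutrient fields, light and
        grazer saturation through the same formulas — including the same
        pool-limiter factors — but contribute nothing back, so a probe
        that clones a resident follows the identical per-capita dynamics.
        """
        C, N, Chl = pstate[:, :, 0], pstate[:, :, 1], pstate[:, :, 2]
        Q = N / np.maximum(C, _TINY)
        Qc = np.clip(Q, probes.Q_min, probes.Q_max)
        span = probes.Q_max - probes.Q_min
        f_up = (probes.Q_max - Qc) / span
        f_gr = (Qc - probes.Q_min) / span
        NO3e = env["NO3"][:, None] * probes.no3_ok
        din = NO3e + env["NO2"][:, None] + env["NH4"][:, None]
        v_up = probes.V_max * f_up * din / (din + probes.K_N)
        share = v_up / np.maximum(din, _TINY)
        upt = (share * NO3e * env["f_no3"][:, None]
               + share * env["NO2"][:, None] * env["f_no2"][:, None]
               + share * env["NH4"][:, None] * env["f_nh4"][:, None])   # per C
        mu = probes.mu_max * env["gT"][:, None] * env["gI"][:, None] * f_gr
        g_spec = env["coef"] @ probes.phi                                # (L, M)
        loss = g_spec + float(self.fw["m"])
        if dt is not None:
            loss = loss * np.minimum(1.0, 1.0 / np.maximum(loss * dt, _TINY))
        theta = float(self.fw["theta_chl_n"])
        dC = mu * C - loss * C
        dN = upt * C - loss * N
        dChl = theta * upt * C - loss * Chl
        return np.stack([dC, dN, dChl], axis=2)


def _pool_factor(pool, sink_rate, dt):
    """Common scaling of all outfluxes so ``pool`` stays non-negative."""
    need = sink_rate * dt
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(need > pool, pool / np.maximum(need, _TINY), 1.0)
    return np.minimum(f, 1.0)


def local_tendencies(state: LocalState, env: Environment,
                     web: FoodWeb, dt: float | None = None) -> LocalState:
    """Single-level wrapper around :meth:`FoodWeb.tendencies`.

    Returns a :class:`LocalState` holding the time-derivative of every
    field.  The biological terms transfer nitrogen between pools only, so
    ``result.total_nitrogen()`` is zero to machine precision.
    """
    if (state.nut < 0).any() or (state.det < 0).any() \
            or (state.phy < 0).any() or (state.zoo < 0).any():
        raise ValueError("negative concentrations violate the state invariants")
    dnut, ddet, dphy, dzoo, _ = web.tendencies(
        state.nut[None, :], state.det[None, :], state.phy[None, :, :],
        state.zoo[None, :, :], np.array([env.temperature]),
        np.array([env.irradiance]), dt=dt)
    return LocalState(nut=dnut[0], det=ddet[0], phy=dphy[0], zoo=dzoo[0])
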