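import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evoplankton.allometry import build_species
from evoplankton.foodweb import (Environment, FoodWeb, LocalState, ZooSpecies,
                                 count_state_equations, droop_terms,
                                 grazing_flux, local_tendencies, palatability,
                                 zooplankton_from_params)


@pytest.fixture(scope="module")
def zoo_one():
    return ZooSpecies(id="z", volume=1e6, I_max=5.0, rho_opt=1000.0,
                      sigma=0.6, assimilation=0.3)


# --- state-equation bookkeeping -----------------------------------------

@pytest.mark.parametrize("n_phyto, expected", [(8, 59), (80, 275)])
def test_equation_count_matches_community_size(n_phyto, expected):
    assert count_state_equations(n_phyto, 9) == expected


def test_equation_count_is_affine_with_three_per_species():
    counts = [count_state_equations(n, 9) for n in range(0, 30)]
    assert set(np.diff(counts)) == {3}


# --- Droop terms ---------------------------------------------------------

def test_droop_uptake_vanishes_at_full_quota(ftypes):
    sp = build_species(ftypes["Synechococcus"], 3.0)
    env = Environment(temperature=10.0, irradiance=100.0)
    up, _ = droop_terms(sp, N=1.0, Q=sp.traits.Q_max, env=env)
    assert up == 0.0


def test_droop_growth_vanishes_at_minimum_quota(ftypes):
    sp = build_species(ftypes["Synechococcus"], 3.0)
    env = Environment(temperature=10.0, irradiance=100.0)
    _, gr = droop_terms(sp, N=1.0, Q=sp.traits.Q_min, env=env)
    assert gr == 0.0


def test_droop_uptake_vanishes_without_nutrient(ftypes):
    sp = build_species(ftypes["Synechococcus"], 3.0)
    env = Environment(temperature=10.0, irradiance=100.0)
    up, _ = droop_terms(sp, N=0.0, Q=sp.traits.Q_min, env=env)
    assert up == 0.0


def test_droop_rejects_quota_outside_bounds(ftypes):
    sp = build_species(ftypes["Synechococcus"], 3.0)
    env = Environment(temperature=10.0, irradiance=100.0)
    with pytest.raises(ValueError):
        droop_terms(sp, N=1.0, Q=sp.traits.Q_max * 1.5, env=env)


# --- grazing kernel -------------------------------------------------------

def test_palatability_peaks_at_optimal_ratio(zoo_one):
    assert palatability(zoo_one.volume / zoo_one.rho_opt, zoo_one) == pytest.approx(1.0)


@given(k=st.floats(1.01, 50.0))
@settings(max_examples=40, deadline=None)
def test_palatability_symmetric_in_log_ratio(k):
    zoo = ZooSpecies(id="z", volume=1e6, I_max=5.0, rho_opt=1000.0,
                     sigma=0.6, assimilation=0.3)
    opt = zoo.volume / zoo.rho_opt
    assert palatability(opt * k, zoo) == pytest.approx(palatability(opt / k, zoo),
                                                       rel=1e-9)


def test_palatability_tail_is_negligible_five_sigma_out(zoo_one):
    opt = zoo_one.volume / zoo_one.rho_opt
    v = opt * np.exp(5 * zoo_one.sigma)
    assert palatability(v, zoo_one) < 1e-5


def test_grazing_zero_without_prey(zoo_one):
    flux = grazing_flux(zoo_one, 1.0, [10.0, 100.0], [0.0, 0.0], k_A=0.5)
    assert np.all(flux == 0.0)


def test_grazing_half_saturation_identity(zoo_one):
    # a single perfectly palatable prey whose biomass equals k_A
    k_A = 0.5
    prey_v = zoo_one.volume / zoo_one.rho_opt
    flux = grazing_flux(zoo_one, 2.0, [prey_v], [k_A], k_A=k_A)
    assert flux.sum() == pytest.approx(zoo_one.I_max * 2.0 / 2.0, rel=1e-12)


def test_unpalatable_prey_receives_zero_flux(zoo_one):
    prey_v = zoo_one.volume / zoo_one.rho_opt
    flux = grazing_flux(zoo_one, 1.0, [prey_v, prey_v * 1e12], [1.0, 50.0], k_A=0.5)
    assert flux[1] < 1e-30


def test_grazing_monotone_in_available_prey(zoo_one):
    prey_v = zoo_one.volume / zoo_one.rho_opt
    totals = [grazing_flux(zoo_one, 1.0, [prey_v], [b], k_A=0.5).sum()
              for b in np.linspace(0, 10, 25)]
    assert np.all(np.diff(totals) >= 0)


def test_default_spectrum_covers_the_phyto_size_range(small_params, ftypes):
    zoo = zooplankton_from_params(small_params)
    assert len(zoo) == 9
    opt_prey = np.array([z.volume / z.rho_opt for z in zoo])
    lo = min(ftypes[n].volume_range[0] for n in ftypes)
    hi = max(ftypes[n].volume_range[1] for n in ftypes)
    assert opt_prey.min() <= lo and opt_prey.max() >= hi


# --- local tendencies: conservation and special cases ---------------------

def _web(small_params, ftypes, names_volumes):
    species = [build_species(ftypes[n], v, sid=f"{n}-{v}")
               for n, v in names_volumes]
    return FoodWeb(species, zooplankton_from_params(small_params), small_params)


def _random_state(rng, n_phyto, n_zoo):
    nut = rng.uniform(0, 5, 4)
    det = rng.uniform(0, 1, 4)
    phy = np.empty((n_phyto, 3))
    phy[:, 0] = rng.uniform(0, 3, n_phyto)
    phy[:, 1] = phy[:, 0] * rng.uniform(0.04, 0.16, n_phyto)
    phy[:, 2] = phy[:, 1] * 1.6
    zoo = np.empty((n_zoo, 3))
    zoo[:, 0] = rng.uniform(0, 2, n_zoo)
    zoo[:, 1] = zoo[:, 0] * rng.uniform(0.1, 0.2, n_zoo)
    zoo[:, 2] = 0.0
    return LocalState(nut=nut, det=det, phy=phy, zoo=zoo)


def test_biological_tendencies_conserve_nitrogen(small_params, ftypes):
    web = _web(small_params, ftypes,
               [("Synechococcus", 3.0), ("diatom", 1e4),
                ("Prochlorococcus", 0.3), ("small-eukaryote", 200.0)])
    env = Environment(temperature=8.0, irradiance=50.0)
    rng = np.random.default_rng(0)
    for _ in range(25):
        state = _random_state(rng, 4, 9)
        d = local_tendencies(state, env, web)
        scale = abs(d.nut).sum() + abs(d.phy[:, 1]).sum() + 1.0
        assert abs(d.total_nitrogen()) < 1e-12 * scale


def test_empty_biota_has_zero_biological_tendencies(small_params, ftypes):
    web = _web(small_params, ftypes, [("Synechococcus", 3.0)])
    state = LocalState(nut=np.array([5.0, 0.0, 0.0, 0.0]), det=np.zeros(4),
                       phy=np.zeros((1, 3)), zoo=np.zeros((9, 3)))
    d = local_tendencies(state, Environment(10.0, 100.0), web)
    assert np.all(d.phy == 0) and np.all(d.zoo == 0) and np.all(d.det == 0)
    assert np.all(d.nut == 0)


def test_negative_state_is_rejected(small_params, ftypes):
    web = _web(small_params, ftypes, [("Synechococcus", 3.0)])
    state = LocalState(nut=np.array([-1.0, 0.1, 0.1, 0.0]), det=np.zeros(4),
                       phy=np.zeros((1, 3)), zoo=np.zeros((9, 3)))
    with pytest.raises(ValueError):
        local_tendencies(state, Environment(10.0, 100.0), web)


def test_prochlorococcus_starves_on_pure_nitrate(small_params, ftypes):
    """With an NO3-only nutrient pool, Prochlorococcus takes up nothing and
    its biomass declines at the background mortality rate."""
    web = _web(small_params, ftypes, [("Prochlorococcus", 0.3)])
    phy = np.array([[1.0, 0.08, 0.0]])
    state = LocalState(nut=np.array([10.0, 0.0, 0.0, 0.0]), det=np.zeros(4),
                       phy=phy, zoo=np.zeros((9, 3)))
    d = local_tendencies(state, Environment(10.0, 100.0), web)
    m = small_params["foodweb"]["m"]
    assert d.nut[0] == 0.0                       # no nitrate drawdown
    assert d.phy[0, 1] == pytest.approx(-m * phy[0, 1])   # pure mortality on N
    # carbon still grows on the standing quota: only uptake is blocked
    assert d.phy[0, 0] <= phy[0, 0] * (web.p_mumax[0] - 0)
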