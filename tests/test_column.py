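import numpy as np
import pytest

from evoplankton.allometry import build_species
from evoplankton.column import (ColumnGrid, diffuse, light_profile,
                                make_forcing, make_grid, sink, state_distance)
from evoplankton.experiment import build_simulator


# --- grid -----------------------------------------------------------------

def test_grid_thicknesses_sum_to_depth():
    g = make_grid(35, 3275.0)
    assert g.n_levels == 35
    assert g.thickness.sum() == pytest.approx(3275.0)
    assert np.all(np.diff(g.thickness) > 0)      # stretched: finest on top


def test_grid_falls_back_to_uniform_when_unstretchable():
    g = make_grid(10, 40.0, min_dz=5.0)
    assert np.allclose(g.thickness, 4.0)


def test_grid_rejects_inconsistent_thicknesses():
    with pytest.raises(ValueError):
        ColumnGrid(np.array([1.0, 2.0]), depth=10.0)


# --- forcing --------------------------------------------------------------

def test_forcing_is_annual_periodic(small_params):
    grid = make_grid(10, 400.0)
    f = make_forcing(small_params, grid)
    for t in (3.7, 100.2, 210.0):
        assert f.at(t)[0] == f.at(t + 365)[0]
        assert np.array_equal(f.at(t)[1], f.at(t + 365)[1])
        assert np.array_equal(f.at(t)[2], f.at(t + 365)[2])


def test_winter_mixing_exceeds_summer_in_upper_column(small_params):
    grid = make_grid(10, 400.0)
    f = make_forcing(small_params, grid)
    iface = np.cumsum(grid.thickness)[:-1]
    upper = iface <= 200.0
    k_winter = f.kappa[15]       # mid-January
    k_summer = f.kappa[196]      # mid-July
    assert np.all(k_winter[upper] >= k_summer[upper])
    assert f.irradiance[172] > f.irradiance[355]     # solstice vs winter


def test_zero_amplitude_seasonality_gives_constant_forcing(small_params):
    from evoplankton.params import deep_merge
    p = deep_merge(small_params, {"forcing": {
        "I_winter": 80.0, "I_summer": 80.0,
        "T_surface_winter": 6.0, "T_surface_summer": 6.0,
        "mld_winter": 100.0, "mld_summer": 100.0}})
    f = make_forcing(p, make_grid(10, 400.0))
    assert np.ptp(f.irradiance) == 0
    assert np.ptp(f.temperature, axis=0).max() == 0
    assert np.ptp(f.kappa, axis=0).max() == 0


# --- light ----------------------------------------------------------------

def test_light_profile_dark_surface_stays_dark():
    grid = make_grid(10, 400.0)
    assert np.all(light_profile(0.0, np.full(10, 0.05), grid) == 0)


def test_light_profile_matches_beer_lambert_closed_form():
    grid = ColumnGrid(np.full(20, 5.0), 100.0)
    k = 0.07
    I = light_profile(200.0, np.full(20, k), grid)
    assert np.allclose(I, 200.0 * np.exp(-k * grid.mid), rtol=1e-12)


def test_extra_absorber_never_brightens_deeper_levels():
    grid = make_grid(10, 400.0)
    base = np.full(10, 0.04)
    shaded = base.copy()
    shaded[2] += 0.5
    I0, I1 = (light_profile(100.0, k, grid) for k in (base, shaded))
    assert np.all(I1 <= I0 + 1e-15)
    assert np.all(np.diff(I1) <= 0)


# --- diffusion ------------------------------------------------------------

def test_diffusion_conserves_column_integral():
    grid = make_grid(12, 600.0)
    rng = np.random.default_rng(1)
    fields = rng.uniform(0, 5, (12, 7))
    kappa = rng.uniform(0.1, 500.0, 11)
    out = diffuse(fields, kappa, grid, dt=0.5)
    before = (fields * grid.thickness[:, None]).sum(0)
    after = (out * grid.thickness[:, None]).sum(0)
    assert np.allclose(after, before, rtol=1e-12)


def test_diffusion_leaves_uniform_profile_unchanged():
    grid = make_grid(12, 600.0)
    fields = np.full((12, 2), 3.3)
    out = diffuse(fields, np.full(11, 100.0), grid, dt=1.0)
    assert np.allclose(out, 3.3, rtol=1e-12)


def test_diffusion_creates_no_new_extrema():
    grid = make_grid(15, 500.0)
    rng = np.random.default_rng(2)
    f = rng.uniform(0, 1, (15, 1))
    out = diffuse(f, np.full(14, 50.0), grid, dt=0.2)
    assert out.min() >= f.min() - 1e-12 and out.max() <= f.max() + 1e-12


def test_two_box_exchange_matches_direct_linear_solve():
    """One implicit step on a 2-level grid equals the closed-form solution
    of the 2x2 backward-Euler system."""
    grid = ColumnGrid(np.array([10.0, 30.0]), 40.0)
    kappa, dt = np.array([25.0]), 0.7
    c0 = np.array([4.0, 1.0])
    a = kappa[0] / grid.iface_dist[0]
    A = np.array([[-a / 10.0, a / 10.0], [a / 30.0, -a / 30.0]])
    expected = np.linalg.solve(np.eye(2) - dt * A, c0)
    out = diffuse(c0.reshape(2, 1), kappa, grid, dt)[:, 0]
    assert np.allclose(out, expected, rtol=1e-12)


# --- sinking --------------------------------------------------------------

def test_sinking_zero_velocity_is_identity():
    grid = make_grid(10, 400.0)
    f = np.arange(10.0).reshape(10, 1)
    out, bottom = sink(f, 0.0, grid, dt=1.0)
    assert np.array_equal(out, f) and bottom[0] == 0.0


def test_sinking_conserves_mass_including_bottom_flux():
    grid = make_grid(10, 400.0)
    rng = np.random.default_rng(3)
    f = rng.uniform(0, 2, (10, 3))
    w = np.array([0.0, 5.0, 40.0])
    out, bottom = sink(f, w, grid, dt=2.0)
    before = (f * grid.thickness[:, None]).sum(0)
    after = (out * grid.thickness[:, None]).sum(0) + bottom
    assert np.allclose(after, before, rtol=1e-12)
    out2, bottom2 = sink(f, w, grid, dt=2.0, closed_bottom=True)
    assert np.all(bottom2 == 0)
    assert np.allclose((out2 * grid.thickness[:, None]).sum(0), before, rtol=1e-12)


def test_sinking_impulse_travels_at_the_prescribed_speed():
    """Centre of mass of an impulse advances by w*dt on a fine grid."""
    grid = ColumnGrid(np.full(400, 1.0), 400.0)
    f = np.zeros((400, 1))
    f[50] = 1.0
    w, dt = 3.0, 10.0
    out, _ = sink(f, w, grid, dt)
    com0 = (grid.mid * f[:, 0]).sum() / f.sum()
    com1 = (grid.mid * out[:, 0]).sum() / out.sum()
    assert com1 - com0 == pytest.approx(w * dt, rel=1e-10)


def test_sinking_cfl_substepping_stays_positive():
    grid = ColumnGrid(np.full(10, 2.0), 20.0)
    f = np.zeros((10, 1))
    f[0] = 1.0
    out, bottom = sink(f, 50.0, grid, dt=1.0)       # w*dt >> dz
    assert out.min() >= 0


# --- integrated column behavior ------------------------------------------

def test_abiotic_winter_column_mixes_toward_uniform(small_params):
    sim = build_simulator(small_params, [], zoo=[])
    sim.state.nut[:] = 0.0          # nitrate only: no remineralization sources
    sim.state.nut[:, 0] = np.linspace(0.0, 12.0, sim.grid.n_levels)
    total0 = (sim.state.nut[:, 0] * sim.grid.thickness).sum()
    sim.run_days(60)                                # deep winter mixing
    no3 = sim.state.nut[:, 0]
    assert np.ptp(no3) < 0.05 * no3.mean()
    total1 = (no3 * sim.grid.thickness).sum()
    assert total1 == pytest.approx(total0, rel=1e-10)


def test_annual_attractor_is_periodic_year_over_year(attractor_sim):
    from evoplankton.evolution import clone_simulator
    sim = clone_simulator(attractor_sim)
    a = sim.snapshot()
    sim.run_years(1)
    assert state_distance(a, sim.snapshot()) < 1e-9


def test_timestep_halving_changes_annual_biomass_little(small_params, ftypes):
    """Integration is converged in dt: halving the step moves the 1-year
    biomass by well under 1 %."""
    from evoplankton.params import deep_merge
    results = {}
    for dt in (0.1, 0.05):
        p = deep_merge(small_params, {"column": {"dt": dt}})
        sim = build_simulator(
            p, [build_species(ftypes["Synechococcus"], 3.0, sid="s")], zoo=[])
        sim.run_years(1)
        results[dt] = sim.resident_biomass()[0]
    assert results[0.05] == pytest.approx(results[0.1], rel=1e-2)
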