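"""Shared fixtures: parameter trees and pre-spun simulators.

Expensive, read-only simulations are session-scoped; tests that need to
advance a shared simulator must clone it first
(:func:`evoplankton.evolution.clone_simulator`).
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from evoplankton.allometry import build_species, functional_types_from_params
from evoplankton.experiment import apply_preset, build_simulator, run_protocol
from evoplankton.params import deep_merge, load_params

# Small fully ventilated test column: winter mixing reaches the bottom so
# the whole column is re-homogenized annually and the seasonal attractor
# is approached quickly.
SMALL_COLUMN = {
    "column": {"n_levels": 10, "depth": 400.0, "dt": 0.1},
    "forcing": {"mld_winter": 400.0},
}


@pytest.fixture(scope="session")
def params():
    return load_params()


@pytest.fixture(scope="session")
def small_params(params):
    return deep_merge(apply_preset(params, "desk"), SMALL_COLUMN)


@pytest.fixture(scope="session")
def ftypes(small_params):
    return functional_types_from_params(small_params)


@pytest.fixture(scope="session")
def attractor_sim(small_params, ftypes):
    """Grazer-free single-species column on its annual attractor.

    Read-only: clone before advancing."""
    sp = [build_species(ftypes["Synechococcus"], 3.0, sid="syn")]
    sim = build_simulator(small_params, sp, zoo=[])
    sim.run_years(12)
    return sim


@pytest.fixture(scope="session")
def mini_run(params):
    """Scaled-down two-phase protocol (8 seeded species, desk column,
    25 evolutionary cycles).  Read-only."""
    p = apply_preset(params, "desk")
    p = deep_merge(p, {"protocol": {"n_phyto_seed": 8, "phase2_years": 75}})
    return run_protocol(p, seed=3)
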