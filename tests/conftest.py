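"""Shared fixtures: small synthetic tessellations and a reusable fitted model.

Everything is generated programmatically at collection time; no data files.
"""

from __future__ import annotations

import pytest
from shapely.geometry import box

from arealgp.geometry import AreaUnit, FactorTable
from arealgp.model import fit_mle
from arealgp.simulate import make_scenario, simulate_dataset


def square_unit(uid, partition, x0, y0, size):
    return AreaUnit(
        id=uid, partition=partition, polygon=box(x0, y0, x0 + size, y0 + size)
    )


@pytest.fixture(scope="session")
def small_scenario():
    """5 coarse / 10 fine Voronoi cells on a 4 km square, 250 m sim grid."""
    return make_scenario(
        domain_size=4000.0, n_coarse=5, n_fine=10, seed=42, sim_grid_spacing=250.0
    )


@pytest.fixture(scope="session")
def small_setup(small_scenario):
    """Simulated data, grid and factor table for the small scenario."""
    scen = small_scenario
    sim = simulate_dataset(scen, seed=7)
    grid = sim.sim_grid
    factors = FactorTable(scen.coarse_units, scen.fine_units, grid)
    return scen, sim, grid, factors


@pytest.fixture(scope="session")
def small_fit(small_setup):
    """Maximum-likelihood fit of the small simulated dataset."""
    scen, sim, grid, factors = small_setup
    return fit_mle(
        sim.data, grid, options={"n_starts": 2, "seed": 0, "factors": factors}
    )


@pytest.fixture(scope="session")
def desk_scenario():
    """The default desk-scale study scenario (30/90 cells on 10 km)."""
    return make_scenario(seed=5)
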