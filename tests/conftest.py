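"""Shared fixtures: reduced-scale ensembles and a cache of converged solves.

Ensembles here are deliberately small (seeded, documented as reduced) so the
whole suite stays fast; statistical observables asserted on them carry
correspondingly loose bounds.
"""

from __future__ import annotations

import numpy as np
import pytest

from oligobrush import (
    BindingConstants,
    ChainGeometry,
    Grid,
    build_sequence,
    generate_ensemble,
    solve_bulk,
)
from oligobrush.core import solve_state_point

CI_SEED = 20181403


@pytest.fixture(scope="session")
def geometry():
    return ChainGeometry()


@pytest.fixture(scope="session")
def grid():
    return Grid()


@pytest.fixture(scope="session")
def constants():
    return BindingConstants.from_parameters()


@pytest.fixture(scope="session")
def ci_ensemble(geometry, grid):
    """Reduced ensemble: 3000 accepted conformations of A6G6, fixed seed."""
    return generate_ensemble(
        build_sequence("A6G6"),
        geometry,
        grid,
        rotations_per_state=1,
        seed=CI_SEED,
        max_conformations=3000,
    )


@pytest.fixture(scope="session")
def midsize_ensemble(geometry, grid):
    """~4e4-conformation A6G6 ensemble for the quantitative brush checks."""
    return generate_ensemble(
        build_sequence("A6G6"), geometry, grid, rotations_per_state=8, seed=CI_SEED
    )


@pytest.fixture(scope="session")
def solve_cache(midsize_ensemble, constants):
    """Converged solutions at canonical state points, solved once per session."""
    cache = {}

    def get(sigma_p: float, c_mg: float):
        key = (sigma_p, c_mg)
        if key not in cache:
            bulk = solve_bulk(0.010, c_mg, 7.0)
            sol = solve_state_point(midsize_ensemble, bulk, constants, sigma_p)
            assert sol.converged, f"solver failed at {key}"
            cache[key] = sol
        return cache[key]

    return get
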