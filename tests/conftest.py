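"""Shared fixtures: toy networks and their decompositions, computed once."""

import numpy as np
import pytest

from fdm.fdm_core import compute_response_matrix, decompose_fluxes
from fdm.fixtures import TOY_KINDS, make_toy_network, synthetic_maintenance_conditions

MU_GRID = np.linspace(0.4, 1.1, 8)
SIGMA0_TRUE, SIGMA_TRUE = 3.0, 5.0


@pytest.fixture(scope="session")
def fixtures_by_kind():
    return {kind: make_toy_network(kind) for kind in TOY_KINDS}


@pytest.fixture(scope="session")
def decompositions(fixtures_by_kind):
    """Finite-difference decomposition of every toy network."""
    out = {}
    for kind, fx in fixtures_by_kind.items():
        xi, base = compute_response_matrix(fx.model, fx.demands, fx.substrate_id)
        out[kind] = (fx, xi, decompose_fluxes(xi, fx.demands, base))
    return out


@pytest.fixture(scope="session")
def overflow_decomp(decompositions):
    return decompositions["overflow"]


@pytest.fixture(scope="session")
def maintenance_conditions_noiseless():
    return synthetic_maintenance_conditions(SIGMA0_TRUE, SIGMA_TRUE, MU_GRID)


@pytest.fixture(scope="session")
def maintenance_conditions_noisy():
    return synthetic_maintenance_conditions(
        SIGMA0_TRUE, SIGMA_TRUE, MU_GRID, noise_sd_frac=0.02, seed=42
    )
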