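"""Shared fixtures and the cached desk-scale simulation runner.

Several acceptance checks need fitted A0 thresholds for overlapping
parameter configurations; ``a0_cache`` runs each configuration once per
session and shares the result across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from a0sim import A0Model, Ellipsoid, GridSpec, SimulationParams

#: Simulations per configuration for threshold-level checks.
DESK_N = 2000
#: Master seed for the desk-scale runs.
DESK_SEED = 20260927


@pytest.fixture(scope="session")
def a0_cache():
    """Memoized runner: parameter overrides -> fitted A0Results."""
    cache: dict[tuple, object] = {}

    def run(n_sims: int = DESK_N, **overrides):
        key = (n_sims, tuple(sorted(overrides.items())))
        if key not in cache:
            params = SimulationParams(seed=DESK_SEED, **overrides)
            cache[key] = A0Model.from_params(params, n_sims=n_sims).fit()
        return cache[key]

    return run


@pytest.fixture
def grid20():
    return GridSpec((20, 20, 20), (1.0, 1.0, 1.0))


@pytest.fixture
def grid40():
    return GridSpec((40, 40, 40), (1.0, 1.0, 1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def sphere_mask(grid: GridSpec, radius: float, center=(0.0, 0.0, 0.0), label="mask"):
    return Ellipsoid.sphere(center, radius).rasterize(grid, label)
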