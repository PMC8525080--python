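from __future__ import annotations

import numpy as np
import pytest

import koalastpp as k


def make_square_study(
    side: float = 12.0,
    resolution: float = 1.0,
    seed: int = 7,
    n_density: int = 2,
    n_roads: int = 3,
):
    """Small synthetic study: square region, smooth covariates, roads."""
    from koalastpp.studies import build_square_study

    return build_square_study(side=side, resolution=resolution, seed=seed,
                              n_density=n_density, n_roads=n_roads)


def simulate_study(
    stack,
    grid,
    params: k.ModelParams,
    T: int,
    seed: int,
    target_total: float | None = None,
    season: k.SeasonCalendar | None = None,
):
    """Calibrate λ0 (if a target is given) and simulate T monthly patterns."""
    if target_total is not None:
        params.lambda0 = k.calibrate_lambda0(target_total, T, stack, grid, params)
    sim = k.SimConfig(
        T=T, true_params=params, seed=seed,
        season=season or k.SeasonCalendar(),
    )
    return k.simulate_stpp(sim, stack, grid)


@pytest.fixture(scope="session")
def small_study():
    return make_square_study()


@pytest.fixture(scope="session")
def unit_square_points():
    return np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
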