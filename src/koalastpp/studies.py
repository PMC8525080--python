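"""Canned synthetic study configurations.

These bundle the generator, fitting and intercept estimation into
single-call study runs used by the test suite, the acceptance script and
as worked examples.  The default truth is a two-density-covariate,
one-bias-covariate configuration with aggregative interaction in both
seasons (stronger in the mating season) and a kernel scale below the
interaction range.
"""

from __future__ import annotations

import numpy as np

from .covariates import CovariateStack, assemble_stack
from .inference import FitResult, estimate_lambda0, fit
from .model import ModelParams
from .region import Grid, StudyRegion, build_grid, build_region
from .synthetic import (
    SimConfig,
    calibrate_lambda0,
    generate_covariate_fields,
    generate_roads,
    simulate_stable,
)

__all__ = ["build_square_study", "default_true_params", "recovery_study"]


def default_true_params() -> ModelParams:
    return ModelParams(gamma=[0.6, -0.4], beta=[-0.7],
                       theta1=2.0, theta2=2.5, phi=0.4)


def build_square_study(
    side: float = 30.0,
    resolution: float = 1.0,
    seed: int = 0,
    n_density: int = 2,
    n_roads: int = 3,
) -> tuple[StudyRegion, Grid, CovariateStack, list]:
    """Square study region with generated covariates and a road network."""
    corners = np.array([[0, 0], [side, 0], [side, side], [0, side]], float)
    region = build_region(corners, dilation=0.0)
    grid = build_grid(region, resolution)
    rasters = generate_covariate_fields(grid, n_density, seed=seed)
    roads = generate_roads(region, n_roads, seed=seed)
    stack = assemble_stack(grid, rasters, roads=roads)
    return region, grid, stack, roads


def recovery_study(
    seed: int,
    side: float = 30.0,
    T: int = 36,
    target_total: float = 3000.0,
    true_params: ModelParams | None = None,
) -> dict:
    """Simulate from known parameters and refit: the parameter-recovery
    experiment.

    Returns a dict with the ground truth, the fitted :class:`FitResult`
    (λ0 estimated), the event count and the number of simulation attempts
    (realizations that tripped the runaway guard are redrawn).
    """
    true = true_params if true_params is not None else default_true_params()
    _, grid, stack, _ = build_square_study(side=side, seed=seed)
    true.lambda0 = calibrate_lambda0(target_total, T, stack, grid, true)
    sim = SimConfig(T=T, true_params=true, seed=seed)
    patterns, true_surfaces, attempts = simulate_stable(sim, stack, grid)
    result: FitResult = fit(patterns, stack, grid)
    estimate_lambda0(result, patterns, stack, grid)
    return {
        "truth": true,
        "fit": result,
        "patterns": patterns,
        "stack": stack,
        "grid": grid,
        "n_events": sum(len(p) for p in patterns),
        "attempts": attempts,
    }
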