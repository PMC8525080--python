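"""Building blocks of the self-exciting spatio-temporal intensity model.

The conditional intensity factorizes as

    λ(x, t | H_t) = λ0 · q(x,t) · r(x,t | H_t) · b(x,t)

with log-linear covariate effects log q = γᵀe(x), log b = βᵀd(x), and a
pairwise-interaction term driven by the previous period's events:

    r(x, t | H_t) = ∏_{j : t_j = t-1} { 1 + [θ(t) - 1] · f(‖x - x_j‖) }

    f(s) = exp(-s/φ)  if s < u,  else 0

where u is the square root of the home-range area (the interaction range)
and φ the decay scale.  θ(t) switches between an off-season value θ1 and a
mating-season value θ2; θ > 1 aggregates, θ = 1 is no interaction, and
0 < θ < 1 inhibits.  λ0·q·r (bias excluded) is the true animal density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .covariates import CovariateStack
from .region import Grid
from .sightings import MonthlyPattern

__all__ = [
    "InteractionConfig",
    "ModelParams",
    "SeasonCalendar",
    "bias_factor_b",
    "covariate_factor_q",
    "intensity_surface",
    "interaction_r",
    "kernel_f",
    "log_interaction",
]


@dataclass
class ModelParams:
    gamma: np.ndarray  # density-covariate coefficients
    beta: np.ndarray  # bias-covariate coefficients
    theta1: float  # off-season interaction strength
    theta2: float  # mating-season interaction strength
    phi: float  # kernel decay scale, km
    lambda0: float | None = None  # intercept, events·km⁻²·period⁻¹

    def __post_init__(self) -> None:
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.theta1 <= 0 or self.theta2 <= 0:
            raise ValueError("theta parameters must be positive")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.lambda0 is not None and self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")


@dataclass(frozen=True)
class SeasonCalendar:
    """Which calendar months use the mating-season interaction θ2."""

    mating_months: frozenset[int] = frozenset({8, 9})

    def __post_init__(self) -> None:
        if not self.mating_months <= set(range(1, 13)):
            raise ValueError("mating months must be calendar months 1..12")

    def theta_at(self, month_index: int, params: ModelParams) -> float:
        """θ(t) for a period index (period 0 = January of the start year)."""
        return (
            params.theta2
            if (month_index % 12 + 1) in self.mating_months
            else params.theta1
        )


@dataclass(frozen=True)
class InteractionConfig:
    """Interaction range u = sqrt(home-range area), km."""

    u: float = math.sqrt(0.35)

    def __post_init__(self) -> None:
        if self.u <= 0:
            raise ValueError("u must be positive")


def covariate_factor_q(gamma: np.ndarray, e_cell: np.ndarray) -> float | np.ndarray:
    """q = exp(γᵀe); accepts a single cell vector or an (n, p) matrix."""
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    e = np.asarray(e_cell, dtype=float)
    if e.shape[-1] != gamma.shape[0]:
        raise ValueError("gamma / covariate length mismatch")
    return np.exp(e @ gamma)


def bias_factor_b(beta: np.ndarray, d_cell: np.ndarray) -> float | np.ndarray:
    """b = exp(βᵀd); b ≡ 1 for an empty bias covariate set."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    d = np.asarray(d_cell, dtype=float)
    if beta.size == 0:
        base = d.shape[:-1] if d.ndim > 1 else ()
        return np.ones(base) if base else 1.0
    if d.shape[-1] != beta.shape[0]:
        raise ValueError("beta / covariate length mismatch")
    return np.exp(d @ beta)


def kernel_f(dist, phi: float, u: float):
    """Truncated-exponential interaction kernel on [0, u): exp(-dist/φ),
    exactly 0 at and beyond the interaction range u."""
    dist = np.asarray(dist, dtype=float)
    if np.any(dist < 0):
        raise ValueError("negative distance")
    if phi <= 0 or u <= 0:
        raise ValueError("phi and u must be positive")
    out = np.where(dist < u, np.exp(-dist / phi), 0.0)
    return float(out) if out.ndim == 0 else out


def log_interaction(
    points: np.ndarray,
    history: np.ndarray,
    theta: float,
    phi: float,
    u: float,
) -> np.ndarray:
    """log r at each query point given the previous period's events.

    Evaluated in log space as Σ_j log1p((θ-1)·f) for numerical safety when
    many history points interact.  Empty history → zeros.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    hist = np.asarray(history, dtype=float).reshape(-1, 2)
    if hist.shape[0] == 0:
        return np.zeros(pts.shape[0])
    dx = pts[:, 0, None] - hist[None, :, 0]
    dy = pts[:, 1, None] - hist[None, :, 1]
    f = kernel_f(np.hypot(dx, dy), phi, u)
    return np.log1p((theta - 1.0) * f).sum(axis=1)


def interaction_r(
    cell: np.ndarray,
    t: int,
    history: MonthlyPattern | np.ndarray | None,
    params: ModelParams,
    season: SeasonCalendar,
    cfg: InteractionConfig,
) -> float | np.ndarray:
    """r(x, t | H_t) at one or more locations, conditioning on the pattern
    of the immediately preceding period (``history``; None or empty → 1)."""
    hist = np.empty((0, 2)) if history is None else _points_of(history)
    theta = season.theta_at(t, params)
    pts = np.asarray(cell, dtype=float).reshape(-1, 2)
    out = np.exp(log_interaction(pts, hist, theta, params.phi, cfg.u))
    return float(out[0]) if np.asarray(cell).ndim == 1 else out


def intensity_surface(
    t: int,
    history: MonthlyPattern | np.ndarray | None,
    stack: CovariateStack,
    grid: Grid,
    params: ModelParams,
    include_bias: bool = True,
    include_intercept: bool = True,
    season: SeasonCalendar | None = None,
    cfg: InteractionConfig | None = None,
) -> np.ndarray:
    """Per-masked-cell intensity at period t: product of the requested
    factors (λ0 iff include_intercept, q, r, and b iff include_bias).

    With the bias excluded this is the true-density predictor λ0·q·r.
    Returns a masked-cell vector (length grid.n_in).
    """
    season = season or SeasonCalendar()
    cfg = cfg or InteractionConfig()
    if stack.e.shape[0] != grid.n_in:
        raise ValueError("covariate stack not aligned with grid")
    log_lam = stack.e @ params.gamma if stack.n_density else np.zeros(grid.n_in)
    if include_bias and stack.n_bias:
        log_lam = log_lam + stack.d @ params.beta
    hist = np.empty((0, 2)) if history is None else _points_of(history)
    log_lam = log_lam + log_interaction(
        grid.masked_centers(), hist, season.theta_at(t, params), params.phi, cfg.u
    )
    if include_intercept:
        if params.lambda0 is None:
            raise ValueError("lambda0 not set on params")
        log_lam = log_lam + math.log(params.lambda0)
    return np.exp(log_lam)


def _points_of(history: MonthlyPattern | np.ndarray) -> np.ndarray:
    if isinstance(history, MonthlyPattern):
        return history.points
    return np.asarray(history, dtype=float).reshape(-1, 2)
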