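"""Partial-likelihood fitting and the plug-in intercept estimator.

The shape parameters ψ = (γ, β, log θ1, log θ2, log φ) are estimated by
maximizing the log partial likelihood

    Lp(ψ) = Σ_i log [ q(x_i,t_i) b(x_i,t_i) r(x_i,t_i|H_{t_i})
                      / ∫_A q b r dx ]

in which the intercept λ0 cancels.  The spatial integral is evaluated per
event period by midpoint quadrature on the analysis grid (cell-centre
value × cell area), and events take the piecewise-constant value of their
containing cell, so the uniform-model identity Lp = -N log|A| is exact.
λ0 is then recovered by equating the model's expected total event count
(bias included) to the observed count N:

    λ0 = N / Σ_t Σ_cells q·b·r·Δx

Standard errors are Wald-type from the inverse negative numerical Hessian
of Lp at the optimum, on the ψ scale; θ and φ intervals are mapped back
through exp.  λ0, being a plug-in, gets no interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import norm

from .covariates import CovariateStack
from .model import InteractionConfig, ModelParams, SeasonCalendar, log_interaction
from .region import Grid
from .sightings import MonthlyPattern

__all__ = [
    "FitOptions",
    "FitResult",
    "estimate_lambda0",
    "expected_total",
    "fit",
    "log_partial_likelihood",
    "wald_ci",
]


@dataclass(frozen=True)
class FitOptions:
    """Quasi-Newton settings; ``start`` overrides the default initial ψ
    (zeros for γ and β, log θ = 0, log φ = log u)."""

    gtol: float = 1e-6
    maxiter: int = 500
    start: np.ndarray | None = None


@dataclass
class FitResult:
    params: ModelParams
    logpl: float
    stderr: np.ndarray  # on the optimization (ψ) scale
    param_names: list[str]
    converged: bool
    n_events: int
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    trace: dict = field(default_factory=dict)


def _unpack(psi: np.ndarray, p: int, m: int) -> ModelParams:
    psi = np.asarray(psi, dtype=float)
    return ModelParams(
        gamma=psi[:p],
        beta=psi[p : p + m],
        theta1=math.exp(psi[p + m]),
        theta2=math.exp(psi[p + m + 1]),
        phi=math.exp(psi[p + m + 2]),
    )


def _param_names(p: int, m: int) -> list[str]:
    return (
        [f"gamma_{i + 1}" for i in range(p)]
        + [f"beta_{i + 1}" for i in range(m)]
        + ["log_theta1", "log_theta2", "log_phi"]
    )


def log_partial_likelihood(
    params: ModelParams,
    patterns: list[MonthlyPattern],
    stack: CovariateStack,
    grid: Grid,
    season: SeasonCalendar | None = None,
    cfg: InteractionConfig | None = None,
) -> float:
    """Lp at the given shape parameters (λ0 is irrelevant and ignored)."""
    season = season or SeasonCalendar()
    cfg = cfg or InteractionConfig()
    base = stack.e @ params.gamma if stack.n_density else np.zeros(grid.n_in)
    if stack.n_bias:
        base = base + stack.d @ params.beta
    centers = grid.masked_centers()
    log_area = math.log(grid.cell_area)
    lut = grid.masked_flat_lookup()

    lp = 0.0
    n_total = 0
    for t, pat in enumerate(patterns):
        n = len(pat)
        if n == 0:
            continue
        n_total += n
        hist = patterns[t - 1].points if t > 0 else np.empty((0, 2))
        theta = season.theta_at(t, params)
        logr = log_interaction(centers, hist, theta, params.phi, cfg.u)
        log_denom = logsumexp(base + logr) + log_area
        iy, ix = grid.cell_of(pat.points[:, 0], pat.points[:, 1])
        if ((ix < 0) | (ix >= grid.nx) | (iy < 0) | (iy >= grid.ny)).any():
            raise ValueError("event outside grid extent")
        idx = lut[iy * grid.nx + ix]
        if (idx < 0).any():
            raise ValueError("event in a masked-out cell")
        lp += float(np.sum(base[idx] + logr[idx]) - n * log_denom)
    if n_total == 0:
        raise ValueError("no events in any period")
    return lp


def fit(
    patterns: list[MonthlyPattern],
    stack: CovariateStack,
    grid: Grid,
    season: SeasonCalendar | None = None,
    cfg: InteractionConfig | None = None,
    opts: FitOptions | None = None,
) -> FitResult:
    """Maximize Lp over ψ = (γ, β, log θ1, log θ2, log φ) by L-BFGS.

    Deterministic given the data and start.  Non-convergence is reported
    through the ``converged`` flag and the optimizer message in ``trace``.
    """
    season = season or SeasonCalendar()
    cfg = cfg or InteractionConfig()
    opts = opts or FitOptions()
    p, m = stack.n_density, stack.n_bias
    n_events = sum(len(pat) for pat in patterns)
    if n_events == 0:
        raise ValueError("no events to fit")

    def neg_lp(psi: np.ndarray) -> float:
        return -log_partial_likelihood(
            _unpack(psi, p, m), patterns, stack, grid, season, cfg
        )

    psi0 = (
        np.asarray(opts.start, dtype=float)
        if opts.start is not None
        else np.concatenate([np.zeros(p + m), [0.0, 0.0, math.log(cfg.u)]])
    )
    res = optimize.minimize(
        neg_lp,
        psi0,
        method="L-BFGS-B",
        options={"maxiter": opts.maxiter, "gtol": opts.gtol, "ftol": 1e-12},
    )
    psi_hat = res.x
    hess = _numerical_hessian(neg_lp, psi_hat)
    stderr = _stderr_from_hessian(hess)

    params = _unpack(psi_hat, p, m)
    result = FitResult(
        params=params,
        logpl=-float(res.fun),
        stderr=stderr,
        param_names=_param_names(p, m),
        converged=bool(res.success),
        n_events=n_events,
        trace={
            "nit": int(res.nit),
            "nfev": int(res.nfev),
            "message": str(res.message),
            "psi_hat": psi_hat.tolist(),
        },
    )
    result.ci95 = wald_ci(result, 0.95)
    return result


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; step scaled per coordinate."""
    n = x.size
    steps = h * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = steps[i]
        for j in range(i, n):
            ej = np.zeros(n)
            ej[j] = steps[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * steps[i] * steps[j])
    return H


def _stderr_from_hessian(hess_neg_lp: np.ndarray) -> np.ndarray:
    """Wald standard errors from the observed-information eigenstructure.

    Directions with (numerically) non-positive curvature are flat at the
    optimum — the data carry no information there — and contribute
    infinite variance; parameters loading on them get se = inf rather
    than contaminating the whole inverse.
    """
    H = 0.5 * (hess_neg_lp + hess_neg_lp.T)
    w, V = np.linalg.eigh(H)
    tol = max(1e-12, 1e-10 * abs(w).max())
    n = H.shape[0]
    se = np.empty(n)
    for j in range(n):
        loads = V[j, :] ** 2
        if (loads[w <= tol] > 1e-10).any():
            se[j] = np.inf
        else:
            se[j] = math.sqrt(float((loads[w > tol] / w[w > tol]).sum()))
    return se


def wald_ci(fit_result: FitResult, level: float = 0.95) -> dict[str, tuple[float, float]]:
    """Wald intervals per parameter on the natural scale.

    Intervals for log-scale parameters (θ1, θ2, φ) are exponentiated, so
    they are positive and asymmetric around the point estimate.  Entries
    with an unavailable standard error map to (nan, nan).
    """
    z = norm.ppf(0.5 + level / 2.0)
    psi = np.asarray(fit_result.trace["psi_hat"], dtype=float)
    out: dict[str, tuple[float, float]] = {}
    for k, name in enumerate(fit_result.param_names):
        se = fit_result.stderr[k]
        lo, hi = psi[k] - z * se, psi[k] + z * se
        if name.startswith("log_"):
            out[name.removeprefix("log_")] = (_safe_exp(lo), _safe_exp(hi))
        else:
            out[name] = (lo, hi)
    return out


def _safe_exp(v: float) -> float:
    # weakly identified directions can have enormous Wald half-widths
    try:
        return math.exp(v)
    except OverflowError:
        return math.inf


def expected_total(
    params: ModelParams,
    patterns: list[MonthlyPattern],
    stack: CovariateStack,
    grid: Grid,
    season: SeasonCalendar | None = None,
    cfg: InteractionConfig | None = None,
    include_intercept: bool = True,
) -> float:
    """Σ_t ∫_A λ0·q·b·r dx by midpoint quadrature (λ0 omitted if asked)."""
    season = season or SeasonCalendar()
    cfg = cfg or InteractionConfig()
    base = stack.e @ params.gamma if stack.n_density else np.zeros(grid.n_in)
    if stack.n_bias:
        base = base + stack.d @ params.beta
    centers = grid.masked_centers()
    total = 0.0
    for t in range(len(patterns)):
        hist = patterns[t - 1].points if t > 0 else np.empty((0, 2))
        theta = season.theta_at(t, params)
        logr = log_interaction(centers, hist, theta, params.phi, cfg.u)
        total += float(np.exp(base + logr).sum()) * grid.cell_area
    if include_intercept:
        if params.lambda0 is None:
            raise ValueError("lambda0 not set")
        total *= params.lambda0
    return total


def estimate_lambda0(
    fit_result: FitResult,
    patterns: list[MonthlyPattern],
    stack: CovariateStack,
    grid: Grid,
    season: SeasonCalendar | None = None,
    cfg: InteractionConfig | None = None,
) -> float:
    """Moment estimator λ0 = N / Σ_t ∫_A q·b·r dx; also stored on
    ``fit_result.params.lambda0``."""
    denom = expected_total(
        fit_result.params, patterns, stack, grid, season, cfg,
        include_intercept=False,
    )
    if denom <= 0:
        raise ValueError("empty region: zero integral")
    n = sum(len(p) for p in patterns)
    lam0 = n / denom
    fit_result.params.lambda0 = lam0
    return lam0
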