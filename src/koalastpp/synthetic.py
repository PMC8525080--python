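"""Synthetic study generator: covariate fields, a road network, and
monthly sighting patterns simulated from the intensity model itself.

The generator exists so the whole pipeline — thinning, stacking, fitting,
prediction — can be exercised end to end with known ground truth and no
external data.  Simulation is generative: per period the per-cell
intensity λ(cell) is computed (including the detection bias iff the
observations are meant to be biased), a Poisson count is drawn per cell
with mean λ·cell_area, events are placed uniformly within their cell, and
the realized pattern becomes the history of the next period.

One global seed drives independent named substreams (covariates, roads,
events) so each component can be regenerated on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString

from .covariates import CovariateStack
from .model import InteractionConfig, ModelParams, SeasonCalendar, log_interaction
from .region import Grid, StudyRegion
from .sightings import HomeRangeConfig, MonthlyPattern, min_separation, thin_month

__all__ = [
    "SimConfig",
    "calibrate_lambda0",
    "generate_covariate_fields",
    "generate_roads",
    "simulate_stable",
    "simulate_stpp",
]

_SUBSTREAM = {"covariates": 101, "roads": 202, "events": 303}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _SUBSTREAM[stream]])


@dataclass
class SimConfig:
    """Ground-truth configuration of a simulated study."""

    T: int
    true_params: ModelParams
    seed: int
    season: SeasonCalendar = field(default_factory=SeasonCalendar)
    cfg: InteractionConfig = field(default_factory=InteractionConfig)
    include_bias_in_observations: bool = True
    max_expected_per_period: float = 1e5  # runaway self-excitation guard
    # Apply the monthly minimum-distance rule to each realized pattern, as
    # the analysis pipeline does to real sightings; the thinned pattern is
    # then both the observation and the next period's history.  This keeps
    # the self-excitation recursion subcritical (at most one history point
    # per home-range disc) exactly as in data the model is ever fitted to.
    thinning: HomeRangeConfig | None = None


def generate_covariate_fields(
    grid: Grid,
    n_layers: int,
    smoothness: float = 8.0,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Smooth random spatial fields on the full grid.

    Each layer is a mixture of low-frequency cosine waves plus a few
    Gaussian bumps; ``smoothness`` is the typical correlation length in km.
    Extremes are softly saturated (tanh) so that layers are bounded, like
    real habitat covariates (temperature, elevation, canopy cover), rather
    than heavy-tailed: under a log-linear intensity an unbounded covariate
    tail produces unrealistically explosive hotspot cells.  Deterministic
    per seed; layers are guaranteed non-constant.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    rng = _rng(seed, "covariates")
    xs, ys = grid.center_coords()
    xx, yy = np.meshgrid(xs, ys)
    extent = max(xs.max() - xs.min(), ys.max() - ys.min(), grid.resolution)
    out: dict[str, np.ndarray] = {}
    for k in range(n_layers):
        field_ = np.zeros_like(xx)
        for _ in range(6):
            freq = rng.uniform(0.3, 1.5) / smoothness
            angle = rng.uniform(0, 2 * math.pi)
            phase = rng.uniform(0, 2 * math.pi)
            amp = rng.uniform(0.5, 1.0)
            field_ += amp * np.cos(
                2 * math.pi * freq * (xx * math.cos(angle) + yy * math.sin(angle))
                + phase
            )
        for _ in range(3):
            cx = rng.uniform(xs.min(), xs.max())
            cy = rng.uniform(ys.min(), ys.max())
            width = rng.uniform(0.5, 1.5) * smoothness
            amp = rng.uniform(-1.5, 1.5)
            field_ += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * width**2))
        if field_[grid.mask].std() <= 1e-6:  # pragma: no cover - guard
            field_ = field_ + (xx - xx.mean()) / extent
        # soft saturation at ±1.2 internal sd
        z = (field_ - field_[grid.mask].mean()) / field_[grid.mask].std()
        out[f"cov{k + 1}"] = 1.2 * np.tanh(z / 1.2)
    return out


def generate_roads(
    region: StudyRegion,
    n_segments: int,
    seed: int = 0,
) -> list[LineString]:
    """Random chords across the region's bounding box, emulating a sparse
    primary-road network."""
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    rng = _rng(seed, "roads")
    minx, miny, maxx, maxy = region.boundary.bounds
    roads = []
    for _ in range(n_segments):
        # pick two points on distinct sides of the bounding rectangle
        sides = rng.choice(4, size=2, replace=False)
        pts = []
        for s in sides:
            u = rng.uniform()
            if s == 0:
                pts.append((minx + u * (maxx - minx), miny))
            elif s == 1:
                pts.append((minx + u * (maxx - minx), maxy))
            elif s == 2:
                pts.append((minx, miny + u * (maxy - miny)))
            else:
                pts.append((maxx, miny + u * (maxy - miny)))
        roads.append(LineString(pts))
    return roads


def calibrate_lambda0(
    target_total: float,
    T: int,
    stack: CovariateStack,
    grid: Grid,
    params: ModelParams,
    include_bias: bool = True,
) -> float:
    """Intercept giving an expected total of ``target_total`` events over
    T periods under the no-interaction approximation (r ≡ 1):
    λ0 = target / (T · Σ_cells q·b·Δx)."""
    log_lam = stack.e @ params.gamma if stack.n_density else np.zeros(grid.n_in)
    if include_bias and stack.n_bias:
        log_lam = log_lam + stack.d @ params.beta
    denom = T * float(np.exp(log_lam).sum()) * grid.cell_area
    return target_total / denom


def simulate_stpp(
    sim: SimConfig,
    stack: CovariateStack,
    grid: Grid,
) -> tuple[list[MonthlyPattern], list[np.ndarray]]:
    """Simulate T monthly patterns from the model.

    Returns the observed patterns (bias included iff configured) and the
    per-period bias-excluded true-density surfaces (masked-cell vectors).
    Raises if the expected count of any period exceeds the configured cap.
    """
    params = sim.true_params
    if params.lambda0 is None:
        raise ValueError("true_params.lambda0 must be set for simulation")
    rng = _rng(sim.seed, "events")
    centers = grid.masked_centers()
    base_true = math.log(params.lambda0) + (
        stack.e @ params.gamma if stack.n_density else np.zeros(grid.n_in)
    )
    log_bias = stack.d @ params.beta if stack.n_bias else np.zeros(grid.n_in)

    patterns: list[MonthlyPattern] = []
    true_surfaces: list[np.ndarray] = []
    prev = np.empty((0, 2))
    for t in range(sim.T):
        theta = sim.season.theta_at(t, params)
        logr = log_interaction(centers, prev, theta, params.phi, sim.cfg.u)
        lam_true = np.exp(base_true + logr)
        true_surfaces.append(lam_true)
        lam_obs = (
            np.exp(base_true + log_bias + logr)
            if sim.include_bias_in_observations
            else lam_true
        )
        mean = lam_obs * grid.cell_area
        if mean.sum() > sim.max_expected_per_period:
            raise RuntimeError(
                f"expected count {mean.sum():.0f} at period {t} exceeds cap "
                f"{sim.max_expected_per_period:.0f} (runaway self-excitation?)"
            )
        counts = rng.poisson(mean)
        pts = _place_uniform(counts, centers, grid.resolution, rng)
        ids = [f"sim-{t}-{i}" for i in range(pts.shape[0])]
        if sim.thinning is not None and pts.shape[0]:
            pat = thin_month(pts, min_separation(sim.thinning),
                             month_index=t, source_ids=ids)
        else:
            pat = MonthlyPattern(t, pts, ids)
        patterns.append(pat)
        prev = pat.points
    return patterns, true_surfaces


def simulate_stable(
    sim: SimConfig,
    stack: CovariateStack,
    grid: Grid,
    max_attempts: int = 25,
) -> tuple[list[MonthlyPattern], list[np.ndarray], int]:
    """Simulate, redrawing the event substream until the runaway guard is
    not tripped.

    A self-exciting process with a multiplicative per-neighbour interaction
    is only conditionally stable: a realization can ignite a local chain
    reaction in a high-intensity cell and diverge.  Those realizations
    yield no finite analysis dataset and are discarded; the simulation is redrawn from
    the next deterministic event substream (seed offset by a fixed prime),
    which amounts to conditioning the process on non-explosion.  Returns
    the patterns, the true surfaces, and the number of attempts used.
    """
    from dataclasses import replace

    last_err: RuntimeError | None = None
    for attempt in range(max_attempts):
        trial = replace(sim, seed=sim.seed + 7919 * attempt)
        try:
            patterns, surfaces = simulate_stpp(trial, stack, grid)
            return patterns, surfaces, attempt + 1
        except RuntimeError as err:
            last_err = err
    raise RuntimeError(
        f"no stable realization in {max_attempts} attempts"
    ) from last_err


def _place_uniform(
    counts: np.ndarray,
    centers: np.ndarray,
    resolution: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform placement of per-cell event counts within their cells."""
    total = int(counts.sum())
    if total == 0:
        return np.empty((0, 2))
    cell_idx = np.repeat(np.arange(counts.size), counts)
    offsets = rng.uniform(-0.5, 0.5, size=(total, 2)) * resolution
    return centers[cell_idx] + offsets
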