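"""Grid-aligned covariate stack.

Covariates are split by role: *density* covariates e(x) enter the
ecological term q(x,t) = exp(γᵀe), while *bias* covariates d(x) (in the
study, standardized distance to primary roads) enter the detection-bias
term b(x,t) = exp(βᵀd).  All layers are standardized (zero mean, unit sd
over masked-in cells) and static in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString

from .region import Grid

__all__ = ["CovariateStack", "assemble_stack", "distance_to_lines", "standardize"]

DIST_ROADS = "distance_to_roads"


@dataclass
class CovariateStack:
    """Standardized covariate layers as masked-cell vectors.

    ``e`` is (n_in, p) in ``e_names`` order; ``d`` is (n_in, m).  ``means``
    and ``sds`` record the raw-scale standardization constants per layer.
    """

    grid: Grid
    e_names: list[str]
    e: np.ndarray
    d_names: list[str]
    d: np.ndarray
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    @property
    def n_density(self) -> int:
        return len(self.e_names)

    @property
    def n_bias(self) -> int:
        return len(self.d_names)


def distance_to_lines(grid: Grid, lines: list[LineString]) -> np.ndarray:
    """Raw raster (ny, nx) of Euclidean distance (km) from each masked-in
    cell centre to the nearest polyline; NaN outside the mask."""
    if not lines:
        raise ValueError("empty line set")
    union = shapely.union_all([shapely.geometry.shape(g) if isinstance(g, dict) else g for g in lines])
    centers = grid.masked_centers()
    pts = shapely.points(centers[:, 0], centers[:, 1])
    dist = shapely.distance(pts, union)
    return grid.full_from_masked(dist)


def standardize(raw: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, float, float]:
    """(raw - mean) / sd over masked-in cells (sd with n-1 denominator).

    Masked-out cells are set to NaN.  Raises on constant layers.
    """
    raw = np.asarray(raw, dtype=float)
    vals = raw[mask]
    if vals.size < 2:
        raise ValueError("need at least 2 masked-in cells")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("zero variance: constant covariate layer")
    out = np.full(raw.shape, np.nan)
    out[mask] = (vals - mean) / sd
    return out, mean, sd


def assemble_stack(
    grid: Grid,
    rasters: dict[str, np.ndarray],
    roads: list[LineString] | None = None,
    bias_names: list[str] | None = None,
) -> CovariateStack:
    """Standardize named raw layers and split them into density (e) and
    bias (d) roles.

    If ``roads`` is given, a ``distance_to_roads`` layer is computed and
    added.  ``bias_names`` (default: [``distance_to_roads``] when roads are
    provided, else []) selects the bias layers; everything else is a
    density layer in declared order.
    """
    layers = dict(rasters)
    if roads is not None:
        layers[DIST_ROADS] = distance_to_lines(grid, roads)
    if bias_names is None:
        bias_names = [DIST_ROADS] if roads is not None else []
    missing = [n for n in bias_names if n not in layers]
    if missing:
        raise ValueError(f"bias layer(s) not provided: {missing}")

    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    std_cols: dict[str, np.ndarray] = {}
    for name, arr in layers.items():
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (grid.ny, grid.nx):
            raise ValueError(
                f"layer {name!r} shape {arr.shape} does not match grid "
                f"({grid.ny}, {grid.nx})"
            )
        std, means[name], sds[name] = standardize(arr, grid.mask)
        std_cols[name] = std[grid.mask]

    e_names = [n for n in layers if n not in bias_names]
    n_in = grid.n_in
    e = (
        np.column_stack([std_cols[n] for n in e_names])
        if e_names
        else np.empty((n_in, 0))
    )
    d = (
        np.column_stack([std_cols[n] for n in bias_names])
        if bias_names
        else np.empty((n_in, 0))
    )
    return CovariateStack(
        grid=grid, e_names=e_names, e=e, d_names=list(bias_names), d=d,
        means=means, sds=sds,
    )
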