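"""Density surfaces, monthly population totals, annual maps, and the
density-category area table.

Predicted true density at period t is λ̂0·q·r — the detection-bias factor
b is excluded, so the surface is interpreted as animals per km².  Annual
maps are the cell-wise mean of a year's 12 monthly surfaces; the category
table bins annual-mean cell values into density classes and reports the
percentage of the study area in each class per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import CovariateStack
from .inference import FitResult
from .model import InteractionConfig, ModelParams, SeasonCalendar, intensity_surface
from .region import Grid
from .sightings import MonthlyPattern

__all__ = [
    "CategoryBreaks",
    "DensitySurface",
    "annual_mean_surface",
    "bias_surface",
    "category_area_table",
    "monthly_totals",
    "predict_series",
]


@dataclass
class DensitySurface:
    """Per-masked-cell predicted intensity for one period."""

    month_index: int
    values: np.ndarray  # (n_in,) animals·km⁻²
    bias_included: bool = False


@dataclass(frozen=True)
class CategoryBreaks:
    """Density class edges (animals·km⁻²); intervals are left-closed,
    right-open, the last one open-ended."""

    edges: tuple = (0.0, 0.0005, 0.01, 0.02, 0.025, 0.03, 0.035, 0.04, np.inf)

    def __post_init__(self) -> None:
        if not all(a < b for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly increasing")

    def labels(self) -> list[str]:
        out = []
        for a, b in zip(self.edges, self.edges[1:]):
            out.append(f">{a:g}" if np.isinf(b) else f"{a:g}-{b:g}")
        return out


def predict_series(
    fit_result: FitResult,
    patterns: list[MonthlyPattern],
    stack: CovariateStack,
    grid: Grid,
    season: SeasonCalendar | None = None,
    cfg: InteractionConfig | None = None,
    include_bias: bool = False,
) -> list[DensitySurface]:
    """One λ̂0·q·r surface per period, conditioning on the observed
    pattern of the preceding period (period 0 has no history)."""
    params = fit_result.params
    if params.lambda0 is None:
        raise ValueError("lambda0 missing: run estimate_lambda0 first")
    out = []
    for t in range(len(patterns)):
        hist = patterns[t - 1] if t > 0 else None
        vals = intensity_surface(
            t, hist, stack, grid, params,
            include_bias=include_bias, include_intercept=True,
            season=season, cfg=cfg,
        )
        out.append(DensitySurface(t, vals, bias_included=include_bias))
    return out


def monthly_totals(surfaces: list[DensitySurface], grid: Grid) -> pd.Series:
    """Expected number of animals per period: Σ_cells density × cell area."""
    flags = {s.bias_included for s in surfaces}
    if len(flags) > 1:
        raise ValueError("mixed bias_included flags in series")
    return pd.Series(
        {s.month_index: float(s.values.sum() * grid.cell_area) for s in surfaces},
        name="expected_count",
    )


def annual_mean_surface(surfaces: list[DensitySurface], year_index: int) -> DensitySurface:
    """Cell-wise mean of the 12 monthly surfaces of one study year
    (year_index 0 = first study year)."""
    months = [s for s in surfaces if s.month_index // 12 == year_index]
    if len(months) != 12:
        raise ValueError(
            f"year {year_index} has {len(months)} monthly surfaces, need 12"
        )
    vals = np.mean([s.values for s in months], axis=0)
    return DensitySurface(
        month_index=12 * year_index, values=vals,
        bias_included=months[0].bias_included,
    )


def category_area_table(
    annual_surfaces: dict[int, DensitySurface] | list[DensitySurface],
    breaks: CategoryBreaks | None = None,
    grid: Grid | None = None,
) -> pd.DataFrame:
    """Percentage of the study area per density class and year.

    Rows are years, columns density classes; every row sums to 100 (all
    masked-in cells have equal area and each falls in exactly one bin).
    """
    breaks = breaks or CategoryBreaks()
    if isinstance(annual_surfaces, list):
        annual_surfaces = {s.month_index // 12: s for s in annual_surfaces}
    edges = np.asarray(breaks.edges, dtype=float)
    rows = {}
    for year, surf in sorted(annual_surfaces.items()):
        counts, _ = np.histogram(surf.values, bins=edges)
        rows[year] = 100.0 * counts / surf.values.size
    return pd.DataFrame.from_dict(rows, orient="index", columns=breaks.labels())


def bias_surface(fit_result: FitResult, stack: CovariateStack, grid: Grid) -> np.ndarray:
    """Estimated detection bias b = exp(β̂ᵀd) per masked-in cell;
    time-constant because d is static."""
    if stack.n_bias == 0:
        return np.ones(grid.n_in)
    return np.exp(stack.d @ fit_result.params.beta)
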