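"""Sighting ingestion, monthly binning, and minimum-distance thinning.

Incidental sightings of the same animal are often reported repeatedly.
Assuming a circular home range of area ``A`` km², two reports closer than
the home-range diameter ``d = 2 * sqrt(A / pi)`` within the same calendar
month are treated as duplicates and collapsed to a single record.  The
rule is applied independently per month, so an animal can contribute at
most one retained sighting per month (12 per year); across months no
separation is enforced, since home ranges overlap over time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd

__all__ = [
    "CRSConfig",
    "HomeRangeConfig",
    "MonthBins",
    "MonthlyPattern",
    "SightingTable",
    "load_sightings",
    "min_separation",
    "month_bins",
    "thin_all",
    "thin_month",
]

# kilometres per degree of latitude (spherical mean radius)
_KM_PER_DEG_LAT = 111.195


@dataclass(frozen=True)
class CRSConfig:
    """How to turn raw coordinates into planar kilometres.

    mode="planar_km": coordinate columns are already projected, in km.
    mode="lonlat": decimal degrees, projected with a local equirectangular
    approximation about (lon0, lat0) (defaults: data centroid).  Adequate
    for study regions a few hundred km across.
    """

    mode: str = "lonlat"
    lon0: float | None = None
    lat0: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("planar_km", "lonlat"):
            raise ValueError(f"unknown CRS mode {self.mode!r}")


@dataclass(frozen=True)
class HomeRangeConfig:
    """Average circular home range; its diameter is the thinning distance."""

    area_A: float = 0.35  # km²
    max_sightings_per_year: int = 12

    def __post_init__(self) -> None:
        if self.area_A <= 0:
            raise ValueError("home-range area must be positive")
        if self.max_sightings_per_year < 1:
            raise ValueError("max_sightings_per_year must be >= 1")


@dataclass
class SightingTable:
    """Validated sighting records in planar km coordinates.

    ``frame`` has columns record_id (str), date (Timestamp), x, y (km).
    """

    frame: pd.DataFrame
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class MonthlyPattern:
    """Point pattern of one monthly period (the process-history unit)."""

    month_index: int
    points: np.ndarray  # (n, 2) planar km
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class MonthBins:
    """Calendar-month binning of the study window."""

    start_year: int
    end_year: int

    @property
    def T(self) -> int:
        return 12 * (self.end_year - self.start_year + 1)

    def index_of(self, when: _date | pd.Timestamp) -> int:
        """Bin index of a date, or -1 if outside the study window."""
        idx = 12 * (when.year - self.start_year) + (when.month - 1)
        return idx if 0 <= idx < self.T else -1

    def calendar_month(self, month_index: int) -> int:
        """Calendar month (1..12) of a period index."""
        return month_index % 12 + 1


def month_bins(start_year: int, end_year: int) -> MonthBins:
    """Monthly bins spanning [start_year, end_year] inclusive."""
    if end_year < start_year:
        raise ValueError("end_year must be >= start_year")
    return MonthBins(start_year, end_year)


def min_separation(home_range: HomeRangeConfig) -> float:
    """Minimum between-animal distance: diameter of the home-range circle."""
    return 2.0 * math.sqrt(home_range.area_A / math.pi)


def load_sightings(
    path: str,
    crs_config: CRSConfig | None = None,
    *,
    date_col: str = "date",
    x_col: str = "lon",
    y_col: str = "lat",
    id_col: str = "id",
) -> SightingTable:
    """Read a sightings CSV, dropping rows with unparseable fields.

    Coordinates are reprojected to planar km according to ``crs_config``.
    Raises if the file is missing or no valid record remains.
    """
    crs_config = crs_config or CRSConfig()
    raw = pd.read_csv(path)
    for col in (date_col, x_col, y_col):
        if col not in raw.columns:
            raise ValueError(f"missing column {col!r} in {path}")

    dates = pd.to_datetime(raw[date_col], errors="coerce", format="mixed")
    xs = pd.to_numeric(raw[x_col], errors="coerce")
    ys = pd.to_numeric(raw[y_col], errors="coerce")
    ok = dates.notna() & np.isfinite(xs) & np.isfinite(ys)
    n_dropped = int((~ok).sum())
    if not ok.any():
        raise ValueError(f"zero valid records in {path}")

    ids = (
        raw[id_col].astype(str)
        if id_col in raw.columns
        else pd.Series([f"r{i}" for i in range(len(raw))], index=raw.index)
    )
    frame = pd.DataFrame(
        {
            "record_id": ids[ok].to_numpy(),
            "date": dates[ok].to_numpy(),
            "x": xs[ok].to_numpy(float),
            "y": ys[ok].to_numpy(float),
        }
    ).reset_index(drop=True)

    if crs_config.mode == "lonlat":
        lon0 = crs_config.lon0 if crs_config.lon0 is not None else frame["x"].mean()
        lat0 = crs_config.lat0 if crs_config.lat0 is not None else frame["y"].mean()
        frame["x"], frame["y"] = lonlat_to_km(
            frame["x"].to_numpy(), frame["y"].to_numpy(), lon0, lat0
        )
    return SightingTable(frame=frame, n_dropped=n_dropped)


def lonlat_to_km(lon, lat, lon0: float, lat0: float):
    """Local equirectangular projection about (lon0, lat0), in km."""
    x = (np.asarray(lon) - lon0) * _KM_PER_DEG_LAT * math.cos(math.radians(lat0))
    y = (np.asarray(lat) - lat0) * _KM_PER_DEG_LAT
    return x, y


def thin_month(
    points: np.ndarray,
    dmin: float,
    month_index: int = 0,
    source_ids: list[str] | None = None,
) -> MonthlyPattern:
    """Greedy sequential thinning: keep a point iff it is >= dmin from
    every already-kept point.  Order of ``points`` is the scan order."""
    if dmin <= 0:
        raise ValueError("dmin must be positive")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    ids = list(source_ids) if source_ids is not None else [str(i) for i in range(len(pts))]
    kept: list[int] = []
    for i in range(pts.shape[0]):
        if not kept:
            kept.append(i)
            continue
        d = np.hypot(*(pts[kept] - pts[i]).T)
        if np.all(d >= dmin):
            kept.append(i)
    return MonthlyPattern(month_index, pts[kept], [ids[i] for i in kept])


def thin_all(
    table: SightingTable,
    home_range: HomeRangeConfig,
    bins: MonthBins,
) -> tuple[list[MonthlyPattern], dict]:
    """Thin every month independently; scan order is ascending report date,
    ties broken by record_id.

    Returns one pattern per period (possibly empty) and a report dict with
    per-month before/after counts.
    """
    dmin = min_separation(home_range)
    frame = table.frame.copy()
    frame["month_index"] = [bins.index_of(d) for d in frame["date"]]
    out_of_window = int((frame["month_index"] < 0).sum())
    frame = frame[frame["month_index"] >= 0]
    frame = frame.sort_values(["month_index", "date", "record_id"], kind="stable")

    patterns: list[MonthlyPattern] = []
    before, after = [], []
    by_month = dict(iter(frame.groupby("month_index")))
    for t in range(bins.T):
        grp = by_month.get(t)
        if grp is None or len(grp) == 0:
            patterns.append(MonthlyPattern(t, np.empty((0, 2)), []))
            before.append(0)
            after.append(0)
            continue
        pat = thin_month(
            grp[["x", "y"]].to_numpy(),
            dmin,
            month_index=t,
            source_ids=grp["record_id"].tolist(),
        )
        patterns.append(pat)
        before.append(len(grp))
        after.append(len(pat))
    report = {
        "dmin_km": dmin,
        "n_periods": bins.T,
        "n_before": int(sum(before)),
        "n_after": int(sum(after)),
        "n_out_of_window": out_of_window,
        "per_month_before": before,
        "per_month_after": after,
    }
    return patterns, report
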