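"""Plain-text serialization of pipeline artifacts.

Rasters travel as ESRI ASCII grids (.asc), vectors as GeoJSON, point
patterns and tables as CSV, and everything else as JSON — all readable
without GIS libraries.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon, shape

from .region import Grid, StudyRegion
from .sightings import MonthlyPattern

__all__ = [
    "read_ascii_grid",
    "read_patterns_csv",
    "read_region_geojson",
    "read_roads_geojson",
    "write_ascii_grid",
    "write_grid_json",
    "read_grid_json",
    "write_patterns_csv",
    "write_region_geojson",
    "write_roads_geojson",
]

_NODATA = -9999.0


def write_ascii_grid(path: str | Path, array: np.ndarray, grid: Grid) -> None:
    """ESRI ASCII grid; NaN cells become the nodata value."""
    arr = np.asarray(array, dtype=float)
    if arr.shape != (grid.ny, grid.nx):
        raise ValueError("array shape does not match grid")
    body = np.where(np.isfinite(arr), arr, _NODATA)
    header = (
        f"ncols {grid.nx}\nnrows {grid.ny}\n"
        f"xllcorner {grid.x0}\nyllcorner {grid.y0}\n"
        f"cellsize {grid.resolution}\nNODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ASCII grid rows run north→south
        np.savetxt(fh, body[::-1], fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1]
    nodata = header.get("nodata_value", _NODATA)
    data = np.where(data == nodata, np.nan, data)
    return data, header


def write_grid_json(path: str | Path, grid: Grid) -> None:
    obj = {
        "x0": grid.x0, "y0": grid.y0, "resolution": grid.resolution,
        "nx": grid.nx, "ny": grid.ny,
        "mask_rle": _rle_encode(grid.mask.ravel()),
    }
    Path(path).write_text(json.dumps(obj))


def read_grid_json(path: str | Path) -> Grid:
    obj = json.loads(Path(path).read_text())
    mask = _rle_decode(obj["mask_rle"], obj["nx"] * obj["ny"]).reshape(
        obj["ny"], obj["nx"]
    )
    return Grid(
        x0=obj["x0"], y0=obj["y0"], resolution=obj["resolution"],
        nx=obj["nx"], ny=obj["ny"], mask=mask,
    )


def _rle_encode(bits: np.ndarray) -> list[int]:
    """Run lengths of a boolean vector, starting with the False run."""
    bits = np.asarray(bits, dtype=bool)
    if bits.size == 0:
        return []
    changes = np.flatnonzero(np.diff(bits)) + 1
    runs = np.diff(np.concatenate([[0], changes, [bits.size]])).tolist()
    if bits[0]:
        runs = [0] + runs
    return [int(r) for r in runs]


def _rle_decode(runs: list[int], n: int) -> np.ndarray:
    out = np.zeros(n, dtype=bool)
    pos, val = 0, False
    for r in runs:
        if val:
            out[pos : pos + r] = True
        pos += r
        val = not val
    return out


def write_patterns_csv(path: str | Path, patterns: list[MonthlyPattern]) -> None:
    rows = []
    for pat in patterns:
        for (x, y), rid in zip(pat.points, pat.source_ids):
            rows.append((pat.month_index, x, y, rid))
    pd.DataFrame(rows, columns=["month_index", "x_km", "y_km", "record_id"]).to_csv(
        path, index=False
    )


def read_patterns_csv(path: str | Path, T: int | None = None) -> list[MonthlyPattern]:
    df = pd.read_csv(path)
    n_periods = T if T is not None else int(df["month_index"].max()) + 1
    out = []
    for t in range(n_periods):
        grp = df[df["month_index"] == t]
        out.append(
            MonthlyPattern(
                t, grp[["x_km", "y_km"]].to_numpy(float),
                grp["record_id"].astype(str).tolist(),
            )
        )
    return out


def write_roads_geojson(path: str | Path, roads: list[LineString]) -> None:
    feats = [
        {"type": "Feature", "properties": {}, "geometry": json.loads(shapely.to_geojson(g))}
        for g in roads
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats})
    )


def read_roads_geojson(path: str | Path) -> list[LineString]:
    obj = json.loads(Path(path).read_text())
    return [shape(f["geometry"]) for f in obj["features"]]


def write_region_geojson(path: str | Path, region: StudyRegion) -> None:
    Path(path).write_text(shapely.to_geojson(region.boundary))


def read_region_geojson(path: str | Path) -> StudyRegion:
    geom = shape(json.loads(Path(path).read_text()))
    if not isinstance(geom, Polygon):
        geom = geom.geoms[0]
    return StudyRegion(boundary=geom)
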