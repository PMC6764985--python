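"""Aggregation of historical whale-catch records onto a 1x1-degree grid.

Each record (lon, lat, count, year) is assigned to the grid cell containing
it under the floor convention — cell (i, j) covers [i, i+1) x [j, j+1) in
lon/lat — after optional half-open longitude/latitude window and year-range
filters.  The grid total therefore equals the count-sum of the records that
pass the filters, exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geodesy import normalize_lon


def grid_catches(
    records: pd.DataFrame,
    lon_window: tuple[float, float] | None = None,
    lat_window: tuple[float, float] | None = None,
    year_range: tuple[int, int] | None = None,
    cell_deg: float = 1.0,
) -> pd.DataFrame:
    """Grid catch records into per-cell totals.

    Parameters
    ----------
    records : DataFrame with columns lon, lat, count, year.
    lon_window, lat_window : half-open [min, max) filters in degrees.
    year_range : inclusive (first, last) year filter.
    cell_deg : cell size in degrees (1 reproduces the standard reporting
        grid; coarser cells must tile the fine ones exactly).

    Returns a frame with columns cell_lon, cell_lat, count sorted by cell,
    containing only non-empty cells.
    """
    rec = records.copy()
    rec["lon"] = normalize_lon(rec["lon"].to_numpy(dtype=float))
    lat = rec["lat"].to_numpy(dtype=float)
    if np.any((lat < -90) | (lat > 90)):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(rec["count"].to_numpy() < 0):
        raise ValueError("negative catch count")
    keep = np.ones(len(rec), dtype=bool)
    if lon_window is not None:
        keep &= (rec["lon"] >= lon_window[0]) & (rec["lon"] < lon_window[1])
    if lat_window is not None:
        keep &= (rec["lat"] >= lat_window[0]) & (rec["lat"] < lat_window[1])
    if year_range is not None:
        keep &= (rec["year"] >= year_range[0]) & (rec["year"] <= year_range[1])
    rec = rec[keep]
    cell_lon = np.floor(rec["lon"].to_numpy() / cell_deg) * cell_deg
    cell_lat = np.floor(rec["lat"].to_numpy() / cell_deg) * cell_deg
    out = (
        pd.DataFrame({"cell_lon": cell_lon, "cell_lat": cell_lat, "count": rec["count"].to_numpy()})
        .groupby(["cell_lon", "cell_lat"], as_index=False)["count"]
        .sum()
        .sort_values(["cell_lon", "cell_lat"])
        .reset_index(drop=True)
    )
    return out
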