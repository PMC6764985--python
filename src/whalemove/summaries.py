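"""Per-whale and overall spatial usage summaries.

Mirrors the study's summary table: per animal, the maximum great-circle
displacement from the tagging location, the total along-track distance, the
number of 6-h locations, the percent of locations decoded as resident
(reported only where at least ``min_locs`` locations are available), the
same count/percent per Southern Ocean management area, and the arrival time
into a focal region.

Management areas are polygons or lon/lat boxes with a category (CCAMLR, IWC,
MPA).  Assignment uses a half-open convention for boxes — south and west
edges inclusive, north and east edges exclusive — so meridian boundaries
(e.g. the 70 deg E IWC Area III/IV boundary) assign boundary points to the
eastern area.  Within a category areas must not overlap, except MPA-layer
areas, which may overlap CCAMLR areas and are summarized as a separate
column; CCAMLR-category points falling in no area are labelled "Northern".

The packaged area geometries are simplified lon/lat boxes approximating the
true management boundaries (which are distributed as external shapefiles);
they can be swapped for exact polygons via any GeoJSON FeatureCollection
with ``name`` and ``category`` properties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape

from .geodesy import great_circle_km, normalize_lon
from .params import RESIDENT, SexLabel

NORTHERN = "Northern"


@dataclass
class ManagementArea:
    """A named management unit: a lon/lat box (half-open) or polygon."""

    name: str
    category: str  # "CCAMLR" | "IWC" | "MPA" | "Northern"
    bbox: tuple[float, float, float, float] | None = None  # (w, s, e, n)
    polygon: object | None = None  # shapely geometry

    def __post_init__(self):
        if (self.bbox is None) == (self.polygon is None):
            raise ValueError("provide exactly one of bbox or polygon")
        if self.polygon is not None and not self.polygon.is_valid:
            raise ValueError(f"invalid geometry for area {self.name!r}")

    def contains(self, lon, lat) -> np.ndarray:
        lon = normalize_lon(np.asarray(lon, dtype=float))
        lat = np.asarray(lat, dtype=float)
        if self.bbox is not None:
            w, s, e, n = self.bbox
            return (lon >= w) & (lon < e) & (lat >= s) & (lat < n)
        return np.array(
            [self.polygon.intersects(Point(x, y)) for x, y in zip(np.atleast_1d(lon), np.atleast_1d(lat))]
        )


def load_areas(path=None) -> list[ManagementArea]:
    """Read management areas from a GeoJSON FeatureCollection (default: the
    packaged simplified Southern Ocean set).  Rectangular rings axis-aligned
    in lon/lat are recognized and given the half-open box rule."""
    if path is None:
        src = resources.files("whalemove").joinpath("data/southern_ocean_areas.geojson")
        gj = json.loads(src.read_text())
    else:
        with open(path) as fh:
            gj = json.load(fh)
    areas = []
    for feat in gj["features"]:
        geom = shape(feat["geometry"])
        props = feat["properties"]
        bbox = None
        if geom.geom_type == "Polygon":
            xs, ys = np.asarray(geom.exterior.coords).T
            ux, uy = np.unique(xs), np.unique(ys)
            if ux.size == 2 and uy.size == 2:
                bbox = (float(ux[0]), float(uy[0]), float(ux[1]), float(uy[1]))
        areas.append(
            ManagementArea(
                name=str(props["name"]),
                category=str(props["category"]),
                bbox=bbox,
                polygon=None if bbox is not None else geom,
            )
        )
    return areas


def assign_area(
    lon, lat, areas: Sequence[ManagementArea], category: str = "CCAMLR"
) -> np.ndarray:
    """Label each location with the containing area of one category.

    Areas are scanned west-to-east (then south-to-north); the first
    containing area wins, which together with the half-open box rule makes
    boundary assignment deterministic.  CCAMLR-category points contained in
    no area are labelled "Northern"; other categories yield "" outside."""
    cat = [a for a in areas if a.category == category]

    def west_edge(a):
        if a.bbox is not None:
            return (a.bbox[0], a.bbox[1])
        return (a.polygon.bounds[0], a.polygon.bounds[1])

    cat.sort(key=west_edge)
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    labels = np.full(lon.shape, NORTHERN if category == "CCAMLR" else "", dtype=object)
    unassigned = np.ones(lon.shape, dtype=bool)
    for a in cat:
        hit = unassigned & a.contains(lon, lat)
        labels[hit] = a.name
        unassigned &= ~hit
    return labels


def location_states(states_per_step: np.ndarray, segment_per_step: np.ndarray) -> np.ndarray:
    """Expand step-level decoded states to location level: each location takes
    the state of the step leaving it; a segment's last location inherits its
    final step's state."""
    states_per_step = np.asarray(states_per_step)
    segment_per_step = np.asarray(segment_per_step)
    out = []
    for s in np.unique(segment_per_step):
        st = states_per_step[segment_per_step == s]
        out.append(np.append(st, st[-1]))
    return np.concatenate(out)


def track_summary(
    lon: np.ndarray,
    lat: np.ndarray,
    loc_states: np.ndarray | None,
    deploy_lonlat: tuple[float, float],
    areas: Sequence[ManagementArea] | None = None,
    track_id: str = "",
    sex: SexLabel = SexLabel.unknown,
    segment: np.ndarray | None = None,
    min_locs: int = 10,
    include_gap_displacement: bool = True,
) -> dict:
    """Summarize one track: displacement, distance, residency and per-area
    usage.

    ``total_distance_km`` sums consecutive step lengths within segments; when
    ``include_gap_displacement`` is set, the net displacement across each
    declared reporting gap (segment break) is added, mirroring the convention
    of reporting a net distance for non-reporting periods.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon.size == 0:
        raise ValueError("empty track")
    if segment is None:
        segment = np.zeros(lon.size, dtype=int)
    seg = np.asarray(segment)
    d_deploy = great_circle_km(deploy_lonlat[0], deploy_lonlat[1], lon, lat)
    steps = great_circle_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    within = seg[:-1] == seg[1:]
    total = float(np.sum(steps[within]))
    if include_gap_displacement:
        total += float(np.sum(steps[~within]))
    row = {
        "id": track_id,
        "sex": SexLabel(sex).value,
        "max_displacement_km": float(np.max(d_deploy)),
        "total_distance_km": total,
        "n_locations": int(lon.size),
        "pct_resident": None,
    }
    if loc_states is not None:
        loc_states = np.asarray(loc_states)
        if loc_states.size != lon.size:
            raise ValueError("loc_states must align with locations")
        if lon.size >= min_locs:
            row["pct_resident"] = 100.0 * float(np.mean(loc_states == RESIDENT))
    if areas is not None:
        for category in ("CCAMLR", "MPA"):
            labels = assign_area(lon, lat, areas, category=category)
            names = [a.name for a in areas if a.category == category]
            if category == "CCAMLR":
                names.append(NORTHERN)
            for name in names:
                mask = labels == name
                n = int(mask.sum())
                row[f"n[{name}]"] = n
                pct = None
                if loc_states is not None and n >= min_locs:
                    pct = 100.0 * float(np.mean(loc_states[mask] == RESIDENT))
                row[f"pct_resident[{name}]"] = pct
    return row


def overall_summary(rows: pd.DataFrame) -> dict:
    """Overall row: mean and sample SD (n-1) of displacement and distance,
    plus location totals (overall and per area where present)."""
    if len(rows) < 2:
        raise ValueError("need at least two per-whale rows")
    out = {
        "n_whales": int(len(rows)),
        "mean_max_displacement_km": float(rows["max_displacement_km"].mean()),
        "sd_max_displacement_km": float(rows["max_displacement_km"].std(ddof=1)),
        "mean_total_distance_km": float(rows["total_distance_km"].mean()),
        "sd_total_distance_km": float(rows["total_distance_km"].std(ddof=1)),
        "total_locations": int(rows["n_locations"].sum()),
    }
    if rows["pct_resident"].notna().any():
        w = rows.dropna(subset=["pct_resident"])
        out["pct_resident_overall"] = float(
            np.average(w["pct_resident"], weights=w["n_locations"])
        )
    for col in rows.columns:
        if col.startswith("n["):
            out[f"total_{col}"] = int(rows[col].fillna(0).sum())
    return out


def arrival_time(
    times: pd.DatetimeIndex,
    lon: np.ndarray,
    lat: np.ndarray,
    region: ManagementArea,
    reference: pd.Timestamp | None = None,
    coastal_points: np.ndarray | None = None,
    coastal_km: float = 100.0,
) -> float | None:
    """Days (fractional) from a departure reference to first entry of a region.

    The reference is, in order of precedence: the supplied timestamp; the
    last fix within ``coastal_km`` of any supplied coastal reference point
    ("leaving coastal waters"); else the track start.  Returns None if the
    region is never entered.
    """
    times = pd.DatetimeIndex(times)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    inside = region.contains(lon, lat)
    if not np.any(inside):
        return None
    t_in = times[int(np.argmax(inside))]
    if reference is None:
        if coastal_points is not None:
            cp = np.atleast_2d(np.asarray(coastal_points, dtype=float))
            d = np.min(
                np.stack([great_circle_km(c[0], c[1], lon, lat) for c in cp]), axis=0
            )
            near = np.flatnonzero(d <= coastal_km)
            reference = times[int(near[-1])] if near.size else times[0]
        else:
            reference = times[0]
    delta_days = (t_in - pd.Timestamp(reference)).total_seconds() / 86400.0
    return max(delta_days, 0.0)


def load_table1() -> pd.DataFrame:
    """The packaged per-whale summary fixture (12 Southern Ocean migrations):
    id, sex, max_displacement_km, total_distance_km, n_locations,
    pct_resident."""
    src = resources.files("whalemove").joinpath("data/whale_summaries.csv")
    with resources.as_file(src) as p:
        return pd.read_csv(p, dtype={"id": str})
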