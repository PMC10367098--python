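"""Survey and polygon I/O, and geographic -> planar-km projection.

Survey tables are CSV with columns (id, group, district, se_ugL, optional
crp_mgL/agp_gL) and either planar coordinates (x_km, y_km) or geographic
ones (lon, lat).  Geographic coordinates are projected to planar km with a
transverse Mercator centred on the data (or polygon) centroid — at district
scale (~50 km) the spherical closed form is exact to well under a metre of
round-trip error, and all distance math downstream is unambiguous km.

Polygons are GeoJSON (Polygon or MultiPolygon taking the first ring's
polygon); geographic polygons are projected with the same transform as the
survey they accompany.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, shape

from .synthetic_survey import SurveyRecord

#: mean Earth radius, km
EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class TransverseMercator:
    """Spherical transverse Mercator about (lon0, lat0), output in km."""

    lon0: float
    lat0: float
    radius: float = EARTH_RADIUS_KM

    def forward(self, lon, lat):
        lon = np.radians(np.asarray(lon, dtype=float))
        lat = np.radians(np.asarray(lat, dtype=float))
        dlon = lon - np.radians(self.lon0)
        B = np.cos(lat) * np.sin(dlon)
        x = self.radius * np.arctanh(B)
        y = self.radius * (
            np.arctan2(np.tan(lat), np.cos(dlon)) - np.radians(self.lat0)
        )
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / self.radius
        D = np.asarray(y, dtype=float) / self.radius + np.radians(self.lat0)
        lat = np.arcsin(np.sin(D) / np.cosh(x))
        lon = np.radians(self.lon0) + np.arctan2(np.sinh(x), np.cos(D))
        return np.degrees(lon), np.degrees(lat)

    def project_polygon(self, polygon: Polygon) -> Polygon:
        ext = np.asarray(polygon.exterior.coords)
        x, y = self.forward(ext[:, 0], ext[:, 1])
        holes = []
        for ring in polygon.interiors:
            arr = np.asarray(ring.coords)
            hx, hy = self.forward(arr[:, 0], arr[:, 1])
            holes.append(np.c_[hx, hy])
        return Polygon(np.c_[x, y], holes)


def read_polygon(path: str | Path) -> Polygon:
    """First polygon from a GeoJSON file (Feature, FeatureCollection or
    bare geometry)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geom = gj["features"][0]["geometry"]
    elif gj.get("type") == "Feature":
        geom = gj["geometry"]
    else:
        geom = gj
    g = shape(geom)
    if g.geom_type == "MultiPolygon":
        g = max(g.geoms, key=lambda p: p.area)
    if g.geom_type != "Polygon":
        raise ValueError(f"expected Polygon geometry, got {g.geom_type}")
    return g


def polygon_is_geographic(polygon: Polygon) -> bool:
    """Heuristic: coordinates within lon/lat bounds and a tiny area."""
    minx, miny, maxx, maxy = polygon.bounds
    return -180 <= minx <= 180 and -90 <= miny <= 90 and \
        -180 <= maxx <= 180 and -90 <= maxy <= 90 and \
        (maxx - minx) < 10 and (maxy - miny) < 10


REQUIRED_COLUMNS = ("id", "group", "district", "se_ugL")


def read_survey(
    path: str | Path,
    max_bad_fraction: float = 0.2,
    transform: TransverseMercator | None = None,
) -> tuple[list[SurveyRecord], dict, TransverseMercator | None]:
    """Read and validate a survey CSV.

    Returns (records, parse_report, transform).  Rows with an unparseable
    Se value are collected (not fatal) unless they exceed
    *max_bad_fraction* of the file.  Missing coordinates are kept as NaN —
    GPS exclusion is a separate, reported step.  When the file carries
    lon/lat instead of x_km/y_km, a transverse Mercator centred on the
    coordinate centroid is built (or the given *transform* reused) and the
    returned transform allows projecting the matching polygon.
    """
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survey CSV missing required columns: {missing}")
    has_planar = "x_km" in df.columns and "y_km" in df.columns
    has_geo = "lon" in df.columns and "lat" in df.columns
    if not has_planar and not has_geo:
        raise ValueError(
            "survey CSV needs coordinates: x_km/y_km or lon/lat"
        )

    se = pd.to_numeric(df["se_ugL"], errors="coerce")
    bad = ~np.isfinite(se) | (se <= 0)
    n_bad = int(bad.sum())
    if n_bad > max_bad_fraction * len(df):
        raise ValueError(
            f"{n_bad}/{len(df)} rows unparseable or non-positive Se "
            f"(> {max_bad_fraction:.0%} allowed)"
        )

    if has_planar:
        x = pd.to_numeric(df["x_km"], errors="coerce").to_numpy()
        y = pd.to_numeric(df["y_km"], errors="coerce").to_numpy()
    else:
        lon = pd.to_numeric(df["lon"], errors="coerce").to_numpy()
        lat = pd.to_numeric(df["lat"], errors="coerce").to_numpy()
        if transform is None:
            transform = TransverseMercator(
                lon0=float(np.nanmean(lon)), lat0=float(np.nanmean(lat))
            )
        x, y = transform.forward(lon, lat)

    crp = pd.to_numeric(df["crp_mgL"], errors="coerce").to_numpy() \
        if "crp_mgL" in df.columns else np.full(len(df), np.nan)
    agp = pd.to_numeric(df["agp_gL"], errors="coerce").to_numpy() \
        if "agp_gL" in df.columns else np.full(len(df), np.nan)

    records = []
    dropped = []
    for i in range(len(df)):
        if bad.iloc[i]:
            dropped.append({"id": str(df["id"].iloc[i]), "tag": "bad_se_value"})
            continue
        records.append(
            SurveyRecord(
                id=str(df["id"].iloc[i]),
                group=str(df["group"].iloc[i]),
                district=str(df["district"].iloc[i]),
                x=float(x[i]) if np.isfinite(x[i]) else float("nan"),
                y=float(y[i]) if np.isfinite(y[i]) else float("nan"),
                se=float(se.iloc[i]),
                crp=float(crp[i]),
                agp=float(agp[i]),
            )
        )
    report = {"n_rows": len(df), "n_parsed": len(records), "dropped": dropped}
    return records, report, transform


def write_survey(records: Sequence[SurveyRecord], path: str | Path) -> None:
    """Write records as the canonical survey CSV."""
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "group": [r.group for r in records],
            "district": [r.district for r in records],
            "x_km": [r.x for r in records],
            "y_km": [r.y for r in records],
            "se_ugL": [r.se for r in records],
            "crp_mgL": [r.crp for r in records],
            "agp_gL": [r.agp for r in records],
        }
    ).to_csv(path, index=False, float_format="%.6f")


def records_xyz(records: Sequence[SurveyRecord]):
    """(coords, values) arrays from records, for the numerics layer."""
    coords = np.array([[r.x, r.y] for r in records], dtype=float)
    values = np.array([r.se for r in records], dtype=float)
    return coords, values


def write_polygon(polygon: Polygon, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "type": "Feature",
                "properties": {},
                "geometry": polygon.__geo_interface__,
            },
            fh,
        )
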