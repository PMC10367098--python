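"""Prediction surfaces, deficiency probabilities, and prevalence tables.

Kriging predictions and variances are computed on a square lattice clipped
to the district polygon (default spacing 250 m).  At each node the
probability that the true concentration falls below a biomarker threshold
is the Gaussian plug-in probability P = Phi((T - zhat)/sigma_k), and is
reported both numerically and on the IPCC calibrated-language scale
("very likely", "about as likely as not", ...), whose verbal labels map to
fixed probability ranges.

Deficiency thresholds (plasma Se, ug/L): 70 (conventional deficiency cut),
and the concentrations for optimal selenoprotein activities — 100 for
SELENOP, 84.9 for GPX3, 64.8 for IDI.  Strict inequality: a value exactly
at the threshold is not deficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from shapely import contains_xy
from shapely.geometry import Polygon
from shapely.prepared import prep

from .kriging import krige_grid
from .synthetic_survey import SurveyRecord
from .variogram import VariogramModel


@dataclass(frozen=True)
class ThresholdSet:
    """Plasma Se deficiency thresholds (ug/L)."""

    generic: float = 70.0
    selenop: float = 100.0
    gpx3: float = 84.9
    idi: float = 64.8

    def __post_init__(self):
        if not (self.idi < self.generic < self.gpx3 < self.selenop):
            raise ValueError("expected idi < generic < gpx3 < selenop")

    def as_dict(self) -> dict[str, float]:
        return {
            "plasma_se_70": self.generic,
            "selenop_100": self.selenop,
            "gpx3_84.9": self.gpx3,
            "idi_64.8": self.idi,
        }


@dataclass
class GridSurface:
    """Values on a polygon-clipped square lattice (planar km)."""

    spacing_km: float
    nodes: np.ndarray                 # (m, 2)
    values: np.ndarray | None = None  # per-node quantity

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)
            if len(self.values) != len(self.nodes):
                raise ValueError("values must align with nodes")

    def with_values(self, values: np.ndarray) -> "GridSurface":
        return GridSurface(self.spacing_km, self.nodes, values)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.nodes, columns=["x_km", "y_km"])
        if self.values is not None:
            df["value"] = self.values
        return df


#: IPCC calibrated-language likelihood scale: (label, p_low, p_high];
#: the lowest class includes 0
IPCC_SCALE = (
    ("exceptionally unlikely", 0.00, 0.01),
    ("very unlikely", 0.01, 0.10),
    ("unlikely", 0.10, 0.33),
    ("about as likely as not", 0.33, 0.66),
    ("likely", 0.66, 0.90),
    ("very likely", 0.90, 0.99),
    ("virtually certain", 0.99, 1.00),
)


def build_grid(polygon: Polygon, spacing_m: float = 250.0) -> GridSurface:
    """Square lattice clipped to *polygon* (planar km coordinates).

    The lattice is anchored at the bounding-box lower-left corner (so output
    is bit-reproducible) and a node is retained iff it is inside the polygon
    or on its boundary (shapely ``covers``, even-odd rule).
    """
    if spacing_m <= 0:
        raise ValueError("spacing must be positive")
    if polygon.is_empty or polygon.area <= 0:
        raise ValueError("polygon is degenerate")
    spacing = spacing_m / 1000.0
    minx, miny, maxx, maxy = polygon.bounds
    xs = np.arange(minx, maxx + 0.5 * spacing, spacing)
    ys = np.arange(miny, maxy + 0.5 * spacing, spacing)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.c_[gx.ravel(), gy.ravel()]
    inside = contains_xy(polygon, pts[:, 0], pts[:, 1])
    # contains_xy is strict interior; admit boundary nodes explicitly
    border = ~inside
    if border.any():
        prepared = prep(polygon)
        from shapely.geometry import Point

        inside[border] = [
            prepared.intersects(Point(x, y)) for x, y in pts[border]
        ]
    nodes = pts[inside]
    if len(nodes) == 0:
        raise ValueError("spacing larger than polygon: no grid nodes")
    return GridSurface(spacing_km=spacing, nodes=nodes)


def predict_surface(
    model: VariogramModel,
    coords: np.ndarray,
    values: np.ndarray,
    grid: GridSurface,
) -> tuple[GridSurface, GridSurface]:
    """Kriging prediction and variance surfaces on *grid*."""
    pred, var = krige_grid(model, coords, values, grid.nodes)
    return grid.with_values(pred), grid.with_values(var)


def deficiency_probability(prediction, variance, threshold: float):
    """P(Z < threshold) from a kriging prediction and variance.

    Gaussian plug-in: Phi((T - zhat)/sigma_k).  Zero variance degenerates
    to the indicator 1{zhat < T}, with the tie zhat == T mapped to 0.5.
    """
    zhat = np.asarray(prediction, dtype=float)
    v = np.asarray(variance, dtype=float)
    if np.any(v < -1e-9):
        raise ValueError("negative kriging variance")
    v = np.maximum(v, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = norm.cdf((threshold - zhat) / np.sqrt(v))
    degenerate = v == 0
    if np.any(degenerate):
        p = np.where(degenerate & (zhat < threshold), 1.0, p)
        p = np.where(degenerate & (zhat > threshold), 0.0, p)
        p = np.where(degenerate & (zhat == threshold), 0.5, p)
    return p if p.ndim else float(p)


def probability_surface(
    prediction: GridSurface, variance: GridSurface, threshold: float
) -> GridSurface:
    """Node-wise deficiency probability surface."""
    p = deficiency_probability(prediction.values, variance.values, threshold)
    return prediction.with_values(np.asarray(p))


def verbal_classify(probability, scale=IPCC_SCALE):
    """IPCC calibrated-language label(s) for probability value(s) in [0, 1]."""
    p = np.asarray(probability, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probability outside [0, 1]")
    labels = np.empty(p.shape, dtype=object)
    for name, lo, hi in scale:
        if lo == 0.0:
            sel = (p >= lo) & (p <= hi)
        else:
            sel = (p > lo) & (p <= hi)
        labels[sel] = name
    if labels.ndim == 0:
        return str(labels[()])
    return labels


def average_district_probability(surface: GridSurface) -> float:
    """Area-average deficiency probability over an equal-area lattice.

    The unweighted node mean; on a square lattice every node represents the
    same area, so this is the spatial average.
    """
    if surface.values is None or len(surface.values) == 0:
        raise ValueError("empty probability surface")
    return float(np.mean(surface.values))


def prevalence_table(
    records: Sequence[SurveyRecord],
    thresholds: ThresholdSet = ThresholdSet(),
) -> pd.DataFrame:
    """Observed deficiency prevalence (%) per district x group per threshold.

    Prevalence = 100 * #(value strictly below threshold) / n.  An "Overall"
    row per group pools the districts (so it equals the n-weighted mean of
    the district rows exactly).
    """
    if len(records) == 0:
        raise ValueError("no records")
    df = pd.DataFrame(
        {
            "district": [r.district for r in records],
            "group": [r.group for r in records],
            "se": [r.se for r in records],
        }
    )
    thr = thresholds.as_dict()
    rows = []

    def stratum_row(group: str, district: str, sub: pd.DataFrame) -> dict:
        row = {"group": group, "district": district, "n": len(sub),
               "median": float(sub["se"].median()),
               "mean": float(sub["se"].mean())}
        for name, t in thr.items():
            row[f"pct_below_{name}"] = 100.0 * float((sub["se"] < t).mean())
        return row

    for group, gsub in df.groupby("group", sort=True):
        for district, dsub in gsub.groupby("district", sort=True):
            rows.append(stratum_row(group, district, dsub))
        rows.append(stratum_row(group, "Overall", gsub))
    return pd.DataFrame(rows)
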