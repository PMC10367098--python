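"""Exploratory analysis of georeferenced biomarker surveys.

Summary statistics in the layout survey reports use (n, mean, median,
quartiles, variance, SD, octile skewness), a robust normality gate on octile
skewness, GPS-based record exclusion, quantile classes for post plots, and
the inflammation-correlation decision rule: plasma Se is only adjusted for
inflammation when it shows a significant *negative* rank correlation with
CRP or AGP, so the pipeline checks and flags but never adjusts.

Quantiles everywhere use one convention — linear interpolation of order
statistics (numpy's default) — chosen once and documented; at survey sizes
of ~200-260 records per stratum the convention is immaterial.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import spearmanr
from shapely.geometry import Point, Polygon

from .synthetic_survey import SurveyRecord


@dataclass
class SummaryStats:
    """Stratum summary; octile_skew is NaN when undefined (n < 8 or constant)."""

    n: int
    mean: float
    median: float
    q1: float
    q3: float
    min: float
    max: float
    variance: float
    sd: float
    octile_skew: float

    def to_dict(self) -> dict:
        return {
            "n": self.n, "mean": self.mean, "median": self.median,
            "q1": self.q1, "q3": self.q3, "min": self.min, "max": self.max,
            "variance": self.variance, "sd": self.sd,
            "octile_skew": self.octile_skew,
        }


@dataclass
class ExclusionReport:
    n_input: int
    n_retained: int
    n_excluded_gps: int
    reasons: dict = field(default_factory=dict)  # record id -> tag

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_excluded_gps": self.n_excluded_gps,
            "reasons": self.reasons,
        }


def octile_skewness(values: np.ndarray) -> float:
    """Robust skewness from the 1st, 4th and 7th octiles.

    ((O7 - O4) - (O4 - O1)) / (O7 - O1), the 12.5/50/87.5% quantiles.
    Bounded in [-1, 1]; |value| < 0.2 is conventionally compatible with
    symmetry.  NaN when n < 8 or the octile spread is zero.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 8:
        return float("nan")
    o1, o4, o7 = np.quantile(values, [0.125, 0.5, 0.875])
    denom = o7 - o1
    if denom == 0:
        return float("nan")
    return float(((o7 - o4) - (o4 - o1)) / denom)


def summarize(values: Sequence[float]) -> SummaryStats:
    """Summary statistics for one stratum of biomarker values (ug/L)."""
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("no values to summarise")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    var = float(np.var(v, ddof=1)) if len(v) > 1 else 0.0
    return SummaryStats(
        n=len(v),
        mean=float(np.mean(v)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=float(np.min(v)),
        max=float(np.max(v)),
        variance=var,
        sd=math.sqrt(var),
        octile_skew=octile_skewness(v),
    )


#: gate threshold on |octile skewness| above which the Gaussian working
#: assumption is considered untenable
OCTILE_SKEW_GATE = 0.2


def normality_gate(stats: SummaryStats, threshold: float = OCTILE_SKEW_GATE):
    """Gate on robust skewness: pass iff |octile_skew| < threshold.

    Returns (verdict, rationale) with verdict in {"pass", "fail",
    "indeterminate"}.  Failing strata are flagged for transformation rather
    than silently processed; transformation itself is out of scope.
    """
    s = stats.octile_skew
    if not np.isfinite(s):
        return "indeterminate", "octile skewness undefined (n < 8 or constant data)"
    if abs(s) < threshold:
        return "pass", f"|octile skew| = {abs(s):.3f} < {threshold}"
    return (
        "fail",
        f"|octile skew| = {abs(s):.3f} >= {threshold}; "
        "stratum needs transformation before kriging",
    )


#: below this stratum size variogram estimation is considered unreliable
MIN_POINTS_VARIOGRAM = 100


def exclude_bad_gps(
    records: Sequence[SurveyRecord],
    polygon: Polygon | None = None,
    buffer_km: float = 1.0,
) -> tuple[list[SurveyRecord], ExclusionReport]:
    """Drop records with missing/non-finite coordinates or far outside the
    district boundary (polygon buffered by *buffer_km*).

    Retained records are passed through untouched.  Warns when the retained
    count falls below the ~100-point minimum for variogram estimation;
    errors when nothing survives.
    """
    poly_b = polygon.buffer(buffer_km) if polygon is not None else None
    retained: list[SurveyRecord] = []
    reasons: dict = {}
    for r in records:
        if not (np.isfinite(r.x) and np.isfinite(r.y)):
            reasons[r.id] = "missing_coordinates"
        elif poly_b is not None and not poly_b.covers(Point(r.x, r.y)):
            reasons[r.id] = "outside_boundary"
        else:
            retained.append(r)
    report = ExclusionReport(
        n_input=len(records),
        n_retained=len(retained),
        n_excluded_gps=len(reasons),
        reasons=reasons,
    )
    if report.n_retained == 0:
        raise ValueError("no records retained after GPS exclusion")
    if report.n_retained < MIN_POINTS_VARIOGRAM:
        warnings.warn(
            f"{report.n_retained} records retained; below the "
            f"{MIN_POINTS_VARIOGRAM}-point minimum recommended for variogram "
            "estimation",
            UserWarning,
            stacklevel=2,
        )
    return retained, report


def quantile_post_classes(values: Sequence[float]) -> np.ndarray:
    """Sample-quartile class (1-4) per value, for classified post plots.

    Ties sitting exactly on a quartile boundary resolve to the lower bin.
    A constant vector puts everything in bin 1 (with a warning).
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError("need at least 4 values for quartile classes")
    cuts = np.quantile(v, [0.25, 0.5, 0.75])
    if cuts[0] == cuts[2]:
        warnings.warn("constant values: all records in quartile bin 1",
                      UserWarning, stacklevel=2)
    return np.searchsorted(cuts, v, side="left") + 1


def inflammation_check(
    records: Sequence[SurveyRecord],
    alpha: float = 0.05,
    min_pairs: int = 10,
):
    """Decide whether inflammation adjustment would be warranted.

    Spearman rank correlation of plasma Se with each of CRP and AGP
    (robust to the right-skew of acute-phase markers).  Decision is
    "flag_for_adjustment" only when some marker correlates *negatively*
    with p < alpha; otherwise "no_adjustment".  "not_assessed" when no
    marker has enough complete pairs.  The pipeline itself never adjusts.

    Returns (decision, table) with one row per marker:
    {marker, n, rho, p_value}.
    """
    se = np.array([r.se for r in records], dtype=float)
    table = []
    any_assessed = False
    flag = False
    for marker in ("crp", "agp"):
        m = np.array([getattr(r, marker) for r in records], dtype=float)
        ok = np.isfinite(se) & np.isfinite(m)
        n = int(ok.sum())
        if n < min_pairs:
            table.append({"marker": marker, "n": n, "rho": float("nan"),
                          "p_value": float("nan")})
            continue
        rho, p = spearmanr(se[ok], m[ok])
        table.append({"marker": marker, "n": n, "rho": float(rho),
                      "p_value": float(p)})
        any_assessed = True
        if rho < 0 and p < alpha:
            flag = True
    if not any_assessed:
        return "not_assessed", table
    return ("flag_for_adjustment" if flag else "no_adjustment"), table
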