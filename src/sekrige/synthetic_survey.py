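"""Synthetic biomarker surveys with known spatial structure.

Real micronutrient survey microdata are rarely redistributable, so every
stage of the pipeline is exercised against simulated surveys whose
ground-truth parameters are known.  The generator emulates the design the
analysis assumes: enumeration-area (EA) clustered household locations inside
a district polygon, and plasma biomarker values drawn from a stationary
Gaussian random field with a nugget + short-range covariance structure
(nugget c0, partial sill c1, distance parameter a of a few km).

Default magnitudes follow the surveyed districts: ~200-260 records per
district per demographic group, means of roughly 37-75 ug/L with variances
of 130-470 (ug/L)^2, and correlation ranges of 5-12 km inside ~50 x 50 km
districts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.linalg import cholesky, LinAlgError
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm
from shapely.geometry import Point, Polygon

from .variogram import SPATIAL_FAMILIES, model_corr

Group = Literal["child", "wra"]


@dataclass
class FieldSpec:
    """Ground truth for one simulated biomarker field.

    mean in ug/L; c0 (nugget) and c1 (partial sill) in (ug/L)^2; a in km.
    Total variance is c0 + c1.
    """

    mean: float = 40.0
    family: str = "exponential"
    c0: float = 40.0
    c1: float = 120.0
    a: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.c0 < 0 or self.c1 < 0:
            raise ValueError("variance components must be non-negative")
        if self.family in SPATIAL_FAMILIES and not self.a > 0:
            raise ValueError("distance parameter must be positive")
        if self.family not in SPATIAL_FAMILIES + ("nugget",):
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def sill(self) -> float:
        return self.c0 + self.c1


@dataclass
class SamplingSpec:
    """Two-stage clustered sampling design.

    n_clusters EA centres uniform in the polygon; per_cluster households
    Gaussian-scattered (sd cluster_sd km) around each centre, rejected back
    into the polygon.  Defaults: 30 EAs x 10 households, within-EA spread
    0.5 km (an EA is ~120 households; the survey design gives no spread, so
    this is a modelling choice).
    """

    polygon: Polygon
    n_clusters: int = 30
    per_cluster: int = 10
    cluster_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters * self.per_cluster < 1:
            raise ValueError("design must yield at least one point")
        if self.polygon.is_empty or self.polygon.area <= 0:
            raise ValueError("polygon is degenerate")


@dataclass
class SurveyRecord:
    """One georeferenced biomarker measurement."""

    id: str
    group: str
    district: str
    x: float          # planar km
    y: float          # planar km
    se: float         # plasma Se, ug/L
    crp: float = float("nan")   # mg/L
    agp: float = float("nan")   # g/L


def child_seed(seed: int, stage: int) -> np.random.Generator:
    """Per-stage RNG fanned out from one global seed (counter-based)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


def square_district(side_km: float = 50.0) -> Polygon:
    """A square study-area polygon of the scale of one rural district."""
    return Polygon(
        [(0, 0), (side_km, 0), (side_km, side_km), (0, side_km)]
    )


# ---------------------------------------------------------------------------
# field simulation
# ---------------------------------------------------------------------------

def simulate_grf(locations: np.ndarray, spec: FieldSpec) -> np.ndarray:
    """One draw of the Gaussian random field at *locations*.

    Covariance C(h) = c1 * rho(h) + c0 * 1{same record}: the nugget sits on
    the diagonal only, so two distinct records at coincident locations share
    the structured component but get independent nugget noise.  Dense
    Cholesky simulation — exact at survey scale (n up to a few thousand).
    """
    locations = np.asarray(locations, dtype=float)
    if locations.ndim != 2 or len(locations) == 0:
        raise ValueError("locations must be a non-empty (n, 2) array")
    n = len(locations)
    rng = np.random.default_rng(spec.seed)

    if spec.family == "nugget" or spec.c1 == 0:
        return spec.mean + np.sqrt(spec.c0 + spec.c1) * rng.standard_normal(n)

    C = spec.c1 * squareform(model_corr(spec.family, pdist(locations), spec.a))
    np.fill_diagonal(C, spec.c1 + spec.c0)
    try:
        L = cholesky(C, lower=True)
    except LinAlgError:
        jitter = 1e-10 * spec.sill
        try:
            L = cholesky(C + jitter * np.eye(n), lower=True)
        except LinAlgError as exc:
            raise RuntimeError(
                f"covariance not factorizable for c0={spec.c0}, c1={spec.c1}, "
                f"a={spec.a}, family={spec.family}"
            ) from exc
    return spec.mean + L @ rng.standard_normal(n)


# ---------------------------------------------------------------------------
# location sampling
# ---------------------------------------------------------------------------

_MAX_REJECT = 10_000


def _uniform_in_polygon(rng, polygon: Polygon, n: int) -> np.ndarray:
    minx, miny, maxx, maxy = polygon.bounds
    out = np.empty((n, 2))
    got = 0
    tries = 0
    while got < n:
        m = max(4 * (n - got), 16)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        ok = np.fromiter(
            (polygon.covers(Point(x, y)) for x, y in zip(xs, ys)), bool, m
        )
        take = min(int(ok.sum()), n - got)
        out[got : got + take] = np.c_[xs[ok], ys[ok]][:take]
        got += take
        tries += m
        if tries > _MAX_REJECT * n:
            raise RuntimeError("rejection sampling failed; polygon too thin?")
    return out


def sample_locations(spec: SamplingSpec) -> np.ndarray:
    """Clustered household locations: EA centres + within-EA Gaussian scatter.

    Deterministic under spec.seed.  Points falling outside the polygon are
    rejection-resampled; a cluster whose scatter cannot be placed raises an
    error naming the cluster.
    """
    rng = np.random.default_rng(spec.seed)
    centres = _uniform_in_polygon(rng, spec.polygon, spec.n_clusters)
    pts = np.empty((spec.n_clusters * spec.per_cluster, 2))
    k = 0
    for c, (cx, cy) in enumerate(centres):
        placed = 0
        attempts = 0
        while placed < spec.per_cluster:
            x = cx + spec.cluster_sd * rng.standard_normal()
            y = cy + spec.cluster_sd * rng.standard_normal()
            attempts += 1
            if spec.cluster_sd == 0 or spec.polygon.covers(Point(x, y)):
                pts[k] = (x, y) if spec.cluster_sd > 0 else (cx, cy)
                k += 1
                placed += 1
            elif attempts > _MAX_REJECT:
                raise RuntimeError(
                    f"cluster {c}: could not place points inside polygon "
                    f"(cluster_sd={spec.cluster_sd} km too large?)"
                )
    return pts


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _copula_correlated(rng, z_std: np.ndarray, rho_s: float, qf) -> np.ndarray:
    """Draw via a Gaussian copula with target Spearman rho against z_std."""
    # Pearson r on the latent Gaussians giving Spearman rho_s
    r = 2.0 * np.sin(np.pi * rho_s / 6.0)
    eps = rng.standard_normal(len(z_std))
    latent = r * z_std + np.sqrt(max(1.0 - r**2, 0.0)) * eps
    return qf(norm.cdf(latent))


def make_district_dataset(
    field: FieldSpec,
    sampling: SamplingSpec,
    group: Group = "child",
    district: str = "synthetic",
    inflammation: str = "independent",
    inflammation_rho: float = -0.5,
    truncate_at: float | None = None,
) -> list[SurveyRecord]:
    """Assemble one stratum (district x group) of synthetic survey records.

    inflammation: "none" (CRP/AGP missing), "independent" (no association
    with Se — the surveyed scenario, where no inflammation correction was
    warranted), or "correlated" (Gaussian-copula rank correlation
    *inflammation_rho* between Se and both markers, to exercise the
    flag-for-adjustment decision rule).

    truncate_at: optional floor (ug/L); a Gaussian model with realistic
    means/SDs can produce negative concentrations, which are retained by
    default so estimator tests see the exact generating model.
    """
    locs = sample_locations(sampling)
    se = simulate_grf(locs, field)
    if truncate_at is not None:
        se = np.maximum(se, truncate_at)

    n = len(se)
    rng = child_seed(field.seed, stage=7)
    crp = np.full(n, np.nan)
    agp = np.full(n, np.nan)
    if inflammation != "none":
        # CRP ~ lognormal around 1 mg/L, AGP ~ lognormal around 0.8 g/L:
        # right-skewed acute-phase marker shapes
        crp_qf = lambda u: np.exp(norm.ppf(u) * 1.0 + 0.0)
        agp_qf = lambda u: np.exp(norm.ppf(u) * 0.3 + np.log(0.8))
        if inflammation == "independent":
            crp = crp_qf(rng.uniform(size=n))
            agp = agp_qf(rng.uniform(size=n))
        elif inflammation == "correlated":
            z_std = (se - np.mean(se)) / max(np.std(se), 1e-12)
            crp = _copula_correlated(rng, z_std, inflammation_rho, crp_qf)
            agp = _copula_correlated(rng, z_std, inflammation_rho, agp_qf)
        else:
            raise ValueError(f"unknown inflammation mode {inflammation!r}")

    return [
        SurveyRecord(
            id=f"{district}-{group}-{i:04d}",
            group=group,
            district=district,
            x=float(locs[i, 0]),
            y=float(locs[i, 1]),
            se=float(se[i]),
            crp=float(crp[i]),
            agp=float(agp[i]),
        )
        for i in range(n)
    ]


#: per-district defaults echoing the surveyed strata (mean ug/L, variance
#: (ug/L)^2, n); ranges 5-7 km except the long-range child stratum
DISTRICT_DEFAULTS = {
    ("Murewa", "child"): dict(mean=37.0, var=156.9, a=6.0, n=208),
    ("Shamva", "child"): dict(mean=40.1, var=129.3, a=12.0, n=223),
    ("Mutasa", "child"): dict(mean=48.5, var=342.1, a=6.0, n=201),
    ("Murewa", "wra"): dict(mean=53.9, var=279.0, a=6.0, n=258),
    ("Shamva", "wra"): dict(mean=59.1, var=290.0, a=4.0, n=260),
    ("Mutasa", "wra"): dict(mean=74.7, var=470.0, a=6.0, n=239),
}


def default_field_spec(district: str, group: Group, seed: int = 0,
                       spatial_fraction: float = 0.5) -> FieldSpec:
    """FieldSpec matching one surveyed stratum's mean/variance scale.

    spatial_fraction = c1 / (c0 + c1); the surveyed districts showed the
    correlated component between "largest relative to the uncorrelated
    variance" and "smaller", so one half is the neutral default.
    """
    d = DISTRICT_DEFAULTS[(district, group)]
    return FieldSpec(
        mean=d["mean"],
        family="exponential",
        c0=(1.0 - spatial_fraction) * d["var"],
        c1=spatial_fraction * d["var"],
        a=d["a"],
        seed=seed,
    )


def make_survey_bundle(
    seed: int = 0,
    districts: Sequence[str] = ("Murewa", "Shamva", "Mutasa"),
    groups: Sequence[Group] = ("child", "wra"),
    side_km: float = 50.0,
) -> tuple[list[SurveyRecord], dict]:
    """Full multi-district synthetic survey + ground-truth sidecar dict."""
    records: list[SurveyRecord] = []
    truth: dict = {}
    stage = 0
    for district in districts:
        for group in groups:
            d = DISTRICT_DEFAULTS[(district, group)]
            sub_seed = int(child_seed(seed, stage).integers(2**31 - 1))
            fs = default_field_spec(district, group, seed=sub_seed)
            n = d["n"]
            per = 10
            ss = SamplingSpec(
                polygon=square_district(side_km),
                n_clusters=int(np.ceil(n / per)),
                per_cluster=per,
                seed=sub_seed + 1,
            )
            recs = make_district_dataset(fs, ss, group=group, district=district)
            recs = recs[:n]
            records.extend(recs)
            truth[f"{district}/{group}"] = {
                "mean": fs.mean, "family": fs.family, "c0": fs.c0,
                "c1": fs.c1, "a": fs.a, "seed": fs.seed, "n": n,
            }
            stage += 1
    return records, truth
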