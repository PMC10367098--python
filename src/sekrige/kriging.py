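"""Ordinary kriging, leave-one-out cross-validation, and model selection.

Ordinary kriging is the best linear unbiased predictor at an unsampled
location under a constant unknown mean: the weights solve the augmented
semivariance system

    [ Gamma  1 ] [ lambda ]   [ gamma0 ]
    [ 1^T    0 ] [  psi   ] = [   1    ]

with Gamma the data-to-data semivariance matrix, gamma0 the data-to-target
semivariances, and psi the Lagrange multiplier enforcing sum(lambda) = 1.
Prediction is lambda^T z; the kriging variance is lambda^T gamma0 + psi.

Model validity is judged by leave-one-out cross-validation: for a correctly
specified model the standardized squared prediction error
theta_i = (z_i - zhat_{-i})^2 / sigma^2_{k,-i} is approximately chi^2_1, so
its median should sit near median(chi^2_1) ~ 0.455.  Candidate variogram
models are ranked by |median SSPE - 0.455|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import binom, chi2
from shapely.geometry import MultiPoint, Point

from .variogram import VariogramModel, gamma_between


def sspe_expected_median() -> float:
    """Median of a chi-squared variate on 1 df — the SSPE calibration constant.

    Computed from the implementation's quantile machinery, ~0.455.
    """
    return float(chi2.ppf(0.5, df=1))


@dataclass
class KrigingResult:
    location: tuple[float, float]
    prediction: float       # ug/L
    variance: float         # (ug/L)^2
    weights: np.ndarray | None = None
    extrapolated: bool = False


@dataclass
class CrossValidationReport:
    sspe: np.ndarray                    # finite fold errors, dimensionless
    median_sspe: float
    ci95: tuple[float, float]           # order-statistic CI for the median
    n: int                              # folds contributing
    n_excluded_folds: int
    model: VariogramModel

    def to_dict(self) -> dict:
        return {
            "median_sspe": self.median_sspe,
            "ci95_lo": self.ci95[0],
            "ci95_hi": self.ci95[1],
            "n": self.n,
            "n_excluded_folds": self.n_excluded_folds,
            "model": self.model.to_dict(),
        }


class _KrigingSystem:
    """Factorised ordinary-kriging system reused across targets."""

    def __init__(self, model: VariogramModel, coords: np.ndarray,
                 values: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        values = np.asarray(values, dtype=float)
        n = len(values)
        if n < 2:
            raise ValueError("ordinary kriging needs at least 2 data points")
        d = pdist(coords)
        if model.c0 == 0 and (len(d) == 0 or np.all(d == 0)):
            raise np.linalg.LinAlgError(
                "all points coincident with zero nugget: singular system"
            )
        G = squareform(gamma_between(model, d))
        np.fill_diagonal(G, 0.0)
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = G
        A[:n, n] = 1.0
        A[n, :n] = 1.0
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            self._lu = lu_factor(A)
        diag = np.abs(np.diag(self._lu[0]))
        # duplicate locations under a zero nugget make Gamma rank-deficient;
        # the system stays consistent, so fall back to a least-squares solve
        self._singular = (not np.all(np.isfinite(diag))) or \
            diag.min() <= 1e-12 * max(diag.max(), 1.0)
        self._A = A if self._singular else None
        self.model = model
        self.coords = coords
        self.values = values
        self.n = n

    def solve(self, targets: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Predictions, variances and weights at (m, 2) targets."""
        targets = np.atleast_2d(np.asarray(targets, dtype=float))
        d0 = cdist(self.coords, targets)
        g0 = gamma_between(self.model, d0)
        g0[d0 == 0.0] = 0.0  # honour the datum exactly at zero separation
        B = np.vstack([g0, np.ones(targets.shape[0])])
        if self._singular:
            sol, _, rank, _ = np.linalg.lstsq(self._A, B, rcond=None)
            resid = self._A @ sol - B
            if not np.all(np.abs(resid) < 1e-8 * max(self.model.sill, 1.0)):
                raise np.linalg.LinAlgError("inconsistent singular kriging system")
        else:
            sol = lu_solve(self._lu, B)
        lam, psi = sol[: self.n], sol[self.n]
        pred = lam.T @ self.values
        var = np.einsum("ij,ij->j", lam, g0) + psi
        # tiny negative values are roundoff from the saddle-point system
        var = np.where((var < 0) & (var > -1e-8 * max(self.model.sill, 1.0)),
                       0.0, var)
        if np.any(var < 0):
            raise np.linalg.LinAlgError("negative kriging variance beyond tolerance")
        return pred, var, lam


def krige(
    model: VariogramModel,
    coords: np.ndarray,
    values: np.ndarray,
    target,
    keep_weights: bool = True,
) -> KrigingResult:
    """Ordinary-kriging prediction and variance at one target point.

    All data are used (global neighbourhood; stratum sizes of a few hundred
    need no moving window).  A target outside the convex hull of the data is
    flagged as extrapolated, not refused.
    """
    sys_ = _KrigingSystem(model, coords, values)
    t = np.asarray(target, dtype=float).reshape(1, 2)
    pred, var, lam = sys_.solve(t)
    hull = MultiPoint([tuple(p) for p in sys_.coords]).convex_hull
    extrap = not hull.covers(Point(t[0, 0], t[0, 1]))
    return KrigingResult(
        location=(float(t[0, 0]), float(t[0, 1])),
        prediction=float(pred[0]),
        variance=float(var[0]),
        weights=lam[:, 0] if keep_weights else None,
        extrapolated=extrap,
    )


def krige_grid(model: VariogramModel, coords, values, targets):
    """Vectorised kriging over many targets: (predictions, variances)."""
    sys_ = _KrigingSystem(model, coords, values)
    pred, var, _ = sys_.solve(targets)
    return pred, var


def median_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Distribution-free CI for the median via binomial order statistics."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 6:
        return float(x[0]), float(x[-1])
    alpha = 1.0 - level
    lo_rank = int(binom.ppf(alpha / 2.0, n, 0.5))          # 0-based lower
    hi_rank = int(binom.isf(alpha / 2.0, n, 0.5))          # 0-based upper
    lo_rank = max(lo_rank, 0)
    hi_rank = min(hi_rank, n - 1)
    return float(x[lo_rank]), float(x[hi_rank])


def loo_cross_validate(
    model: VariogramModel,
    coords: np.ndarray,
    values: np.ndarray,
) -> CrossValidationReport:
    """Leave-one-out cross-validation of a fitted variogram model.

    Each record is omitted in turn and predicted by ordinary kriging from
    the rest; the model parameters are held fixed across folds (they are
    not re-estimated).  Folds with zero kriging variance (duplicate
    locations under a zero nugget) are excluded and counted.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 records for cross-validation")
    sspe = []
    excluded = 0
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        try:
            sys_ = _KrigingSystem(model, coords[keep], values[keep])
            pred, var, _ = sys_.solve(coords[i].reshape(1, 2))
        except np.linalg.LinAlgError:
            excluded += 1
            continue
        if var[0] <= 1e-10 * max(model.sill, 1.0):  # degenerate fold
            excluded += 1
            continue
        sspe.append((values[i] - pred[0]) ** 2 / var[0])
    sspe = np.array(sspe)
    if len(sspe) == 0:
        raise ValueError("every fold had zero kriging variance")
    return CrossValidationReport(
        sspe=sspe,
        median_sspe=float(np.median(sspe)),
        ci95=median_ci(sspe),
        n=len(sspe),
        n_excluded_folds=excluded,
        model=model,
    )


_FAMILY_ORDER = {"nugget": 0, "exponential": 1, "spherical": 2}


def select_model(
    candidates: Sequence[CrossValidationReport],
) -> tuple[CrossValidationReport, dict]:
    """Choose the candidate whose median SSPE is closest to median(chi^2_1).

    Primary rule: minimise |median SSPE - 0.455|.  Ties break toward the
    model with fewer parameters, then exponential before spherical.  The
    rationale also reports, for each candidate, whether 0.455 falls inside
    its 95% CI for the median — the complementary validity reading.
    """
    if len(candidates) == 0:
        raise ValueError("no candidate models")
    target = sspe_expected_median()

    def key(c: CrossValidationReport):
        return (
            abs(c.median_sspe - target),
            c.model.n_params,
            _FAMILY_ORDER.get(c.model.family, 99),
        )

    chosen = min(candidates, key=key)
    rationale = {
        "rule": "minimise |median SSPE - 0.455|; ties -> fewer parameters, "
                "then exponential before spherical",
        "target": target,
        "candidates": [
            {
                "family": c.model.family,
                "median_sspe": c.median_sspe,
                "abs_distance": abs(c.median_sspe - target),
                "ci95": list(c.ci95),
                "target_in_ci": bool(c.ci95[0] <= target <= c.ci95[1]),
            }
            for c in candidates
        ],
        "chosen_family": chosen.model.family,
    }
    return chosen, rationale
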