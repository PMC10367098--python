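# Methods

## Model and assumptions

Plasma Se concentration over one district × demographic-group stratum is
modelled as a second-order stationary Gaussian random field with a constant
mean:

    Z(x) = μ + η(x) + ε,        Var(Z) = c1·R(a) + c0·I

with `η` a zero-mean correlated component (exponential correlogram
`exp(−h/a)` or spherical, reaching zero exactly at `h = a`) and `ε`
uncorrelated noise. The semivariogram is `γ(h) = c0 + c1(1 − ρ(h))` for
`h > 0` and 0 at the origin. Assumptions the pipeline checks rather than
takes on faith:

* **Marginal symmetry** — octile skewness (robust, bounded in [−1, 1]) must
  satisfy |skew| < 0.2 or the stratum is flagged "needs transformation" and
  excluded from kriging. The absolute value is gated (a strongly
  left-skewed stratum is as un-Gaussian as a right-skewed one).
* **No spatial trend** — the constant-mean model; quartile-classed post
  plots are exported for visual trend checks. Trend (universal kriging)
  fixed effects are out of scope.
* **Outliers** — retained; robustness is delegated to the Cressie–Hawkins
  estimator for exploration. Estimation is by REML, not by fitting to the
  binned variogram, so single outliers influence the fit only through the
  likelihood.
* **Inflammation** — plasma Se is only considered for inflammation
  adjustment when significantly *negatively* rank-correlated with CRP or
  AGP; the pipeline computes Spearman correlations (robust to the
  right-skew of acute-phase proteins) and flags, but never adjusts.

## Parameters that matter

| parameter | unit | default | why |
|---|---|---|---|
| `c0` (nugget) | (μg/L)² | fit / half the stratum variance in simulations | measurement error + sub-km variation |
| `c1` (partial sill) | (μg/L)² | fit / other half | spatially structured variance |
| `a` (distance param.) | km | fit; simulations use 4–12 | effective range ≈ 3a (exponential), = a (spherical) |
| grid spacing | m | 250 | map resolution; nodes scale as area/spacing² |
| octile-skew gate | — | 0.2 | conventional symmetry bound |
| min stratum n | — | 100 (warning) | below ~100–150 points variogram estimation is unreliable |
| thresholds | μg/L | 70 / 100 / 84.9 / 64.8 | deficiency cut; optimal SELENOP / GPX3 / IDI activity |
| α (inflammation) | — | 0.05 | two-sided Spearman significance |
| lag bin width | km | 1 | matches ranges of 4–12 km inside ~50 km districts |
| max lag | km | half max inter-point distance | pairs beyond carry little information |

Probability maps use GPX3 (84.9 μg/L) for women of reproductive age and
IDI (64.8 μg/L) for children 6–59 months; both are configurable.

## The synthetic-survey generator

The generator emulates the design the analysis assumes: cluster centres
uniform in a district polygon (default 30 enumeration areas), 10 households
Gaussian-scattered per cluster (`cluster_sd` 0.5 km — chosen as plausible
for an EA of ~120 households; survey reports do not state a within-EA
spread), and field values drawn by dense Cholesky from the exact model
covariance, with the nugget applied per record so duplicate locations
differ by measurement error. Per-district defaults reproduce the surveyed
strata scales: 201–260 records per stratum, means 37–75 μg/L, variances
129–470 (μg/L)².

What it does **not** emulate — hence what passing tests do not show about
real data: non-Gaussian marginals and detection limits (a Gaussian with
mean 37 and SD 12.5 can dip below zero; values are deliberately not
truncated so estimator tests see the exact generating model — a
`truncate_at` option exists for demonstrations), sampling weights and PPS
selection probabilities, GPS error, inter-district edge effects, and any
Se–inflammation dependence beyond an optional Gaussian-copula rank
correlation.

One global seed fans out to per-stage child seeds through
`numpy.random.SeedSequence` spawn keys, so every stage is independently
reproducible and all outputs are bitwise stable under a fixed seed.

## Numerical choices

* **Quantiles** — linear interpolation of order statistics (numpy default)
  everywhere, including octiles; at n ≈ 200–260 the convention is
  immaterial, but it is fixed and documented.
* **Quartile classes** — boundary ties resolve to the lower bin.
* **REML** — error-contrast likelihood for the constant mean; the total
  variance σ² = c0 + c1 is profiled out analytically, leaving a 2-D
  optimisation over (log a, s = c1/σ²) by bounded L-BFGS-B, multi-started
  at a ∈ {1, 2.5, 5, 10, 20} km. Log-determinants via Cholesky; a
  factorisation failure triggers one retry with a 10⁻¹⁰·σ² diagonal
  jitter. The fitted μ equals the GLS mean under the fitted covariance (an
  identity used as an internal consistency test).
* **Range lower bound** — `a` is bounded below at 1 km by default. Ranges
  below the within-cluster point spacing are not identifiable from an
  EA-clustered design: a sub-cluster-scale exponential is an alias of the
  nugget, and allowing it lets the optimiser park spurious variance in
  `c1` at micro-ranges. (We verified the unbounded optimum against an
  independent REML implementation; the bound is a modelling restriction,
  not an optimisation fix.) Even with the bound, REML on purely
  uncorrelated clustered data attributes > 5 % of the variance to a
  short-range component in roughly a fifth of realisations — users should
  read small fitted `c1` fractions with corresponding scepticism.
* **Kriging** — the ordinary-kriging system is assembled in semivariance
  form (valid for unbounded models later) and LU-factorised once per data
  set, shared across all grid nodes. Weights sum to 1 by construction;
  variances within −10⁻⁸·sill of zero are clipped to 0. Duplicate data
  locations under a zero nugget make the system rank-deficient but
  consistent; a least-squares solve handles them, and an all-coincident
  configuration with zero nugget errors. A datum coinciding with the
  target is honoured exactly (γ₀ = 0), so kriging interpolates the data.
* **LOOCV** — model parameters held fixed across folds (no per-fold
  re-estimation); folds with kriging variance ≤ 10⁻¹⁰·sill are excluded
  and counted. The 95 % CI for the median SSPE uses distribution-free
  binomial order statistics.
* **Model selection** — minimise |median SSPE − median(χ²₁)| with
  median(χ²₁) ≈ 0.4549 computed, not hard-coded; ties break toward fewer
  parameters, then exponential before spherical. Whether 0.455 lies in each
  candidate's CI is reported alongside as a complementary validity reading.
  (An alternative reading — pick the greatest median inside the CI — is
  reported but not used as the decision rule.)
* **Grid** — lattice anchored at the polygon bounding-box lower-left
  corner (bit-reproducible); nodes kept iff inside or on the boundary
  (even-odd rule). Spacing is accepted in metres and converted to km once
  at the boundary; all internal distances are km.
* **Deficiency** — strictly below threshold; a value exactly at the
  threshold is not deficient. Zero-variance nodes degenerate to the
  indicator, with the tie ẑ = T mapped to 0.5.
* **Projection** — geographic inputs are projected with a spherical
  transverse Mercator centred on the data centroid (closed form, exactly
  invertible; round-trip error ≪ 1 m at district scale). Ellipsoidal
  corrections (~0.1 % scale) are irrelevant at 50 km extents.

## Design choices where the design was open

* District-average deficiency probability is the unweighted mean over grid
  nodes (an equal-area lattice makes this the spatial average); averaging
  over household locations instead is exposed by calling
  `deficiency_probability` on per-household predictions.
* The IPCC verbal scale boundaries (0.01/0.10/0.33/0.66/0.90/0.99) follow
  the calibrated-language guidance and are configurable.
* Global kriging neighbourhood: strata have n ≤ 260, so exactness beats a
  moving window.
* Strata are processed independently (district × group); pooling across
  districts is intentionally not offered.

## Validation problem sizes

Calibration and recovery statistics are computed on replicate synthetic
surveys of 250 points (25 clusters × 10) in a 50 × 50 km district —
100 replicates for LOOCV calibration and REML recovery, 50 for the
contamination study — sizes at which the Monte-Carlo error of the reported
medians is small relative to the tolerances asserted. The acceptance script
runs one district map at the production 250 m spacing (40,401 nodes).

## Known limitations

* Variogram-parameter uncertainty is not propagated into the probability
  maps (plug-in kriging variance only).
* No anisotropy, no Matérn family, no Bayesian estimation.
* The Gaussian probability transform is exact only under the model; heavy
  upper tails in real Se data would distort near-threshold probabilities.
* Prevalence tables are unweighted; survey designs with unequal selection
  probabilities need external weighting.
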