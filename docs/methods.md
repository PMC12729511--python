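# Methods

This note records the models implemented in `qregions`, the defaults and why
they were chosen, what the synthetic landscapes do and do not emulate, and
the numerical choices a maintainer would want to know.

## Geometry and rasters

All coordinates are geographic WGS84; there is no projected CRS anywhere.
Distances are haversine on the mean-radius sphere (R = 6371.0088 km) and
cell areas are `dx·dy·(π/180)²·R²·cos(lat)`. At the sub-national scales this
package targets, both are accurate to well under 1% — the recomputed
published centroid-migration distances agree with the source's
projected-plane values to <1% on steps above 100 km and ~1% on a 45-km step,
which is the expected size of the projection ambiguity.

Cell membership is half-open, `[edge, edge + d)`, with north-up row order;
a point on a west/north edge belongs to the adjacent cell deterministically.
Nodata is NaN internally and a sentinel on disk (ESRI ASCII `NODATA_value`,
GeoTIFF `GDAL_NODATA`); any stage receiving nodata in any input layer emits
nodata at that cell. GeoTIFF support is deliberately minimal: single band,
`ModelPixelScale`/`ModelTiepoint`/geokey EPSG:4326, written through
tifffile. ESRI ASCII accepts `xllcorner` or `xllcenter` on read and always
writes `xllcorner` (the convention of the maxent ecosystem).

## Occurrence processing

Spatial rarefaction is greedy sequential thinning: records are visited in a
deterministic order (sorted by longitude, then latitude; optionally a seeded
shuffle to emulate stochastic thinning toolboxes) and kept iff ≥ 10 km
(haversine, configurable) from every already-kept record. Greedy thinning is
order-dependent in general; the fixed order makes the operation a pure
function of its input, which the idempotence property test relies on. The
design table pairs the thinned presences with a uniform sample of up to
10,000 non-nodata background cells (the conventional cap); duplicate
presence cells are collapsed; presences may coincide with background cells
(standard presence–background practice, with an exclusion switch).

## Maximum-entropy engine

The model, objective and penalties are stated in the README. Implementation
details that are genuine choices rather than forced by the definition:

* **Feature construction.** Variables are min–max scaled to [0, 1] over the
  design. Hinge knots sit at 10 evenly spaced sample quantiles per direction
  (forward and reverse), dropping degenerate knots at 0/1. Constant
  variables keep only a linear feature.
* **Optimizer.** Cyclic coordinate descent. Each coordinate takes a Newton
  step on the smooth part (gradient `E_presence[f_j] − E_q[f_j]`, curvature
  `Var_q[f_j]`), soft-thresholded by `β_j`, then backtracks (halving) until
  the exact objective change is nonnegative — so the objective is
  non-decreasing by construction, and the fitted raw distribution sums to 1
  over the background to 1e-9. A "cycle" is one pass over all features;
  convergence is a full-cycle gain below 1e-5 (the conventional threshold),
  cap 500 cycles by default (configurable; the historical tool's enormous
  iteration caps are unnecessary at these problem sizes, and non-convergence
  is flagged on the model rather than fatal).
* **Cloglog.** `p = 1 − exp(−e^H q)` with H the entropy of the training raw
  distribution, frozen for all later predictions and projections.
* **Percent contribution** is the classical path-dependent bookkeeping:
  every accepted update credits its objective gain to the feature's parent
  variable; credits are normalized to 100. It is reproducible because the
  cyclic order is fixed. The jackknife refits with each variable alone and
  omitted; gain is objective minus the uniform model's `−log |B|`.
* **Validation.** k-fold (default 10) cross-validation partitions presences
  only; each fold refits against the full background and scores the
  held-out presences by the Mann–Whitney rank AUC against the background.
  A single 75/25 split mode is also provided. Fold refits may warm-start
  from the full-model coefficients: the problem is convex, so the optimum is
  unchanged, only reached faster.
* **Response curves** sweep one variable over its observed range with the
  others at the background mean, Z and H frozen; the suitable range is the
  maximal interval(s) with p ≥ 0.5 and the adaptive threshold is the argmax
  (ties broken toward the smallest value — relevant when cloglog saturates
  at 1.0 in double precision).

## Variable selection

Contribution screen (preliminary maxent fit, zero-contribution variables
dropped) → pairwise prune (process pairs by descending |r|; for |r| > 0.8
drop the lower-contribution member, ties lexicographic) → VIF loop (OLS
`VIF = 1/(1−R²)`, drop the max until all < 10; exact collinearity counts as
infinite). Correlations and VIFs are computed on the background sample by
default: collinearity is a property of the predictor field, not of where
the species happens to occur (switchable). "Ecological significance" is not
computable, so expert retention is an explicit configuration list
(`retain=[...]`) instead of a heuristic.

## Geostatistics

Empirical (cross-)semivariograms use equal-width distance bins up to half
the maximum pairwise distance (12 lags by default); fits are weighted least
squares with weights `N_bin/h²`, nonnegativity bounds, and multiple range
starts. The linear model of coregionalization is restricted to nugget + one
shared structure with a common family and range: the shared range is
profiled (per-pair coefficients have a linear LS solution at fixed range;
golden-section refinement of the profiled cost), direct-pair coefficients
are solved under nonnegativity, and B0/B1 are projected to the nearest PSD
matrices by eigenvalue clipping with the Frobenius adjustment recorded.
This restriction guarantees a valid co-kriging system at the cost of some
flexibility — appropriate for tables of ~26 sites, where a richer nested
model would be unidentifiable.

Ordinary co-kriging uses covariances `C_ij(h) = B0_ij·δ(h) + B1_ij·(1−g)`,
with the primary variable's weights constrained to sum to 1 and each
secondary's to 0. Secondary data enter at the sample sites only (isotopic
sampling, no collocated secondary at the prediction cell): the kriging LHS
is then identical at every cell, so grid prediction is one factorization
plus a batched right-hand side — and with no secondaries the system *is*
ordinary kriging, exactly interpolating at zero nugget. Leave-one-out
validation removes only the held-out primary datum (the secondary
covariates are environmental layers, known everywhere), re-solves the
weights with the variogram fixed, and reports ME, RMSE and the standardized
RMSE `sqrt(mean(((ẑ−z)/σ_k)²))` — the statistic whose proximity to 1 is
read as "the kriging uncertainty is honest". Aspect-like layers are used as
supplied; an optional cosine transform exists but is off by default, since
the screened association is computed on the raw layer.

## Integration and zoning

Kriged compound maps are min–max normalized and fused cell-wise (mean by
default; min and weighted-mean alternatives). The integrated index is the
convex combination `C = w_e·E + w_q·Q` with equal weights 0.5/0.5 by
default; E is the cloglog surface used as-is (it is already 0–1; an option
re-normalizes it first). Habitat classes use the fixed printed breaks
0.1/0.3/0.5 — where fixed bounds are published, they win over a data-driven
method. The integrated index, for which no bounds are published, is
classified by exact Fisher–Jenks (dynamic program minimizing within-class
SSD over contiguous classes of the sorted values, k = 4 for symmetry with
the habitat classes; ties break toward smaller lower classes). The DP is
O(k·n²), so grids above 10,000 valid cells are classified via a seeded
subsample of 10,000 values whose breaks are then applied everywhere; the
class boundaries are midpoints between adjacent class extremes, making
classification reproduce the optimal partition exactly on the optimized
sample.

The centroid of the suitable range is the area-weighted mean center of
cells with p ≥ 0.1 (the total-suitable threshold) by default; both the
threshold and a suitability-weighted mode are switches recorded in the
output, since published workflows rarely state which was used.

## Synthetic landscapes

The generator emulates the statistical structure the analysis assumes, not
any real geography:

* **Environmental layers** are a deterministic lon/lat gradient plus a
  stationary Gaussian random field simulated by circulant embedding on the
  cell lattice (exact covariance on the embedding torus; ranges in cell
  units). The default scenario has a 120×120 grid of 0.05° cells, two
  gradient covariates (a "Bio18-like" northward precipitation gradient and
  an "aspect-like" eastward gradient, jointly planting the favourable
  corner in the northeast quadrant), three further informative fields, and
  three nuisance layers sharing one parent field (pairwise r ≈ 0.93–0.96)
  to exercise the collinearity pruning.
* **Truth law**: logistic in the layers (one quadratic term), calibrated
  once so the landscape reproduces the reported statistics of the study
  system — a range-restricted species (~15% of the region above p = 0.5),
  true-suitability discrimination and cross-validated AUC near 0.9, and
  presence samples of 170 cells drawn proportional to truth.
* **Compounds**: concentration = intercept + β₁·cov1 + β₂·cov2 + correlated
  residual, truncated at 0; 26 sites sampled with nugget noise (β sized so
  the site-level Spearman ρ with each covariate is ≈ 0.6–0.7, the magnitude
  of the stronger published flavonoid–environment associations, giving the
  α = 0.05 screen realistic power at n = 26). The nugget default is 10% of
  the field variance and configurable — literature-compiled assay tables
  carry no stated noise model.

What the generator does **not** emulate: real WorldClim marginal
distributions, anisotropy, nonstationarity, sampling bias in occurrence
collection, and future-climate scenario grids (scenario labels are treated
as raster-set metadata only). Passing recovery tests on these landscapes
therefore demonstrates the correctness of the machinery under the model's
own assumptions, not the field validity of any particular real-world map.

## Pipeline and reproducibility

Stages run in the fixed order simulate → thin → select → fit → project →
classify → centroids → screen → krige → integrate; quality stages are
skipped without a compound table. One global seed is expanded into
per-stage seeds through a fixed `SeedSequence` derivation, every artifact
is written once into the run directory, and the manifest records per stage
the parameters, output paths, SHA-256 hashes, warnings and wall-clock time;
identically seeded runs produce identical artifact hashes. Problem sizes
throughout (10,000-cell backgrounds, 120×120 grids, 20–50-seed Monte-Carlo
loops) are chosen to make the full suite and the acceptance script run in
a few minutes on one CPU while keeping every estimate's Monte-Carlo error
well inside the asserted margins.

## Known limitations

* No product/threshold/categorical maxent features, sampling-bias grids, or
  extrapolation (MESS) diagnostics.
* The LMC's single shared structure cannot represent variables with very
  different spatial scales.
* Kriging with ~26 sites is strongly smoothing; secondary site data add
  little information far from the sites (no collocated co-kriging).
* Spherical geometry, not geodesic: systematic <0.3% distance error.
* Greedy thinning does not maximize the retained record count.
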