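# Methods

## Scope and data model

The package analyses islands or archipelagos characterised by four
predictors — `Area` (km²), `Topography` (topographic complexity, m),
`Isolation` (dimensionless fraction in [0, 1]) and `Population` (human
population density, km⁻²) — and two responses: the total taxon count `Spp`
and the proportion of narrow-endemic taxa `Prop = Endemics/Spp`. The
packaged fixture carries the eight-island Mediterranean dataset; arbitrary
island tables load from CSV with the same column names. Proportions used in
modelling are always the exact count ratios; 1-decimal percentages are
presentation formatting only.

## Topographic complexity (index of roughness)

For each non-masked grid point, the mean of |Δelevation| over its available
immediate neighbours is computed; the index is the arithmetic mean of these
per-point means over all points that have at least one usable neighbour.
Decisions taken where the definition is genuinely open:

- **Neighbourhood.** "Immediate neighbours" defaults to the 8-cell queen
  neighbourhood — the common ruggedness-index convention on a square lattice
  — with the 4-cell rook variant selectable. On single-row grids the two
  coincide (no diagonals exist), which the tests assert.
- **Averaging scheme.** The per-point neighbour-mean averaged over points,
  not a global mean over unordered cell pairs. The two differ on edge-heavy
  grids; the per-point reading is fixed and documented here.
- **Nodata.** Masked cells contribute neither as centres nor as neighbours;
  fewer than two usable points is a degenerate-input error.
- **Scale.** The index is scale-dependent by construction. The grid spacing
  is a field of the input type and is echoed in every result; the package
  never resamples implicitly.

Consequences used as test oracles: a flat grid scores 0; the index is
invariant under elevation shifts and positively homogeneous of degree one
(|aΔ| = a|Δ|); a diagonal ramp with constant axial step `d` has rook
roughness exactly `d`; the 2×2 grid [[0,1],[2,3]] scores 5/3 (queen) and
3/2 (rook) by hand enumeration.

## Isolation

The survey disc is the set of cells whose *centres* lie within the radius of
the focal centre cell's centre (no area weighting of boundary cells —
deterministic and enumerable by brute force). Neighbouring land is land
outside the focal island's own mask: an island is not isolated from itself,
and observed values below 1 for tiny islands next to large ones are only
consistent with that exclusion. Isolation = 1 − (neighbouring land area)/
(disc area), so all-sea surroundings give 1 and a fully land-locked disc 0.
Distances are planar Euclidean on cell centres; geodesic handling is out of
scope for the abstract rasters the package treats. A disc that would leave
the raster raises a coverage error — truncating silently would bias the
metric upward.

`choose_radius` increases the radius in increments (default 100 km) until
the focal masks are circumscribed. Whether *one* island or *all* islands
must be circumscribed is ambiguous in the protocol this mirrors; "all" is
the default (the alternative would let the smallest island set the survey
scale) and "any" is selectable. The default radius constant is 300 km.

## Count models

NB2 negative-binomial GLM: log link, linear predictor on untransformed
predictors, variance `mu + mu²/theta`. The dispersion is estimated by
profile maximum likelihood: for fixed `theta` the mean coefficients are the
IRLS solution (statsmodels GLM with the fixed-dispersion NB family), and the
exact NB2 log-likelihood is maximised over `log theta` by bounded 1-D
optimisation (tolerance 1e−10 on `log theta`, bounds e⁻⁶–e¹⁸). This is the
same joint ML that `MASS::glm.nb` performs, and the two agree to at least
four significant figures on the packaged dataset.

Deviances use the NB2 formula `2 Σ [y log(y/μ) − (y+θ) log((y+θ)/(μ+θ))]`
(the `y log y` term vanishing at `y = 0`); the null deviance evaluates an
intercept-only mean (which at fixed `theta` is exactly the arithmetic mean)
*at the full model's fitted dispersion*, which is why the null deviance
differs between models with different predictor sets. Explained deviance is
`1 − residual/null`. Wald p-values are two-sided normal, from the IRLS
covariance at the fitted dispersion (dispersion treated as fixed, the
standard GLM-summary convention).

Internally predictors are standardised (areas span five orders of
magnitude); coefficients and covariances are mapped back to the raw scale
exactly, so reported estimates are raw-scale per-unit effects.

## Proportion models

Beta regression with logit mean link and constant precision:
`y ~ Beta(μφ, (1−μ)φ)`, `logit μ = γ₀ + γᵀx`, fitted by joint ML
(statsmodels `BetaModel` behind the package surface, same standardisation
and back-transform). Pseudo-R² is the squared sample correlation between
the fitted linear predictor and `logit y`. Responses exactly 0 or 1 are a
hard error by default; the Smithson–Verkuilen shrinkage
`(y(n−1)+0.5)/n` is available behind an explicit `boundary="shrink"` flag
and is never applied silently.

## Information criteria and model selection

`AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)`, with `k` counting the intercept, the
slopes and the dispersion/precision parameter (`k = p + 2`). Ranking in
`best_subsets` is by AICc ascending, ties broken by fewer parameters and
then label. Every fit also carries the plain `AIC = −2ℓ + 2k` under the same
`k` convention: published NB model tables in this literature sometimes print
that uncorrected quantity under an AICc heading, and on the packaged fixture
it is the `AIC` column that reproduces the published criterion values
(e.g. 108.20 for the two-predictor count model, `k = 4`, `n = 8`), while the
ranking of models is identical under both conventions. Reports mark
predictor p-values significant at α = 0.05.

## Synthetic data

The generators are pure functions of (config, seed) using numpy's PCG64
(`default_rng`); identical seeds give bit-identical output.

- **DEMs**: white Gaussian noise of standard deviation `amplitude` (default
  120 m) convolved with a Gaussian kernel (`smoothing` = 4 cells), so
  roughness is exactly linear in amplitude at fixed seed. They emulate the
  smooth, spatially correlated relief a coarse elevation sampling produces —
  not drainage networks, coastlines or other real-DEM structure.
- **Land/sea rasters**: `n_landmasses` disc-shaped islands (default 5)
  rejection-placed without overlap to total `land_fraction` (default 0.10)
  of a 201×201 grid of 5 km cells; the first disc is the focal island at the
  grid centre. Real coastline fractality is deliberately absent.
- **Island tables**: predictors uniform on Mediterranean-like ranges
  (Area 300–26 000 km², Topography 50–500 m, Isolation 0.5–1,
  Population 30–1 800 km⁻²); `Spp` drawn NB2 via the gamma–Poisson mixture;
  endemics coupled to the counts as `round(Spp · p)` with
  `p ~ Beta(μφ, (1−μ)φ)`, which enforces `Endemics ≤ Spp` by construction
  (the proportion model is the generative target; the rounding adds
  O(1/Spp) noise that is negligible at the count magnitudes generated).

Default generative effects were chosen once, by power analysis, to be
unambiguously strong at n = 50 (per-standard-deviation link-scale effects of
≈0.2–0.3, Wald z ≈ 8–9): count model `β₀ = 6.0`, `β_Area = 4·10⁻⁵`,
`β_Topography = 2·10⁻³`, `θ = 20`; proportion model `γ₀ = −4.9`,
`γ_Topography = 4·10⁻³`, `γ_Isolation = 2.5`, `φ = 60`. The magnitudes
mirror the fitted Mediterranean coefficients scaled up ~2.5× so that
recovery failures indicate implementation defects rather than noise.

Passing tests on these synthetic tables demonstrate correct inference under
the models' own assumptions (independent islands, exact functional form,
no measurement error in predictors); they do not speak to spatial
autocorrelation, floristic survey error or other features of real data.

## Numerical choices and degenerate inputs

Fitting is fully deterministic: closed-form or IRLS starts, fixed iteration
caps, convergence failures raised as explicit errors (never silently
accepted). Zero-variance predictors, constant responses, counts below the
parameter count, proportions on the boundary, ragged grid files, all-nodata
grids and survey discs leaving the raster all raise typed errors; the CLI
maps validation errors to exit code 2 and convergence failures to 3.

## Known limitations

- AICc subset selection retains its well-known finite overfit probability:
  with three spurious supersets of a true two-predictor model at n = 50, the
  long-run exact-recovery rate of the true subset is ≈0.81 regardless of
  effect strength (each spurious predictor is admitted when its deviance
  reduction exceeds the ≈2.5-point AICc penalty, probability ≈0.12). Exact
  subset recovery claims near 80% are therefore knife-edge by construction.
- The isolation metric is planar; at 300 km scales on real coastlines the
  planar/geodesic discrepancy is not modelled.
- Beta-regression pseudo-R² definitions vary across software; the squared
  correlation definition used here can differ from published values computed
  under other conventions, so cross-study comparisons of pseudo-R² should be
  qualitative.
- The eight-island dataset is small; n = 8 inference leans heavily on the
  parametric assumptions, and the AICc correction term is large for the
  four-predictor models (n − k − 1 = 1).

## Problem sizes used in the test suite

Unit and property tests run on grids up to 201×201 and tables of 5 000 rows;
oracle-equivalence checks use 20 tiny (n ≤ 8) instances against zoomed dense
grid search; parameter recovery uses 50 replicates at n = 200 and subset
selection 100 replicates at n = 50. These sizes make the full suite complete
in well under a minute of statistical computation while keeping Monte Carlo
error far below the asserted tolerances.
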