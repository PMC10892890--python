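# insulametrics

Drivers of vascular-plant richness and narrow endemism on Mediterranean
islands: two bespoke geospatial metrics plus the count/proportion regression
and model-selection machinery to analyse them, packaged as a tested,
reproducible pipeline.

The package is aimed at island biogeographers and macroecologists who want to
go beyond the classic species–area relationship `S = cA^z` and quantify how
*topographic complexity*, *isolation*, *area* and *human population density*
jointly shape both the number of taxa on an island and the proportion of
those taxa that are narrow endemics.

## What it computes

**Topographic complexity (index of roughness).** Given a gridded digital
elevation model, each grid point is compared with its immediate neighbours
(8-neighbour "queen" by default, 4-neighbour "rook" selectable) and the index
is the arithmetic mean over points of the mean absolute elevation difference
to the available neighbours — edge and nodata points use only the neighbours
that exist. The estimate is scale-dependent; the grid spacing is always
carried and reported.

**Isolation.** Given a binary land/sea raster centred on a focal island, the
isolation is the fraction of a survey disc (default radius 300 km) *not*
occupied by neighbouring land, where the focal island's own cells never count
as neighbours. `choose_radius` finds the smallest multiple of a given
increment (default 100 km) that circumscribes every island in a sample.

**Regression models.** For taxon counts `Spp`, NB2 negative-binomial GLMs
(log link, variance `mu + mu^2/theta`, dispersion `theta` estimated by
profile maximum likelihood, untransformed predictors). For endemic
proportions `Prop = Endemics/Spp`, beta regressions (logit mean link,
constant precision `phi`). Models are compared with the small-sample Akaike
criterion `AICc = -2l + 2k + 2k(k+1)/(n-k-1)` with the dispersion/precision
parameter counted in `k`; the plain `AIC` under the same `k` convention is
reported alongside, since some published model tables print that quantity
under the AICc heading. `best_subsets` ranks every predictor subset (or an
explicit labelled suite) and reports Wald p-values, deviances or pseudo-R²,
and the ranking.

**Data.** The eight-row Mediterranean dataset (Corsica, Crete, Sardinia,
Sicily, Cyprus and the Malta, Balearic and Tuscan archipelagos) ships as a
packaged fixture. A fully deterministic synthetic-data module generates DEMs
(smoothed Gaussian random fields), land/sea rasters and island tables drawn
from the exact generative models the regressions assume, so every stage is
testable with known ground truth.

## Worked example

```sh
$ insulametrics fit --response count --predictors Area,Topography
M1  **Area, <0.0001**  **Topography, <0.0001**  null dev 216.07  resid dev 8.07 (96.3%)  AIC 108.20  AICc 121.53
```

Read: on the eight-island dataset, the NB2 model of taxon counts on area and
topographic complexity leaves a residual deviance of 8.07 out of a null
deviance of 216.07 — it explains 96.3% of the deviance in the number of taxa
— and both predictors are significant at any conventional level. The same
numbers are available from Python:

```python
from insulametrics import load_fixture, fit_negative_binomial

fit = fit_negative_binomial(load_fixture(), ["Area", "Topography"])
print(round(100 * fit.explained_deviance, 1))  # 96.3
print(round(fit.aic, 1))                       # 108.2  (k = 4: intercept, 2 slopes, theta)
print(round(fit.theta, 1))                     # 265.1
```

The one-shot reproduction command writes the full analysis — exploratory
correlations, the five-model NB suite (A1–E1), the four-model beta suite
(A2–D2) and the prediction surface of the best count model — to an output
directory, with a run manifest:

```sh
$ insulametrics reproduce --out reproduction
$ cat reproduction/correlations.txt
r(Spp vs Area) = 0.834
r(log Spp vs log Area) = 0.850
r(Spp vs Topography) = 0.908
r(Endemics vs Topography) = 0.851
power law: S = 425.3 * A^0.179
```

Taxon counts rise with area (r = 0.834; 0.850 after the log–log transform of
the species–area law) and even more tightly with topographic complexity.
In the ranked NB suite the two-predictor Area + Topography model comes first
by AICc; isolation and population density are never significant for counts,
while topography is significant in every model of both suites.

Other commands: `insulametrics roughness GRID.asc`, `insulametrics isolation
RASTER.asc --radius-km 300`, `insulametrics simulate --what dem|raster|table`,
and a config-driven `insulametrics pipeline` that chains grids → metrics →
table assembly → fits → reports.

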