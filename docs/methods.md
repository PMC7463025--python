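# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Response construction

Survey effort is the length of trackline per 500 × 500 m cell, computed
by exact parametric clipping of each segment at grid lines, so per-cell
lengths sum to the total clipped track length to 1e-6 relative. The
surveyed corridor is the union of 250 m flat-capped (butt-end) buffers;
flat caps make a single straight segment's corridor an exact
`length × 500 m` rectangle. Cells are half-open
`[x, x+500) × [y, y+500)`, which assigns boundary sightings
deterministically. A cell is a presence if it holds ≥ 1 sighting.
True absences are the surveyed, sighting-free marine cells with the
highest effort, matched in number to presences; ties at the selection
boundary are broken by ascending cell index and logged. The effort of
the last selected cell is reported as the absence threshold, the
quantity a field study would quote (several kilometres per cell under a
multi-year programme).

No detection function is fitted: the response is presence/absence at the
cell scale, not density, so availability and perception bias are out of
scope.

## Predictor layers

* **Distance to coast** is the straight-line (Euclidean) distance from
  the cell centroid to the coastline; cells whose footprint touches the
  target get 0.
* **Cost distances** (boat ramps, reef crest, sanctuary zones, reef
  passages) are shortest paths over the marine lattice with 8-connected
  moves (orthogonal = 500 m, diagonal = 500·√2 m), so land is walked
  around, not crossed. A shore-bound target that falls inside a land
  cell is snapped to the nearest marine cell (logged). Cells unreachable
  from a target are flagged infinite and excluded from the feature table
  with a warning. The lattice metric can exceed the straight-line
  distance by at most ~8.3 % in open water; it never undercuts it beyond
  half a cell diagonal of discretisation.
* **Slope** is the maximum gradient magnitude to any marine 3 × 3
  neighbour, `atan(|Δz|/distance)` in degrees; **complexity** is the
  population standard deviation of depth over the marine neighbourhood
  including the centre cell. Edge cells use the neighbours that exist;
  isolated cells get 0. These operators are documented stand-ins for the
  standard GIS surface derivatives; other definitions exist and would
  shift the absolute values but not the screening or ranking behaviour
  tested here.
* **Ordinary kriging** uses a spherical semivariogram
  `γ(h) = nugget + (sill − nugget)(1.5 h/a − 0.5 (h/a)³)` for `h ≤ a`,
  constant `sill` beyond, `γ(0) = 0`, and the nearest ≤ 12 samples per
  cell (the "12-point variable search radius" of common GIS kriging
  tools, read as a nearest-neighbour count). Duplicate sample locations
  are averaged before solving; the Lagrange constraint guarantees the
  weights sum to 1, and with zero nugget the interpolator is exact at
  sample locations. The kriged SST surface is produced for inspection
  but excluded from the default predictor set, which comprises the eight
  variables of the reference analysis (habitat, depth, slope,
  complexity, and the four distances) plus the distance-to-passage
  screening candidate.
* **Benthic habitat** is sampled per cell as the class of majority area;
  ties break lexicographically; uncovered cells become "unclassified"
  and are excluded from the feature table with a warning.

## Collinearity screening

`vifcor`: while the largest pairwise |Pearson r| exceeds 0.7, drop the
member of that pair with the higher VIF (computed on the current
variable set); `vifstep`: while the largest VIF exceeds 3, drop that
variable. VIF_j = 1/(1 − R²_j) with R² from an intercept-including OLS
regression of j on the other retained variables; exact dependence is
reported as infinite VIF rather than an exception so the loops handle
it. The pipeline runs vifcor first and vifstep on its survivors, logging
both reports. VIF ties break toward the later variable in input order.
The categorical habitat layer is excluded from screening (Pearson
correlation is undefined for unordered classes) and always retained.

## Ensemble model

`EnsembleSDM.fit()` draws `n_runs` (default 10) stratified 75/25
calibration/testing splits — largest-remainder allocation keeps the
overall split exactly 75/25 with each class balanced within one row —
and fits six classifiers per split:

| label | realisation | key settings |
|---|---|---|
| GAM | penalised binomial logit on cubic B-spline bases | 5 uniform knots/variable, L2, C = 10 |
| GBM | gradient-boosted trees | 100 trees, depth 3, learning rate 0.1 |
| CTA | single classification tree | depth ≤ 6, ≥ 8 rows/leaf |
| FDA | linear discriminant analysis on a piecewise-linear spline basis | 4 knots, degree 1 |
| RF | random forest | 100 trees, ≥ 5 rows/leaf |
| MAXENT | L2 logistic regression on linear + quadratic + hinge expansions | 6 hinge knots, C = 1 |

The MAXENT realisation relies on the equivalence between maximum-entropy
density estimation and logistic regression once the response is
presence/absence rather than presence/background. Regression-family
members use the binomial error distribution with the logit link. A
failed fit is retried once with a documented fallback (standardised
ridge logistic regression); persistent failures are logged and the run
dropped, with an abort if more than 20 % of runs fail.

**AUC** is the rank-sum (Mann–Whitney) concordance statistic with ties
counted one half — the probability a random presence outranks a random
absence.

**Permutation importance** for variable v is
`clip(1 − mean_r Pearson(pred, pred with v permuted), 0, 1)` over 10
seeded permutations, evaluated on the calibration rows. A constant
standard prediction yields importance 0 for every variable (correlation
treated as 1, logged); a permutation that flattens the prediction
contributes correlation 0. The alternative reading — rescaling mean
correlations across variables — would change absolute values but not
ranks; 1 − mean r is implemented because it needs no cross-variable
normalisation.

**Weighting.** Models with test AUC strictly above 0.5 enter the
ensemble with weights proportional to their test AUC (the simplest
monotone "weighted by predictive accuracy" rule); the per-cell ensemble
probability is the convex combination of member predictions, evaluated
over every marine cell. The ensemble's own held-out AUC averages, over
splits, the AUC of the weighted combination of that split's qualifying
models on that split's test quarter — so it is directly comparable to
the members' test AUCs.

## Zoning assessment

Bands are Low = [0, 0.3], Medium = (0.3, 0.6], High = (0.6, 1]: the
half-open convention closes the gap a two-decimal presentation
("< 0.3" / "0.31–0.6" / "> 0.6") leaves between 0.30 and 0.31, keeps
High strictly above 0.6, and makes the partition total. Zone summaries
report area, cell count, mean ± SD (population SD), median and range per
sanctuary zone, combined sanctuary cells, and outside cells
(recreation + general use).

The randomization test counts High cells inside sanctuary zones, then
relocates the k High cells uniformly at random without replacement over
the N marine cells 5,000 times (vectorised as the k smallest of N random
keys per permutation) and reports the one-sided upper-tail
`p = Pr(null index ≥ observed)`. This null is exactly a hypergeometric
draw, which the tests exploit as an independent oracle. Zero High cells
gives p = 1 with a warning. The number of High cells is held fixed
across permutations — the only reading consistent with relocating the
observed cells — and the null ignores spatial autocorrelation; a
contiguity-preserving null would be an extension.

## Synthetic-data generator

The generator is the package's stand-in for an unreleased survey dataset
and defines the default study conditions:

* **Geometry.** A 50 × 6 km frame; sinusoidal coastline (±300 m,
  25 km wavelength); marine band width 1.9–4.5 km (mean 3.2 km), giving
  ~160 km² of water and ~640 cells at 500 m. Coordinates are projected
  planar metres throughout; no geographic math.
* **Depth.** `depth = 1 + 44 u^{e(x)} + ε`, where u is the relative
  offshore position, `e(x)` is 1.3 modulated by two along-shore
  harmonics (amplitudes 0.7 and 0.3, wavelengths 9 and 3.7 km, floored
  at 0.35) and ε is N(0, 4 m) cell noise. Depth increases monotonically
  offshore along any shore-normal transect up to the noise. The
  modulation and noise keep the depth/distance-to-coast correlation
  near 0.55 among responding cells — deep enough structure for both
  drivers to be identifiable, as in the reference data where both
  survived screening.
* **Zones.** Thirteen along-shore segments (6 sanctuary, 5 recreation,
  2 general-use) with breakpoints placed on the cumulative marine-area
  integral so areal fractions hit 26/60/14 % within a cell-quantisation
  tolerance.
* **Structures.** The reef crest sweeps diagonally across the band
  (relative position 0.45 → 0.9 along the coast) with 12 passage points
  on it, so distance-to-reef and distance-to-passage are collinear
  (r ≈ 0.9) — the engineered analogue of the reference screening outcome
  — while neither is a clean proxy for the occurrence drivers. Two boat
  ramps sit on the coastline. The benthic map is a 1.25 km patch mosaic
  whose class mix shifts with cross-shore position but is heavily
  randomized, as digitised habitat maps are.
* **Transects.** Two opposing, evenly spaced zig-zag sets (2 km
  spacing, 500 m margins) repeated over 22 along-shore-jittered passes,
  emulating a multi-year programme: ~3,200 km of cumulative trackline
  and per-cell effort up to ~13 km, so the effort-ranked absence
  threshold lands in the several-km range a real programme reports.
* **Occurrence.** `logit p = 1 − ((depth − 10)/5)² − 4·d_coast_km`,
  plus optional linear nuisance terms and a latent N(0, 1.2) per-cell
  logit disturbance drawn with the sighting seed. The latent term
  represents drivers absent from the predictor set and keeps the
  presence/absence response from being perfectly separable. Schools
  (one point each; school sizes generated but unused downstream) are a
  Poisson number of candidates placed uniformly in the 250 m corridor
  and thinned by p; the candidate rate is calibrated via a Monte-Carlo
  estimate of the mean acceptance probability so the expected school
  count is 169. Sighting probability does not scale with school size or
  observer conditions.

Every generator is deterministic under its seed. Pipeline stages derive
their seeds from the master seed by hashing `"{seed}:{stage}"`
(SHA-256, reduced below 2³¹), so stages can be re-run in isolation.

### What the synthetic data do and do not show

The generator reproduces the *structure* of the reference study —
sample sizes, zoning fractions, effort magnitudes, driver preferences,
a collinear predictor pair — but it is smoother and more favourable
than field data: detection is perfect inside the corridor, the latent
noise is spatially independent, and the drivers are exactly the two
variables supplied to the models. Consequently the ensemble reaches
held-out AUCs near 0.95, higher than the ~0.8 a comparable field study
reports, and passing tests demonstrate correctness and qualitative
recovery (driver ranking, ensemble superiority, null calibration) — not
that the pipeline would reach any particular AUC on real surveys.
Absolute importance values likewise depend on predictor correlations
and are only meaningful as ranks.

## Problem sizes and tolerances

The default analysis uses the full study conditions (~640 marine cells,
~130 responding cells, 60 models). Repeated-survey checks in the test
suite use 50 independent seeds with 3 splits per algorithm — enough for
stable pass/fail margins on rank-recovery and AUC-threshold properties.
Oracle comparisons are exact (1e-12 for AUC and correlations, 1e-6 m for
lattice distances); Monte-Carlo comparisons use 3 standard errors at
5,000 permutations; length conservation holds to 1e-6 relative. The
uniformity check of the randomization test's p-values uses a
wide-support configuration (N = 1,200, k = 400) because the p-value of a
discrete statistic is only near-uniform when no single outcome carries
appreciable mass.

## Known limitations

* No distance-sampling detection function, availability or perception
  bias correction; no seasonal or behaviour-specific models.
* The cost-distance lattice metric overestimates open-water distances by
  up to ~8 %; ArcGIS-style path smoothing is not implemented.
* Slope/complexity definitions are standard but not the (unpublished)
  ones of the reference analysis; their strong mutual correlation means
  screening usually removes one of them on synthetic data.
* The randomization null ignores spatial autocorrelation of the
  occurrence surface.
* Kriging solves one small linear system per cell with no variogram
  fitting; variogram parameters are user-supplied.
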