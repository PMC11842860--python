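# Methods

This note records the models implemented in `stemcover`, their assumptions,
the parameters that matter, and the design choices made where the design
was genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and conventions

The analysis operates on an equal-area grid of square cells (default
10 km) in abstract planar km coordinates; no geodesy is performed, since
everything downstream is area arithmetic on an equal-area grid.  Cell
(0, 0) is the south-west corner, cell centres sit at (i + 0.5)·cell_size,
and `cell_id = iy · n_x + ix`.  Dates are ISO-8601; day-of-year runs 1–366;
week 1 is January 1–7 and week 53 is the 2-day remainder.  Fractions are
stored as decimals in [0, 1]; percentages appear only at the reporting
layer.

A *checklist* is one sampling event in one cell on one day: either a
complete list (all species recorded; its length is its species count) or a
casual cell-day (only the total number of observer × species combinations
is known).  Effort is observable only through these totals — the central
constraint the pipeline is built around.

## Pseudo-complete lists

Complete-list length is regressed on (x, y, month, elevation, nine habitat
fractions) with a random forest (default 100 trees, fixed seed; the
hyperparameters are config-exposed since nothing in the problem pins them).
Month rather than day is deliberately coarse: the model's job is a
generalisable local expectation, not a phenological curve.  A casual
cell-day is promoted iff its record total is **greater than or equal to**
the predicted length — an inclusive comparison on the real-valued
prediction, with no rounding.  The promoted list's presences are the union
of its casually recorded species; all other modelled species count as
absences, which is what makes the list usable as detection/non-detection
data.  Promotion is monotone in the record total by construction.

## STEM ensemble

Non-stationarity is handled by partitioning space-time into stixels
(default 500 km × 500 km × 40 days) and fitting an independent base model
per stixel; n = 10 randomly offset partitions (uniform offsets in one
stixel width per axis) give each point up to n covering models.  Stixel
membership is `floor((coord − offset)/width)` per axis; the temporal axis
is linear in day-of-year with clipped edge stixels — the study species are
essentially absent from the area in mid-winter, so circular time buys
nothing.

Base models are gradient-boosted classification trees (1000 trees, bag
fraction 0.95, interaction depth 3; learning rate 0.1, config-exposed) on
easting, northing, year, ordinal day, list total, data type
(complete/pseudo), elevation, habitat fractions and climate covariates.
Stixels with fewer than 30 lists are skipped; single-class stixels get a
constant-probability model (so an all-absence stixel predicts 0, which the
0.01 floor preserves).

A weekly surface evaluates every covering base model at the week's 4th day
(the mid-week day; clamped to day 366 for week 53) under reference
conditions — list total 25, year 2018, data type complete — then takes the
arithmetic mean, the between-model **sample** variance (n−1; support 1 →
variance 0 by convention) and the support count.  Averaged probabilities
below 0.01 are set to zero *after* averaging; cells with support 0 are
flagged missing and excluded from coverage rather than imputed.

Predictive skill uses 5-fold cross-validation with environmental blocking:
folds are k-means clusters of the standardised cell covariates, so test
data occupy regions of environmental space the training data do not — a
deliberately harder test than random folds.  Fold AUC is computed on
held-out detections against ensemble probabilities at the checklists' own
covariates; single-class test folds are reported undefined and excluded
from the mean with a warning.

## Protected areas and coverage

Polygon processing follows standard practice for the world protected-area
database: keep features with status Designated/Inscribed/Established; drop
biosphere reserves, OECMs and features whose designation type is not
assigned/reported/defined; buffer point features to circles of their
reported area (r = √(A/π)); repair invalid geometries.  Overlaps are
dissolved progressively Ia → Ib → II → III → IV → V → VI → unassigned, so
stricter designations claim contested ground; the dissolved layer is
reported per category group {I–IV, V–VI, undesignated} and intersected
with the grid to give disjoint per-cell fractions.  The category filter
used for the strict-protection variant keeps I–IV *and* undesignated
(category is simply unreported for about half of European protected land,
not known-weak).

Weekly coverage is the ratio estimator C = 100·Σpᵢaᵢ/Σpᵢ, which assumes
birds are evenly distributed within a 10-km cell over the week.  It is
invariant to rescaling all pᵢ and bounded in [0, 100].  A thresholded
variant (cell fully protected iff aᵢ ≥ 0.10 or 0.50) quantifies
sensitivity to that assumption.

Weekly range area is cell_area × count of cells with floored p > 0 — a
count-based area, consistent with treating the 0.01 floor as the range
boundary (a probability-weighted area is the obvious alternative; the
count-based one matches how the floored surfaces are used everywhere
else).  The range-adjusted target is 100% for ranges ≤ 1,000 km², the
policy baseline (17% or 30%) for ranges ≥ 250,000 km², loglinear in
between — linear in ln(area), hence independent of logarithm base; both
boundaries are closed so the function is total, continuous and
non-increasing.

The season window runs from the earliest to the latest week whose summed
occurrence is ≥ 25% of the species' maximum; interior dips stay inside the
window (they are detectability lows, not absences).  Season categories are
spring passage (weeks 5–18), breeding (19–31), autumn passage (32–48);
weeks 1–4 and 49–53 extend the nearest passage category so every in-window
week has a label for the mixed model.

## Association models

Weekly coverage is modelled as pct ~ z(range) + season + (1 | species) by
REML; range size enters standardised, and the raw-scale slope (scaled
β / SD) is reported alongside.  Mean per-species coverage is related to
habitat class (farmland incl. grassland / forest / other) by OLS with
Tukey-adjusted pairwise contrasts; levels with a single species are
excluded with a warning.  Long-term population trend enters as
log₁₀((100 + trend%)/100), which makes the same *geometric* change
symmetric about zero — doubling pairs with halving.  (A ±50% pair is *not*
symmetric under this transform; the formula is implemented literally.)
Trend is regressed on mean coverage and mean range size, optionally plus
one of habitat, migration class or log body mass — at most three
predictors, since only ~28 species carry trends — and a refit excluding
short-distance migrants checks that the coverage association is not a
migration-distance surrogate.  Standard mixed-model and least-squares
machinery (statsmodels) stands behind these fits; the module's content is
the model specifications, transformations and contrasts.

## Synthetic world

The generator reproduces the structure the analysis assumes, with known
ground truth:

* **Covariates** — smoothed Gaussian noise fields; habitat fractions are
  softmax shares of per-class propensity fields scaled by a < 1
  "classified" share, so the nine fractions sum to ≤ 1; temperature falls
  with northing and elevation.
* **Protection** — a smooth propensity field shifted on the logit scale by
  `farmland_bias × crops` (default −2: protection avoids arable land, the
  documented siting bias), raised to a power solved by bisection so the
  area-weighted mean equals the requested total (default 0.201, the
  study-area share); per-cell protection is split among category groups by
  softmax weights around the observed 28.5 / 20.5 / 51.1% mix.
* **Species** — occupancy(day, cell) = seasonal amplitude × Gaussian
  latitudinal band around a moving centroid × logistic habitat
  suitability.  The centroid enters from the south, reaches the breeding
  latitude, holds, and returns; the amplitude gives the breeding season a
  1.6× boost over passage, since during passage part of the population is
  strung out along the flyway outside the study area.  Default suitability
  effects are strong (trees +8, crops −4 on the logit scale): the
  parameter-recovery tests are defined for a strongly covariate-driven
  species.
* **Effort** — events per cell-day are Poisson with habitat-biased
  placement weights (default: urban oversampled, forest undersampled, the
  documented citizen-science bias); 60% of events are complete lists.
  Complete-list length is focal presences plus 1 + Poisson background
  richness that increases with tree cover (real lists count all birds, not
  just the modelled species).  Detection is Bernoulli(occupancy ×
  detectability); detectability defaults to 0.8 (a well-detected singing
  passerine), with casual detections thinned by a further 0.8.  Casual
  cell-days carry a single observer × species combination total
  (1 + Poisson, mean 15 per event); that rate is calibrated so the
  promoted:complete ratio of the default world (~0.57) matches the roughly
  0.6 : 1 mix of pseudo-complete to complete lists the production analysis
  works with.

What the generator does **not** emulate: observer identities and
per-observer skill, time-of-day detectability cycles, multi-portal
reporting heterogeneity, remote-island artefacts, and any real geography.
Passing recovery tests therefore demonstrates that the estimator chain is
consistent under the model's own assumptions — not that those assumptions
hold for any particular real dataset.

## Problem sizes and numerical choices

Tests and the worked examples run a reduced study: a 40 × 40 grid of 10-km
cells, one year, ~20k checklists, 5 partitions and 100-tree base models.
The stixel dimensions are kept at the production 500 km × 40 days — it is
the world that is reduced, not the block recipe; under environmental-block
extrapolation, shrinking stixels to 200 km measurably hurt held-out
discrimination.  Rule parameters (30-list minimum, 0.01 floor, 25% season
cutoff, 17/30% baselines, reference conditions) always keep their
production values; `PipelineConfig()` defaults to the full production
recipe (1000 trees, n = 10).

Degenerate inputs are handled explicitly: all-zero occurrence weeks raise
(coverage undefined); all-zero summed-occurrence series raise (no season
window); identical covariates everywhere make environmental blocking
impossible and raise; constant responses yield zero slopes and vacuous
contrasts rather than NaNs.  Seeded operations are bit-reproducible; GBM
base-model seeds are derived deterministically from the ensemble seed and
the stixel index.

## Known limitations

* Occurrence, not abundance: summed occurrence weights cells by
  probability of presence, which saturates where the species is common.
* The within-cell uniformity assumption of the coverage ratio is untested
  at sub-cell scale; the 10/50% thresholded variant brackets it.
* Environmental blocking uses k-means on cell covariates; other blocking
  schemes (spatial blocks, dissimilarity-based) would give different — often
  harsher — skill estimates.
* The synthetic world's effort process is far simpler than real
  citizen-science effort; recovery results transfer to real data only to
  the extent the real effort biases are captured by list length and data
  type, as the method assumes.
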