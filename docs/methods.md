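# Methods

## The ecometric model

Let each sampling point `p` carry a community — the set of species whose
range polygon covers `p` (boundary-inclusive "covers" semantics, so a point
on a range edge counts as inside). With species-level trait values
`t_1 … t_k` for the trait-bearing members, the point's community summaries
are

    m(p) = mean(t_i),      s(p) = SD(t_i)   (n − 1 denominator)

by default; both summary functions are pluggable (any function of a nonempty
numeric vector — a maximum, a quantile, a functional-diversity index). The
SD is undefined for single-species communities and recorded missing. A point
is **valid** when at least `min_species_valid` (default 3) trait-bearing
species are present; only valid points train models. Species with a range
but no trait record count toward richness but not toward
`richness_with_trait` or the metrics.

The (m, s) plane — the ecometric trait space — is partitioned into a `B1 ×
B2` grid of equal-width bins spanning the training range on each axis.
Intervals are half-open `[e_i, e_{i+1})` except the last, which is closed so
the maximum datum is binned. Bin counts default to Scott's rule per axis:

    h = 3.49 · s · n^(−1/3),    B = max(1, ceil(range(x) / h))

with `s` the sample SD. Constant data cannot be binned and is an error.

**Categorical environments.** Per bin `(i, j)` the model stores the count
`c_ijk` of training points with category `k`, the frequencies `π_ijk =
c_ijk / Σ_k c_ijk`, and the prediction `argmax_k π_ijk` — the
maximum-likelihood category. Modal ties break deterministically: first to
the category with the higher global training frequency, then
lexicographically. Empty bins carry no prediction and nothing is imputed at
fit time. Training accuracy (*sensitivity*) is the share of training points
whose observed category equals their bin's prediction.

**Continuous environments.** The variable is discretized into `E`
equal-width intervals spanning its training range (`E` again from Scott's
rule unless given). Per trait bin the model stores interval frequencies and
predicts the midpoint of the modal interval — the ML estimate under the
discretized distribution — with ties resolved to the lower interval. The
per-bin mean of raw values is stored alongside as a secondary summary.
Diagnostics are the Pearson correlation of observed vs predicted over the
training points and the per-point anomaly (observed − predicted).
Predictions are bounded by the training environmental range by construction;
the model cannot extrapolate.

## Reconstruction

A fossil site contributes only its (m, s) summaries. It is assigned a trait
bin by the same interval rule; summaries outside the modern grid are
**clamped** to the nearest edge bin and flagged `out_of_range` rather than
dropped, keeping the extrapolation visible. A fossil landing in an empty bin
borrows the nearest non-empty bin by Euclidean distance on bin-index
coordinates (ties toward smaller indices) and is flagged `imputed_bin`. The
site inherits the bin's prediction and full probability vector.

Nearest-modern-analogue matching uses the spherical haversine distance with
mean Earth radius 6371.0088 km; ranking nearby points does not need
ellipsoidal geodesy. The search runs over **all** modern sampling points,
valid or not — the nearest place is a geographic statement, not a modelling
one — and distance ties break to the lexicographically smallest point id.
When the analogue was a training point its own trait bin is reported too,
for past-vs-present comparison in trait space.

## Sensitivity analysis

Robustness is probed by repeated subsampling **without replacement**: at
each sample size `s` and replicate, `min(s, n)` valid points train a fresh
model and the complement is held out. Sampling with replacement would leak
training duplicates and leave no clean test set, so a subsample/complement
split is used while the procedure is still driven by repeated random
resampling. Held-out points falling in bins the replicate never occupied
cannot be predicted; they are excluded from test accuracy and reported
separately as `test_coverage` (the fraction of held-out points in occupied
bins), so unpredictability and misclassification stay distinct. Replicates
whose training draw is degenerate (a single category, constant environment)
are recorded as failed and the run continues. Default 50 replicates per
size; all draws come from one seeded generator, so identical seeds give
identical record tables.

## The synthetic world

The generator emulates the structure of a continental ecometric study
without reproducing any real dataset. Its defaults are the package's
reference study conditions:

| parameter | default | meaning |
|---|---|---|
| domain | 60° × 20° (lon −30…30, lat −10…10) | study region |
| `n_species` | 80 | species pool |
| range half-widths | U(3°, 8°) per axis | box or ellipse ranges |
| `n_points` | 2000 | sampling points, uniform |
| `rho` | 0.95 | trait–environment coupling |
| `noise_sd` | 1.0 | SD of species-level trait noise |
| `env_kind` | categorical, K = 4 bands | or a smooth linear gradient |
| `n_fossils` | 15 | fossil sites |
| `fossil_noise_sd` | 0.01 | noise on fossil summaries |
| `fossil_jitter_deg` | 0.2° | fossil location jitter |

The environment varies along longitude only — the simplest geometry in which
point-in-polygon assignment, binning and recovery are all exercised and
human-checkable. Categorical worlds slice the gradient into K equal
longitudinal bands (labelled with vegetation-type names for K ≤ 5).
Species-level traits derive from the scaled environment at the **range
centroid** (`trait = rho · e + (1 − rho) · ε`), mirroring the real data
model in which one species has one trait value but occupies many points.
Fossil sites copy the summaries of randomly chosen valid sampling points,
perturbed by small metric noise and location jitter, with the true
environment at the fossil location recorded for scoring.

What the world does **not** emulate: realistic range shapes and richness
gradients, phylogenetic correlation of traits, spatially autocorrelated
sampling, preservation bias, and environments varying in two dimensions.
Passing recovery tests therefore demonstrates that the estimators are
implemented correctly and behave as designed under known signal, not that
any particular real trait predicts any particular real environment.

Under the reference conditions roughly 90% of points are valid, held-out
classification accuracy sits a little above 0.9 on a 25 × 25 grid, and the
residual errors concentrate at band boundaries, where communities genuinely
mix species from adjacent environments — at the chosen range sizes the
community acts as a spatial smoother with a scale of a few degrees, which is
the designed behaviour, not an artefact.

## Numerical conventions and edge cases

- Bin indices are 0-based. Grid membership of training points is stored in
  the model and archived, so diagnostics can be recomputed from an archive.
- Model archives are single versioned JSON documents; floats survive
  round-trips bit-identically (JSON doubles via repr-faithful encoding).
  Unknown versions or corrupt files raise an explicit archive error.
- Species names normalize whitespace runs to single underscores
  (idempotent). Duplicate ids, out-of-range coordinates and negative fossil
  SDs are validation errors that name the offending rows.
- Invalid range geometries are repaired (`make_valid`); species whose
  geometry stays invalid are dropped with a warning rather than aborting the
  run. Multi-feature species are unioned. Missing CRS declarations are
  assumed WGS84 with a warning.
- The spatial index (STRtree) used for point-in-polygon assignment is purely
  a performance device; tests assert its results equal a brute-force
  per-(point, polygon) containment scan.
- Fitting is deterministic: identical inputs give bit-identical models.
  Randomness exists only in the synthetic generator, point inspection
  sampling and the sensitivity resampler, each driven by an explicit seed.
- A summary function that raises on some community records that metric as
  missing for that point; the run continues.
- Problem sizes in the test suite and acceptance script (2000-point worlds,
  25 × 25 grids, 20-replicate sensitivity ladders) match the reference
  study conditions above; unit tests use smaller worlds where the contract
  under test does not depend on scale.

## Design choices

- **Boundary-inclusive containment** ("covers"): deterministic and matches
  common GIS practice; a point on a shared edge of two ranges belongs to
  both communities.
- **Raw frequencies, no smoothing** of bin probabilities: the model is a
  pure summary of observed data; regularization is left to the user's
  binning choice.
- **Clamping over dropping** for out-of-range fossils: every fossil receives
  an estimate, and the flag preserves honesty about extrapolation.
- **Midpoint-of-modal-interval** as the continuous ML estimator: fully
  specified, testable, and consistent with the categorical model's modal
  rule under discretization.
- **Fossil/analogue outline colours** in ecometric-space plots default to
  black/red and are user-overridable.

## Known limitations

Equal-width binning is sensitive to outliers in the trait summaries (one
extreme community stretches the grid); no quantile or adaptive binning is
provided. Models with more than two summary metrics are out of scope. The
probability vectors quantify within-bin heterogeneity only — they carry no
uncertainty from range maps, trait measurement or binning choices. GeoJSON
is the only supported polygon format.
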