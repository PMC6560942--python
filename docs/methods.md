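# Methods

This note documents the models, the synthetic study system, the numerical
choices and the known limitations of `nichetrunc`.

## The problem being modelled

A species driven out of most of its range by people persists where people
are not — typically steep, high, inaccessible terrain.  Its *current*
occurrences then sample a truncated corner of its climatic niche, and any
distribution model calibrated on them alone will equate "where it survives"
with "where it can live".  The package's central comparison is therefore
between models calibrated on current records only and models calibrated on
current plus historical records (records of extirpated populations,
identifiable only to genus), with the difference in predicted suitable area
as the measure of truncation.

## Grids and areas

All layers live on one projected equal-area grid (cells of `cell_size` km,
default 5 km), so a cell's area is exactly `cell_size²` and every area in
the package is a cell count times that constant.  Layers with mismatched
geometry are rejected, never resampled: silent resampling hides alignment
bugs, and resampling policy belongs to the user's GIS, not to the analysis.
Missing data is `nan` in memory; every window or block statistic ignores it,
and a statistic over zero valid values is itself missing.

Topographic derivatives use the Horn 3×3 method for slope (degrees, on the
projected grid), the 3×3 windowed standard deviation for STD, and slope of
the slope layer for roughness (TR).  Edge cells use the available
neighbourhood via edge replication, and missing neighbours are replaced by
the window's centre value — the usual DEM convention.  3×3 is an assumption;
no window size is canonical for these derivatives at 5-km resolution.

## Occurrence preparation

Range polygons become one current-period record per cell whose **centre**
falls inside the polygon.  Filters then drop current records outside the
species' elevation range or in cells with tree cover below 50%, population
density above 100 persons/km², or Human Influence Index above 20 — all
strict exclusions, so records exactly at a threshold are kept.  Historical
records bypass every habitat filter: 2010 tree cover or human pressure says
nothing about habitat centuries ago.

Spatial thinning removes the record with the highest Gaussian-kernel local
density (bandwidth two grid cells by default), iterating until a target
count or minimum spacing is reached; density ties are broken by a seeded
draw so runs are reproducible.  This is a deterministic, density-targeted
re-specification of the usual probabilistic thinning tools, not a
re-implementation of any of them.

The historical temperature adjustment subtracts a fixed Δ ∈ {0, 0.7, 1.5,
2.0} °C from the four temperature covariates of the *historical records
only*, before calibration.  Prediction always uses unadjusted current
climate: the adjustment models what the climate was when the record was
observed, not what the landscape looks like now.  This calibration-side
reading is the only one consistent with suitable area *shrinking* as Δ
grows (a larger Δ pulls the historical warm margin down).

## The maximum-entropy model

Features: linear, quadratic, pairwise products, forward and reverse hinges
(30 knots per variable at equally spaced background quantiles) and
thresholds (10 knots), all evaluated on variables min–max normalised over
the background and clamped to [0, 1] when predicting outside it.

Fitting minimises

    J(λ) = −(1/m) Σᵢ λ·f(xᵢ) + log Z(λ) + Σⱼ βⱼ|λⱼ|

with βⱼ = (regularisation multiplier) × (per-class base, interpolated on
presence count: linear/quadratic/product 1.0→0.05 over m = 10→100, hinge
0.5, threshold 2.0→1.0) × (presence-sample standard deviation of the
feature, floored at 0.05) / √m.  The default multiplier is 2.5 and the
iteration cap 5,000.  The non-smooth L1 term is handled exactly by the
split λ = λ⁺ − λ⁻ with non-negativity bounds, solved by L-BFGS-B; the
problem is convex, and the optimiser tolerances are set so that fits from
random initialisations agree in objective to ~1e−9 (the package's
reproducibility check demands 1e−4).

Background: all valid study-area cells, or a seeded uniform sample of
10,000 if there are more.  Raw output is exp(λ·f)/Z, summing to 1 over the
training background; logistic output is e^H·q/(1+e^H·q) with H the entropy
of the fitted distribution (equivalent to the conventional prevalence-0.5
transform).  Training gain is the penalised improvement of mean presence
log-likelihood over the uniform background model.  Response curves sweep
one variable over its background range with the others held at their mean
presence values.  Jackknife importance refits with each variable alone and
left out; cross-validation partitions presences into seeded folds and
averages held-out AUC and the logistic maps.

AICc uses the likelihood of the raw output re-normalised over the
background at the presence records, with k = the number of non-zero
weights; it is undefined (reported missing) when m ≤ k + 1.

## The envelope model

Bounds are exact per-variable minima and maxima over the calibration
records — closed intervals, so a cell exactly at a bound is suitable.  No
percentile trimming: the point of the model here is its monotonicity
(adding records can only widen the envelope), which turns the
historical-records comparison into a one-sided guarantee rather than an
empirical tendency.

## Evaluation

Background cells stand in for absences, so AUC is computed presence vs
background (rank-sum form, ties at half) and its ceiling is below 1.  TSS
uses sensitivity = fraction of presences at/above the cutoff, specificity =
fraction of background below it; in auto mode the cutoff maximises their
sum, ties resolved to the lowest cutoff, and the cutoff used is always
reported.  Thresholded maps count a cell as present when suitability is
**at or above** the cutoff, so the training presence defining the
10th-percentile threshold is itself classified present; the P10 cutoff is
the order statistic at 0-based index ⌊0.1 m⌋, which guarantees ≥90%
training coverage for every m.  Mann–Whitney tests are exact by enumeration
for combined n ≤ 12 without ties and use the tie-corrected normal
approximation otherwise; a pooled sample with zero variance is reported as
p = 1.

## The synthetic study system

The generator produces the structure the analysis assumes, not any real
region:

- **Elevation**: a smoothed Gaussian field (correlation length 5 cells),
  centred at 2500 m, spread ~900 m.
- **Temperature**: a shared driver (synoptic field minus a 6 °C/km lapse
  rate times elevation).  Each temperature variable adds independent smooth
  noise whose variance is chosen analytically so the pairwise correlations
  with annual mean temperature hit configured targets (defaults 0.98 /
  0.96 / 0.92 for MinTCM / MTCQ / MTWQ, the magnitudes real bioclimatic
  grids show); the generator verifies each target empirically to ±0.05 and
  raises otherwise.
- **Precipitation**: positively inter-correlated fields, wetter where
  warmer — reproducing the conflict at the heart of the refugee story, that
  the climatically best land is also the most settled.
- **Human pressure** (HII 0–64, population density) concentrated in the
  lowlands; **tree cover** rising with elevation and falling with HII;
  **protected areas** as smoothed-noise blobs covering ~10% of cells.
- **Truth**: a product of Gaussian responses, by default centred at
  MTCQ = 8 °C (width 3.5) and PANN = 1400 mm (width 350) — log-quadratic in
  the variables, hence exactly representable by the quadratic feature
  class.
- **Occurrences**: historical records (default 60) sample all cells with
  probability proportional to truth; current records (default 150) sample
  the same truth restricted to cells above 3000 m with HII ≤ 20.  Both are
  drawn without replacement at cell centres, fully seeded.

Default problem sizes — a 60×60 grid for the main scenario, 40×40 with 100
presences for the replicate studies — were chosen as the smallest
landscapes on which the spatial fields still have room for distinct
high/low-elevation regions; the replicate studies use 12–20 seeded
replicates.

What passing tests on this system do **not** show: real ranges have
georeferencing error, sampling bias correlated with access, climates with
structure no smoothed noise reproduces, and historical records whose
"period climate" is genuinely unknown rather than a configurable Δ.  The
synthetic results validate the machinery and the directional logic, not any
real-world area figure.

## Design choices made where the design was open

- **Model grid**: four variable subsets — {PANN, PDryQ, MTCQ, MTWQ},
  {PANN, PDryQ, MinTCM, MTWQ}, {PANN, PDryQ, MinTCM}, {PANN, PDryQ, MTCQ} —
  each fitted current-only and current+historical.  MinTCM and MTCQ never
  co-occur (they correlate at ~0.98) and MTWQ appears in half the models.
- **TSS threshold**: reported TSS uses the max-sensitivity+specificity
  cutoff, recorded alongside the value.
- **Ensemble intersection**: each model is binarised at its own training
  threshold, then counts are summed; "minimum one model" and "all models"
  masks feed the area accounting.
- **Tree-cover classes are nested** (≥75% within ≥50%) in the area summary.
- **Per-model thresholds** rather than a shared one, since every model
  reports its own training threshold.
- **CLI stages** (`simulate`, `prepare`, `fit`, `evaluate`, `ensemble`,
  `envelope`, `overlay`, `nichetest`, `run-all`) are thin wrappers over
  stage functions that read and write one run directory, so any stage can
  be re-run in place; artefacts carry the configuration hash and runs are
  byte-identical for a fixed seed.

## Known limitations

- No reprojection or geodesic area: inputs must already be co-registered on
  an equal-area grid.
- No categorical features or clamping diagnostics in the maxent core;
  predictions clamp features to their background range.
- Species-level envelopes assume the per-species records were already
  elevation-filtered.
- The thinning algorithm targets density, not the exact behaviour of any
  published thinning tool.
- AUC/TSS against background pseudo-absences measure discrimination from
  the landscape, not from verified absences.
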