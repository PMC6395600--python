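# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the known limitations of `racbrt`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The modelling pipeline

### Boosted regression trees

The learner is stage-wise gradient boosting of shallow regression trees on
Bernoulli deviance, provided by scikit-learn's `GradientBoostingClassifier`.
The ecological-workflow layer — cross-validated ensemble-size selection, the
lr/tc tuning rule, backward simplification, influence rescaling, partial
dependence, and the spatial correction — is implemented in this package.

- **Tree complexity** `tc` is the number of splits per tree, mapped to
  `max_leaf_nodes = tc + 1` (best-first growth). `tc = 1` yields stumps
  (no interactions); `tc = 2, 3, 5` allow progressively deeper interactions.
- **Ensemble size** is the minimizer of the mean held-out Bernoulli deviance
  across stratified k folds (default k = 10); the final model is refit on
  all data at that size. `cv_auc` is the mean held-out AUC at the selected
  size and `cv_auc_se` its standard error over folds. Deviance explained is
  100·(1 − CV deviance / null deviance), both held-out; a training-based
  variant can be computed from the fitted estimator directly.
- **Tuning rule**: iterate tc ascending, lr descending within tc, and return
  the first configuration whose CV-selected size reaches the tree floor
  (1000 trees in the field-scale configuration; `desk_scale_config()` uses
  300 with grids lr ∈ {0.05, 0.01}, tc ∈ {2, 3}). Shrinkage controls how
  many trees are needed, so large lr fails the floor and small lr passes.
- **Simplification** drops the lowest-influence variable and keeps the drop
  while CV AUC falls by ≤ 0.005 and deviance explained by ≤ 0.5 percentage
  points (both configurable). "No change" needed quantifying; these
  tolerances are of the order of one tenth of the between-fold noise at
  n = 272. When a protected correction term (the RAC) is present, at least
  one substantive covariate is always retained: a RAC-only model is spatial
  interpolation, not an ecological hypothesis, and would starve the hybrid
  variable selection.

### Spatial statistics

- **Weights**: queen contiguity, row-standardized, is the default for both
  Moran's I and the RAC; rook and inverse-distance (optional cutoff) are
  available. Grid coordinates are planar km; no reprojection.
- **Moran's I** uses the standard cross-product statistic with expectation
  −1/(N−1); p-values by the closed-form randomization variance (normal
  approximation) or by permutation (999 draws, seeded). The generic function
  defaults to a two-sided test. The *pipeline's* residual checks are
  one-sided for positive autocorrelation: the RAC correction exists to
  remove positive residual structure, and autocovariate refits typically
  overshoot into slight negative residual autocorrelation (fitting the
  neighbourhood mean induces deviations-from-local-mean behaviour); a
  two-sided test would flag that known artifact rather than the failure
  mode the check is about.
- **RAC**: each cell's value is the weighted mean of *sampled* neighbouring
  cells' response-scale residuals (y − p̂, in-sample); weights over
  unsampled neighbours are dropped and renormalized; a cell with no sampled
  neighbour receives the global mean residual. Deviance residuals are not
  used (response-scale is the default and only implemented choice; the
  method's focal-mean formulation operates on the residual raster).
- **Grid-wide prediction** assigns sampled cells their own RAC and
  non-sampled cells the mean RAC over sampled cells (≈ 0 for a calibrated
  model); a per-neighbourhood interpolation policy is available.

### Favourability, validation, scenarios

- F = odds(P) / (n₁/n₀ + odds(P)), extended continuously to F(0) = 0 and
  F(1) = 1. "Favourable" means F ≥ 0.50 everywhere in this package (the
  boundary is included); 0.45 ≤ F < 0.50 is the near-threshold band and
  F > 0.75 marks highly favourable cells in regional summaries.
- Validation against an independent presence set reports the favourable and
  near-threshold percentages and the false-negative percentage
  (100 − % favourable).
- Scenarios apply multiplicative/additive climate deltas (default 2040
  signal: precipitation ×0.90, temperature +1.5 °C) and landcover
  replacements or remappings; frozen variables (default *Eucalyptus*,
  whose cover is legally capped) are asserted bit-identical. Projection
  reuses the training prevalence (n₁, n₀). The scenario comparison is a
  χ² homogeneity test on favourable/unfavourable counts across the scenario
  maps, df = n_scenarios − 1; with four scenarios df = 3, the parameterism
  consistent with the reference statistic/p-value pair (1.392 → 0.707).

## The synthetic landscape

The generator manufactures worlds with the statistical structure the
analysis assumes; it does not emulate real geography (a schematic 33×30
mask with exactly 987 cells stands in for the national 10-km grid).

- **Covariates** (33 registry variables in four hypothesis groups) are
  Gaussian-kernel-smoothed white-noise fields (kernel sd =
  `spatial_range_cells`; landcover/disturbance 3 cells, topography 4,
  climate 8) whose marginals are mapped by a rank-uniform power transform
  onto each variable's mean and range: x = lo + (hi−lo)·U^a with
  a = (hi−lo)/(mean−lo) − 1. This matches the mean exactly, spans the full
  range, and gives the right-skewed, zero-inflated marginals typical of
  percentage-cover and livestock-density variables — which matters because
  the response thresholds (e.g. podzols > 50%) must be reachable. An affine
  rescale cannot reach the range bounds of skewed variables without
  absurd variance and was rejected for that reason. `Sediment` is generated
  as 100 − (other lithology shares) + noise so the VIF screen has a true
  offender; `Hunting` is a thresholded field with mean 0.5 (no reference
  mean exists for a binary layer).
- **Survey**: knight's-move lattice {(2r + c) mod 5 = 0} pre-selects ~1/5
  of blocks (198 of 987; the field campaign's rule yielding exactly 180 is
  not reconstructible); a seeded subset of 136 blocks is surveyed, two
  random 5-km quadrants each → 272 cells, five 500-m transects per cell.
  Transect attrition (the campaign walked 1315, not 1360 transects) is not
  simulated; effort arithmetic takes transect counts as inputs.
- **Response**: latent occupancy is Bernoulli with logit = intercept +
  Σ piecewise-linear effects + spatially correlated noise. The default
  effects encode the qualitative ecology of the emulated system
  (herbaceous/shrubland optimum at 5–10% cover, *Eucalyptus* penalty above
  ~15%, podzol/eruptive bonus above 50%, goat-and-sheep bonus above
  4 ind/km², cattle penalty, optima at 800–1000 mm and 15–16 °C), with
  amplitudes calibrated once so a tuned BRT reaches CV AUC in the mid-0.8s
  at 272 cells — the discriminability regime of the emulated study. The
  intercept is solved by bisection so expected observed prevalence is 35%.
  Detection is imperfect: each transect detects an occupied cell with
  probability 0.4 (five transects → 92% per cell); a cell is positive iff
  any transect detects.
- **Latent noise** defaults to sd 0.8, range 1 cell. With a coarse, strong
  field the paired quadrants share noise, the RAC leaks neighbour labels,
  absorbs ~90% influence, and grid-wide maps collapse to the mean-RAC
  constant — a regime far from the mild residual autocorrelation and
  26–55% retained covariate influence the pipeline is meant to reproduce.
  Fine-scale noise restores that regime.

### What the synthetic worlds do and do not show

Smooth covariates on a small grid can proxy location, so an in-sample
boosted fit absorbs a *coarse* latent field through them and default-world
residuals show little positive autocorrelation. The spatial-correction
recovery therefore runs under `spatial_stress_conditions()` — spatially
uncorrelated covariates plus a dominant coarse field — where the
uncorrected model's residuals fail the Moran test decisively (I ≈ 0.1–0.3,
p ≈ 0) and the RAC takes ~20–50% influence. Passing tests demonstrate that
the machinery detects and removes residual spatial structure where it is
present and attributes influence to true drivers under the sparse survey;
they do not demonstrate performance on real landscapes, where covariate
maps are not stationary Gaussian fields, detection varies with habitat, and
spatial structure mixes scales.

The recovery experiments (`racbrt.recovery`) use reduced settings — 5 CV
folds, 500-tree cap, fixed lr = 0.01 / tc = 2, no simplification — chosen
as the package's desk-scale configuration; the properties checked (Moran
repair, influence ranking, projection identity) do not depend on the extra
polish. Twenty seeds per experiment; the spatial experiment runs on a
17×16 fully surveyed grid (272 cells), the ranking experiment on the full
33×30 national analogue with the 136-block survey.

## Numerical and interface choices

- Cell ids are `row·n_cols + col`, row 0 northernmost; centroids at
  ((col+0.5)·s, (row+0.5)·s) km. Rasters are single-band float32 TIFFs with
  NaN nodata and an ESRI world-file sidecar carrying the affine transform.
- One global seed fans out to per-stage seeds by CRC-hashing stage names
  (all seeds < 2³¹); identical seed + configuration reproduces every output
  bit for bit, which the manifest (SHA-256 per artifact) makes checkable.
- VIF screening runs group-wise (within each hypothesis's variable set) by
  default, matching how the hypothesis models consume the variables; global
  screening is available. Ties in the max-VIF removal break by column order.
- Perfect collinearity returns a +inf VIF sentinel (R² within 1e-12 of 1).
- The hybrid-selection rule is the shortest influence-ordered prefix whose
  cumulative non-RAC influence reaches 50% of the non-RAC total. On the
  reference influence tables it reproduces three of the four published
  bold sets exactly; for the topography/geology hypothesis it keeps a third
  variable (Alt_mean) where the published table bolds two — no single
  simple rule reproduces all four sets, and the divergence is surfaced in
  the tests rather than special-cased. Alternative rules (top half by
  count, fixed top-k) are provided.
- `compare_hypotheses` sorts by CV AUC descending with lexicographic
  tie-break and flags ties explicitly.

## Known limitations

- The RAC is computed once on all sampled cells before cross-validation, so
  CV AUC of RAC models is optimistic (neighbour labels leak into the
  autocovariate). This is inherent to the method as practised; rankings
  among hypotheses remain comparable because all models share the
  treatment, but absolute AUCs of RAC models should be read cautiously.
- Projection under scenarios extrapolates a tree ensemble, which is
  piecewise-constant outside the training hull: covariate shifts beyond
  observed ranges saturate rather than extrapolate trends.
- The generator's fields are stationary and isotropic; real ecogeographic
  layers are neither. Binary detection is homogeneous across transects.
- The χ² homogeneity test treats cells as independent; spatial correlation
  inflates its effective sample size. It is used descriptively, as in the
  reference workflow.
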