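# racbrt — spatially corrected boosted-tree distribution models for a rear-edge population

`racbrt` implements a complete species-distribution-modelling (SDM) pipeline
of the kind used to study the European badger (*Meles meles*) at the
southwestern, rear-edge limit of its range: competing ecological hypotheses
are fitted as boosted regression trees (BRT) with a residuals-autocovariate
(RAC) spatial correction, model probabilities are converted to prevalence-
independent favourability, maps are validated against independent presence
records, and fitted models are projected under joint landcover/climate-change
scenarios. A synthetic-landscape generator reproduces the statistical
structure of the field campaign — 987 10-km national grid cells, knight's-move
block pre-selection, 136 surveyed blocks with two 5-km quadrants each
(272 cells, five 500-m transects per cell), ~35% observed prevalence,
deliberately collinear covariates, and spatially structured residuals — so
the entire analysis runs and is tested at desk scale, without the field data.

It is aimed at spatial ecologists who want the full RAC-BRT workflow as a
reusable, tested library rather than a one-off script collection.

## The model

For a binary presence/absence response y over grid cells with covariates x,
each hypothesis H fits a gradient-boosted ensemble of shallow regression
trees on Bernoulli deviance. The workflow is:

1. **Collinearity screen.** Iterative VIF = 1/(1 − R²); the worst variable
   (VIF > 5) is removed per round until all retained VIFs ≤ 5.
2. **Tuning rule.** The largest learning rate *lr* and smallest tree
   complexity *tc* whose cross-validation-selected ensemble still reaches a
   minimum tree count (1000 in the field setting; 300 at desk scale).
3. **Fit and simplify.** The ensemble size minimizes mean held-out deviance
   over 10 stratified folds; the lowest-influence variable is dropped while
   neither CV AUC nor % deviance explained degrades beyond tolerance.
4. **Spatial correction (RAC).** Response-scale residuals r = y − p̂ on the
   sampled cells are summarised per cell as the weighted mean of
   neighbouring sampled cells' residuals (queen contiguity, row-standardized)
   and appended to the model as one extra predictor; the refit is simplified
   again with the RAC protected. Moran's I (randomization variance or
   permutation) verifies that no positive residual autocorrelation remains.
5. **Hypothesis competition.** H1 landcover, H2 anthropogenic disturbance,
   H3 topography/geology, H4 climate; a hybrid H5 is assembled from the
   variables carrying the top half of each hypothesis's non-RAC influence.
   Hypotheses are ranked by cross-validated AUC.
6. **Favourability.** With n₁ presences and n₀ absences,
   F = (P/(1−P)) / (n₁/n₀ + P/(1−P)), so F = 0.5 exactly where P equals the
   prevalence; cells with F ≥ 0.5 favour presence regardless of prevalence.
7. **Scenario projection.** Covariate deltas (default 2040 signal:
   annual precipitation −10%, annual mean temperature +1.5 °C; *Eucalyptus*
   frozen) are applied cell-wise, the grid is re-mapped at the training
   prevalence, and shifts are summarized with a χ² homogeneity test of
   favourable-cell counts across scenarios.

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
landscape (outputs under `scratch/analysis/`):

```bash
python analysis/01_simulate_landscape.py --seed 1
python analysis/02_screen_collinearity.py
python analysis/03_fit_hypotheses.py --seed 1
python analysis/04_map_and_validate.py --seed 1
python analysis/05_project_scenarios.py
```

With seed 1 this prints (abridged):

```
survey: 136 blocks, 272 sampled 5-km cells, 1360 transects = 680.0 km walked
presence: 99 positive cells (prevalence 36.4%); Moran I = 0.476 (one-sided p = 0.0000)
removed: ['Sediment']
H5 candidate variables: ['Herbaceous', 'Shrublands', 'Goat&sheep', 'Unpaved_roads',
                         'Lithosols', 'Ann_Prec', 'Ann_Temp']
hypothesis   cv_auc  cv_auc_se  deviance_explained_pct  best
        H5 0.878885   0.019338               34.724600  True
        H1 0.863983   0.019559               32.045387 False
        H4 0.836993   0.023885               25.370715 False
        H3 0.824557   0.028886               26.213025 False
        H2 0.757262   0.038935               18.116589 False
baseline: 15.30% of cells favourable (F >= 0.5)
mean change: -1.05 percentage points (chi2 = 0.653, df = 3, p = 0.884)
```

Reading this: the survey and prevalence match the emulated design; the VIF
screen finds exactly the built-in collinear lithology share; the hybrid
hypothesis (drawing drivers from landcover, disturbance, geology and
climate) beats every single-facet hypothesis on cross-validated AUC, with
the spatial correction absorbing the residual autocorrelation (final
residual Moran p ≫ 0.05 for every model); and the 2040 scenarios shift the
favourable fraction by an amount the χ² test calls non-significant.

The same pipeline is scriptable (`racbrt.run.run_pipeline`) and exposed as a
CLI (`sdm simulate|screen|fit|map|validate|project|report`).

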