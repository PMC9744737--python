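# csfseverity

Modeling multiple sclerosis (MS) severity from cerebrospinal-fluid (CSF)
aptamer proteomics.

MS severity — the speed at which a patient accumulates disability — cannot be
read off a single clinic visit, and no single CSF protein correlates with it
strongly (the best single markers reach Spearman ρ ≈ 0.3–0.4). This package
implements a complete analysis pipeline that aggregates a ~1305-analyte CSF
panel (log-scale relative fluorescence units, RFU) into validated severity
models, together with a synthetic-cohort generator that plants every effect
the pipeline is supposed to recover, so each stage can be tested against
ground truth.

The pipeline stages:

1. **Confounder adjustment** — a two-tier screen identifies analytes with
   physiological age/sex effects: tier 1 prioritizes analytes flagged in a
   large external serum reference and requires a direction-concordant,
   significant association in healthy-volunteer (HV) CSF plus an
   FDR-significant association in the MS cohort; tier 2 rescues the rest by
   Bonferroni-significant HV associations. Selected analytes are adjusted by
   subtracting the **HV-fitted** regression component
   `x_adj = x − β_age (age − age̅_HV) − β_sex (sex − sex̅_HV)` from every
   sample. Anchoring on HV regressions (rather than regressing age out of
   the MS cohort) preserves disease-related age trends: an analyte whose MS
   slope exceeds its physiological slope keeps the excess after adjustment,
   and analytes whose age association flips sign between cohorts (candidate
   disease processes) are flagged discordant.
2. **Aging clock** — elastic net (α-blend 0.5, leave-one-out CV with the
   1-SE rule) predicting chronological age from the HV panel; delta-age
   (predicted − observed) contrasts between diagnostic groups use rank-sum
   tests with Benjamini–Hochberg (BH) adjustment.
3. **Outcomes** — brain-volume-deficit (BVD) severity as the residual of
   `1 − BPFr` regressed on age over MS baseline samples (BPFr = brain
   parenchymal fraction), and the one-way random-effects intraclass
   correlation ICC = (MSB − MSW)/(MSB + (k₀−1) MSW) quantifying the
   intra-individual stability of longitudinal severity scores.
4. **Univariate screen** — Spearman ρ of every adjusted analyte against each
   severity outcome with BH control, exporting ranked gene lists for
   external enrichment tools.
5. **Ratio-forest severity models** — every analyte and every pairwise
   log-ratio (p + p(p−1)/2 features) enters a backward-elimination loop:
   10 random forests per step, out-of-bag (OOB) mean-squared error recorded,
   node-impurity importances averaged, the bottom 10% of features dropped,
   iterated down to 3 features; the cut is the step minimizing mean OOB
   error. The final model is a single forest with
   `ntree = 40,000` and `mtry = 3√p`.
6. **Evaluation** — Spearman ρ, R² (squared Pearson of observed vs
   predicted) and Lin's concordance correlation coefficient
   CCC = 2s_xy / (s_x² + s_y² + (x̄−ȳ)²) on the training and an independent
   validation cohort; correlation of model predictions with prospectively
   measured progression slopes; cohort-balance tests (Yates-corrected
   chi-square for sex, rank-sum for quantitative variables).
7. **Heterogeneity** — Ward ("ward.D2") hierarchical clustering of z-scored
   model-selected analytes into protein modules (rows) and patient clusters
   (columns).

The forests are fitted by a compact numba-compiled CART regression-forest
engine (`csfseverity._rf`) designed for the small-n / very-wide-feature
regime of the elimination loop; it is cross-checked against scikit-learn's
RandomForestRegressor in the test suite.

## Worked example

```python
from csfseverity import (SimulationConfig, generate_cohort, validation_config,
                         PipelineConfig, RFParams, expand_ratios,
                         iterative_selection, fit_final_model, predict,
                         evaluate_predictions, adjust_panel)
from csfseverity.pipeline import stage_adjust
from csfseverity.forest import features_from_panel

sim = SimulationConfig(seed=42)                      # 24 HV + 129 MS, 60 analytes
panel, meta, reference, truth = generate_cohort(sim)
vpanel, vmeta, _, _ = generate_cohort(validation_config(sim))

cfg = PipelineConfig(rf=RFParams(ntree_selection=200, ntree_final=2000))
_, adjusted, models = stage_adjust(panel, meta, reference, cfg)
vadjusted = adjust_panel(vpanel, vmeta, models)      # frozen HV models

ms, vms = meta.cohort == "MS", vmeta.cohort == "MS"
y = meta.loc[ms, "msdss_baseline"].to_numpy()
feats = expand_ratios(adjusted.loc[ms[ms].index])    # 60 + 1770 = 1830 features
sel = iterative_selection(feats, y, cfg.rf, seed=1)
model = fit_final_model(feats.subset(sel.selected), y, cfg.rf, seed=2)

vfeats = features_from_panel(vadjusted.loc[vms[vms].index], model.feature_ids)
report = evaluate_predictions(vmeta.loc[vms, "msdss_baseline"],
                              predict(model, vfeats), cohort="validation")
print(len(sel.selected), len(model.unique_analytes))
print(round(report["spearman_rho"], 3), round(report["ccc"], 3))
```

Output (seed 42):

```
18 23
0.575 0.438
```

The elimination kept 18 of 1830 features (23 unique analytes, including 5
of the 6 planted severity drivers), and the frozen model transfers to the
unseen validation cohort with held-out Spearman ρ = 0.58 and CCC = 0.44 — the
expected large drop from the near-interpolating training fit, since random
forests overfit the training cohort by construction.

The same flow is available from the shell:

```bash
csfseverity simulate --seed 42 --outdir data
csfseverity run-all --config config.yaml --outdir results \
    --longitudinal data/longitudinal.tsv
```

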