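# Methods

## Data model

All analyte values are carried internally as natural-log RFU; the readers
apply `log` on load when the input is raw RFU (strictly positive values
required, missing values rejected rather than imputed — aptamer panels are
normally complete). Sex is coded M/F and mapped to an indicator with M as
the reference level (recorded in the run manifest). A single master seed
drives the pipeline; every stochastic stage derives a 31-bit child seed via
`SeedSequence(master, spawn_key=(stage_index, repeat))`, so stages are
reproducible independently of execution order.

## Confounder adjustment

Per-analyte associations are ordinary least squares of log RFU on age and
the sex indicator, fitted separately in the HV and MS cohorts; two-sided
coefficient p-values come from the t reference with n−3 degrees of freedom.

Tier 1 operates on the analytes flagged significant in the external serum
reference table: an analyte is selected when (A) its HV-CSF association has
p < 0.05 with the same sign as the serum coefficient, and (B) its MS-cohort
association is significant after BH adjustment within the candidate list,
per covariate. The BH choice for criterion B is a design decision — FDR is
the multiplicity method used everywhere else in the pipeline — and is
deliberately confined to the reference-prioritized family so the small HV
cohort's p-values are spent on a short, pre-justified list. Each selected
analyte is labelled concordant/discordant by comparing the MS and HV
coefficient signs; discordance flags a candidate disease-related process
but does not block adjustment. Tier 2 rescues analytes absent from the
reference whose HV association survives Bonferroni across that remaining
family (per covariate).

Adjustment subtracts the HV-estimated component for the selected covariates
and re-centers at the HV anchor (mean age, sex-indicator mean), keeping
values on an interpretable log-RFU scale. Analytes selected for both age
and sex are adjusted from one joint HV regression to avoid double-counting
shared variance. HV samples are adjusted with the same models as MS
samples. Consequences asserted in tests: refitting the HV regressions on
adjusted data gives zero coefficients (to numerical precision at zero
noise); re-adjustment is the identity; unselected analytes pass through
bit-identical; and a planted MS-only excess age slope survives adjustment.

## Aging clock

Elastic net (mixing 0.5) on HV-standardized analytes predicting
chronological age. With ~24 HV samples, k-fold CV is unstable, so the
penalty is chosen by leave-one-out CV on a 30-point geometric grid from the
critical penalty (all coefficients zero) down by 10⁻⁴, with the
one-standard-error rule (largest penalty within one SE of the minimum LOO
MSE) guarding against overfit. Standardization parameters and the penalty
are frozen from the HV fit; predictions elsewhere are pure functions of the
frozen model. Delta-age contrasts between diagnostic groups use two-sided
rank-sum tests (the groups are independent) with BH adjustment; groups with
fewer than two members are excluded with a warning.

## Outcomes

BVD severity is the residual of `1 − BPFr` on age, fitted by OLS over MS
baseline samples only; positive residuals mean more tissue loss than age
peers. The fitted slope, t-statistic and p-value are retained. The ICC is
the one-way random-effects estimator from the ANOVA decomposition with the
standard unbalanced-design group size k₀ = (N − Σk_i²/N)/(n−1); it may be
negative when the between-subject variance estimate is non-positive, and is
NaN (with a warning) when both mean squares vanish. The one-way form is
deliberate: visits are exchangeable repeats, not a crossed rater factor.

## Univariate screen

Spearman ρ is computed as Pearson on average ranks with the t-reference
p-value (ties get average ranks); BH adjustment is applied within each
outcome family. Enrichment exports are plain text, one symbol per line:
ordered by decreasing |ρ| and by increasing p, plus significant
positive/negative sublists at q < 0.05. Enrichment statistics themselves
are out of scope (external services).

## Ratio-forest severity models

Feature space: every analyte plus one log-difference per unordered analyte
pair, oriented with the lexicographically smaller ID as numerator —
p + p(p−1)/2 features (1305 analytes → 852,165).

Selection: at each step, 10 regression forests (default 200 trees each)
with distinct child seeds are fitted on the surviving features with
mtry = 3√p (rounded half-up, clipped to [1, p]); the OOB MSE mean/SD and
the across-forest average of node-impurity importances are recorded; the
`max(1, floor(0.1 p))` least important features are dropped (ties broken
lexicographically by feature ID for determinism) until 3 remain. The cut
point is the step minimizing the mean OOB error — the explicit,
reproducible form of eliminating until the error has minimized. A
one-standard-error alternative (smallest feature count within one SD of the
minimum) is available by configuration; it yields sparser models but, on
planted-truth cohorts, measurably worse driver recovery and held-out
correlation, because at these effect sizes the OOB curve is shallow and the
1-SE band reaches deep into underfitted models.
The final model is a single forest with 40,000 trees by default; the
scaled-down study conditions used throughout the tests are 60 analytes
(1830 features), selection forests of 200 trees and final forests of 2000
trees, which keep a full 10-seed end-to-end recovery experiment within a
desk-scale compute budget.

The forest engine (`csfseverity._rf`) is a numba-compiled CART regression
forest written for this regime (n ≈ 100–250 samples, p up to ~10⁶
features): presorted feature orders are shared across the 10 forests of a
step, in-bag samples are partitioned in place with node statistics carried
on the traversal stack, and small nodes switch from presorted scans to
direct insertion sorts. Minimum node size defaults to 5 (the regression
default of the ranger package). Importance is the total within-node
variance reduction per feature, divided by the bootstrap weight total and
averaged over trees — the usual impurity importance. Split thresholds are
placed at the largest left-child value (rule `x ≤ a` at an observed value)
rather than midpoints, so tree structure *and* routing depend only on the
order of feature values: exponentiating a log-ratio feature (or any
strictly monotone transform) leaves predictions bit-identical under the
same seed. The engine is validated against scikit-learn's
RandomForestRegressor (OOB error, impurity importances, predictions) in the
test suite; scikit-learn is not used for the pipeline forests because its
per-tree overhead dominates at these tree counts.

## Evaluation

R² is the squared Pearson correlation of observed vs predicted (symmetric,
matching the simple-regression R² of either orientation). Lin's CCC uses
population (divide-by-n) moments — Lin's original estimator — with a
sample-moment variant behind a flag; |CCC| ≤ |r| always, with equality only
under exact location/scale agreement. Cohort balance uses the
Yates-corrected 2×2 chi-square for sex (the correction is what reproduces
the conventional reported p-value for cohorts of this size; configurable)
and two-sided rank-sum tests for quantitative variables. Progression-slope
validation correlates each supplied predictor column with the slope column
(Spearman, BH across the predictor family); slope construction itself is an
upstream input.

## Heterogeneity

Model-selected analytes (union over the severity models) are z-scored per
analyte over the MS cohort (zero-variance analytes dropped with a warning)
and clustered with Ward minimum-variance linkage on Euclidean distances in
the squared-update convention ("ward.D2", scipy's `linkage(method="ward")`).
Default cuts are 7 patient clusters and 4 protein modules, both
configurable. Clustering is deterministic; equal-cost merges follow scipy's
lowest-index ordering.

## Synthetic cohorts

The generator emulates the study structure: 24 HV plus 129 MS (37 RRMS /
31 SPMS / 61 PPMS) for training-like cohorts and 98 MS (33/24/41) for
validation-like cohorts; HV ages uniform on 20–70, MS ages subtype-shifted
normals (RRMS ≈ 40.9 ± 11.1, SPMS ≈ 52.3 ± 9.0, PPMS ≈ 54.8 ± 7.9 years),
reproducing the age confounding the adjustment must handle. Analyte
categories are disjoint: age-concordant (HV slope 0.02 log-RFU/yr, one
carrying an extra MS-only 0.02 slope), age-discordant (−0.02 in HV, +0.02
in MS), reference-absent age analytes with slope 0.04 (strong enough to
survive Bonferroni at n=24), sex-shifted (0.5 log-RFU), reference-only
nulls (flagged in serum, silent in CSF — the false-positive probe for
tier 1), four severity modules, and noise. Residual SD 0.3 makes the
planted effects ≥ 3× their standard errors at n_HV = 24.

Module members load (loading 1.0, member noise SD 0.7) on a shared
per-sample module factor; the latent severity is the weighted sum of module
analyte values (module weights +1, −1, +0.8, −0.8 — two risk and two
protective modules) plus noise. The severity noise SD (4.0) is calibrated
in closed form so the strongest single-marker population Spearman ρ is
≈ 0.39, mimicking the weak single-marker regime the models must overcome;
this calibration was fixed before any pipeline run. Brain volume deficit is
linear in age (slope 0.002/yr) plus a subject deficit (SD 0.02) correlated
0.5 with standardized severity; longitudinal severity uses subject random
intercepts (variance 9) and visit noise (variance 1), i.e. population
ICC 0.9.

Analyte-level parameters (per-analyte baselines) are drawn from a dedicated
`analyte_seed`, which `validation_config` inherits from the training
configuration: training and validation cohorts of one study come from the
same measurement model with fresh subjects, as in a real paired-cohort
design. Two cohorts with unrelated analyte seeds simulate different assay
runs instead.

What the generator does **not** emulate: assay batch/plate effects,
non-linear age trends, treatment effects, correlated noise across
non-module analytes, and missingness. Passing tests therefore demonstrate
estimator and pipeline correctness under the planted model, not robustness
to those real-data artifacts.

## Numerical and degenerate-input conventions

Constant covariates, constant outcomes, out-of-range BPFr and p-values,
duplicate IDs, and missing analytes referenced by a model are all fatal
with the offending name in the message. Constant analytes in the screen
and constant inputs to CCC yield NaN with a warning. The BH and Bonferroni
adjusters are exact step-up / min(1, m·p) implementations, tested against
statsmodels and closed forms to 1e-12.

## Known limitations

- The elimination loop's OOB-based cut is a heuristic; with very weak
  signal the 1-SE rule can cut aggressively (down to the 3-feature floor).
- The clock's LOO-CV grid is geometric with a fixed 10⁻⁴ span; extremely
  low-noise panels could warrant a deeper grid.
- Exact elastic-net prediction invariance under feature duplication holds
  only in the pure-lasso limit; with mixing 0.5 the duplicated feature
  slightly changes the effective ridge penalty (tests assert near-, not
  exact, invariance).
- `expand_ratios` materializes the full feature matrix; at 1305 analytes
  this is ~0.9 GB at n ≈ 130 samples. The elimination loop works on the
  materialized matrix, so full-platform runs need memory of that order.
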