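# Methods

## Model class and segmentation

Activity tables are timepoints × ROIs in percent signal change: each raw
column is expressed relative to its full-series mean,
`100·(x − mean)/mean`, so converted columns are exactly zero-mean.  The
converter refuses columns with zero mean (including already-converted
data) instead of silently rescaling.

Each target ROI is modeled as an intercept-free weighted sum of the other
ROIs.  The series is partitioned into training = `[0, ⌊T/2⌋)`,
validation = `[⌊T/2⌋, ⌊3T/4⌋)` and test = `[⌊3T/4⌋, T)` (0-based,
half-open).  The floor rule for odd lengths is a package choice (for the
canonical 661-sample series it gives 330/165/166); it is recorded in the
run manifest.

Before every fit, columns are centered by their training-segment means and
predictors scaled to unit training-segment standard deviation; returned
weights are rescaled to the percent-signal-change scale and the offsets
stored on the model so validation/test predictions apply them too.
Standardization makes the elimination criterion ("smallest weight")
scale-invariant — the model class itself is unchanged.  Averages
(prediction-error denominator, tSNR variance) use the population
convention (divide by n).

## Fitting methods

* **OLS** — `numpy.linalg.lstsq`; minimum-norm solution with a warning when
  predictors outnumber training rows.
* **Lasso / elastic net** — cyclic coordinate descent (scikit-learn path
  solvers; deterministic).  The penalty is
  `⟨(y−x)²⟩ + c·[mix·|ω|₁ + (1−mix)·½‖ω‖₂²]`, which maps exactly onto the
  solver's `alpha = c/2`, `l1_ratio = mix`.  The magnitude grid is 200
  (Lasso) or 50-per-mix (elastic net, mixes 0.01/0.05/0.1/0.5/1, 250
  candidates) log-spaced values from `c_max` (smallest all-zero penalty)
  down to `c_max·10⁻⁴`.  The candidate with the smallest validation error
  wins; ties prefer fewer nonzero predictors, then larger penalty
  (parsimony is the point of the method).  Zero-weight predictors are
  dropped from the returned model; if even the best candidate is empty the
  fit is refused as uninformative.
* **Single best predictor** — OLS on the one ROI with the largest absolute
  training-segment Pearson correlation with the target; exact ties break
  to the lowest roi_id.

## Recursive feature elimination

From the full predictor set, repeat: fit OLS, record the validation error,
remove the predictor with the smallest absolute *standardized* weight
(ties to the lowest roi_id), until one predictor remains — one predictor
per iteration.  Two final-model rules:

* **RFE (primary)** — keep the predictor eliminated after step *t* iff
  `v_t < min_{s>t} v_s`, i.e. its removal strictly raised the smallest
  validation error among all later iterations; equality counts as "did not
  raise" and the predictor is dropped.  The final survivor is always kept
  (the rule is defined only for eliminated predictors, and an empty model
  would be meaningless).  The kept set is refit by OLS on the training
  segment.
* **RFE2** — the stored model at the minimum of the validation curve, ties
  to the latest step (fewest predictors), without refitting.

Every kept elimination occurs at or after the global minimum of the curve,
so the RFE set is provably nested in the RFE2 set.

## Error, nulls and the gain

Prediction error is `100·⟨(y−x)²⟩ / ⟨(x−x̄)²⟩` with `x̄` the observed mean
of the *same* segment; predicting that mean scores exactly 100%.  Null
models for a fitted model's error reorder its weights uniformly across its
own predictors (500 permutations by default); p-values use the add-one
estimator `(1 + #{null ≤ observed})/(n+1)`, bounded away from zero.

The multiregional prediction gain is `error_single − error_multi` on the
test segment.  Its significance is a *paired* t-test over per-timepoint
squared errors — the two error series share timepoints, so pairing is the
natural layout; identical models yield gain 0 with p = 1 by convention.
tSNR is `⟨|x|⟩ / Var(x)`.

## Group analysis

Normalized weights are `100·|ω_j| / Σ|ω_k|` (percent of the total absolute
weight onto the target).  Bootstrap means use 500 resamples with a
percentile 95% interval.

**Key predictors.** For each candidate predictor of a target, per-subject
normalized weights (0 when absent from that subject's model) are compared
against null models that reassign each subject's weight multiset uniformly
across the full candidate pool of R−1 predictor slots.  Averaged over all
reassignments the null normalized weight per slot is exactly
`100/(R−1)`, which is used in closed form — deterministic, and exactly
invariant to subject ordering.  The comparison is a paired t-test across
subjects; p-values are Bonferroni-multiplied by the number of comparisons
and capped at 1, with key status requiring both corrected p < 0.05 and a
mean observed weight above the null mean.  A narrower null that reorders
weights only *within* each subject's fitted model was considered and
rejected as the test statistic: when a model's weights are close to equal
(exactly the situation for a well-recovered balanced ground truth, and
common for strongly pruned models), within-model reordering leaves the
normalized weights essentially unchanged, so observed and null means
coincide and no predictor could ever be flagged.  The pool-wide
reassignment preserves how much weight a model carries while randomizing
which regions receive it — the property the key-predictor question
actually tests.  The within-model reordering null is still used, as
stated, for prediction-error null models.

Integration-network edges (target → key predictor, for targets whose
bootstrap-mean gain exceeds the integrator threshold, default 13%) are
classified by Euclidean centroid distance with a 50 mm short/long
threshold, homotopy (same label, opposite hemisphere) and
inter-hemisphericity.  Partial correlations of per-subject measures with
age control for head motion by residualizing both on motion (with
intercept) and correlating residuals, with n−3 degrees of freedom.

## Synthetic ground truth

`make_scenario` defaults define the study conditions: 32 ROIs, 5 true
predictors per integrator at weight 0.2, six integrator ROIs, one coupled
pair (source driver and partner, correlation 0.85), one low-tSNR driver
rendered at 2.5× amplitude, and white observation noise sized so the
irreducible model error is ~20% of integrator variance
(`noise_sd = √(k·w²·f/(1−f)) ≈ 0.224`).  Drivers are AR(1) series
(coefficient 0.5, empirically standardized to unit variance, 100-sample
burn-in), emulating BOLD autocorrelation at a ~2 s sampling interval.
Series default to T = 660 samples.  Parcels are fabricated
deterministically with homotopic label pairs and lattice centroids
spanning both sides of the 50 mm threshold.  The structure seed fixes the
sparsity pattern; the noise seed varies the activity, so one scenario can
generate a multi-subject group.

What the generator does *not* emulate: hemodynamic convolution, recurrent
(feedback) coupling, physiological noise, motion artifacts, or spatially
correlated noise between neighboring parcels.  Passing tests therefore
demonstrate correctness of the algorithms under the model-class
assumptions, not robustness to real-scanner confounds.

## Problem sizes and numerics

The test suite and the acceptance script run the full-size scenario
(R = 32, T = 660) over 10–20 seeds per check — a per-target elimination
trace is 31 least-squares fits, and a Lasso path 200 coordinate-descent
solves, so a complete sweep takes seconds on one CPU; the defaults were
chosen so a whole-subject analysis (all ROIs, all methods) stays in the
minutes range.  Coordinate descent converges at tolerance 1e-9 (max
100,000 iterations), which keeps every path candidate within 1e-6 of the
exact L1 subgradient conditions.  Validation-error ties, elimination ties
and correlation ties all break deterministically (documented above), so
every fit is reproducible bit-for-bit given the input and seeds.

## Known limitations

* The linear, instantaneous, intercept-free model cannot represent lagged
  or nonlinear coupling; gains are conditional on this model class.
* The suffix-minimum rule is one consistent formalization of "elimination
  raised the smallest later validation error"; it keys on the error of the
  model *before* each elimination.
* With a single fixed train/validation/test split (no cross-validation, by
  design), selection is sensitive to segment-specific noise; the
  validation curve's fluctuations are exactly what the primary rule prunes
  against.
* Group key-predictor inference assumes subjects share a parcellation and
  treats absent predictors as zero weight, so it reflects selection
  frequency as well as magnitude.
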