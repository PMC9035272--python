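# Methods

## Model

`twostay` predicts a non-negative, heavily right-skewed continuous outcome —
in-hospital length of stay (LOS) in days — as a two-stage hurdle:

1. **Stage 1 (gate).** Every training row is labelled prolonged iff
   y ≥ τ_c (default 7 days; the boundary is included in the prolonged class,
   consistent with a "≥ 7 days" group definition — for continuous stays the
   boundary has essentially measure zero). A binary classifier is fit on all
   rows. Its decision cutoff c\* on the prolonged-class probability is tuned
   on *out-of-fold* scores from a stratified fivefold split: among all
   distinct observed scores (plus the "classify nothing prolonged" point just
   above the maximum, when that is still a probability), choose the cutoff
   that maximizes prolonged-class sensitivity subject to short-class
   sensitivity ≥ the target (default 0.99). Because prolonged sensitivity is
   non-increasing and short sensitivity non-decreasing in the cutoff, this is
   the smallest admissible cutoff, and ties resolve toward smaller cutoffs.
   If no cutoff is admissible (possible only when scores reach 1.0), an
   infeasibility error reports the best attainable value. An alternative mode
   constrains prolonged-class sensitivity instead and maximizes short-class
   sensitivity; the default parameterization by short-class sensitivity is
   the operating point the two-stage design is built around.
2. **Stage 2 (regressor).** A regressor is fit only on rows with y ≤ τ_r
   (default 35 days) — the extreme tail is excluded entirely, not truncated —
   with the target transformed (natural log by default) and predictions
   back-transformed to days. τ_r ≥ τ_c by construction: the regressor must
   see 7–35-day stays to be able to predict beyond the gate threshold.
3. **Prediction.** A new sample with probability ≥ c\* is flagged prolonged
   and receives no number; otherwise it receives the stage-2 estimate,
   clipped at 0 (identity-transform linear regressors can otherwise produce
   small negative day values).

**Assumptions.** The features carry signal about *whether* a stay will be
prolonged but little about *how long* a prolonged stay lasts; short-stay
durations are predictable at roughly day resolution; the short/prolonged mix
is stable between training and deployment. When the first assumption fails
in the other direction (durations of long stays are predictable), a
single-stage model may be preferable.

## Losses and evaluation statistics

MSE, MAE and MRE are means of per-sample terms on the day scale (test
outcomes are never transformed). MRE requires strictly positive truths and
refuses zeros by index. The customized loss (see README for the formula)
scores the whole gated pipeline: gated samples enter with the imputed
prediction ŷ = τ_c, the only convention under which the three-branch rule is
computable for samples that carry a flag instead of a number; a correct gate
then costs 0 and a wrong gate |τ_c − y|. It is pointwise dominated by MAE
and converges to MAE as τ_c → ∞.

Stratified reports bin by the *true* outcome into half-open intervals
([0,2), [2,4), [4,7), [7,∞) by default), so each sample lands in exactly one
bin; an empty bin reports an absent value, never 0. Because all losses are
means of per-sample terms, the overall loss equals the count-weighted mean
of per-bin losses.

Calibration slope is defined here as the OLS slope of **observed on
predicted** outcome (cov(y, ŷ)/var(ŷ)); a slope below 1 means large
outcomes are under-predicted. It is computed over samples with numeric
predictions only and is undefined for constant predictions. Short-class
sensitivity counts a gated sample as predicted-short iff it is not flagged;
for numeric predictions the rule is ŷ < τ_c. PR/ROC summaries use the
standard step-wise average precision Σ(R_k − R_{k−1})·P_k and the rank-based
AUC with ties counted half (delegated to scikit-learn; the test suite
cross-checks both against exhaustive enumeration). Confidence intervals are
two-sided percentile bootstrap over test-set rows only — models are not
refit — with undefined resamples redrawn and counted; percentile was chosen
over BCa as the simplest method matching the design.

## Base learners

Three families behind one contract: L1-penalized linear/logistic regression,
random forest, and a multilayer perceptron. Preprocessing is median
imputation with missing-indicator columns, one-hot encoding with an explicit
reference level, and standardized numerics for the scale-sensitive families
(penalized linear, MLP). Hyperparameters are selected by internal fivefold
CV over small default grids (penalty strength for the linear models, tree
depth for the forest, weight decay for the MLP), scored by negative MAE for
regression and AUC for classification; grids are exposed in configuration
and a single-candidate grid skips the search. The cutoff-tuning out-of-fold
scores are produced with the *selected* hyperparameters refit per fold (one
CV pass), not a fully nested re-search; the fold partition uses a seed
derived from, but distinct from, the hyperparameter-CV seed. All fits are
reproducible from the spec seed; forest and linear predictions are
bit-identical across reruns, the MLP is deterministic given its seed.

A structural property used throughout: tree-ensemble predictions are
averages of training targets and can never leave the training-target range.
A forest trained on outcomes truncated at 7 days therefore cannot predict
past 7, and its prolonged-class sensitivity under the ŷ ≥ 7 rule is 0 —
truncation trades the tail's leverage for complete blindness to it. The same
mechanism makes the largest stage-2 prediction grow with τ_r.

## Synthetic cohort generator

The generator emulates the data regime the method targets, with known
ground truth and no real patient data: covariates in the usual pre-admission
families (age ~ clipped N(58, 19²); sex ~ Bernoulli(0.52 female); race in
four categories; smoking; BMI category; Poisson hospital and emergency
encounter counts and an overdispersed negative-binomial ambulatory count).
Prolonged status is Bernoulli with a logistic linear predictor in the
covariates; short stays are log-normal (sd-log 0.60) truncated to
[0.25, 7) days with mild covariate shifts of the log-mean; prolonged stays
are 7 days plus a generalized-Pareto draw (shape 0.35, scale 6), giving
admissible maxima in the hundreds of days. Tail durations are deliberately
independent of the covariates — beyond the short/prolonged distinction, the
features carry no information about how long a prolonged stay lasts, which
is exactly the regime in which the hurdle design helps.

Two quantities are calibrated per draw rather than hard-coded: the risk
intercept is solved (Brent's method) so the mean risk on the drawn
covariates equals the configured prevalence (default 0.099), and the
short-stay base log-mean is solved so the truncated mixture median over the
rows that realize short stays equals the configured 2.3 days. Both targets
are therefore met within pure sampling error at any n. Default risk-effect
magnitudes were sized during generator design so the latent (Bayes-optimal)
score discriminates at AUC ≈ 0.8 — a realistic ceiling for pre-admission
features — with smoking and utilization history dominating and age nearly
flat. A `separable_mode` makes prolonged status a deterministic function of
the smoking feature for pipeline tests that need a perfect gate. The latent
prolonged indicator, risk score and short-stay log-mean are retained for
recovery tests; the fitted stage-1 AUC can approach but not exceed the
latent score's AUC on an independent draw.

**What the generator does not emulate:** real EHR feature richness
(procedure codes, medications, comorbidities), informative missingness,
temporal drift (e.g. pandemic-era shifts in discharge practice), site
effects, or measurement error in the outcome. Passing tests demonstrate the
machinery is correct and the design behaves as intended *under the stated
generative assumptions*; they do not certify performance on any real cohort.

## Problem sizes and test design

The suite exercises the full pipeline at sizes chosen to keep a laptop run
short while leaving no property under-powered: loss and statistic oracles
use exhaustive enumeration at n ≤ 12 and 10³ random pairs; generator
calibration checks use n = 10⁴ with 3-sampling-SD bands (binomial for the
prevalence, a plug-in density estimate for the median's SD); the
two-stage-versus-one-stage comparison runs 20 independent replicates at
n = 1500 with 60-tree forests and requires a ≥ 15/20 majority; the
acceptance script uses n = 6000 with 150-tree forests and a two-point depth
grid. Forest sizes and grids are configuration, not constants — production
use should scale them up.

## Numerical conventions and edge cases

* Empty prediction pairs, length mismatches, negative or non-finite truths:
  rejected at construction.
* Train/test split: seeded permutation, train size = round(fraction·n),
  clamped to leave both sides non-empty; sizes are within 1 of exact.
* CV comparison harness sorts rows by index before fold assignment, so
  results are invariant to row order; per-cell failures are recorded and the
  remaining grid still runs. CV losses are computed on pooled out-of-fold
  predictions (the mean-of-fold-losses alternative is not currently exposed).
* Bootstrap redraw cap: 100 consecutive undefined resamples abort with an
  error rather than looping.
* Manifests record config hash, seed and package version but no timestamps,
  so same-seed CLI reruns are byte-identical.
* Log transform with zeros in the outcome raises by index; a positive
  `log_offset` is the supported escape hatch. Truncation is not invertible
  and says so when asked.

## Known limitations

* The gated model's MAE mixes numeric errors with the τ_c-imputation for
  flagged samples; comparisons of plain MAE across gated and ungated models
  should be read with that convention in mind (the customized loss is the
  intended comparison metric).
* Cutoff tuning assumes the out-of-fold score distribution transfers to
  deployment; under covariate shift the achieved short-class sensitivity
  will drift from the target.
* The MLP family is the weakest fit at the cohort sizes used in the tests
  (consistent with its data appetite) and is included for completeness of
  the comparison grid rather than as a recommended default.
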