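# Methods

This note records the modeling assumptions, default parameters, and open
design choices behind the package, in the order data flows through it.

## Synthetic generating model

The generator stands in for heterogeneous clinical datasets (diabetes,
cardiology, movement-disorder style tables) whose originals are external.
It is deliberately a *known-truth* model rather than a realistic one:

- Labels are Bernoulli with prior `class_prior` (default 0.5).
- Numeric features are class-conditionally Gaussian with means `±Δμ/2` and
  unit within-class standard deviation. `mean_separation` (Δμ) is therefore
  expressed in σ units. Default Δμ = 1 with 4 numeric features, which puts
  the closed-form Bayes accuracy at Φ(√4·1/2) = Φ(1) ≈ 0.8413 — a ceiling
  that end-to-end tests can measure against.
- Categorical features have a 3-level vocabulary; class 0 draws uniformly,
  class 1 moves probability mass `categorical_skew` (default 0.3) onto the
  first level.
- Time-series channels are stationary AR(1), `x_t = μ_y + φ(x_{t−1} − μ_y) + ε_t`,
  around the class level `μ_y = ±Δμ/2`, with φ = `ar_coefficient`
  (default 0.5, length 20) and stationary initial draws, so the lag-1
  autocorrelation equals φ.
- Corruption is a separate step: cells go missing completely at random
  (MCAR), and outlier cells are displaced ≥ 8 within-class standard
  deviations from their class mean, so both the |Z| > 3 rule and the Tukey
  fences provably flag them. Labels and schema are never touched.

What this emulates: class-conditional signal spread over several weak
features, mixed measurement types, missingness, and gross recording errors.
What it does not: realistic clinical marginals (skewed lab values, zero
inflation), informative missingness, label noise, feature interactions, or
imaging content. Tests passing on this bed demonstrate that the pipeline
recovers a known signal under controlled nuisance conditions — not that it
matches any particular clinical dataset's difficulty.

## Preprocessing

The published pipeline lists splitting after the fitted transforms; fitting
anything on held-out rows would leak, so here the stratified split indices
are drawn first (from labels only) and every fitted quantity — imputation
statistics, scaler parameters, PCA loadings, selected features — is estimated
on the training part and applied frozen elsewhere. Specific conventions:

- Imputation: numeric → training median; categorical → training mode with
  ties broken toward the lexicographically smallest level; time-series rows →
  mean of the k = 5 nearest complete training rows (Euclidean distance on
  co-observed numeric cells). Imputation is idempotent.
- Outlier flags: Z-score uses the population σ (ddof 0) and a strict
  inequality |Z| > 3 (threshold configurable); the IQR rule uses type-7
  (linearly interpolated) quartiles with fences Q1 − 1.5·IQR, Q3 + 1.5·IQR.
  The pipeline default removes flagged *training* rows only; validation and
  test rows are never dropped, keeping evaluation honest.
- Scaling: design matrices are min–max scaled to [0,1] because the
  Bernoulli-visible energy model treats inputs as activation probabilities;
  values outside the training range extrapolate in the standalone function
  and are clipped to [0,1] only when feeding the probabilistic models.
- Encoding: one-hot keeps every level (rows sum to 1, no reference drop);
  ordinal features map to ranks scaled into [0,1].
- PCA keeps components covering ≥ 95% variance when a count is not given;
  explained variances follow the ddof-1 convention. The RFE scorer is a
  closed-form ridge regression (α = 1) on ±1 targets over standardized
  features, dropping the smallest |coefficient| each round — deterministic.
- Split rounding: per-class floor of the 0.70/0.15/0.15 targets, leftover
  rows assigned train-first, then validation, then test.

## Energy model and training

Visible units are Bernoulli; continuous features enter as probabilities in
[0,1]. No Gaussian-visible variant is provided. Contrastive divergence
defaults to k = 1; positive statistics use data-clamped hidden
*probabilities* (the standard variance reduction), the negative chain samples
both layers and finishes with hidden probabilities. Between stacked layers,
activations propagate as mean-field probabilities.

RBM weights initialize at scale 1/√(fan-in). This is larger than the common
0.01 convention on purpose: with a handful of weakly-dependent features the
maximum-likelihood weights are small, CD shrinks W toward zero, and an
unrolled network started from near-zero weights backpropagates vanishing
gradients. Starting at 1/√(fan-in) leaves pretraining free to shrink what it
doesn't need while keeping fine-tuning well-conditioned.

Fine-tuning unrolls the stack (logistic activations, weights and hidden
biases from each RBM), adds a 2-class softmax head, and trains everything —
all layers update — on cross-entropy + λ‖W‖² (λ default 1e-4, biases not
penalized). Dropout 0.5 (inverted scaling) applies to the head input only,
during training only. The default optimizer is plain mini-batch gradient
descent at η = 0.001 with a ×0.1 step decay every 10 epochs and
patience-5 early stopping on validation loss; Adam is available by config
and is what the end-to-end experiments use (η = 0.01), since on desk-scale
problems the decayed plain-SGD schedule freezes before the unrolled network
escapes its initial plateau. Cross-entropy clips probabilities at 1e-12;
softmax subtracts the row max.

Base-learner architectures are not prescribed anywhere, so the defaults are
chosen to train in seconds on desk-scale data: dense = [32, 16] rectifier
layers; attention = model dimension 16, one head, scaled dot-product
self-attention over time steps, mean pooling. Tabular inputs reach the
attention learner as a sequence of scalar tokens (one per feature) with a
learned per-position value embedding and positional bias — without position
information the attention stack is permutation-invariant over features and
cannot tell them apart. All learners share one contract: `predict_proba`
returns an (n, 2) row-stochastic matrix, deterministically (dropout off).

## Ensemble

The literature this design follows states *two* update rules for the
ensemble weights — a softmax of negative losses, and gradient descent on an
L2-regularized total loss — which are irreconcilable as written. Resolution
here: the softmax rule is authoritative for the ensemble weights `w_m`
(computed from validation cross-entropy, never training loss); gradient
descent and the L2 regularizer govern the base-learner *parameters*. The
recalibration loop re-derives losses and weights while aggregated validation
accuracy sits below `performance_threshold` (default 0, so the loop runs
once) up to `max_recalibration` = 10; every (losses, weights) pair is
recorded. Hard labels break argmax ties toward class 0.

## Metrics

Zero-denominator rates return NaN as an explicit undefined marker rather
than a silent 0; MCC alone returns 0 on a degenerate matrix, the field's
convention. SSIM uses the standard constants K1 = 0.01, K2 = 0.03, an 11×11
Gaussian window with σ = 1.5, and the data's own dynamic range (delegated to
scikit-image). "Proportion of correct patches" has no standard operational
definition; here it is the fraction of non-overlapping 16×16 tiles (masks
zero-padded to tile boundaries) whose pixelwise agreement is ≥ 0.9 — both
knobs are explicit parameters and the choice is flagged as package-specific.
Display rounding is half-up at the printed precision (whole percent for the
rate family, 4 decimals for the error/MCC family).

Known inconsistencies in the published reference numbers: the Dataset-1
counts (TP 18000, FP 2000, FN 2200, TN 24800) yield precision 90%,
FPR 0.0746 and FDR 0.1000, while the accompanying text/tables print 84%,
0.0700 and 0.0628; similarly MCC is quoted both as 0.8232 and 0.8176 for
Dataset 1 and as 0.8932 and 0.8846 for Dataset 4, and the Dataset-4
precision/specificity/recall claims do not match their own counts. The
package reproduces only the internally consistent quantities (accuracy,
recall, specificity, FNR, MCC from the printed counts); the rest are
documented here and not asserted anywhere.

## Problem sizes and numerical checks

Exact enumeration is guarded at ≤ 20 total units. The oracle experiments use
3-visible × 2-hidden models (normalization to 1e-12; stationary CD moments
from 4000 chains of 300 Gibbs steps, agreeing with enumeration within ~3
Monte-Carlo standard errors ≈ 0.04) and an 8-pattern, 4-visible toy set for
the likelihood-ascent check. Gradient checks use central differences with
step 1e-6 on 3-sample batches; rectifier pre-activations are biased away
from the kink, where the loss is not differentiable and the check is
ill-posed. The end-to-end recovery experiment fits 3000-sample datasets
(70/15/15) and scores 100,000 fresh held-out samples per replicate — large
enough that the Monte-Carlo standard error on accuracy (~0.0012) is
negligible against the [0.80, 0.85] acceptance band around the Φ(1) ceiling.

## Limitations

Binary classification only; no Gaussian-visible RBMs, persistent CD, or
convolutional/image models (only segmentation *metrics* are provided, since
the reference framework defines no segmentation algorithm); no calibration
or ROC analysis; the ensemble is fixed at three learners. The synthetic bed's
caveats above bound what any green test implies about real clinical data.
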