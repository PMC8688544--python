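# Methods

## Model

The classifier treats K-class discrimination of expression profiles as t
= K coupled binary tasks sharing one predictor matrix X ∈ ℝ^{n×p}
(samples × genes, continuous variance-stabilized scale).  Task *i* owns
a coefficient column W_i ∈ ℝ^p and intercept C_i, with responses Y_i ∈
{+1, −1}^n marking membership in class *i*.  The fitted objective is the
sum of per-task mean logistic losses plus two penalties on the p×t
matrix W:

- λ₁‖W‖₂,₁ — the sum of Euclidean norms of the gene rows.  Its proximal
  map is row-wise group soft-thresholding, so rows whose norm falls
  below the threshold become *exactly* zero: a gene is discarded from
  every task simultaneously (joint feature selection).
- λ₂‖W‖²_F — a ridge term that stabilizes correlated predictors.

Intercepts are not penalized: the penalties express beliefs about gene
effects, not about class prevalences, and the unpenalized intercept of
an otherwise-empty model converges to the log-odds of task prevalence,
which is the natural null.  At t = 1 the model reduces to ordinary
penalized logistic regression, which the tests exploit as an oracle.

Per-task losses are averaged over all n samples (every task sees the
full shared matrix) and then summed over tasks, so λ values are
comparable across datasets of different size.

Prediction applies σ(X W_i + C_i) per task.  Rows of the probability
matrix are *not* normalized across tasks — each is an independent
one-vs-rest probability.  A sample is assigned the argmax class; ties
break to the lowest task index, and a sample whose best probability is
≤ 0.5 is still assigned but flagged low-confidence, so downstream
confusion-matrix accounting never drops samples.

## Optimizer

The objective is convex, smooth-plus-L2,1.  It is minimized by FISTA
(accelerated proximal gradient) with:

- backtracking line search on the Lipschitz estimate (step halved until
  the quadratic upper bound holds; initial step 1.0);
- the λ₂ term kept in the smooth part (gradient 2λ₂W), so the prox stays
  the closed-form row shrinkage;
- a monotone safeguard with adaptive restart: if the momentum candidate
  would raise the objective, momentum is reset and a plain proximal
  gradient step is taken (which cannot ascend under backtracking).  The
  recorded objective trace is therefore non-increasing, which the test
  suite asserts on every fixture;
- initialization at W = 0, C = 0, whose objective is analytically
  t·ln 2 plus nothing — making traces reproducible and testable;
- stopping when the relative objective change drops below `tolerance`
  (default 1e-6) or after `max_iterations` (default 5000).

Softplus is evaluated as `logaddexp(0, −margin)` so large-magnitude
margins never overflow; sigmoids are never clipped inside gradients.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| λ₁ | 1e-4 | L2,1 strength; larger ⇒ fewer genes kept (row sparsity is monotone in λ₁) |
| λ₂ | 1e-5 | ridge strength on W |
| tolerance | 1e-6 | relative objective change at which iteration stops |
| max_iterations | 5000 | outer FISTA iteration cap |
| test_fraction | 0.2 | stratified holdout share (8:2 protocol) |
| n_folds × n_repeats | 10 × 10 | reference cross-validation protocol for penalty selection |
| CV grid | 10^{−6..0} × 10^{−6..0} | logarithmic default, overridable |
| reg_c | 0.01 | inverse penalty weight of the linear coefficient-ranking trainer |
| mRMR bins | 5 | equal-frequency discretization bins |

The default (λ₁, λ₂) = (1e-4, 1e-5) is the cross-validated optimum
reported for the 22-class pan-cancer task this model family was built
for; on other data the CV search should be rerun.

## Synthetic data

The generator emulates what the classifier consumes *after* upstream
differential-expression filtering and variance-stabilizing
transformation: a continuous matrix restricted to genes that are
differentially expressed in at least one class.  Background values are
i.i.d. Normal(baseline_mean=5, noise_sd=1); class k's block of
`signal_genes_per_class` genes is shifted upward by `effect_size ×
noise_sd` (default 2 SDs) in class-k samples only.  Blocks are disjoint
by default (an `overlap` fraction is available for harder settings);
class sizes may be imbalanced.  The standard study used throughout the
tests and the acceptance script is 6 classes × 50 samples, 300 genes,
10 signal genes per class, effect 2.

What the generator does *not* emulate: gene–gene correlation, batch and
library-size effects, count-level (negative-binomial) noise,
heavy-tailed outliers, and class-dependent variance.  Passing tests
therefore demonstrate correctness of the machinery — optimization,
selection, evaluation, reproducibility — and sensible behaviour under
the stated noise model, not performance claims about real tumor panels.

## Evaluation conventions

- Confusion matrix: rows = true class, columns = predicted.
- Multiclass MCC from the marginals; if either factor under the square
  root is zero (e.g. all predictions in one class) the statistic is
  defined as 0.
- Log loss: rows of the one-vs-rest probability matrix are renormalized
  to sum to 1 (they are independent sigmoids, not a softmax), then
  clipped to [1e-15, 1 − 1e-15] before the natural log.  An all-zero row
  falls back to the uniform distribution.
- Precision of a never-predicted class is 0 (logged warning); F1 of a
  0/0 pair is 0; weighted aggregates weight by true support.
- ROC/PR: samples sorted by descending score with equal scores grouped
  into one threshold; AUC by the trapezoid rule (equals the
  Mann–Whitney statistic with half-credit ties); PR curves start at
  recall 0 / precision 1.  Classes absent from the truth are omitted
  with a warning.

## Splitting and model selection

Stratified splitting draws, per class, round-half-up(n_class × fraction)
test samples (at least 1, at most n_class − 1) with a seeded generator;
classes are processed in sorted order so a seed fully determines the
partition.  CV folds are assigned per class by round-robin after a
seeded shuffle, so every fold contains every class whenever feasible.
Grid ties break toward larger λ₁ then larger λ₂ — the sparser, more
regularized model.  The selection score defaults to multiclass MCC, the
metric of record for imbalanced panels; accuracy and log loss are
available.

## Feature ranking

The coefficient ranker trains one-vs-rest linear max-margin classifiers
(sample-averaged squared-hinge loss + L2 penalty weighted by 1/reg_c,
solved by L-BFGS) and merges the K columns by max-|coefficient| per gene
(sum-abs is an option); averaging the loss makes the fit invariant to
sample duplication, and exact parity with any particular SVM solver is
explicitly not a goal — only the ranking behaviour is contractual.
mRMR uses the MID (difference) criterion on equal-frequency-binned
columns; binning resolves ties by stable sample order and places equal
values in one bin, so constant genes carry zero mutual information.
All ranking tie-breaks are lexicographic by gene id.

## Problem sizes and determinism

The test suite and acceptance script run entirely on generated data.
The acceptance run uses the standard study above with a 3-point λ₁ grid
{1e-4, 1e-2, 1} × {1e-5}, 5 folds × 2 repeats at a relaxed solver budget
(tol 1e-5) for the search, followed by a full-precision refit — sizes
chosen so the whole pipeline, including the small-panel refit, completes
in seconds on one CPU while leaving the selection problem non-trivial
(the λ₁ = 1 arm is intercept-only and scores near chance).  Every source
of randomness (simulation, split, folds) flows from explicit integer
seeds, and the experiment report is byte-identical across reruns of the
same configuration.

## Known limitations

- No warm-start path across the λ grid; each grid point is fitted cold.
- One-vs-rest probabilities are uncalibrated; log loss uses plain row
  renormalization rather than a fitted calibration map.
- The mRMR implementation is O(k·p) mutual-information evaluations and
  is intended for panels up to a few thousand genes, not genome-wide
  matrices.
- Count-level preprocessing (differential-expression filtering,
  variance-stabilizing transformation) is upstream and out of scope; the
  package assumes its input is already on a homoskedastic continuous
  scale.
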