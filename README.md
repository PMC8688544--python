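# exprmtl

Multi-class classification of gene-expression profiles — e.g. assigning a
tumor sample to one of many cancer types, plus an adjacent-normal class —
by **L2,1-regularized multi-task logistic regression** with joint gene
selection, together with the evaluation metrics, feature-ranking
procedures, and synthetic-data generator needed to exercise the whole
pipeline offline.

## The model

Each of the K classes becomes one binary one-vs-rest *task* over a shared
predictor matrix X ∈ ℝ^{n×p} (n samples, p genes, VST-like normalized
expression).  Task *i* has responses Y_i ∈ {+1, −1}^n (+1 for samples of
class *i*) and parameters (W_i, C_i).  Fitting minimizes

    min_{W,C}  Σ_{i=1}^{t} (1/n) Σ_{k=1}^{n} log(1 + exp(−Y_{i,k}(X_k W_i + C_i)))
               + λ₁‖W‖₂,₁ + λ₂‖W‖²_F

where ‖W‖₂,₁ = Σ_j ‖W_{j,·}‖₂ sums Euclidean norms of the *gene rows* of
the p×t coefficient matrix.  Because a row is shared across all tasks,
the penalty zeroes genes jointly — a gene is kept only if it helps
discriminate at least one class — while λ₂ adds ridge-type stabilization.
The composite objective is minimized by a monotone accelerated
proximal-gradient method (FISTA with backtracking and adaptive restart);
the L2,1 term enters only through its closed-form proximal operator,
row-wise group soft-thresholding.  Prediction applies a sigmoid per task,
σ(X W_i + C_i), and assigns the argmax class (flagging samples whose best
probability is ≤ 0.5).

Around the model the package provides:

- **Evaluation** (`exprmtl.metrics`): confusion matrix, accuracy,
  per-class precision/recall/F1, the confusion-matrix form of the
  multiclass Matthews correlation coefficient, natural-log cross-entropy
  on renormalized one-vs-rest probabilities, and per-class ROC/PR curves
  with trapezoidal AUC.
- **Feature ranking** (`exprmtl.features`): absolute-coefficient ranking
  from one-vs-rest linear max-margin classifiers, and mRMR (mutual
  information, equal-frequency bins, MID criterion), plus nested-subset
  performance curves (test MCC vs panel size).
- **Model selection** (`exprmtl.crossval`): repeated stratified k-fold
  grid search for (λ₁, λ₂) — the reference protocol is 10-fold repeated
  10 times — and an end-to-end, fully seeded experiment runner.
- **Synthetic data** (`exprmtl.simulate`): Gaussian expression on a
  VST-like scale with class-specific differentially-expressed gene
  blocks of known identity, so recovery can be measured exactly.

## Worked example

```python
from exprmtl import MultiTaskLogit, stratified_split
from exprmtl.simulate import SimulationSpec, simulate

sim = simulate(SimulationSpec(n_classes=4, samples_per_class=[40]*4,
                              n_genes=120, signal_genes_per_class=8,
                              effect_size=2.0, seed=7))
split = stratified_split(sim.dataset, 0.2, seed=0)
res = MultiTaskLogit.from_dataset(split.train).fit(lambda1=1e-2, lambda2=1e-5)
print(res.summary())
report = res.evaluate(split.test)
print(f"accuracy={report.accuracy:.4f}  MCC={report.mcc:.4f}  "
      f"log_loss={report.log_loss:.4f}")
```

prints

```
Multi-task L2,1-regularized logistic regression
========================================================
tasks:              4
genes:              120 (88 with nonzero rows)
lambda1 (L2,1):     0.01
lambda2 (ridge):    1e-05
iterations:         618 (converged=True, tol=1e-06)
final objective:    0.232069
--------------------------------------------------------
task               intercept  nnz coef
C01                  -0.0037        88
C02                  -0.0052        88
C03                  -0.0060        88
C04                  -0.0057        88
========================================================
accuracy=1.0000  MCC=1.0000  log_loss=0.0356
```

At λ₁ = 0.01 the L2,1 penalty has eliminated 32 of 120 genes from every
task at once; the 88 surviving rows include all 32 planted signal genes
(`res.selected_genes()`), and the held-out 32 samples are classified
perfectly.  MCC is the balanced agreement statistic (+1 = perfect,
0 = chance); log loss scores the probabilities rather than the labels
(0 = perfectly confident and correct).

The same pipeline is scriptable from the shell:

```bash
exprmtl simulate --classes 6 --samples-per-class 50 --genes 300 --outdir data/
exprmtl run --config config.yaml
exprmtl rank-features data/expression.tsv data/labels.tsv --method mrmr \
    --top 100 --out ranking.tsv
```

All inputs and outputs are plain tab-separated text (expression matrix
with gene-id header and sample-id first column; two-column label table);
models are saved as a JSON header plus TSV coefficient matrices that
round-trip float64 exactly.

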