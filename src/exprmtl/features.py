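"""Gene-ranking procedures for small-panel classification.

Two rankers are provided.  The first trains one-vs-rest linear
max-margin classifiers (sample-averaged squared-hinge loss with an L2
penalty weighted by ``1/reg_c``) and ranks genes by the absolute size of
their coefficients across the per-class separating hyperplanes.  The
second is minimum-redundancy-maximum-relevance (mRMR): a greedy forward
selection over equal-frequency-discretized expression columns that at
each step maximizes mutual information with the class label minus the
mean mutual information with the genes already picked (the difference,
"MID", criterion).  A nested-subset evaluator refits the classifier on
growing gene panels and traces test MCC against panel size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import ExpressionDataset, stratified_split
from .metrics import confusion_matrix, multiclass_mcc

__all__ = [
    "FeatureRanking",
    "train_linear_ovr",
    "rank_by_coefficients",
    "mrmr_rank",
    "subset_performance_curve",
]


@dataclass
class FeatureRanking:
    """Ordered gene list, most important first, with its provenance."""

    method: str  # "coefficient" or "mrmr"
    genes: list[str]
    scores: list[float]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must be parallel lists")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranking contains duplicate genes")

    def top(self, k: int) -> list[str]:
        return self.genes[:k]

    def write_tsv(self, path, params_path=None) -> None:
        pd.DataFrame({"gene": self.genes, "score": self.scores}).to_csv(
            path, sep="\t", index=False
        )
        if params_path is not None:
            with open(params_path, "w") as fh:
                json.dump({"method": self.method, **self.params}, fh, indent=2, sort_keys=True)
                fh.write("\n")

    @classmethod
    def read_tsv(cls, path, method: str = "coefficient") -> "FeatureRanking":
        tab = pd.read_csv(path, sep="\t")
        return cls(
            method=method,
            genes=list(tab.iloc[:, 0].astype(str)),
            scores=list(tab.iloc[:, 1].astype(float)),
        )


def _squared_hinge_objective(theta, X, y, inv_c):
    w, c = theta[:-1], theta[-1]
    m = y * (X @ w + c)
    h = np.maximum(0.0, 1.0 - m)
    n = X.shape[0]
    value = float(np.mean(h * h) + 0.5 * inv_c * (w @ w))
    dm = -2.0 * h * y / n
    grad_w = X.T @ dm + inv_c * w
    grad_c = float(dm.sum())
    return value, np.r_[grad_w, grad_c]


def train_linear_ovr(data: ExpressionDataset, reg_c: float = 0.01):
    """One-vs-rest linear classifiers for coefficient extraction.

    Each class's problem minimizes a sample-averaged squared-hinge loss
    plus ``(0.5/reg_c) ||w||^2`` with an unpenalized intercept, solved by
    L-BFGS.  Averaging the loss makes the fit invariant to duplicating
    samples.  The default ``reg_c=0.01`` mirrors the regularization
    strength tuned for the pan-cancer panels.  Returns ``(coef, intercepts,
    class_names)`` with ``coef`` of shape ``(p, K)`` and classes sorted.
    """
    if reg_c <= 0:
        raise ValueError("reg_c must be positive")
    classes = data.classes
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train one-vs-rest models")
    X = data.X
    labels = np.asarray(data.labels, dtype=object)
    p = X.shape[1]
    coef = np.zeros((p, len(classes)))
    intercepts = np.zeros(len(classes))
    inv_c = 1.0 / reg_c
    for j, cls in enumerate(classes):
        y = np.where(labels == cls, 1.0, -1.0)
        res = minimize(
            _squared_hinge_objective,
            np.zeros(p + 1),
            args=(X, y, inv_c),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
        )
        coef[:, j] = res.x[:-1]
        intercepts[j] = res.x[-1]
    return coef, intercepts, classes


def rank_by_coefficients(coef, gene_ids, aggregate: str = "max") -> FeatureRanking:
    """Rank genes by the absolute size of their fitted coefficients.

    Per-class coefficient columns are merged by the maximum absolute
    value (default) — preserving genes decisive for even a single class —
    or by the sum of absolute values.  Ties break lexicographically by
    gene id.
    """
    coef = np.asarray(coef, dtype=float)
    gene_ids = [str(g) for g in gene_ids]
    if coef.ndim != 2 or coef.shape[0] != len(gene_ids):
        raise ValueError(
            f"coef shape {coef.shape} does not match {len(gene_ids)} genes"
        )
    if aggregate == "max":
        scores = np.abs(coef).max(axis=1)
    elif aggregate == "sum":
        scores = np.abs(coef).sum(axis=1)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}; use 'max' or 'sum'")
    order = sorted(range(len(gene_ids)), key=lambda j: (-scores[j], gene_ids[j]))
    return FeatureRanking(
        method="coefficient",
        genes=[gene_ids[j] for j in order],
        scores=[float(scores[j]) for j in order],
        params={"aggregate": aggregate},
    )


def _equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Deterministic equal-frequency discretization.

    Ties are resolved by the stable order of the sample index, so the
    binning is identical across runs and platforms.
    """
    n = x.shape[0]
    order = np.argsort(x, kind="stable")
    pos_codes = (np.arange(n) * bins) // n
    xs = x[order]
    # equal values share one bin (that of their first stable occurrence),
    # so a constant column lands in a single bin and carries zero MI
    group_start = np.r_[0, np.flatnonzero(np.diff(xs)) + 1]
    reps = np.diff(np.r_[group_start, n])
    codes = np.empty(n, dtype=np.int64)
    codes[order] = np.repeat(pos_codes[group_start], reps)
    return codes


def _mutual_information(a: np.ndarray, b: np.ndarray, na: int, nb: int) -> float:
    """MI (nats) of two discrete code vectors from their contingency table."""
    n = a.shape[0]
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb) / n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    outer = pa[:, None] * pb[None, :]
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def mrmr_rank(data: ExpressionDataset, k: int, bins: int = 5) -> FeatureRanking:
    """Greedy mRMR forward selection of ``k`` genes (MID criterion).

    Expression columns are discretized into ``bins`` equal-frequency
    bins; relevance is the mutual information with the class label and
    redundancy the mean mutual information with the genes already
    selected.  The first pick is the max-relevance gene; each later step
    takes argmax(relevance - redundancy), ties broken lexicographically
    by gene id.  Recorded scores are the criterion values at pick time.
    """
    if bins < 2:
        raise ValueError("bins must be at least 2")
    p = data.n_genes
    if not 1 <= k <= p:
        raise ValueError(f"k={k} must lie in [1, p={p}]")
    disc = np.column_stack(
        [_equal_frequency_bins(data.X[:, j], bins) for j in range(p)]
    )
    classes = data.classes
    y = np.array([classes.index(c) for c in data.labels], dtype=np.int64)
    ny = len(classes)
    relevance = np.array(
        [_mutual_information(disc[:, j], y, bins, ny) for j in range(p)]
    )
    gene_ids = data.gene_ids

    def pick(scores, available):
        best = max(available, key=lambda j: (scores[j], ))
        # lexicographic tie-break on gene id among equal scores
        tied = [j for j in available if scores[j] == scores[best]]
        return min(tied, key=lambda j: gene_ids[j])

    available = set(range(p))
    first = pick(relevance, available)
    selected = [first]
    picked_scores = [float(relevance[first])]
    available.remove(first)
    redundancy_sum = np.array(
        [_mutual_information(disc[:, j], disc[:, first], bins, bins) for j in range(p)]
    )
    while len(selected) < k:
        n_sel = len(selected)
        crit = relevance - redundancy_sum / n_sel
        j = pick(crit, available)
        selected.append(j)
        picked_scores.append(float(crit[j]))
        available.remove(j)
        if len(selected) < k:
            new = np.array(
                [_mutual_information(disc[:, i], disc[:, j], bins, bins) for i in range(p)]
            )
            redundancy_sum += new
    return FeatureRanking(
        method="mrmr",
        genes=[gene_ids[j] for j in selected],
        scores=picked_scores,
        params={"bins": bins, "k": k, "criterion": "MID"},
    )


def subset_performance_curve(
    data: ExpressionDataset,
    ranking: FeatureRanking,
    sizes,
    model_factory=None,
    split_seed: int = 0,
    test_fraction: float = 0.2,
):
    """Test MCC of the classifier refitted on growing top-``s`` gene panels.

    ``model_factory(train_dataset)`` must return a fitted object with a
    ``predict(X) -> labels`` method; the default fits the multi-task
    model at its default penalties.  Returns a list of ``(size, mcc)``.
    """
    if model_factory is None:
        from .model import MultiTaskLogit

        def model_factory(train):
            return MultiTaskLogit.from_dataset(train).fit()

    sizes = [int(s) for s in sizes]
    for s in sizes:
        if s > len(ranking.genes):
            raise ValueError(
                f"requested top-{s} genes but the ranking has only "
                f"{len(ranking.genes)}"
            )
    class_names = data.classes
    curve = []
    for s in sizes:
        subset = data.restrict_genes(ranking.top(s))
        split = stratified_split(subset, test_fraction, split_seed)
        fitted = model_factory(split.train)
        predicted = fitted.predict(split.test.X)
        cm = confusion_matrix(split.test.labels, predicted, class_names)
        curve.append((s, multiclass_mcc(cm)))
    return curve
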