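"""Multi-class evaluation: confusion matrix, accuracy, PRF, the
confusion-matrix form of the multiclass Matthews correlation
coefficient, cross-entropy (log loss), and one-vs-rest ROC/PR curves.

With confusion matrix ``C`` (rows = true class, columns = predicted),
``t_j = sum_i C[i, j]`` true occurrences, ``p_j = sum_i C[j, i]``
predictions, ``n_c = trace(C)`` correct and ``n_s`` total, the
multiclass MCC is

    MCC = (n_c * n_s - sum_j p_j t_j)
          / sqrt((n_s^2 - sum_j p_j^2) * (n_s^2 - sum_j t_j^2))

which reduces to the familiar binary MCC at two classes and is well
suited to class-imbalanced panels.  Log loss is the natural-log
cross-entropy of the (renormalized) class-probability rows against the
one-hot truth.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion_matrix",
    "multiclass_mcc",
    "log_loss",
    "per_class_prf",
    "ovr_curves",
    "evaluate_predictions",
]

_EPS = 1e-15  # probability clip before taking logs


@dataclass
class ConfusionMatrix:
    """Counts matrix with rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        m = len(self.class_names)
        if self.counts.shape != (m, m):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {m} classes"
            )
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.n_samples

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names, columns=self.class_names)

    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "true\\predicted"
        df.to_csv(path, sep="\t")


def confusion_matrix(true_labels, predicted_labels, class_names) -> ConfusionMatrix:
    """Tally ``counts[a, b]`` = samples with true class ``a`` predicted ``b``."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"{len(true_labels)} true vs {len(predicted_labels)} predicted labels"
        )
    class_names = [str(c) for c in class_names]
    index = {c: i for i, c in enumerate(class_names)}
    counts = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            raise KeyError(f"unknown true label {t!r}")
        if p not in index:
            raise KeyError(f"unknown predicted label {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_names=class_names)


def multiclass_mcc(confusion: ConfusionMatrix) -> float:
    """Multiclass MCC from the confusion-matrix marginals.

    Returns 0 when either factor under the square root vanishes (e.g.
    every prediction in one class) — the standard degenerate convention.
    """
    C = confusion.counts.astype(float)
    if C.sum() == 0:
        raise ValueError("empty confusion matrix")
    n_s = C.sum()
    n_c = np.trace(C)
    # rows = true / cols = predicted, so true marginals are row sums
    t_j = C.sum(axis=1)  # times each class truly occurs
    p_j = C.sum(axis=0)  # times each class is predicted
    num = n_c * n_s - float(p_j @ t_j)
    d1 = n_s * n_s - float(p_j @ p_j)
    d2 = n_s * n_s - float(t_j @ t_j)
    if d1 <= 0.0 or d2 <= 0.0:
        return 0.0
    return num / math.sqrt(d1 * d2)


def log_loss(true_labels, proba, class_names) -> float:
    """Natural-log cross-entropy averaged over samples.

    One-vs-rest probabilities do not sum to 1 per sample, so rows are
    first renormalized; values are then clipped to ``[1e-15, 1-1e-15]``
    before the log so a confident miss stays finite.
    """
    proba = np.asarray(proba, dtype=float)
    true_labels = list(true_labels)
    class_names = [str(c) for c in class_names]
    if proba.ndim != 2 or proba.shape[1] != len(class_names):
        raise ValueError(
            f"proba shape {proba.shape} does not match {len(class_names)} classes"
        )
    if len(true_labels) != proba.shape[0]:
        raise ValueError(f"{len(true_labels)} labels for {proba.shape[0]} rows")
    if (proba < 0).any():
        raise ValueError("probabilities must be nonnegative")
    row_sums = proba.sum(axis=1, keepdims=True)
    safe = np.where(row_sums > 0.0, row_sums, 1.0)
    norm = np.where(row_sums > 0.0, proba / safe, 1.0 / proba.shape[1])
    norm = np.clip(norm, _EPS, 1.0 - _EPS)
    index = {c: i for i, c in enumerate(class_names)}
    try:
        cols = [index[t] for t in true_labels]
    except KeyError as exc:
        raise KeyError(f"unknown true label {exc.args[0]!r}") from None
    picked = norm[np.arange(len(true_labels)), cols]
    return float(-np.mean(np.log(picked)))


def per_class_prf(confusion: ConfusionMatrix):
    """Per-class precision/recall/F1 plus macro and support-weighted means.

    A class never predicted gets precision 0 (logged, not raised); F1 of
    a 0/0 pair is 0.  Weighted aggregates weight by true support.
    """
    C = confusion.counts.astype(float)
    if C.sum() == 0:
        raise ValueError("empty confusion matrix")
    t_j = C.sum(axis=1)  # true support
    p_j = C.sum(axis=0)  # predicted count
    diag = np.diag(C)
    rows = []
    for i, name in enumerate(confusion.class_names):
        if p_j[i] == 0:
            logger.warning("class %r never predicted; precision set to 0", name)
            prec = 0.0
        else:
            prec = diag[i] / p_j[i]
        rec = diag[i] / t_j[i] if t_j[i] > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
        rows.append(
            {
                "class": name,
                "precision": float(prec),
                "recall": float(rec),
                "f1": float(f1),
                "support": int(t_j[i]),
            }
        )
    prec = np.array([r["precision"] for r in rows])
    rec = np.array([r["recall"] for r in rows])
    f1 = np.array([r["f1"] for r in rows])
    weights = t_j / t_j.sum()
    macro = {
        "precision": float(prec.mean()),
        "recall": float(rec.mean()),
        "f1": float(f1.mean()),
    }
    weighted = {
        "precision": float(prec @ weights),
        "recall": float(rec @ weights),
        "f1": float(f1 @ weights),
    }
    return rows, macro, weighted


def _roc_pr_one_class(y_true: np.ndarray, scores: np.ndarray):
    """ROC and PR points for one binary problem, ties grouped per threshold."""
    order = np.argsort(-scores, kind="stable")
    y = y_true[order]
    s = scores[order]
    # last index of each tie group of equal scores
    distinct = np.flatnonzero(np.diff(s)) if s.size > 1 else np.array([], dtype=int)
    cut = np.r_[distinct, s.size - 1]
    tps = np.cumsum(y)[cut].astype(float)
    fps = np.cumsum(1 - y)[cut].astype(float)
    P = float(y_true.sum())
    N = float(y_true.size - y_true.sum())
    tpr = np.r_[0.0, tps / P]
    fpr = np.r_[0.0, fps / N] if N > 0 else np.r_[0.0, np.zeros_like(fps)]
    auc = float(np.trapezoid(tpr, fpr))
    precision = tps / (tps + fps)
    recall = tps / P
    pr_recall = np.r_[0.0, recall]
    pr_precision = np.r_[1.0, precision]
    return fpr, tpr, auc, pr_recall, pr_precision


def ovr_curves(true_labels, proba, class_names):
    """Per-class one-vs-rest ROC (with trapezoidal AUC) and PR curves.

    Classes absent from ``true_labels`` are omitted with a logged
    warning (their TPR is undefined).  Returns a dict keyed by class
    name with ``fpr``, ``tpr``, ``auc``, ``pr_recall``, ``pr_precision``.
    """
    proba = np.asarray(proba, dtype=float)
    true_labels = np.asarray(list(true_labels), dtype=object)
    class_names = [str(c) for c in class_names]
    if proba.shape[1] != len(class_names):
        raise ValueError(
            f"proba has {proba.shape[1]} columns for {len(class_names)} classes"
        )
    out = {}
    for j, name in enumerate(class_names):
        y = (true_labels == name).astype(int)
        if y.sum() == 0:
            logger.warning("class %r absent from true labels; curves omitted", name)
            continue
        fpr, tpr, auc, prr, prp = _roc_pr_one_class(y, proba[:, j])
        out[name] = {
            "fpr": fpr.tolist(),
            "tpr": tpr.tolist(),
            "auc": auc,
            "pr_recall": prr.tolist(),
            "pr_precision": prp.tolist(),
        }
    return out


@dataclass
class EvaluationReport:
    """Everything the evaluation stage computes for one prediction set."""

    confusion: ConfusionMatrix
    accuracy: float
    mcc: float
    log_loss: float
    per_class: list[dict]
    macro: dict
    weighted: dict
    curves: dict

    def to_dict(self) -> dict:
        return {
            "class_names": self.confusion.class_names,
            "confusion": self.confusion.counts.tolist(),
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "log_loss": self.log_loss,
            "per_class": self.per_class,
            "macro": self.macro,
            "weighted": self.weighted,
            "curves": self.curves,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())
            fh.write("\n")

    def write_curves_tsv(self, roc_path, pr_path) -> None:
        roc_rows, pr_rows = [], []
        for name, c in self.curves.items():
            roc_rows += [(name, f, t) for f, t in zip(c["fpr"], c["tpr"])]
            pr_rows += [(name, r, p) for r, p in zip(c["pr_recall"], c["pr_precision"])]
        pd.DataFrame(roc_rows, columns=["class", "fpr", "tpr"]).to_csv(
            roc_path, sep="\t", index=False
        )
        pd.DataFrame(pr_rows, columns=["class", "recall", "precision"]).to_csv(
            pr_path, sep="\t", index=False
        )


def evaluate_predictions(true_labels, predicted_labels, proba, class_names) -> EvaluationReport:
    """Assemble the full report from labels and one-vs-rest probabilities."""
    cm = confusion_matrix(true_labels, predicted_labels, class_names)
    rows, macro, weighted = per_class_prf(cm)
    return EvaluationReport(
        confusion=cm,
        accuracy=cm.accuracy,
        mcc=multiclass_mcc(cm),
        log_loss=log_loss(true_labels, proba, class_names),
        per_class=rows,
        macro=macro,
        weighted=weighted,
        curves=ovr_curves(true_labels, proba, class_names),
    )
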