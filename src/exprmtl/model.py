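"""Model/Results interface over the multi-task solver.

``MultiTaskLogit`` is the model object: it holds the task structure
(shared predictors, one +1/-1 response column per class) and exposes
``fit``.  ``fit`` returns :class:`RmtlResults`, which carries the
coefficient matrix W (genes x tasks), the per-task intercepts, the
penalties, the optimizer trace, and the prediction / evaluation /
serialization methods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import core
from .core import FitOptions, FitTrace
from .data import ExpressionDataset, TaskSet, build_tasks
from .metrics import EvaluationReport, evaluate_predictions

__all__ = ["MultiTaskLogit", "RmtlResults"]


class MultiTaskLogit:
    """One-vs-rest multi-task logistic regression with joint gene selection.

    Parameters
    ----------
    taskset : TaskSet
        Shared predictor matrix with per-class +1/-1 responses; build one
        with :func:`exprmtl.data.build_tasks` or use the convenience
        constructors below.
    """

    def __init__(self, taskset: TaskSet):
        self.taskset = taskset

    @classmethod
    def from_dataset(
        cls, data: ExpressionDataset, class_order: list[str] | None = None
    ) -> "MultiTaskLogit":
        return cls(build_tasks(data, class_order=class_order))

    @classmethod
    def from_dataframe(cls, expr: pd.DataFrame, labels: pd.Series) -> "MultiTaskLogit":
        return cls.from_dataset(ExpressionDataset.from_dataframe(expr, labels))

    @property
    def n_tasks(self) -> int:
        return self.taskset.n_tasks

    @property
    def n_genes(self) -> int:
        return self.taskset.X.shape[1]

    def fit(
        self,
        lambda1: float = 1e-4,
        lambda2: float = 1e-5,
        options: FitOptions | None = None,
        **option_kwargs,
    ) -> "RmtlResults":
        """Minimize the penalized objective and return the results object.

        Defaults are the cross-validated penalties reported for the
        pan-cancer task (lambda1=1e-4, lambda2=1e-5).  Extra keyword
        arguments are forwarded to :class:`FitOptions`.
        """
        if options is None:
            options = FitOptions(**option_kwargs)
        elif option_kwargs:
            raise TypeError("pass either options= or keyword options, not both")
        W, C, trace = core.fit_fista(
            self.taskset.X, self.taskset.Y, lambda1, lambda2, options
        )
        return RmtlResults(
            model=self,
            W=W,
            C=C,
            lambda1=float(lambda1),
            lambda2=float(lambda2),
            task_names=list(self.taskset.task_names),
            gene_ids=list(self.taskset.gene_ids),
            trace=trace,
        )


@dataclass
class RmtlResults:
    """Fitted coefficients, diagnostics, and prediction methods."""

    W: np.ndarray
    C: np.ndarray
    lambda1: float
    lambda2: float
    task_names: list[str]
    gene_ids: list[str]
    trace: FitTrace
    model: MultiTaskLogit | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.C = np.asarray(self.C, dtype=float).ravel()
        p, t = self.W.shape
        if len(self.gene_ids) != p or len(self.task_names) != t:
            raise ValueError(
                f"W shape {self.W.shape} does not match {len(self.gene_ids)} genes "
                f"x {len(self.task_names)} tasks"
            )
        if self.C.shape[0] != t:
            raise ValueError(f"C has length {self.C.shape[0]}, expected {t}")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalties must be nonnegative")
        if len(set(self.task_names)) != t:
            raise ValueError("task names are not unique")
        if len(set(self.gene_ids)) != p:
            raise ValueError("gene ids are not unique")

    # alias used by callers thinking in terms of per-task intercepts
    @property
    def intercepts(self) -> np.ndarray:
        return self.C

    @property
    def objective(self) -> float:
        return self.trace.objective_values[-1]

    def selected_genes(self, atol: float = 0.0) -> list[str]:
        """Genes with a nonzero coefficient row (survivors of the L2,1 prox)."""
        norms = np.linalg.norm(self.W, axis=1)
        return [g for g, r in zip(self.gene_ids, norms) if r > atol]

    def _matrix_for(self, X) -> np.ndarray:
        if isinstance(X, ExpressionDataset):
            if X.gene_ids != self.gene_ids:
                raise ValueError(
                    "gene order of the input does not match the fitted model; "
                    "reindex the dataset columns to model.gene_ids first"
                )
            return X.X
        if isinstance(X, pd.DataFrame):
            if list(X.columns.astype(str)) != self.gene_ids:
                raise ValueError(
                    "gene order of the DataFrame does not match the fitted model; "
                    "reindex its columns to model.gene_ids first"
                )
            return X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def predict_proba(self, X) -> np.ndarray:
        """One-vs-rest probabilities, one column per task (rows unnormalized)."""
        return core.predict_proba(self.W, self.C, self._matrix_for(X))

    def predict(self, X, return_low_confidence: bool = False):
        """Class label per sample: argmax task probability.

        Samples whose best probability is <= 0.5 are flagged when
        ``return_low_confidence`` is set.
        """
        proba = self.predict_proba(X)
        labels, flags = core.predict_labels(proba, self.task_names)
        if return_low_confidence:
            return labels, flags
        return labels

    def evaluate(self, data: ExpressionDataset) -> EvaluationReport:
        """Score the fitted model on a labeled dataset."""
        proba = self.predict_proba(data)
        labels, _ = core.predict_labels(proba, self.task_names)
        return evaluate_predictions(data.labels, labels, proba, self.task_names)

    def summary(self) -> str:
        """Plain-text fit summary in the style of statsmodels results."""
        norms = np.linalg.norm(self.W, axis=1)
        nnz = int((norms > 0).sum())
        lines = [
            "Multi-task L2,1-regularized logistic regression",
            "=" * 56,
            f"tasks:              {len(self.task_names)}",
            f"genes:              {len(self.gene_ids)} ({nnz} with nonzero rows)",
            f"lambda1 (L2,1):     {self.lambda1:g}",
            f"lambda2 (ridge):    {self.lambda2:g}",
            f"iterations:         {self.trace.n_iterations}"
            f" (converged={self.trace.converged}, tol={self.trace.tolerance:g})",
            f"final objective:    {self.objective:.6f}",
            "-" * 56,
            f"{'task':<16}{'intercept':>12}{'nnz coef':>10}",
        ]
        for i, name in enumerate(self.task_names):
            lines.append(
                f"{name:<16}{self.C[i]:>12.4f}{int((self.W[:, i] != 0).sum()):>10}"
            )
        lines.append("=" * 56)
        return "\n".join(lines)

    # --- serialization: JSON header + tab-separated numeric text ---------

    def save(self, prefix) -> None:
        """Write ``<prefix>.json`` + ``<prefix>.W.tsv`` + ``<prefix>.C.tsv``.

        Numeric text uses 17 significant digits so float64 values
        round-trip exactly.
        """
        prefix = Path(prefix)
        header = {
            "task_names": self.task_names,
            "gene_ids": self.gene_ids,
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "trace": {
                "n_iterations": self.trace.n_iterations,
                "converged": self.trace.converged,
                "tolerance": self.trace.tolerance,
                "final_objective": self.objective,
                "objective_values": self.trace.objective_values,
            },
        }
        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump(header, fh, indent=2, sort_keys=True)
            fh.write("\n")
        np.savetxt(f"{prefix}.W.tsv", self.W, delimiter="\t", fmt="%.17g")
        np.savetxt(f"{prefix}.C.tsv", self.C[None, :], delimiter="\t", fmt="%.17g")

    @classmethod
    def load(cls, prefix) -> "RmtlResults":
        prefix = Path(prefix)
        with open(prefix.with_suffix(".json")) as fh:
            header = json.load(fh)
        W = np.loadtxt(f"{prefix}.W.tsv", delimiter="\t", ndmin=2)
        C = np.loadtxt(f"{prefix}.C.tsv", delimiter="\t", ndmin=2).ravel()
        tr = header["trace"]
        trace = FitTrace(
            objective_values=list(tr.get("objective_values", [tr["final_objective"]])),
            n_iterations=int(tr["n_iterations"]),
            converged=bool(tr["converged"]),
            tolerance=float(tr["tolerance"]),
        )
        return cls(
            W=W,
            C=C,
            lambda1=float(header["lambda1"]),
            lambda2=float(header["lambda2"]),
            task_names=list(header["task_names"]),
            gene_ids=list(header["gene_ids"]),
            trace=trace,
        )
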