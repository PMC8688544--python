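"""L2,1-regularized multi-task logistic regression.

The model couples ``t`` one-vs-rest binary tasks that share a single
predictor matrix ``X`` (``n`` samples x ``p`` genes).  Task ``i`` owns a
coefficient column ``W[:, i]`` and an intercept ``C[i]``, its labels are
``Y[:, i]`` in {+1, -1}, and the fitted objective is

    sum_i (1/n) sum_k log(1 + exp(-Y[k, i] (X[k] @ W[:, i] + C[i])))
        + lambda1 * ||W||_{2,1} + lambda2 * ||W||_F^2

where ``||W||_{2,1} = sum_j ||W[j, :]||_2`` sums the Euclidean norms of
the gene rows.  Penalizing it zeroes entire rows, i.e. removes a gene
from *every* task at once (joint feature selection); the squared
Frobenius term is a ridge stabilizer.  The composite objective is
minimized by a monotone accelerated proximal-gradient method (FISTA with
backtracking); the non-smooth L2,1 part enters only through its
closed-form proximal operator, row-wise group soft-thresholding.
Intercepts are unpenalized and follow plain gradient steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "FitOptions",
    "FitTrace",
    "logistic_loss",
    "l21_norm",
    "objective",
    "objective_value",
    "loss_gradient",
    "prox_l21",
    "fit_fista",
    "predict_proba",
    "predict_labels",
]


@dataclass
class FitOptions:
    """Solver settings for :func:`fit_fista`.

    Parameters
    ----------
    max_iterations : int
        Hard cap on outer FISTA iterations.
    tolerance : float
        Relative-objective-change stopping rule:
        ``|f_k - f_{k-1}| / max(1, |f_{k-1}|) < tolerance``.
    initial_step : float
        First trial step size (inverse Lipschitz estimate).
    backtracking_factor : float
        Multiplier in (0, 1) applied to the step size when the quadratic
        upper bound fails.
    """

    max_iterations: int = 5000
    tolerance: float = 1e-6
    initial_step: float = 1.0
    backtracking_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be a positive integer")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.initial_step <= 0:
            raise ValueError("initial_step must be positive")
        if not 0.0 < self.backtracking_factor < 1.0:
            raise ValueError("backtracking_factor must lie strictly in (0, 1)")


@dataclass
class FitTrace:
    """Diagnostics recorded while optimizing the composite objective."""

    objective_values: list[float] = field(default_factory=list)
    step_sizes: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False
    tolerance: float = 1e-6


def _as_2d(X, name: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got ndim={X.ndim}")
    return X


def _check_pm1(y: np.ndarray, name: str) -> None:
    bad = np.setdiff1d(np.unique(y), [-1.0, 1.0])
    if bad.size:
        raise ValueError(f"{name} must contain only +1/-1, found {bad.tolist()}")


def logistic_loss(X, y, w, c: float) -> float:
    """Mean logistic loss ``(1/n) sum_k log(1 + exp(-y_k (x_k.w + c)))``.

    Labels are +1/-1; the natural logarithm is used.  Evaluated through
    ``log1p``/softplus so large-magnitude margins never overflow.
    """
    X = _as_2d(X, "X")
    y = np.asarray(y, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"y has length {y.shape[0]}, expected n={n} to match X {X.shape}")
    if w.shape[0] != p:
        raise ValueError(f"w has length {w.shape[0]}, expected p={p} to match X {X.shape}")
    _check_pm1(y, "y")
    margins = y * (X @ w + c)
    # log(1 + e^{-m}) == logaddexp(0, -m), stable for any magnitude
    return float(np.mean(np.logaddexp(0.0, -margins)))


def l21_norm(W) -> float:
    """Sum over rows of the Euclidean row norm, ``sum_j ||W[j, :]||_2``."""
    W = _as_2d(W, "W")
    if W.size == 0:
        raise ValueError("W must be non-empty")
    return float(np.linalg.norm(W, axis=1).sum())


def _smooth_value(X, Y, W, C, lambda2: float) -> float:
    """Differentiable part: summed per-task mean losses + ridge term."""
    n = X.shape[0]
    margins = Y * (X @ W + C)
    return float(np.logaddexp(0.0, -margins).sum() / n + lambda2 * (W * W).sum())


def objective(taskset, model) -> float:
    """Full penalized objective of a fitted (or candidate) model on a task set.

    ``taskset`` needs attributes ``X`` and ``Y``; ``model`` needs ``W``,
    ``C``, ``lambda1``, ``lambda2``.  All tasks share ``taskset.X``.
    """
    return objective_value(
        taskset.X, taskset.Y, model.W, model.C, model.lambda1, model.lambda2
    )


def objective_value(X, Y, W, C, lambda1: float, lambda2: float) -> float:
    """Penalized objective from raw arrays (see module docstring)."""
    X = _as_2d(X, "X")
    Y = _as_2d(Y, "Y")
    W = _as_2d(W, "W")
    C = np.asarray(C, dtype=float).ravel()
    n, p = X.shape
    t = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError(f"Y has {Y.shape[0]} rows, expected n={n}")
    if W.shape != (p, t):
        raise ValueError(f"W has shape {W.shape}, expected ({p}, {t})")
    if C.shape[0] != t:
        raise ValueError(f"C has length {C.shape[0]}, expected t={t}")
    _check_pm1(Y, "Y")
    return _smooth_value(X, Y, W, C, lambda2) + lambda1 * l21_norm(W)


def loss_gradient(X, Y, W, C):
    """Gradient of the summed per-task mean logistic losses.

    Returns ``(grad_W, grad_C)`` with shapes ``(p, t)`` and ``(t,)``.
    Per task ``i``:

        dL/dW_i = -(1/n) sum_k sigma(-m_{ik}) Y_{ik} X_k
        dL/dC_i = -(1/n) sum_k sigma(-m_{ik}) Y_{ik}

    with margin ``m_{ik} = Y_{ik}(X_k.W_i + C_i)`` and sigmoid ``sigma``.
    """
    X = _as_2d(X, "X")
    Y = _as_2d(Y, "Y")
    W = _as_2d(W, "W")
    C = np.asarray(C, dtype=float).ravel()
    n, p = X.shape
    t = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError(f"Y has {Y.shape[0]} rows, expected n={n}")
    if W.shape != (p, t):
        raise ValueError(f"W has shape {W.shape}, expected ({p}, {t})")
    if C.shape[0] != t:
        raise ValueError(f"C has length {C.shape[0]}, expected t={t}")
    _check_pm1(Y, "Y")
    margins = Y * (X @ W + C)
    G = -(expit(-margins) * Y) / n  # n x t
    return X.T @ G, G.sum(axis=0)


def prox_l21(W, tau: float) -> np.ndarray:
    """Proximal operator of ``tau * ||.||_{2,1}``: row-wise group shrinkage.

    Each row ``r`` maps to ``max(0, 1 - tau/||r||_2) * r``; rows with
    ``||r||_2 <= tau`` become exactly zero, eliminating the gene from all
    tasks simultaneously.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    W = _as_2d(W, "W")
    norms = np.linalg.norm(W, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(norms > 0.0, np.maximum(0.0, 1.0 - tau / norms), 0.0)
    return W * scale[:, None]


def fit_fista(X, Y, lambda1: float, lambda2: float, options: FitOptions | None = None):
    """Minimize the composite objective by monotone FISTA with backtracking.

    The smooth part (losses + ridge) supplies gradients; the L2,1 part is
    handled by :func:`prox_l21` on ``W`` only, and intercepts take plain
    gradient steps.  The monotone variant keeps the best iterate so the
    recorded objective sequence never increases, while momentum is still
    built from the proximal candidate.

    Returns ``(W, C, trace)``.
    """
    if options is None:
        options = FitOptions()
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalties must be nonnegative")
    X = _as_2d(X, "X")
    Y = _as_2d(Y, "Y")
    if not np.isfinite(X).all():
        raise ValueError("predictor matrix contains non-finite values")
    _check_pm1(Y, "Y")
    n, p = X.shape
    t = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError(f"Y has {Y.shape[0]} rows, expected n={n}")

    W = np.zeros((p, t))
    C = np.zeros(t)
    Wz, Cz = W.copy(), C.copy()
    W_prev, C_prev = W.copy(), C.copy()
    tk = 1.0
    L = 1.0 / options.initial_step

    f_curr = _smooth_value(X, Y, W, C, lambda2) + lambda1 * l21_norm(W)
    trace = FitTrace(tolerance=options.tolerance)
    trace.objective_values.append(f_curr)

    restarted = False
    for _ in range(options.max_iterations):
        margins = Y * (X @ Wz + Cz)
        G = -(expit(-margins) * Y) / n
        gW = X.T @ G + 2.0 * lambda2 * Wz
        gC = G.sum(axis=0)
        fz = _smooth_value(X, Y, Wz, Cz, lambda2)

        while True:
            step = 1.0 / L
            Wc = prox_l21(Wz - step * gW, lambda1 * step)
            Cc = Cz - step * gC
            dW = Wc - Wz
            dC = Cc - Cz
            fc = _smooth_value(X, Y, Wc, Cc, lambda2)
            quad = (
                fz
                + float((gW * dW).sum() + (gC * dC).sum())
                + 0.5 * L * float((dW * dW).sum() + (dC * dC).sum())
            )
            if fc <= quad + 1e-12:
                break
            L /= options.backtracking_factor

        F_cand = fc + lambda1 * l21_norm(Wc)
        trace.step_sizes.append(step)
        trace.n_iterations += 1

        if F_cand > f_curr:
            # monotone safeguard: momentum overshot.  From a restarted
            # extrapolation point (Wz == W) the prox step cannot increase
            # the objective, so a second failure means we are at the
            # optimum up to round-off.
            trace.objective_values.append(f_curr)
            if restarted:
                trace.converged = True
                break
            tk = 1.0
            Wz, Cz = W.copy(), C.copy()
            W_prev, C_prev = W.copy(), C.copy()
            restarted = True
            continue
        restarted = False

        t_next = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * tk * tk))
        Wz = Wc + ((tk - 1.0) / t_next) * (Wc - W_prev)
        Cz = Cc + ((tk - 1.0) / t_next) * (Cc - C_prev)
        W_prev, C_prev = Wc, Cc

        rel_change = abs(F_cand - f_curr) / max(1.0, abs(f_curr))
        W, C, tk, f_curr = Wc, Cc, t_next, F_cand
        trace.objective_values.append(f_curr)
        if rel_change < options.tolerance:
            trace.converged = True
            break

    return W, C, trace


def predict_proba(W, C, X) -> np.ndarray:
    """One-vs-rest task probabilities ``sigma(X W + C)``.

    Entry ``(k, i)`` is the probability that sample ``k`` is a positive
    of task ``i``.  Rows are *not* normalized across tasks: each column
    is an independent binary probability.
    """
    W = _as_2d(W, "W")
    X = _as_2d(X, "X")
    C = np.asarray(C, dtype=float).ravel()
    if X.shape[1] != W.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} columns but the model has {W.shape[0]} genes"
        )
    return expit(X @ W + C)


def predict_labels(proba, task_names):
    """Assign each sample the task name of its highest probability.

    Ties break toward the lowest column index.  A sample whose maximum
    probability is <= 0.5 is still assigned the argmax class but flagged
    low-confidence, so confusion-matrix accounting stays complete.

    Returns ``(labels, low_confidence)`` — a list of class names and a
    boolean array.
    """
    proba = _as_2d(proba, "proba")
    if proba.size == 0:
        raise ValueError("probability matrix is empty")
    task_names = list(task_names)
    if proba.shape[1] != len(task_names):
        raise ValueError(
            f"proba has {proba.shape[1]} columns but {len(task_names)} task names given"
        )
    idx = np.argmax(proba, axis=1)  # first occurrence wins ties
    best = proba[np.arange(proba.shape[0]), idx]
    labels = [task_names[i] for i in idx]
    return labels, best <= 0.5
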