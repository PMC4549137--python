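"""Linear soft-margin SVM trained by sequential minimal optimization (SMO).

The dual problem

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j <x_i, x_j>
    s.t.   0 <= a_i <= C,   sum_i a_i y_i = 0

is solved by SMO with maximal-violating-pair working-set selection: at
every iteration the pair of multipliers that most violates the
Karush-Kuhn-Tucker (KKT) conditions is optimized analytically, until no
pair violates them beyond ``tol``.  For the linear kernel the weight
vector w = sum_i a_i y_i x_i is maintained incrementally.

The decision function is f(x) = w.x + b; exact ties on the hyperplane are
assigned to the positive (patient) class deterministically.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SvmModel:
    w: np.ndarray
    b: float
    alpha: np.ndarray
    C: float
    support: np.ndarray      # indices with alpha > 0
    X: np.ndarray
    y: np.ndarray

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.w.shape[0]:
            raise ValueError(
                f"feature dimension mismatch: model has {self.w.shape[0]}, "
                f"input has {X.shape[1]}")
        return X @ self.w + self.b

    def dual_objective(self) -> float:
        """Value of the dual objective at the fitted multipliers."""
        ay = self.alpha * self.y
        return float(self.alpha.sum() - 0.5 * ay @ (self.X @ self.X.T) @ ay)


def train_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0,
              tol: float = 1e-3, max_iter: int = 100_000) -> SvmModel:
    """Fit a linear soft-margin SVM by SMO.

    Parameters
    ----------
    X : samples x features
    y : labels in {-1, +1}
    C : box constraint on the dual multipliers
    tol : KKT violation tolerance for the stopping rule
    max_iter : cap on pairwise updates

    The algorithm is deterministic: the working pair is always the maximal
    KKT violator, with numpy argmax/argmin tie-breaking.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be samples x features with one label per row")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("labels must be in {-1, +1}")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    if C <= 0:
        raise ValueError("C must be positive")

    n = X.shape[0]
    K = X @ X.T
    alpha = np.zeros(n)
    w = np.zeros(X.shape[1])
    eps = 1e-12 * max(1.0, C)

    for _ in range(max_iter):
        # g_i = y_i - w.x_i constrains the feasible bias b (see _bias_from_kkt);
        # optimality <=> max lower bound <= min upper bound within tol
        g = y - X @ w
        lower = ((alpha < C - eps) & (y > 0)) | ((alpha > eps) & (y < 0))
        upper = ((alpha < C - eps) & (y < 0)) | ((alpha > eps) & (y > 0))
        li = np.flatnonzero(lower)
        ui = np.flatnonzero(upper)
        if li.size == 0 or ui.size == 0:
            break
        i = int(li[np.argmax(g[li])])
        j = int(ui[np.argmin(g[ui])])
        if g[i] - g[j] <= tol:
            break
        if not _take_step(i, j, alpha, y, g, K, C, w, X, eps):
            break

    w_final = (alpha * y) @ X
    model = SvmModel(w=w_final, b=0.0, alpha=alpha, C=float(C),
                     support=np.flatnonzero(alpha > 1e-8 * max(1.0, C)),
                     X=X, y=y)
    model.b = _bias_from_kkt(model)
    return model


def _take_step(i1, i2, alpha, y, g, K, C, w, X, eps) -> bool:
    """Analytic two-variable subproblem; returns True if alphas moved."""
    a1_old, a2_old = alpha[i1], alpha[i2]
    y1, y2 = y[i1], y[i2]
    s = y1 * y2
    if s > 0:
        L, H = max(0.0, a1_old + a2_old - C), min(C, a1_old + a2_old)
    else:
        L, H = max(0.0, a2_old - a1_old), min(C, C + a2_old - a1_old)
    if H - L < eps:
        return False
    eta = K[i1, i1] + K[i2, i2] - 2.0 * K[i1, i2]
    # E_i - E_j is bias-free: E_i = w.x_i + b - y_i = b - g_i
    dE = g[i2] - g[i1]
    if eta > eps:
        a2 = np.clip(a2_old + y2 * dE / eta, L, H)
    else:
        # flat direction (duplicate/collinear points): jump to the better bound
        a2 = L if y2 * dE < 0 else H
    if abs(a2 - a2_old) < eps:
        return False
    a1 = a1_old + s * (a2_old - a2)
    alpha[i1], alpha[i2] = a1, a2
    w += y1 * (a1 - a1_old) * X[i1] + y2 * (a2 - a2_old) * X[i2]
    return True


def _bias_from_kkt(model: SvmModel) -> float:
    """Bias as the midpoint of the interval the KKT conditions permit.

    Each sample constrains b through y_i (w.x_i + b) {>=, <=, =} 1
    according to whether its multiplier sits at 0, at C, or strictly
    between; the midpoint of the resulting [lo, hi] interval is a
    deterministic choice that is exact whenever free support vectors exist.
    """
    g = model.y - model.X @ model.w
    y, alpha, C = model.y, model.alpha, model.C
    eps = 1e-9 * max(1.0, C)
    lower = ((alpha < C - eps) & (y > 0)) | ((alpha > eps) & (y < 0))
    upper = ((alpha < C - eps) & (y < 0)) | ((alpha > eps) & (y > 0))
    lo = g[lower].max() if lower.any() else -np.inf
    hi = g[upper].min() if upper.any() else np.inf
    if np.isfinite(lo) and np.isfinite(hi):
        return float(0.5 * (lo + hi))
    return float(lo if np.isfinite(lo) else (hi if np.isfinite(hi) else 0.0))


def predict(model: SvmModel, X: np.ndarray) -> np.ndarray:
    """Labels in {-1, +1}; exact zeros map to +1 (patient) deterministically."""
    f = model.decision_function(X)
    return np.where(f >= 0, 1, -1)
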