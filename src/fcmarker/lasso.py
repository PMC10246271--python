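"""L1-penalised logistic regression along a warm-started penalty path.

Sparse logistic regression is the workhorse of the marker-training loop:
every outer fold of every subsample fits a penalty path on each inner fold,
and the permutation nulls retrain the whole ensemble hundreds of times.
The solver here is the standard coordinate-descent scheme for penalised
GLMs: an outer IRLS loop builds a weighted least-squares approximation of
the logistic loss, and an inner cyclic coordinate-descent loop with
soft-thresholding solves the weighted lasso, restricted to the active set
between full sweeps.  Successive penalties are warm-started from the
previous solution, so a whole path costs little more than a single fit.

Objective (penalty ``lam``, intercept unpenalised)::

    (1/n) * sum_i log(1 + exp(-t_i * (w0 + x_i.w))) + lam * ||w||_1

with t_i = 2*y_i - 1.  The default penalty grid runs from ``lam_max`` (the
smallest penalty with an all-zero solution) down three decades, log-spaced.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "logistic_lasso_path",
    "logistic_lasso_cv",
    "lambda_grid",
    "lambda_max",
    "binomial_deviance",
]

_PMIN = 1e-5


@njit(cache=False, fastmath=True)
def _inner_cd(X, v, xv, r, w, w0, lam, tol, max_epochs):
    """Cyclic coordinate descent for the weighted lasso subproblem.

    Minimises (1/2n) sum v_i (z_i - w0 - x_i.w)^2 + lam ||w||_1; the
    working residual r = z - w0 - X w is maintained in place.  xv holds the
    precomputed weighted column norms sum_i v_i x_ij^2 / n.
    """
    n, p = X.shape
    active = np.zeros(p, dtype=np.bool_)
    for j in range(p):
        active[j] = w[j] != 0.0
    vsum = 0.0
    for i in range(n):
        vsum += v[i]
    full_sweep = True
    for _ in range(max_epochs):
        max_change = 0.0
        # unpenalised intercept
        num = 0.0
        for i in range(n):
            num += v[i] * r[i]
        d0 = num / vsum
        if d0 != 0.0:
            w0 += d0
            for i in range(n):
                r[i] -= d0
            max_change = abs(d0)
        for j in range(p):
            if not (full_sweep or active[j]):
                continue
            if xv[j] <= 0.0:
                continue
            gj = 0.0
            for i in range(n):
                gj += v[i] * X[i, j] * r[i]
            gj = gj / n + xv[j] * w[j]
            if gj > lam:
                new = (gj - lam) / xv[j]
            elif gj < -lam:
                new = (gj + lam) / xv[j]
            else:
                new = 0.0
            d = new - w[j]
            if d != 0.0:
                w[j] = new
                active[j] = new != 0.0
                for i in range(n):
                    r[i] -= d * X[i, j]
                if abs(d) > max_change:
                    max_change = abs(d)
        if max_change < tol:
            if full_sweep:
                break
            full_sweep = True  # converged on active set: verify with a full sweep
        else:
            full_sweep = False
    return w0


@njit(cache=False, fastmath=True)
def _fit_single(X, y, w, w0, lam, tol, max_outer, max_epochs):
    """One IRLS fit at a single penalty, warm-started from (w, w0) in place."""
    n, p = X.shape
    eta = np.empty(n)
    v = np.empty(n)
    r = np.empty(n)
    xv = np.empty(p)
    for _ in range(max_outer):
        for i in range(n):
            eta[i] = w0
        for j in range(p):
            wj = w[j]
            if wj != 0.0:
                for i in range(n):
                    eta[i] += X[i, j] * wj
        for i in range(n):
            pr = 1.0 / (1.0 + np.exp(-eta[i]))
            if pr < _PMIN:
                pr = _PMIN
            elif pr > 1.0 - _PMIN:
                pr = 1.0 - _PMIN
            vi = pr * (1.0 - pr)
            v[i] = vi
            r[i] = (y[i] - pr) / vi  # working residual about current eta
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += v[i] * X[i, j] * X[i, j]
            xv[j] = s / n
        w_old0 = w0
        w_old = w.copy()
        w0 = _inner_cd(X, v, xv, r, w, w0, lam, tol, max_epochs)
        delta = abs(w0 - w_old0)
        for j in range(p):
            d = abs(w[j] - w_old[j])
            if d > delta:
                delta = d
        if delta < tol:
            break
    return w0


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the lasso solution is all-zero.

    At the intercept-only solution p_i = mean(y) the KKT conditions give
    lam_max = max_j |x_j . (y - ybar)| / n.
    """
    resid = y - y.mean()
    return float(np.max(np.abs(X.T @ resid)) / len(y))


def lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    n_lambdas: int = 30,
    lambda_min_ratio: float = 1e-3,
) -> np.ndarray:
    """Log-spaced decreasing penalty grid from lambda_max down the stated ratio."""
    lmax = lambda_max(X, y)
    if lmax <= 0:
        raise ValueError("degenerate design: lambda_max is zero")
    return np.geomspace(lmax, lmax * lambda_min_ratio, n_lambdas)


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be coded 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return y


def logistic_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray | None = None,
    n_lambdas: int = 30,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-5,
    max_outer: int = 30,
    max_epochs: int = 500,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit the L1 logistic path over a decreasing penalty grid.

    Parameters
    ----------
    X : (n, p) float array of features; standardise columns before calling
        so the penalty treats them comparably.
    y : (n,) array of {0, 1} labels; both classes must be present.
    lambdas : optional explicit decreasing penalty grid; defaults to
        :func:`lambda_grid`.

    Returns
    -------
    lambdas, coefs (L, p), intercepts (L,)
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = _check_labels(y)
    if lambdas is None:
        lambdas = lambda_grid(X, y, n_lambdas, lambda_min_ratio)
    else:
        lambdas = np.asarray(lambdas, dtype=np.float64)
        if np.any(np.diff(lambdas) > 0):
            raise ValueError("penalty grid must be decreasing")
    L = len(lambdas)
    coefs = np.zeros((L, X.shape[1]))
    intercepts = np.zeros(L)
    w = np.zeros(X.shape[1])
    w0 = float(np.log(y.mean() / (1.0 - y.mean())))
    for k in range(L):
        w0 = _fit_single(X, y, w, w0, float(lambdas[k]), tol, max_outer, max_epochs)
        coefs[k] = w
        intercepts[k] = w0
    return lambdas, coefs, intercepts


def binomial_deviance(y: np.ndarray, prob: np.ndarray) -> float:
    """Mean binomial deviance, -2/n * log-likelihood, with clipped probabilities."""
    p = np.clip(prob, _PMIN, 1 - _PMIN)
    y = np.asarray(y, dtype=float)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def logistic_lasso_cv(
    X: np.ndarray,
    y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    n_lambdas: int = 30,
    lambda_min_ratio: float = 1e-3,
    patience: int = 5,
    tol: float = 1e-5,
    max_outer: int = 30,
    max_epochs: int = 500,
) -> tuple[float, np.ndarray, float, np.ndarray, np.ndarray]:
    """Select the penalty by cross-validated deviance and refit on all rows.

    The penalty grid is walked from the sparse end downwards, warm-starting
    every fold's solution; walking stops early once the mean held-out
    deviance has not improved for `patience` consecutive grid points, since
    deviance curves along the path are effectively unimodal and the deep,
    dense end is by far the most expensive to fit.  Ties prefer the larger
    penalty (the sparser model).

    Parameters
    ----------
    folds : list of (train_idx, test_idx) index pairs into the rows of X.

    Returns
    -------
    chosen_lambda, coef (p,), intercept, mean_cv_deviance (over the walked
    prefix of the grid), lambdas (full grid).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = _check_labels(y)
    lambdas = lambda_grid(X, y, n_lambdas, lambda_min_ratio)
    p = X.shape[1]
    states = []
    for tr, _ in folds:
        ytr = y[tr]
        if ytr.min() == ytr.max():
            raise ValueError("a cross-validation fold lost one class entirely")
        w0 = float(np.log(ytr.mean() / (1.0 - ytr.mean())))
        states.append((np.ascontiguousarray(X[tr]), ytr, np.zeros(p), w0))
    mean_dev = []
    for k in range(len(lambdas)):
        lam = float(lambdas[k])
        dev = 0.0
        for f, (tr, te) in enumerate(folds):
            Xtr, ytr, w, w0 = states[f]
            w0 = _fit_single(Xtr, ytr, w, w0, lam, tol, max_outer, max_epochs)
            states[f] = (Xtr, ytr, w, w0)
            prob = 1.0 / (1.0 + np.exp(-(w0 + X[te] @ w)))
            dev += binomial_deviance(y[te], prob)
        mean_dev.append(dev / len(folds))
        if k - int(np.argmin(mean_dev)) >= patience:
            break
    mean_dev = np.asarray(mean_dev)
    best = int(np.argmin(mean_dev))  # first minimum = largest penalty on ties
    chosen = float(lambdas[best])
    # refit on all rows, warm-starting down the path to the chosen penalty
    w = np.zeros(p)
    w0 = float(np.log(y.mean() / (1.0 - y.mean())))
    for k in range(best + 1):
        w0 = _fit_single(X, y, w, w0, float(lambdas[k]), tol, max_outer, max_epochs)
    return chosen, w, float(w0), mean_dev, lambdas
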