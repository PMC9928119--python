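"""Numerical core: L1-penalized and unpenalized logistic regression.

The penalized objective is

    J(b0, b) = (1/n) * sum_i [ log(1 + exp(eta_i)) - y_i * eta_i ] + lam * ||b||_1,

with ``eta = b0 + X b`` and the intercept unpenalized.  It is minimized by a
proximal-Newton scheme: each outer iteration forms the iteratively-reweighted
least-squares quadratic at the current point and solves the resulting
weighted lasso by cyclic coordinate descent with soft-thresholding, which
yields exactly-zero coefficients.  Warm starts across a decreasing penalty
grid make whole solution paths cheap, which the cross-validation and
bootstrap layers rely on.

The inner kernels are numba-compiled; the first call in a process pays the
JIT cost.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "logistic_objective",
    "fit_l1_logistic",
    "lasso_path",
    "lambda_max",
    "fit_logistic_mle",
    "mean_deviance",
]

_P_CLIP = 1e-9


@njit(cache=True)
def _objective(X, y, beta0, beta, lam):
    n = X.shape[0]
    eta = X @ beta
    nll = 0.0
    for i in range(n):
        e = beta0 + eta[i]
        if e > 0.0:
            nll += e + np.log1p(np.exp(-e)) - y[i] * e
        else:
            nll += np.log1p(np.exp(e)) - y[i] * e
    pen = 0.0
    for j in range(beta.shape[0]):
        pen += abs(beta[j])
    return nll / n + lam * pen


@njit(cache=True)
def _sweep(X, w, z, r, beta, coords, lam, n):
    """One coordinate-descent pass over the listed coordinates (in place).

    Returns the largest absolute coefficient change of the pass.
    """
    dmax = 0.0
    for idx in range(coords.shape[0]):
        j = coords[idx]
        bj = beta[j]
        rho = 0.0
        vj = 0.0
        for i in range(n):
            xij = X[i, j]
            rho += w[i] * xij * (r[i] + xij * bj)
            vj += w[i] * xij * xij
        rho /= n
        vj /= n
        if vj <= 0.0:
            new = 0.0
        elif rho > lam:
            new = (rho - lam) / vj
        elif rho < -lam:
            new = (rho + lam) / vj
        else:
            new = 0.0
        d = new - bj
        if d != 0.0:
            beta[j] = new
            for i in range(n):
                r[i] -= X[i, j] * d
            if abs(d) > dmax:
                dmax = abs(d)
    return dmax


@njit(cache=True)
def _cd_weighted(X, w, z, beta0, beta, lam, tol, max_sweeps):
    """Cyclic coordinate descent on the weighted-lasso subproblem.

    Minimizes (1/(2n)) sum_i w_i (z_i - b0 - x_i b)^2 + lam ||b||_1 in place;
    returns the updated intercept.  After each full pass, iteration is
    restricted to the active (nonzero) set until it stabilizes — the
    standard lasso speed trick, exact because a converged active-set
    solution is re-checked by the next full pass.
    """
    n, p = X.shape
    r = z - beta0 - X @ beta
    wsum = w.sum()
    all_coords = np.arange(p)
    for _ in range(max_sweeps):
        # intercept (unpenalized)
        num = 0.0
        for i in range(n):
            num += w[i] * r[i]
        d0 = num / wsum
        beta0 += d0
        for i in range(n):
            r[i] -= d0
        dmax = _sweep(X, w, z, r, beta, all_coords, lam, n)
        if dmax < tol and abs(d0) < tol:
            break
        active = np.flatnonzero(beta)
        if active.shape[0] == 0:
            continue
        for _ in range(max_sweeps):
            num = 0.0
            for i in range(n):
                num += w[i] * r[i]
            d0 = num / wsum
            beta0 += d0
            for i in range(n):
                r[i] -= d0
            dmax = _sweep(X, w, z, r, beta, active, lam, n)
            if dmax < tol and abs(d0) < tol:
                break
    return beta0


@njit(cache=True)
def _fit_l1_core(X, y, lam, beta0, beta, tol, max_outer):
    n = X.shape[0]
    p = beta.shape[0]
    w = np.empty(n)
    z = np.empty(n)
    b_old = np.empty(p)
    obj = _objective(X, y, beta0, beta, lam)
    for _ in range(max_outer):
        eta = X @ beta
        for i in range(n):
            e = beta0 + eta[i]
            pi = 1.0 / (1.0 + np.exp(-e))
            if pi < _P_CLIP:
                pi = _P_CLIP
            elif pi > 1.0 - _P_CLIP:
                pi = 1.0 - _P_CLIP
            wi = pi * (1.0 - pi)
            w[i] = wi
            z[i] = e + (y[i] - pi) / wi
        b0_old = beta0
        for j in range(p):
            b_old[j] = beta[j]
        beta0 = _cd_weighted(X, w, z, beta0, beta, lam, 1e-12, 2000)
        new_obj = _objective(X, y, beta0, beta, lam)
        if new_obj > obj + 1e-12 * (1.0 + abs(obj)):
            # quadratic model overshot (rare, near machine precision):
            # damped step on the proximal-Newton direction
            t = 0.5
            best_obj = obj
            best_t = 0.0
            d0 = beta0 - b0_old
            while t > 1e-6:
                cand_obj = _objective_damped(X, y, b0_old, b_old, beta, d0, t, lam)
                if cand_obj < best_obj:
                    best_obj = cand_obj
                    best_t = t
                    break
                t *= 0.5
            if best_t == 0.0:
                beta0 = b0_old
                for j in range(p):
                    beta[j] = b_old[j]
                break
            beta0 = b0_old + best_t * d0
            for j in range(p):
                beta[j] = b_old[j] + best_t * (beta[j] - b_old[j])
            new_obj = best_obj
        if abs(obj - new_obj) < tol * (1.0 + abs(new_obj)):
            obj = new_obj
            break
        obj = new_obj
    return beta0


@njit(cache=True)
def _objective_damped(X, y, b0_old, b_old, b_new, d0, t, lam):
    p = b_old.shape[0]
    cand = np.empty(p)
    for j in range(p):
        cand[j] = b_old[j] + t * (b_new[j] - b_old[j])
    return _objective(X, y, b0_old + t * d0, cand, lam)


def logistic_objective(
    X: np.ndarray, y: np.ndarray, beta0: float, beta: np.ndarray, lam: float
) -> float:
    """Penalized mean negative log-likelihood at (beta0, beta)."""
    return float(
        _objective(
            np.asfortranarray(X, dtype=np.float64),
            np.ascontiguousarray(y, dtype=np.float64),
            float(beta0),
            np.ascontiguousarray(beta, dtype=np.float64),
            float(lam),
        )
    )


def fit_l1_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    beta0_init: float = 0.0,
    beta_init: np.ndarray | None = None,
    tol: float = 1e-11,
    max_outer: int = 200,
) -> tuple[float, np.ndarray]:
    """Fit the L1-penalized logistic model; returns ``(beta0, beta)``.

    ``X`` should already be standardized if coefficients are to be comparable
    across features.  Coefficients shrunk out by the penalty are exactly 0.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    X = np.asfortranarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    beta = (
        np.zeros(X.shape[1])
        if beta_init is None
        else np.ascontiguousarray(beta_init, dtype=np.float64).copy()
    )
    beta0 = _fit_l1_core(X, y, float(lam), float(beta0_init), beta, tol, max_outer)
    return float(beta0), beta


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which all slopes are zero (KKT bound at beta = 0
    with the intercept at the class-frequency logit)."""
    y = np.asarray(y, dtype=np.float64)
    pbar = y.mean()
    grad = X.T @ (y - pbar) / len(y)
    return float(np.abs(grad).max())


def default_lambda_grid(
    X: np.ndarray, y: np.ndarray, n_lambdas: int = 50, min_ratio: float | None = None
) -> np.ndarray:
    """Geometric penalty grid from lambda_max down, decreasing."""
    lmax = lambda_max(X, y)
    if lmax <= 0:
        lmax = 1e-3
    if min_ratio is None:
        min_ratio = 0.01 if X.shape[0] < X.shape[1] else 1e-4
    return np.geomspace(lmax, lmax * min_ratio, n_lambdas)


def lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-11,
) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started solution path along a decreasing penalty grid.

    Returns ``(beta0s, betas)`` with ``betas`` of shape ``(len(lambdas), p)``.
    """
    lambdas = np.asarray(lambdas, dtype=np.float64)
    if len(lambdas) > 1 and not np.all(np.diff(lambdas) < 0):
        raise ValueError("lambda grid must be strictly decreasing")
    X = np.asfortranarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    p = X.shape[1]
    beta0s = np.empty(len(lambdas))
    betas = np.empty((len(lambdas), p))
    b0 = float(np.log(y.mean() / (1 - y.mean()))) if 0 < y.mean() < 1 else 0.0
    b = np.zeros(p)
    for k, lam in enumerate(lambdas):
        b0 = _fit_l1_core(X, y, float(lam), b0, b, tol, 200)
        beta0s[k] = b0
        betas[k] = b
    return beta0s, betas


def fit_logistic_mle(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
    ridge: float = 1e-10,
) -> tuple[float, np.ndarray]:
    """Unpenalized logistic MLE by Newton–Raphson (IRLS).

    A vanishing ridge keeps the Hessian solvable; on (quasi-)separable data
    iterations are capped, which saturates predictions without failing.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    Z = np.column_stack([np.ones(n), X])
    theta = np.zeros(p + 1)
    pbar = y.mean()
    if 0 < pbar < 1:
        theta[0] = np.log(pbar / (1 - pbar))
    for _ in range(max_iter):
        eta = Z @ theta
        prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        prob = np.clip(prob, _P_CLIP, 1 - _P_CLIP)
        grad = Z.T @ (y - prob) / n
        if np.abs(grad).max() < tol:
            break
        w = prob * (1 - prob)
        H = (Z * w[:, None]).T @ Z / n + ridge * np.eye(p + 1)
        step = np.linalg.solve(H, grad)
        # damped Newton: halve until the log-likelihood does not decrease
        ll_old = float(y @ eta - np.logaddexp(0, eta).sum())
        t = 1.0
        while t > 1e-8:
            cand = theta + t * step
            eta_c = Z @ cand
            ll_new = float(y @ eta_c - np.logaddexp(0, eta_c).sum())
            if ll_new >= ll_old - 1e-12:
                break
            t *= 0.5
        theta = theta + t * step
    return float(theta[0]), theta[1:]


def mean_deviance(y: np.ndarray, prob: np.ndarray) -> float:
    """Mean binomial deviance, -2 * mean log-likelihood."""
    prob = np.clip(np.asarray(prob, dtype=np.float64), _P_CLIP, 1 - _P_CLIP)
    y = np.asarray(y, dtype=np.float64)
    return float(-2.0 * np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))
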