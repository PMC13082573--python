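"""Coordinate-descent solvers used by the nuisance models.

Two primitives:

* :func:`penalized_logistic` — weighted logistic regression with
  per-coefficient L1 penalty factors and optional L2 term, solved by IRLS
  with cyclic coordinate descent on the working quadratic (glmnet-style).
  The intercept is never penalized.
* :func:`penalized_quadratic` — minimize ``0.5 b'Db - d'b + sum_j lam1_j
  |b_j| + 0.5 lam2_j b_j^2`` by cyclic coordinate descent; this is the
  penalized form of the Lin-Ying least-squares estimating equations.

Objectives are written per-unit-weight (logistic loss divided by the total
observation weight) so penalty levels are comparable across sample sizes.
"""

from __future__ import annotations

import numpy as np

MAX_ABS_COEF = 30.0  # on a standardized design; beyond this we call it separation


class SeparationError(RuntimeError):
    """Perfect separation: deviance collapsing with unbounded coefficients."""


class SingularDesignError(RuntimeError):
    """The quadratic system matrix is singular for the unpenalized columns."""


def soft_threshold(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def _cd_quadratic(D, d, lam1, lam2, b0, tol=1e-12, max_iter=10000):
    """Cyclic CD for 0.5 b'Db - d'b + lam1'|b| + 0.5 lam2'b^2 (vector lams)."""
    p = len(d)
    b = b0.copy()
    Db = D @ b
    diag = np.diag(D)
    dead = (diag <= 0) & (lam2 <= 0)
    if np.any(dead & (lam1 <= 0)):
        j = int(np.flatnonzero(dead & (lam1 <= 0))[0])
        raise SingularDesignError(
            f"zero curvature for coefficient {j}; add penalty or prune columns"
        )
    live = np.flatnonzero(~dead)  # penalized zero-curvature coords stay at 0
    b[dead] = 0.0
    for _ in range(max_iter):
        max_delta = 0.0
        for j in live:
            bj_old = b[j]
            # partial residual gradient excluding j's own contribution
            z = d[j] - (Db[j] - diag[j] * bj_old)
            bj_new = soft_threshold(z, lam1[j]) / (diag[j] + lam2[j])
            if bj_new != bj_old:
                delta = bj_new - bj_old
                Db += D[:, j] * delta
                b[j] = bj_new
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            break
    return b


def penalized_quadratic(
    D: np.ndarray,
    d: np.ndarray,
    lam1: np.ndarray,
    lam2: np.ndarray | float = 0.0,
    b_init: np.ndarray | None = None,
    tol: float = 1e-12,
) -> np.ndarray:
    """Solve the penalized quadratic program (see module docstring)."""
    D = np.asarray(D, dtype=float)
    d = np.asarray(d, dtype=float)
    p = len(d)
    lam1 = np.broadcast_to(np.asarray(lam1, dtype=float), (p,)).copy()
    lam2 = np.broadcast_to(np.asarray(lam2, dtype=float), (p,)).copy()
    b0 = np.zeros(p) if b_init is None else np.asarray(b_init, dtype=float).copy()
    return _cd_quadratic(D, d, lam1, lam2, b0, tol=tol)


def penalized_logistic(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    lam1: np.ndarray | float = 0.0,
    lam2: np.ndarray | float = 0.0,
    coef_init: np.ndarray | None = None,
    intercept_init: float = 0.0,
    tol: float = 1e-9,
    max_irls: int = 100,
    check_separation: bool = True,
) -> tuple[float, np.ndarray]:
    """Weighted L1/L2-penalized logistic regression; returns (intercept, coef).

    Minimizes ``(1/W) sum_i w_i [log(1 + e^eta_i) - y_i eta_i]
    + sum_j lam1_j |b_j| + 0.5 sum_j lam2_j b_j^2`` with W the total weight.
    ``lam1``/``lam2`` broadcast per coefficient; the intercept is free.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    W = w.sum()
    if W <= 0:
        raise ValueError("total observation weight must be positive")
    lam1 = np.broadcast_to(np.asarray(lam1, dtype=float), (p,)).copy()
    lam2 = np.broadcast_to(np.asarray(lam2, dtype=float), (p,)).copy()
    b = np.zeros(p) if coef_init is None else np.asarray(coef_init, dtype=float).copy()
    b0 = float(intercept_init)

    newton = not np.any(lam1 > 0)  # no L1 term: solve each IRLS step exactly
    cols = [np.ascontiguousarray(X[:, j]) for j in range(p)]
    all_idx = np.arange(p)
    dev_prev = np.inf
    for _ in range(max_irls):
        eta = b0 + X @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        s = np.maximum(mu * (1.0 - mu), 1e-5)
        z = eta + (y - mu) / s
        sw = w * s / W  # quadratic weights, normalized
        sw_sum = sw.sum()

        if newton:
            G = np.column_stack([np.ones(n), X])
            M = (G * sw[:, None]).T @ G + np.diag(np.r_[0.0, lam2])
            rhs = (G * sw[:, None]).T @ z
            try:
                sol = np.linalg.solve(M, rhs)
            except np.linalg.LinAlgError:
                sol = np.linalg.lstsq(M, rhs, rcond=None)[0]
            b0, b = float(sol[0]), sol[1:]
            eta_new = b0 + X @ b
            if np.max(np.abs(eta_new - eta)) < tol:
                break
            dev = 2.0 * np.sum(w * (np.logaddexp(0.0, eta_new) - y * eta_new)) / W
            pen = 0.5 * np.sum(lam2 * b * b)
            if dev_prev - (dev + pen) < 1e-9 * (1.0 + abs(dev + pen)):
                break
            dev_prev = dev + pen
            if np.max(np.abs(b), initial=abs(b0)) > MAX_ABS_COEF:
                break
            continue

        # coordinate descent on the working least squares, with an
        # active-set strategy: full sweeps only to refresh the active set
        xtx = sw @ (X * X)  # per-column curvature
        r = z - eta  # working residual at current coefficients

        def sweep(idx) -> float:
            nonlocal b0, r
            max_delta = (sw @ r) / sw_sum
            if max_delta != 0.0:
                b0 += max_delta
                r -= max_delta
                max_delta = abs(max_delta)
            for j in idx:
                xj = cols[j]
                g = sw @ (xj * r) + xtx[j] * b[j]
                denom = xtx[j] + lam2[j]
                bj_new = soft_threshold(g, lam1[j]) / denom if denom > 0 else 0.0
                if bj_new != b[j]:
                    delta = bj_new - b[j]
                    r -= xj * delta
                    b[j] = bj_new
                    max_delta = max(max_delta, abs(delta))
            return max_delta

        # the working quadratic need not be solved exactly: a few active-set
        # rounds per IRLS step suffice for outer convergence
        inner_tol = max(tol * 0.1, 1e-10)
        for _ in range(10):
            if sweep(all_idx) < inner_tol:
                break
            active = np.flatnonzero(b != 0.0)
            if active.size:
                for _ in range(20):
                    if sweep(active) < inner_tol:
                        break

        eta_new = b0 + X @ b
        if np.max(np.abs(eta_new - eta)) < tol:
            break
        # penalized deviance plateau: catches quasi-separated fits whose
        # coefficients drift while the fit itself has converged
        dev = 2.0 * np.sum(w * (np.logaddexp(0.0, eta_new) - y * eta_new)) / W
        pen = np.sum(lam1 * np.abs(b)) + 0.5 * np.sum(lam2 * b * b)
        if dev_prev - (dev + pen) < 1e-9 * (1.0 + abs(dev + pen)):
            break
        dev_prev = dev + pen
        if np.max(np.abs(b), initial=abs(b0)) > MAX_ABS_COEF:
            # a coefficient is running away (quasi-separation); predictions
            # are saturated, further IRLS refinement is pointless
            break

    if check_separation and np.all(lam1 == 0):
        eta = b0 + X @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        fitted_perfectly = np.max(np.abs(y - mu)) < 1e-4
        if fitted_perfectly and np.max(np.abs(b), initial=0.0) > 10.0:
            raise SeparationError(
                "perfect separation: deviance ~ 0 with unbounded coefficients; "
                "use a positive penalty floor"
            )
    return b0, b


def logistic_deviance(
    X: np.ndarray, y: np.ndarray, intercept: float, coef: np.ndarray,
    sample_weight: np.ndarray | None = None,
) -> float:
    """Mean weighted binomial deviance."""
    eta = intercept + X @ coef
    w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    # log(1 + e^eta) - y*eta, numerically stable
    ll = np.logaddexp(0.0, eta) - y * eta
    return float(2.0 * np.sum(w * ll) / np.sum(w))
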