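"""Nuisance models for the doubly robust estimators.

Four components, all fitted on the baseline design matrix:

* propensity model — adaptive-LASSO logistic regression of arm on
  covariates, predictions truncated away from 0 and 1;
* fixed-horizon outcome model — adaptive-LASSO logistic regression of the
  known 5-year status on (arm, covariates), arm unpenalized, rows weighted
  by inverse censoring probability;
* conditional survival model — Lin-Ying additive hazards regression
  ``lambda(t|A,X) = lambda0(t) + theta A + beta'X`` solved from the
  closed-form least-squares system with adaptive-LASSO shrinkage on the
  covariate block and a Breslow-type cumulative baseline;
* censoring model — Kaplan-Meier estimate of the last-encounter
  (censoring-time) survival function, evaluated with left limits.

Adaptive weights come from a ridge initial fit: ``w_j = 1 / |b_init_j|^gamma``;
the penalty level is chosen by K-fold cross-validation over a geometric
grid and can be frozen for bootstrap refits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from ehrcausal._solvers import (
    SeparationError,
    SingularDesignError,
    logistic_deviance,
    penalized_logistic,
    penalized_quadratic,
)

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

_WEIGHT_CAP = 1e8  # adaptive weight above which a coefficient is dead


class PositivityError(RuntimeError):
    """Censoring survival below the IPCW floor for a weighted subject."""


__all__ = [
    "AdaptiveLassoSpec",
    "PropensityModel",
    "OutcomeLogisticModel",
    "AdditiveHazardsModel",
    "CensoringModel",
    "NuisanceBundle",
    "PositivityError",
    "SeparationError",
    "SingularDesignError",
    "fit_adaptive_lasso_logistic",
    "fit_propensity",
    "fit_outcome_logistic",
    "fit_additive_hazards",
    "fit_censoring_km",
    "fit_nuisances",
]


@dataclass
class AdaptiveLassoSpec:
    """Tuning contract shared by all penalized nuisance fits."""

    gamma: float = 1.0
    ridge_alpha: float = 1e-2
    n_lambda: int = 20
    lambda_min_ratio: float = 1e-4
    cv_folds: int = 10
    cv_rule: str = "min"  # "min" (minimum deviance) or "1se"
    seed: int = 0
    eps_truncation: float = 0.01
    ipcw_floor: float = 0.05
    penalize_treatment: bool = False
    arm_specific_censoring: bool = False
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.lambda_min_ratio > 1e-3:
            raise ValueError("penalty grid must span at least 3 orders of magnitude")
        if not 0 <= self.eps_truncation < 0.5:
            raise ValueError("eps_truncation must be in [0, 0.5)")
        if self.cv_rule not in ("min", "1se"):
            raise ValueError("cv_rule must be 'min' or '1se'")


def _standardize(X: np.ndarray, sample_weight: np.ndarray | None = None):
    """Weighted column standardization; constant columns get sd=inf (dead)."""
    w = np.ones(len(X)) if sample_weight is None else sample_weight
    w = w / w.sum()
    mu = w @ X
    var = w @ (X - mu) ** 2
    sd = np.sqrt(var)
    dead = sd < 1e-12
    sd_safe = np.where(dead, np.inf, sd)
    return (X - mu) / sd_safe, mu, sd_safe


def _lambda_grid(lam_max: float, spec: AdaptiveLassoSpec) -> np.ndarray:
    lam_max = max(lam_max, 1e-10)
    return np.geomspace(lam_max, lam_max * spec.lambda_min_ratio, spec.n_lambda)


def _canonical_order(*arrays: np.ndarray) -> np.ndarray:
    """Row order determined by data values only (invariant to input order)."""
    keys = []
    for a in arrays:
        a = np.asarray(a, dtype=float)
        if a.ndim == 1:
            keys.append(a)
        else:
            keys.extend(a.T)
    return np.lexsort(keys[::-1])


def _select_lambda(cv_total: np.ndarray, fold_vals: np.ndarray, spec: AdaptiveLassoSpec) -> int:
    """Grid index of the selected penalty: CV minimum, or 1-SE if requested.

    The grid is ordered from the largest penalty down, so under "1se" the
    first index within one standard error of the minimum is the most
    parsimonious qualifying model.
    """
    k_min = int(np.argmin(cv_total))
    if spec.cv_rule == "min":
        return k_min
    se = fold_vals[:, k_min].std(ddof=1) / np.sqrt(fold_vals.shape[0])
    mean = fold_vals.mean(axis=0)
    qualifying = np.flatnonzero(mean <= mean[k_min] + se)
    return int(qualifying[0])


def _cv_folds(n: int, k: int, seed: int, order: np.ndarray | None = None) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n) if order is None else np.asarray(order)[rng.permutation(n)]
    return [idx[i::k] for i in range(k)]


@dataclass
class LogisticLassoFit:
    intercept: float
    coef: np.ndarray  # on the original covariate scale
    lambda_: float
    deviance: float

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = self.intercept + np.asarray(X, dtype=float) @ self.coef
        return 1.0 / (1.0 + np.exp(-eta))


def fit_adaptive_lasso_logistic(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    spec: AdaptiveLassoSpec | None = None,
    unpenalized: tuple[int, ...] = (),
    lambda_fixed: float | None = None,
    warm_fit: "LogisticLassoFit | None" = None,
) -> LogisticLassoFit:
    """Adaptive-LASSO logistic regression with CV penalty selection.

    Columns are standardized internally; coefficients are reported on the
    original scale and the intercept is unpenalized.  ``unpenalized`` marks
    column indices exempt from the L1 penalty (e.g. the treatment term).
    ``lambda_fixed`` skips cross-validation (bootstrap refits).
    """
    spec = spec or AdaptiveLassoSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < spec.cv_folds:
        raise ValueError(f"n={n} smaller than cv_folds={spec.cv_folds}")
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)

    Xs, mu, sd = _standardize(X, w)
    pen_mask = np.ones(p, dtype=bool)
    pen_mask[list(unpenalized)] = False

    # ridge initial estimator for the adaptive weights
    b0_init, b_init = penalized_logistic(
        Xs, y, w, lam1=0.0, lam2=np.full(p, spec.ridge_alpha),
        check_separation=False, tol=spec.tol,
    )
    aw = np.where(
        pen_mask,
        1.0 / np.maximum(np.abs(b_init), 1e-300) ** spec.gamma,
        0.0,
    )
    aw = np.minimum(aw, _WEIGHT_CAP)

    if lambda_fixed is None:
        ybar = (w @ y) / w.sum()
        score = np.abs((w * (y - ybar)) @ Xs) / w.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(pen_mask & (aw > 0), score / aw, 0.0)
        grid = _lambda_grid(float(np.max(ratio)) * 1.05, spec)
        folds = _cv_folds(n, spec.cv_folds, spec.seed, order=_canonical_order(y, X))
        cv_dev = np.zeros(len(grid))
        fold_dev = np.zeros((len(folds), len(grid)))
        for fi, holdout in enumerate(folds):
            mask = np.ones(n, dtype=bool)
            mask[holdout] = False
            # adaptive weights recomputed on the training fold only, so the
            # validation deviance is not contaminated by full-data weights
            _, b_init_f = penalized_logistic(
                Xs[mask], y[mask], w[mask], lam1=0.0,
                lam2=np.full(p, spec.ridge_alpha), check_separation=False,
            )
            aw_f = np.where(
                pen_mask, 1.0 / np.maximum(np.abs(b_init_f), 1e-300) ** spec.gamma, 0.0
            )
            aw_f = np.minimum(aw_f, _WEIGHT_CAP)
            bi, b = 0.0, np.zeros(p)
            for k, lam in enumerate(grid):
                bi, b = penalized_logistic(
                    Xs[mask], y[mask], w[mask], lam1=lam * aw_f, coef_init=b,
                    intercept_init=bi, check_separation=False,
                )
                dev_k = logistic_deviance(Xs[holdout], y[holdout], bi, b, w[holdout])
                fold_dev[fi, k] = dev_k
                cv_dev[k] += dev_k * len(holdout)
        lam_star = float(grid[_select_lambda(cv_dev, fold_dev, spec)])
        path = grid[grid >= lam_star]
    else:
        lam_star = float(lambda_fixed)
        path = np.asarray([lam_star])

    bi, b = 0.0, np.zeros(p)
    if warm_fit is not None and len(warm_fit.coef) == p:
        # map an original-scale solution onto this sample's standardization
        finite = np.isfinite(sd)
        b = np.zeros(p)
        b[finite] = warm_fit.coef[finite] * sd[finite]
        bi = warm_fit.intercept + float(np.sum(warm_fit.coef[finite] * mu[finite]))
    for lam in path:
        bi, b = penalized_logistic(
            Xs, y, w, lam1=lam * aw, coef_init=b, intercept_init=bi,
            check_separation=(lam == 0.0), tol=spec.tol,
        )
    if lam_star == 0.0 or np.all(aw[pen_mask] == 0):
        # fully unpenalized limit: run the separation check
        bi, b = penalized_logistic(Xs, y, w, lam1=0.0, coef_init=b, intercept_init=bi)
    coef = b / sd
    intercept = bi - float((b * mu / sd).sum())
    dev = logistic_deviance(X, y, intercept, coef, w)
    return LogisticLassoFit(intercept=float(intercept), coef=coef, lambda_=lam_star, deviance=dev)


@dataclass
class PropensityModel:
    fit: LogisticLassoFit
    eps: float

    @property
    def lambda_(self) -> float:
        return self.fit.lambda_

    def predict(self, X: np.ndarray) -> np.ndarray:
        """P(A=1 | X), truncated to [eps, 1-eps]."""
        return np.clip(self.fit.predict_proba(X), self.eps, 1.0 - self.eps)


@dataclass
class OutcomeLogisticModel:
    fit: LogisticLassoFit  # design is [A, X]

    @property
    def lambda_(self) -> float:
        return self.fit.lambda_

    def predict(self, X: np.ndarray, a: int) -> np.ndarray:
        """m_a(x) = P(Y=1 | A=a, X=x)."""
        Z = np.column_stack([np.full(len(X), float(a)), np.asarray(X, dtype=float)])
        return self.fit.predict_proba(Z)


def _check_arms(A: np.ndarray, minimum: int) -> None:
    n1 = int(A.sum())
    if n1 < minimum or len(A) - n1 < minimum:
        raise ValueError(f"each arm needs at least {minimum} subjects (got {len(A) - n1} / {n1})")


def fit_propensity(
    X: np.ndarray, A: np.ndarray, spec: AdaptiveLassoSpec | None = None,
    lambda_fixed: float | None = None, warm: PropensityModel | None = None,
) -> PropensityModel:
    spec = spec or AdaptiveLassoSpec()
    _check_arms(np.asarray(A), spec.cv_folds)
    fit = fit_adaptive_lasso_logistic(
        X, A, spec=spec, lambda_fixed=lambda_fixed,
        warm_fit=warm.fit if warm is not None else None,
    )
    return PropensityModel(fit=fit, eps=spec.eps_truncation)


def fit_outcome_logistic(
    X: np.ndarray,
    A: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    spec: AdaptiveLassoSpec | None = None,
    lambda_fixed: float | None = None,
    warm: OutcomeLogisticModel | None = None,
) -> OutcomeLogisticModel:
    """Logistic outcome model on (A, X); the treatment column is unpenalized
    unless the spec says otherwise.  Callers restrict rows to subjects with
    known horizon status and pass IPCW weights."""
    spec = spec or AdaptiveLassoSpec()
    A = np.asarray(A, dtype=float)
    _check_arms(A, spec.cv_folds)
    Z = np.column_stack([A, np.asarray(X, dtype=float)])
    unpen = () if spec.penalize_treatment else (0,)
    fit = fit_adaptive_lasso_logistic(
        Z, y, sample_weight, spec=spec, unpenalized=unpen, lambda_fixed=lambda_fixed,
        warm_fit=warm.fit if warm is not None else None,
    )
    return OutcomeLogisticModel(fit=fit)


# ---------------------------------------------------------------------------
# Lin-Ying additive hazards
# ---------------------------------------------------------------------------


def _linying_system(Z: np.ndarray, U: np.ndarray, event: np.ndarray):
    """Closed-form least-squares system of the additive hazards model.

    ``D = (1/n) sum_i int_0^tau Y_i(t) (Z_i - Zbar(t)) (Z_i - Zbar(t))' dt``
    and ``d = (1/n) sum_i int_0^tau (Z_i - Zbar(t)) dN_i(t)``, with
    ``U = min(T, tau)`` in years and ``event`` marking dN jumps within the
    horizon.  Also returns the pieces needed for the Breslow baseline:
    interval grid, at-risk averages and event jumps.
    """
    n, p = Z.shape
    order = np.argsort(U, kind="stable")
    Us, Zs, es = U[order], Z[order], event[order].astype(bool)
    uu, first, inv = np.unique(Us, return_index=True, return_inverse=True)
    m = len(uu)
    widths = np.diff(np.concatenate([[0.0], uu]))
    S0 = (n - first).astype(float)

    if n * p * p <= 32_000_000:
        # vectorized suffix sums of Z and ZZ' over the at-risk sets
        S1_all = np.cumsum(Zs[::-1], axis=0)[::-1]
        S1 = S1_all[first]
        outer_all = np.cumsum((Zs[:, :, None] * Zs[:, None, :])[::-1], axis=0)[::-1]
        S2 = outer_all[first]
        zbars = S1 / S0[:, None]
        D = np.einsum("k,kij->ij", widths, S2) - np.einsum(
            "k,ki,kj->ij", widths / S0, S1, S1
        )
        d = (Zs[es] - zbars[inv[es]]).sum(axis=0)
        jumps = np.add.reduceat(es.astype(float), first) / S0
    else:
        D = np.zeros((p, p))
        d = np.zeros(p)
        S1 = np.zeros(p)
        S2 = np.zeros((p, p))
        jumps = np.zeros(m)
        zbars = np.zeros((m, p))
        # sweep unique times descending, growing the at-risk set
        for k in range(m - 1, -1, -1):
            lo = first[k]
            hi = first[k + 1] if k + 1 < m else n
            block = Zs[lo:hi]
            S1 += block.sum(axis=0)
            S2 += block.T @ block
            zbar = S1 / S0[k]
            zbars[k] = zbar
            D += widths[k] * (S2 - np.outer(S1, S1) / S0[k])
            ev = es[lo:hi]
            n_ev = int(ev.sum())
            if n_ev:
                jumps[k] = n_ev / S0[k]
                d += (block[ev] - zbar).sum(axis=0)
    return D / n, d / n, uu, widths, zbars, jumps


@dataclass
class AdditiveHazardsModel:
    """Fitted additive hazards model with Breslow-type baseline.

    ``theta`` (treatment) and ``beta`` (covariates) are hazard differences
    per person-year; the cumulative baseline is stored as knots
    ``(baseline_times, baseline_values)`` in years, nondecreasing.
    """

    theta: float
    beta: np.ndarray
    baseline_times: np.ndarray
    baseline_values: np.ndarray
    lambda_: float

    def cumulative_baseline(self, t_years: float) -> float:
        """Lambda0(t), linearly interpolated between knots, flat beyond."""
        return float(np.interp(t_years, self.baseline_times, self.baseline_values))

    def predict_survival(self, tau_years: float, a: int, X: np.ndarray) -> np.ndarray:
        """S(tau | a, x) = exp(-Lambda0(tau) - (theta a + beta'x) tau), clipped."""
        lin = (self.theta * a + np.asarray(X, dtype=float) @ self.beta) * tau_years
        s = np.exp(-self.cumulative_baseline(tau_years) - lin)
        n_clip = int(np.sum((s < 0) | (s > 1)))
        if n_clip > 0.01 * len(s):
            logger.info("additive-hazards survival clipped on %d of %d rows", n_clip, len(s))
        return np.clip(s, 0.0, 1.0)


def fit_additive_hazards(
    X: np.ndarray,
    A: np.ndarray,
    T_days: np.ndarray,
    delta: np.ndarray,
    spec: AdaptiveLassoSpec | None = None,
    tau_days: int | None = None,
    lambda_fixed: float | None = None,
    warm: AdditiveHazardsModel | None = None,
) -> AdditiveHazardsModel:
    """Fit the Lin-Ying model with adaptive-LASSO shrinkage on covariates.

    The treatment coefficient is unpenalized (unless the spec penalizes
    it); the penalty level minimizes the cross-validated quadratic loss
    ``0.5 b'D_val b - d_val'b``.  ``X`` may have zero columns, in which
    case the baseline reduces to the Nelson-Aalen estimator adjusted for
    treatment.
    """
    spec = spec or AdaptiveLassoSpec()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    A = np.asarray(A, dtype=float)
    T_days = np.asarray(T_days, dtype=float)
    delta = np.asarray(delta).astype(bool)
    n = len(A)
    if not np.all(T_days > 0):
        raise ValueError("follow-up times must be positive")
    if tau_days is None:
        tau_days = int(T_days.max())
    U = np.minimum(T_days, tau_days) / DAYS_PER_YEAR
    event = delta & (T_days <= tau_days)
    if not event.any():
        raise ValueError("no events within the horizon")

    Xs, mu, sd = _standardize(X)
    Z = np.column_stack([A, Xs]) if X.shape[1] else A[:, None]
    p = Z.shape[1]
    pen_mask = np.ones(p, dtype=bool)
    if not spec.penalize_treatment:
        pen_mask[0] = False

    D, d, uu, widths, zbars, jumps = _linying_system(Z, U, event.astype(float))

    # ridge initial estimator for adaptive weights
    try:
        b_init = np.linalg.solve(D + spec.ridge_alpha * np.diag(pen_mask.astype(float)), d)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError("Lin-Ying system singular; add penalty or prune columns") from exc
    aw = np.where(pen_mask, 1.0 / np.maximum(np.abs(b_init), 1e-300) ** spec.gamma, 0.0)
    aw = np.minimum(aw, _WEIGHT_CAP)

    if lambda_fixed is None and pen_mask.any() and X.shape[1]:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(pen_mask & (aw > 0), np.abs(d) / aw, 0.0)
        grid = _lambda_grid(float(np.max(ratio)) * 1.05, spec)
        folds = _cv_folds(n, spec.cv_folds, spec.seed,
                          order=_canonical_order(U, event, A, X))
        cv_loss = np.zeros(len(grid))
        fold_loss = np.zeros((len(folds), len(grid)))
        for fi, holdout in enumerate(folds):
            mask = np.ones(n, dtype=bool)
            mask[holdout] = False
            Dtr, dtr, *_ = _linying_system(Z[mask], U[mask], event[mask].astype(float))
            Dva, dva, *_ = _linying_system(Z[holdout], U[holdout], event[holdout].astype(float))
            # per-fold adaptive weights (no validation leakage)
            try:
                b_init_f = np.linalg.solve(
                    Dtr + spec.ridge_alpha * np.diag(pen_mask.astype(float)), dtr
                )
            except np.linalg.LinAlgError:
                b_init_f = b_init
            aw_f = np.where(
                pen_mask, 1.0 / np.maximum(np.abs(b_init_f), 1e-300) ** spec.gamma, 0.0
            )
            aw_f = np.minimum(aw_f, _WEIGHT_CAP)
            b = np.zeros(p)
            for k, lam in enumerate(grid):
                b = penalized_quadratic(Dtr, dtr, lam1=lam * aw_f, b_init=b)
                loss = 0.5 * b @ Dva @ b - dva @ b
                fold_loss[fi, k] = loss
                cv_loss[k] += loss
        lam_star = float(grid[_select_lambda(cv_loss, fold_loss, spec)])
    else:
        lam_star = float(lambda_fixed or 0.0)

    if warm is not None and len(warm.beta) == X.shape[1]:
        finite = np.isfinite(sd)
        scaled = np.zeros(len(warm.beta))
        scaled[finite] = warm.beta[finite] * sd[finite]
        warm_b = np.r_[warm.theta, scaled]
    else:
        warm_b = None
    b = penalized_quadratic(D, d, lam1=lam_star * aw, b_init=warm_b)

    theta = float(b[0])
    if X.shape[1]:
        beta = b[1:] / sd
        drift_shift = float(np.sum(b[1:] * mu / sd))
    else:
        beta = np.zeros(0)
        drift_shift = 0.0

    # Breslow baseline on the original covariate scale:
    # Lambda0(t) = sum_{events <= t} dNbar/S0 - int_0^t b'Zbar(s) ds,
    # with the standardization shift folded back in
    drift = zbars @ b + drift_shift
    cum = np.cumsum(jumps - widths * drift)
    times = np.concatenate([[0.0], uu])
    values = np.concatenate([[0.0], cum])
    mono = np.maximum.accumulate(values)
    if np.max(mono - values) > 1e-10:
        logger.info("Breslow baseline locally decreasing; isotonic correction applied "
                    "(max gap %.3g)", float(np.max(mono - values)))
    return AdditiveHazardsModel(
        theta=theta, beta=beta, baseline_times=times, baseline_values=mono,
        lambda_=lam_star,
    )


# ---------------------------------------------------------------------------
# Censoring Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class CensoringModel:
    """Product-limit estimate of the censoring-time survival K(t).

    Fitted on follow-up times with censoring (delta = 0) treated as the
    event of interest; observed outcome events act as censored observations
    of the censoring time.  ``evaluate_left`` returns K(t-) and enforces a
    positivity floor for subjects that receive weight.
    """

    knot_times: np.ndarray  # days, ascending
    knot_values: np.ndarray  # K immediately after each knot
    floor: float = 0.05

    def evaluate(self, t_days: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.knot_times, np.asarray(t_days, dtype=float), side="right")
        return np.where(idx == 0, 1.0, np.concatenate([[1.0], self.knot_values])[idx])

    def evaluate_left(self, t_days: np.ndarray, required: np.ndarray | None = None) -> np.ndarray:
        """K(t-): the product limit strictly before t."""
        t = np.asarray(t_days, dtype=float)
        idx = np.searchsorted(self.knot_times, t, side="left")
        K = np.concatenate([[1.0], self.knot_values])[idx]
        req = np.ones(len(t), dtype=bool) if required is None else np.asarray(required, dtype=bool)
        if np.any(K[req] < self.floor):
            worst = float(np.min(K[req]))
            raise PositivityError(
                f"censoring survival {worst:.4f} below floor {self.floor} for a weighted subject"
            )
        return K


def fit_censoring_km(
    T_days: np.ndarray, delta: np.ndarray, floor: float = 0.05
) -> CensoringModel:
    """Pooled Kaplan-Meier of the censoring distribution (roles swapped)."""
    T = np.asarray(T_days, dtype=float)
    cens = 1 - np.asarray(delta).astype(int)
    if len(T) == 0:
        raise ValueError("empty sample")
    order = np.argsort(T, kind="stable")
    Ts, cs = T[order], cens[order]
    uu, first = np.unique(Ts, return_index=True)
    n = len(T)
    d = np.add.reduceat(cs.astype(float), first)
    at_risk = (n - first).astype(float)
    has = d > 0
    K = np.cumprod(1.0 - d[has] / at_risk[has])
    return CensoringModel(
        knot_times=uu[has].astype(float),
        knot_values=K,
        floor=floor,
    )


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------


@dataclass
class NuisanceBundle:
    """All fitted nuisances plus the penalty levels selected on full data."""

    propensity: PropensityModel
    outcome_logistic: OutcomeLogisticModel | None
    additive_hazards: AdditiveHazardsModel | None
    censoring: CensoringModel
    spec: AdaptiveLassoSpec = field(default_factory=AdaptiveLassoSpec)

    @property
    def lambdas(self) -> dict[str, float]:
        out = {"propensity": self.propensity.lambda_}
        if self.outcome_logistic is not None:
            out["outcome_logistic"] = self.outcome_logistic.lambda_
        if self.additive_hazards is not None:
            out["additive_hazards"] = self.additive_hazards.lambda_
        return out

    def to_json(self, path) -> None:
        obj = {
            "spec": asdict(self.spec),
            "propensity": {
                "intercept": self.propensity.fit.intercept,
                "coef": self.propensity.fit.coef.tolist(),
                "lambda": self.propensity.lambda_,
                "eps": self.propensity.eps,
            },
            "outcome_logistic": None if self.outcome_logistic is None else {
                "intercept": self.outcome_logistic.fit.intercept,
                "coef": self.outcome_logistic.fit.coef.tolist(),
                "lambda": self.outcome_logistic.lambda_,
            },
            "additive_hazards": None if self.additive_hazards is None else {
                "theta": self.additive_hazards.theta,
                "beta": self.additive_hazards.beta.tolist(),
                "baseline_times": self.additive_hazards.baseline_times.tolist(),
                "baseline_values": self.additive_hazards.baseline_values.tolist(),
                "lambda": self.additive_hazards.lambda_,
            },
            "censoring": {
                "knot_times": self.censoring.knot_times.tolist(),
                "knot_values": self.censoring.knot_values.tolist(),
                "floor": self.censoring.floor,
            },
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)


def fit_nuisances(
    X: np.ndarray,
    A: np.ndarray,
    T_days: np.ndarray,
    delta: np.ndarray,
    tau_days: int,
    spec: AdaptiveLassoSpec | None = None,
    lambdas_fixed: dict[str, float] | None = None,
    components: tuple[str, ...] = ("outcome_logistic", "additive_hazards"),
    warm: "NuisanceBundle | None" = None,
) -> NuisanceBundle:
    """Fit the nuisance bundle on one cohort.

    The outcome logistic model uses only subjects whose horizon status is
    known, weighted by the inverse censoring probability evaluated with
    left limits at ``min(T, tau)``.  ``components`` restricts which outcome
    models are fitted (the propensity and censoring models always are).
    """
    spec = spec or AdaptiveLassoSpec()
    lf = lambdas_fixed or {}
    A = np.asarray(A).astype(int)
    T_days = np.asarray(T_days, dtype=float)
    delta = np.asarray(delta).astype(int)
    y_tau = ((delta == 1) & (T_days <= tau_days)).astype(float)
    known = (y_tau == 1) | (T_days >= tau_days)

    censoring = fit_censoring_km(T_days, delta, floor=spec.ipcw_floor)
    K = censoring.evaluate_left(np.minimum(T_days, tau_days), required=known)
    ipcw = np.where(known, 1.0 / K, 0.0)

    propensity = fit_propensity(X, A, spec, lambda_fixed=lf.get("propensity"),
                                warm=warm.propensity if warm else None)
    outcome = None
    if "outcome_logistic" in components:
        outcome = fit_outcome_logistic(
            X[known], A[known], y_tau[known], sample_weight=ipcw[known], spec=spec,
            lambda_fixed=lf.get("outcome_logistic"),
            warm=warm.outcome_logistic if warm else None,
        )
    hazards = None
    if "additive_hazards" in components:
        hazards = fit_additive_hazards(
            X, A, T_days, delta, spec, tau_days=tau_days,
            lambda_fixed=lf.get("additive_hazards"),
            warm=warm.additive_hazards if warm else None,
        )
    return NuisanceBundle(
        propensity=propensity, outcome_logistic=outcome,
        additive_hazards=hazards, censoring=censoring, spec=spec,
    )
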