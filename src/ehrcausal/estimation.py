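"""Doubly robust estimation of the fixed-horizon effect parameters.

Two estimands, both at horizon tau (default 5 years):

* risk difference — augmented IPW of the horizon event probability,
  ``psi_a = mean[ m_a(X) + 1{A=a}/pi_a(X) * Delta/K(min(T,tau)-) *
  (Y - m_a(X)) ]``, point = psi_1 - psi_0;
* event-free survival ratio — augmented IPCW with the additive-hazards
  conditional survival as the augmentation,
  ``S_a = mean[ 1{A=a}/pi_a(X) * Delta (1-Y)/K(min(T,tau)-)
  + (1 - 1{A=a}/pi_a(X)) * S(tau|a,X) ]``, point = S_1 / S_0.

Either estimator is consistent when the propensity model or the
corresponding outcome model is correct.  Inference is nonparametric
bootstrap (patient-level resampling, nuisances refit per replicate with
the penalty frozen at the full-data selection) with normal-approximation
confidence intervals; ratio inference is on the log scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import stats

from ehrcausal.cohort import DEFAULT_TAU_DAYS
from ehrcausal.nuisance import (
    AdaptiveLassoSpec,
    AdditiveHazardsModel,
    CensoringModel,
    NuisanceBundle,
    OutcomeLogisticModel,
    PropensityModel,
    fit_nuisances,
)

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

SURVIVAL_FLOOR = 1e-6


class EmptyArmError(RuntimeError):
    """A queried arm has no subjects."""


@dataclass
class AnalysisConfig:
    """Estimation settings: horizon, comparison, style, bootstrap, CI."""

    tau_days: int = DEFAULT_TAU_DAYS
    comparison: tuple[str, str] = ("insulin", "sulfonylureas")
    style: str = "intent-to-treat"
    n_bootstrap: int = 500
    seed: int = 0
    ci_level: float = 0.95
    ratio_log_scale: bool = True
    max_redraw_fraction: float = 0.10
    estimands: tuple[str, ...] = ("risk_difference", "survival_ratio")

    def __post_init__(self) -> None:
        if self.n_bootstrap < 2:
            raise ValueError("n_bootstrap must be at least 2")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.style not in ("intent-to-treat", "per-protocol"):
            raise ValueError(f"unknown analysis style {self.style!r}")
        bad = set(self.estimands) - {"risk_difference", "survival_ratio"}
        if bad:
            raise ValueError(f"unknown estimands: {sorted(bad)}")


@dataclass
class EffectEstimate:
    """One estimand's point estimate with bootstrap-normal inference."""

    estimand: str  # risk_difference | survival_ratio
    point: float
    arm1_component: float
    arm0_component: float
    sd: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_bootstrap: int
    seed: int
    style: str
    n_redraws: int = 0

    def __post_init__(self) -> None:
        if not self.ci_low <= self.point <= self.ci_high:
            raise ValueError("CI must contain the point estimate")
        if self.estimand == "survival_ratio" and self.point <= 0:
            raise ValueError("survival ratio must be positive")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value out of [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def _status_arrays(T_days, delta, tau_days):
    T_days = np.asarray(T_days, dtype=float)
    delta = np.asarray(delta).astype(int)
    Y = ((delta == 1) & (T_days <= tau_days)).astype(float)
    known = ((Y == 1) | (T_days >= tau_days)).astype(float)
    return Y, known


def _pi_arm(pi, X, a):
    """P(A=a | X) from a PropensityModel or a precomputed pi_1 array."""
    p1 = pi.predict(X) if isinstance(pi, PropensityModel) else np.asarray(pi, dtype=float)
    return p1 if a == 1 else 1.0 - p1


def _m_arm(m, X, a):
    if isinstance(m, OutcomeLogisticModel):
        return m.predict(X, a)
    if callable(m):
        return np.asarray(m(X, a), dtype=float)
    return np.asarray(m, dtype=float)


def _K_left(K, T_days, tau_days, required):
    if isinstance(K, CensoringModel):
        return K.evaluate_left(np.minimum(T_days, tau_days), required=required)
    return np.asarray(K, dtype=float)


def aipw_risk(X, A, T_days, delta, pi, m, K, a: int, tau_days: int = DEFAULT_TAU_DAYS) -> float:
    """Augmented IPW estimate of the arm-a horizon event probability.

    ``pi``/``m``/``K`` accept fitted models or precomputed arrays (the
    latter allows oracle injection).  Returns the unclipped mean.
    """
    A = np.asarray(A).astype(int)
    if not np.any(A == a):
        raise EmptyArmError(f"no subjects in arm {a}")
    Y, known = _status_arrays(T_days, delta, tau_days)
    pia = _pi_arm(pi, X, a)
    ma = _m_arm(m, X, a)
    ind = (A == a).astype(float)
    need_K = (ind == 1) & (known == 1)
    Kv = _K_left(K, T_days, tau_days, required=need_K)
    correction = np.where(need_K, ind / pia * known / np.maximum(Kv, 1e-300) * (Y - ma), 0.0)
    return float(np.mean(ma + correction))


def dr_survival(X, A, T_days, delta, pi, surv, K, a: int, tau_days: int = DEFAULT_TAU_DAYS) -> float:
    """Augmented IPCW estimate of the arm-a horizon event-free survival.

    ``surv`` is an AdditiveHazardsModel, a callable ``(X, a) -> S`` or a
    precomputed array of S(tau | a, X).  Result clipped to (0, 1].
    """
    A = np.asarray(A).astype(int)
    if not np.any(A == a):
        raise EmptyArmError(f"no subjects in arm {a}")
    Y, known = _status_arrays(T_days, delta, tau_days)
    pia = _pi_arm(pi, X, a)
    if isinstance(surv, AdditiveHazardsModel):
        Sa = surv.predict_survival(tau_days / DAYS_PER_YEAR, a, X)
    elif callable(surv):
        Sa = np.asarray(surv(X, a), dtype=float)
    else:
        Sa = np.asarray(surv, dtype=float)
    ind = (A == a).astype(float)
    need_K = (ind == 1) & (known == 1)
    Kv = _K_left(K, T_days, tau_days, required=need_K)
    ipw_term = np.where(need_K, ind / pia * known * (1.0 - Y) / np.maximum(Kv, 1e-300), 0.0)
    value = float(np.mean(ipw_term + (1.0 - ind / pia) * Sa))
    if value <= 0:
        logger.warning("survival estimate %.3g <= 0; floored at %.0e", value, SURVIVAL_FLOOR)
        value = SURVIVAL_FLOOR
    elif value > 1:
        logger.info("survival estimate %.3g > 1; clipped", value)
        value = 1.0
    return value


def _points_from_bundle(X, A, T_days, delta, bundle: NuisanceBundle, tau_days: int):
    """(psi_1, psi_0, S_1, S_0) for one (sub)sample and fitted bundle.

    Entries are NaN for estimands whose nuisances were not fitted."""
    args = (X, A, T_days, delta)
    psi1 = psi0 = s1 = s0 = float("nan")
    if bundle.outcome_logistic is not None:
        psi1 = aipw_risk(*args, bundle.propensity, bundle.outcome_logistic, bundle.censoring, 1, tau_days)
        psi0 = aipw_risk(*args, bundle.propensity, bundle.outcome_logistic, bundle.censoring, 0, tau_days)
    if bundle.additive_hazards is not None:
        s1 = dr_survival(*args, bundle.propensity, bundle.additive_hazards, bundle.censoring, 1, tau_days)
        s0 = dr_survival(*args, bundle.propensity, bundle.additive_hazards, bundle.censoring, 0, tau_days)
    return psi1, psi0, s1, s0


def estimate_effects(
    X: np.ndarray,
    A: np.ndarray,
    T_days: np.ndarray,
    delta: np.ndarray,
    switched: np.ndarray | None = None,
    config: AnalysisConfig | None = None,
    spec: AdaptiveLassoSpec | None = None,
) -> dict[str, EffectEstimate]:
    """Estimate both doubly robust estimands with joint bootstrap inference.

    Per-protocol style drops switch-flagged patients before any fitting.
    Bootstrap replicates share the patient resample across estimands and
    refit every nuisance with the penalty frozen at the full-data value;
    replicates that lose an arm (or all events) are redrawn and counted.
    """
    config = config or AnalysisConfig()
    spec = spec or AdaptiveLassoSpec()
    X = np.asarray(X, dtype=float)
    A = np.asarray(A).astype(int)
    T_days = np.asarray(T_days, dtype=float)
    delta = np.asarray(delta).astype(int)

    if config.style == "per-protocol":
        if switched is None:
            raise ValueError("per-protocol style requires switch flags")
        keep = ~np.asarray(switched).astype(bool)
        X, A, T_days, delta = X[keep], A[keep], T_days[keep], delta[keep]
    n = len(A)
    if not (np.any(A == 1) and np.any(A == 0)):
        raise EmptyArmError("both arms must be non-empty")

    tau = config.tau_days
    components = tuple(
        c for c, est in (("outcome_logistic", "risk_difference"),
                         ("additive_hazards", "survival_ratio"))
        if est in config.estimands
    )
    bundle = fit_nuisances(X, A, T_days, delta, tau, spec, components=components)
    psi1, psi0, s1, s0 = _points_from_bundle(X, A, T_days, delta, bundle, tau)
    rd_point = psi1 - psi0
    sr_point = s1 / max(s0, SURVIVAL_FLOOR)

    rng = np.random.default_rng(config.seed)
    boot_spec = replace(spec, tol=max(spec.tol, 1e-6))
    B = config.n_bootstrap
    rd_reps = np.empty(B)
    logsr_reps = np.empty(B)
    redraws = 0
    max_redraws = int(np.ceil(config.max_redraw_fraction * B))
    b = 0
    while b < B:
        idx = rng.integers(0, n, n)
        Ab = A[idx]
        try:
            if not (np.any(Ab == 1) and np.any(Ab == 0)):
                raise EmptyArmError("replicate lost an arm")
            rb = fit_nuisances(
                X[idx], Ab, T_days[idx], delta[idx], tau, boot_spec,
                lambdas_fixed=bundle.lambdas, components=components, warm=bundle,
            )
            p1, p0, t1, t0 = _points_from_bundle(X[idx], Ab, T_days[idx], delta[idx], rb, tau)
        except (EmptyArmError, ValueError):
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError(
                    f"more than {config.max_redraw_fraction:.0%} of bootstrap replicates "
                    "were degenerate; sample too small for bootstrap inference"
                )
            continue
        rd_reps[b] = p1 - p0
        if "survival_ratio" in config.estimands:
            logsr_reps[b] = np.log(max(t1, SURVIVAL_FLOOR)) - np.log(max(t0, SURVIVAL_FLOOR))
        b += 1

    z = stats.norm.ppf(0.5 + config.ci_level / 2)

    def _wald(point, sd, null=0.0):
        if sd == 0:
            return 1.0 if point == null else 0.0
        return float(2 * (1 - stats.norm.cdf(abs(point - null) / sd)))

    results: dict[str, EffectEstimate] = {}
    rd_sd = float(np.std(rd_reps, ddof=1)) if "risk_difference" in config.estimands else 0.0
    rd = None if "risk_difference" not in config.estimands else EffectEstimate(
        estimand="risk_difference",
        point=float(rd_point),
        arm1_component=float(np.clip(psi1, 0.0, 1.0)),
        arm0_component=float(np.clip(psi0, 0.0, 1.0)),
        sd=rd_sd,
        ci_low=float(rd_point - z * rd_sd),
        ci_high=float(rd_point + z * rd_sd),
        p_value=_wald(rd_point, rd_sd),
        n=n, n_bootstrap=B, seed=config.seed, style=config.style, n_redraws=redraws,
    )
    if rd is not None:
        results["risk_difference"] = rd
        if (psi1 < 0 or psi1 > 1) or (psi0 < 0 or psi0 > 1):
            logger.info("arm risk outside [0,1] before clipping: psi1=%.4f psi0=%.4f", psi1, psi0)

    if "survival_ratio" not in config.estimands:
        return results

    log_point = float(np.log(sr_point))
    sr_sd_log = float(np.std(logsr_reps, ddof=1))
    if config.ratio_log_scale:
        sr = EffectEstimate(
            estimand="survival_ratio",
            point=float(sr_point),
            arm1_component=float(s1),
            arm0_component=float(s0),
            sd=sr_sd_log,
            ci_low=float(np.exp(log_point - z * sr_sd_log)),
            ci_high=float(np.exp(log_point + z * sr_sd_log)),
            p_value=_wald(log_point, sr_sd_log),
            n=n, n_bootstrap=B, seed=config.seed, style=config.style, n_redraws=redraws,
        )
    else:
        sr_reps = np.exp(logsr_reps)
        sd_plain = float(np.std(sr_reps, ddof=1))
        sr = EffectEstimate(
            estimand="survival_ratio",
            point=float(sr_point),
            arm1_component=float(s1),
            arm0_component=float(s0),
            sd=sd_plain,
            ci_low=float(sr_point - z * sd_plain),
            ci_high=float(sr_point + z * sd_plain),
            p_value=_wald(sr_point, sd_plain, null=1.0),
            n=n, n_bootstrap=B, seed=config.seed, style=config.style, n_redraws=redraws,
        )
    results["survival_ratio"] = sr
    return results


def risk_difference(X, A, T_days, delta, switched=None, config=None, spec=None) -> EffectEstimate:
    """Doubly robust 5-year risk difference (arm 1 minus arm 0)."""
    return estimate_effects(X, A, T_days, delta, switched, config, spec)["risk_difference"]


def survival_ratio(X, A, T_days, delta, switched=None, config=None, spec=None) -> EffectEstimate:
    """Doubly robust 5-year event-free survival ratio (arm 1 over arm 0)."""
    return estimate_effects(X, A, T_days, delta, switched, config, spec)["survival_ratio"]
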