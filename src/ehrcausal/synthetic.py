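"""Synthetic longitudinal EHR generator with a known causal ground truth.

Patients are simulated from an additive-hazards outcome model
``lambda(t | A, X) = lambda0 + theta * A + beta' X`` (constant in time, so
event times are exponential given covariates), with confounded treatment
assignment through a logistic model on the same covariates, a competing
death process, and censoring at the last encounter of an independent
renewal process.  Two output granularities share one sampling core:

* :func:`generate_arrays` — per-patient analysis arrays (covariates, arm,
  follow-up, event indicators), used by simulation studies;
* :func:`generate_population` — a full coded event stream (encounters,
  medication pairs, demographics, labs, windowed confounder codes,
  HF/death events) that the cohort builder can consume, together with
  per-patient bookkeeping for exact cross-checks.

:func:`oracle_estimands` computes the true marginal fixed-horizon risk
difference and survival ratio by Monte-Carlo averaging of the closed-form
conditional survival over the covariate distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from ehrcausal.cohort import DEFAULT_TAU_DAYS

DAYS_PER_YEAR = 365.25

#: Event systems cycled through for windowed confounder codes.
_FEATURE_SYSTEMS = ("DIAG", "NOTE_CUI", "PROC")

_LAB_CODES = ("HBA1C", "LDL", "HDL", "TCHOL", "BMI")
_LAB_MEANS = {"HBA1C": 8.2, "LDL": 100.0, "HDL": 48.0, "TCHOL": 180.0, "BMI": 32.0}
_LAB_SDS = {"HBA1C": 1.4, "LDL": 25.0, "HDL": 12.0, "TCHOL": 35.0, "BMI": 6.0}


class InfeasibleConfigError(RuntimeError):
    """Raised when hazard positivity cannot be achieved by resampling."""


@dataclass
class SimConfig:
    """Generating-model parameters for the synthetic population.

    The covariate vector is ``[history counts (n_history_features),
    recent counts (n_recent_features), sex]``; both coefficient vectors
    must have length ``n_history_features + n_recent_features + 1``.
    Hazards are in events per person-year.
    """

    n_patients: int = 1000
    n_history_features: int = 3
    n_recent_features: int = 3
    confounder_effect_on_treatment: list[float] = field(default_factory=lambda: [0.0] * 7)
    confounder_effect_on_hazard: list[float] = field(default_factory=lambda: [0.0] * 7)
    propensity_intercept: float = 0.0
    baseline_hazard: float = 0.04
    treatment_effect: float = 0.02
    death_hazard: float = 0.0
    censoring_mean_years: float = 8.0
    admin_horizon_years: float = 10.0
    encounter_rate: float = 6.0
    index_spacing_days: tuple[int, int] = (200, 500)
    tau_days: int = DEFAULT_TAU_DAYS
    switch_prob: float = 0.0
    nb_mean: float = 1.5
    nb_dispersion: float = 1.0
    lab_missing_rate: float = 0.2
    comparison: tuple[str, str] = ("insulin", "sulfonylureas")
    max_rejections: int = 100
    seed: int = 0

    @property
    def n_covariates(self) -> int:
        return self.n_history_features + self.n_recent_features + 1

    @property
    def tau_years(self) -> float:
        return self.tau_days / DAYS_PER_YEAR

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.tau_days <= 0:
            raise ValueError("tau_days must be positive")
        for name in ("confounder_effect_on_treatment", "confounder_effect_on_hazard"):
            v = getattr(self, name)
            if len(v) != self.n_covariates:
                raise ValueError(
                    f"{name} must have length {self.n_covariates} "
                    f"(history + recent + sex), got {len(v)}"
                )
        if self.baseline_hazard < 0 or self.death_hazard < 0:
            raise ValueError("hazards must be nonnegative")
        if self.baseline_hazard + min(self.treatment_effect, 0.0) < 0 and not any(
            self.confounder_effect_on_hazard
        ):
            raise ValueError("baseline + treatment hazard negative; infeasible")

    def covariate_names(self) -> list[str]:
        return (
            [f"H{j:03d}_history" for j in range(self.n_history_features)]
            + [f"R{j:03d}_recent" for j in range(self.n_recent_features)]
            + ["sex_female"]
        )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["index_spacing_days"] = list(self.index_spacing_days)
        d["comparison"] = list(self.comparison)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["index_spacing_days"] = tuple(d.get("index_spacing_days", (200, 500)))
        d["comparison"] = tuple(d.get("comparison", ("insulin", "sulfonylureas")))
        return cls(**d)


@dataclass
class GroundTruth:
    """True marginal estimands at the configured horizon, plus MC error."""

    true_risk_difference: float
    true_survival_ratio: float
    true_risk_1: float
    true_risk_0: float
    true_theta: float
    true_propensity_coefficients: list[float]
    mc_se: dict[str, float]
    n_mc: int

    def __post_init__(self) -> None:
        if self.true_survival_ratio <= 0:
            raise ValueError("survival ratio must be positive")
        if abs(self.true_risk_difference) > 1:
            raise ValueError("risk difference out of [-1, 1]")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _draw_covariates(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw n covariate vectors [history counts, recent counts, sex].

    Counts are negative-binomial (overdispersed, sparse); sex is Bernoulli.
    """
    k = cfg.n_history_features + cfg.n_recent_features
    r = cfg.nb_dispersion
    p = r / (r + cfg.nb_mean)
    counts = rng.negative_binomial(r, p, size=(n, k)).astype(float)
    sex = rng.binomial(1, 0.5, size=(n, 1)).astype(float)
    return np.hstack([counts, sex])


def _hazards(cfg: SimConfig, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """HF hazard per arm (columns a=0, a=1), events per person-year."""
    beta = np.asarray(cfg.confounder_effect_on_hazard, dtype=float)
    base = cfg.baseline_hazard + X @ beta
    return base, base + cfg.treatment_effect


def _draw_feasible_covariates(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Rejection-sample covariates so the HF hazard is nonnegative in both arms.

    The same rule is used by the generator and the Monte-Carlo oracle so
    both target the identical covariate distribution.
    """
    X = _draw_covariates(cfg, rng, n)
    for _ in range(cfg.max_rejections):
        h0, h1 = _hazards(cfg, X)
        bad = np.flatnonzero((h0 < 0) | (h1 < 0))
        if bad.size == 0:
            return X
        X[bad] = _draw_covariates(cfg, rng, bad.size)
    raise InfeasibleConfigError(
        f"hazard still negative after {cfg.max_rejections} resampling rounds; "
        "config is infeasible"
    )


def _sample_patients(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Shared sampling core: covariates, arm, event/censoring times in days."""
    cfg.validate()
    n = cfg.n_patients
    X = _draw_feasible_covariates(cfg, rng, n)
    alpha = np.asarray(cfg.confounder_effect_on_treatment, dtype=float)
    logit = cfg.propensity_intercept + X @ alpha
    propensity = 1.0 / (1.0 + np.exp(-logit))
    A = rng.binomial(1, propensity)

    h0, h1 = _hazards(cfg, X)
    hf_rate = np.where(A == 1, h1, h0)  # per year
    with np.errstate(divide="ignore"):
        t_hf = np.where(hf_rate > 0, rng.exponential(1.0, n) / np.maximum(hf_rate, 1e-300), np.inf)
        t_death = (
            rng.exponential(1.0 / cfg.death_hazard, n) if cfg.death_hazard > 0
            else np.full(n, np.inf)
        )
    t_event_years = np.minimum(t_hf, t_death)
    death_first = t_death < t_hf

    # last-encounter censoring: >30 days post index by construction, truncated
    # at an administrative horizon
    c_years = 31.0 / DAYS_PER_YEAR + rng.exponential(cfg.censoring_mean_years, n)
    c_years = np.minimum(c_years, cfg.admin_horizon_years)

    event_days = np.where(
        np.isfinite(t_event_years),
        np.maximum(np.round(t_event_years * DAYS_PER_YEAR), 1),
        np.inf,
    )
    cens_days = np.maximum(np.round(c_years * DAYS_PER_YEAR), 31).astype(int)
    event = (event_days <= cens_days).astype(int)
    follow_days = np.where(event == 1, event_days, cens_days).astype(int)

    outcome_by_tau = ((event == 1) & (follow_days <= cfg.tau_days)).astype(int)
    status_known = ((outcome_by_tau == 1) | (follow_days >= cfg.tau_days)).astype(int)

    switched = np.zeros(n, dtype=bool)
    if cfg.switch_prob > 0:
        candidate = np.minimum(follow_days, cfg.tau_days) >= 80
        switched = candidate & (rng.random(n) < cfg.switch_prob)

    df = pd.DataFrame(X, columns=cfg.covariate_names())
    df.insert(0, "patient_id", [f"P{i:06d}" for i in range(n)])
    df["propensity"] = propensity
    df["arm"] = A
    df["follow_days"] = follow_days
    df["event"] = event
    df["death_first"] = death_first & (event == 1)
    df["outcome_by_tau"] = outcome_by_tau
    df["status_known"] = status_known
    df["switched"] = switched
    # maintained-care eligibility can fail when the composite event lands
    # within 30 days of index (no later encounter exists)
    df["eligible"] = follow_days > 30
    return df


def generate_arrays(config: SimConfig) -> pd.DataFrame:
    """Generate per-patient analysis arrays directly (no event emission).

    Columns: covariates (``config.covariate_names()``), ``arm``,
    ``follow_days``, ``event``, ``outcome_by_tau``, ``status_known``,
    ``switched``, ``propensity``, ``eligible``.
    """
    rng = np.random.default_rng(config.seed)
    return _sample_patients(config, rng)


def feature_dictionary(config: SimConfig) -> list[dict]:
    """Feature-dictionary entries for the windowed confounder codes."""
    out = []
    for j in range(config.n_history_features):
        out.append({"system": _FEATURE_SYSTEMS[j % 3], "code": f"H{j:03d}", "label": f"history feature {j}"})
    for j in range(config.n_recent_features):
        out.append({"system": _FEATURE_SYSTEMS[j % 3], "code": f"R{j:03d}", "label": f"recent feature {j}"})
    return out


def _emit(rows, pid, day, system, code, value=np.nan):
    rows.append((pid, int(day), system, code, value))


def generate_population(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full coded event stream plus per-patient bookkeeping.

    Returns ``(events, truth)`` where ``events`` has internal columns
    ``patient_id, day, system, code, value`` and ``truth`` is the frame of
    :func:`generate_arrays` extended with ``index_day`` and ``drug_class``.
    The stream is constructed so that, for every patient flagged
    ``eligible``, the cohort builder recovers index date, arm, follow-up
    and event status exactly.
    """
    rng = np.random.default_rng(config.seed)
    truth = _sample_patients(config, rng)
    n = len(truth)
    arm1_class, arm0_class = config.comparison

    class_ingredients = {
        "insulin": ["insulin"],
        "sulfonylureas": ["glipizide", "glyburide", "glimepiride"],
        "DPP4i": ["sitagliptin", "linagliptin"],
        "GLP1RA": ["liraglutide", "dulaglutide", "semaglutide"],
    }
    switch_pool = [c for c in class_ingredients if c not in config.comparison] or [
        arm0_class, arm1_class
    ]

    lo, hi = config.index_spacing_days
    rows: list[tuple] = []
    index_days = np.empty(n, dtype=int)
    classes: list[str] = []
    n_hist, n_rec = config.n_history_features, config.n_recent_features
    Xc = truth[config.covariate_names()].to_numpy()
    fdict = feature_dictionary(config)

    for i in range(n):
        pid = truth.at[i, "patient_id"]
        index_day = int(rng.integers(4000, 5500))
        index_days[i] = index_day
        spacing = int(rng.integers(lo, hi + 1))
        m0 = index_day - spacing

        # demographics: birth date carries age; others are coded values
        age_years = rng.uniform(40, 75)
        birth_day = index_day - int(round(age_years * DAYS_PER_YEAR))
        demog_day = index_day - 500
        _emit(rows, pid, birth_day, "DEMOG", "BIRTH_DATE")
        _emit(rows, pid, demog_day, "DEMOG", "SEX", float(Xc[i, -1]))
        _emit(rows, pid, demog_day, "DEMOG", "RACE", float(rng.integers(0, 4)))
        _emit(rows, pid, demog_day, "DEMOG", "ETHNICITY", float(rng.random() < 0.05))
        _emit(rows, pid, demog_day, "DEMOG", "RESIDENCE", float(rng.random() < 0.95))

        # first T2D diagnosis sets diabetes duration
        _emit(rows, pid, m0 - int(rng.integers(100, 2000)), "DIAG", "T2D")

        # metformin qualifying pair, strictly pre-index
        _emit(rows, pid, m0, "MED", "metformin")
        _emit(rows, pid, m0 + int(rng.integers(30, 181)), "MED", "metformin")

        # second-line qualifying pair defines the index
        cls = arm1_class if truth.at[i, "arm"] == 1 else arm0_class
        classes.append(cls)
        ingredient = class_ingredients[cls][int(rng.integers(0, len(class_ingredients[cls])))]
        _emit(rows, pid, index_day, "MED", ingredient)
        _emit(rows, pid, index_day + int(rng.integers(30, 181)), "MED", ingredient)

        # labs within the year before index, missing at random
        for code in _LAB_CODES:
            if rng.random() >= config.lab_missing_rate:
                day = index_day - int(rng.integers(1, 366))
                _emit(rows, pid, day, "LAB", code, rng.normal(_LAB_MEANS[code], _LAB_SDS[code]))

        if rng.random() < 0.05:
            _emit(rows, pid, index_day - int(rng.integers(400, 1500)), "DIAG", "HF")
        if rng.random() < 0.01:
            d = index_day - 600
            _emit(rows, pid, d, "MED", "empagliflozin")
            _emit(rows, pid, d + 45, "MED", "empagliflozin")

        # windowed confounder codes: history counts strictly before
        # index-365, recent counts in [index-365, index)
        for j in range(n_hist):
            for _ in range(int(Xc[i, j])):
                day = index_day - int(rng.integers(366, 1200))
                _emit(rows, pid, day, fdict[j]["system"], fdict[j]["code"])
        for j in range(n_rec):
            for _ in range(int(Xc[i, n_hist + j])):
                day = index_day - int(rng.integers(1, 366))
                ent = fdict[n_hist + j]
                _emit(rows, pid, day, ent["system"], ent["code"])

        # encounters: established care guaranteed, renewal up to the end of
        # observation; the last encounter defines the censoring date
        first_enc = index_day - 366 - int(rng.integers(1, 400))
        follow = int(truth.at[i, "follow_days"])
        end_day = index_day + follow
        day = first_enc
        mean_gap = DAYS_PER_YEAR / config.encounter_rate
        while day < end_day:
            _emit(rows, pid, day, "ENCOUNTER", "ENC")
            day += max(1, int(round(rng.exponential(mean_gap))))
        _emit(rows, pid, end_day, "ENCOUNTER", "ENC")

        if truth.at[i, "event"] == 1:
            code = "DEATH" if truth.at[i, "death_first"] else "HF_HOSP"
            _emit(rows, pid, end_day, code, code)

        if truth.at[i, "switched"]:
            s = int(rng.integers(31, min(follow, config.tau_days) - 45))
            sw_cls = switch_pool[int(rng.integers(0, len(switch_pool)))]
            sw_ing = class_ingredients[sw_cls][0]
            _emit(rows, pid, index_day + s, "MED", sw_ing)
            _emit(rows, pid, index_day + s + 45, "MED", sw_ing)

    events = pd.DataFrame(rows, columns=["patient_id", "day", "system", "code", "value"])
    events = events.sort_values(["patient_id", "day", "system", "code"], kind="stable").reset_index(drop=True)
    truth = truth.copy()
    truth["index_day"] = index_days
    truth["drug_class"] = classes
    return events, truth


def oracle_estimands(config: SimConfig, n_mc: int = 10**6, seed: int | None = None) -> GroundTruth:
    """Monte-Carlo oracle for the true marginal estimands at the horizon.

    Averages the closed-form conditional survival
    ``exp(-(lambda0 + death_hazard + theta*a + beta'X) * tau)`` over the
    (rejection-sampled) covariate distribution, with both arms evaluated on
    the same covariate draws; reports Monte-Carlo standard errors.
    """
    if n_mc < 10**5:
        raise ValueError("n_mc must be at least 1e5 for a usable oracle")
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tau = config.tau_years
    s0_draws_all = []
    s1_draws_all = []
    chunk = 200_000
    done = 0
    while done < n_mc:
        m = min(chunk, n_mc - done)
        X = _draw_feasible_covariates(config, rng, m)
        h0, h1 = _hazards(config, X)
        s0_draws_all.append(np.exp(-(h0 + config.death_hazard) * tau))
        s1_draws_all.append(np.exp(-(h1 + config.death_hazard) * tau))
        done += m
    s0 = np.concatenate(s0_draws_all)
    s1 = np.concatenate(s1_draws_all)
    m0, m1 = s0.mean(), s1.mean()
    risk0, risk1 = 1.0 - m0, 1.0 - m1
    rd = risk1 - risk0
    sr = m1 / m0
    diff = s0 - s1
    se_rd = diff.std(ddof=1) / np.sqrt(n_mc)
    cov = np.cov(s1, s0, ddof=1)
    var_sr = (
        cov[0, 0] / m0**2 + (m1**2 / m0**4) * cov[1, 1] - 2 * (m1 / m0**3) * cov[0, 1]
    ) / n_mc
    se_sr = float(np.sqrt(max(var_sr, 0.0)))
    return GroundTruth(
        true_risk_difference=float(rd),
        true_survival_ratio=float(sr),
        true_risk_1=float(risk1),
        true_risk_0=float(risk0),
        true_theta=float(config.treatment_effect),
        true_propensity_coefficients=list(config.confounder_effect_on_treatment),
        mc_se={"risk_difference": float(se_rd), "survival_ratio": se_sr},
        n_mc=int(n_mc),
    )
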