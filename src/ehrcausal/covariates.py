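"""Baseline covariate assembly.

Expert-selected variables (demographics, durations, history flags, labs and
BMI with nearest-within-a-year retrieval) plus per-code event counts in two
pre-index temporal windows:

* recent window: ``[index - 365, index)`` — within one year prior;
* history window: ``(-inf, index - 365)`` — more than one year prior.

Index-day events are excluded everywhere (strictly pre-index baseline).
Count columns occurring in too few patients are removed by a prevalence
filter; remaining missingness is mean-imputed on the pooled cohort.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ehrcausal.cohort import MedicationEpisode

logger = logging.getLogger(__name__)

WINDOW_DAYS = 365

EXPERT_VARIABLES = (
    "age", "sex", "race", "ethnicity", "bmi", "residence",
    "t2d_duration", "metformin_duration", "prior_hf", "prior_sglt2i",
    "hba1c", "ldl", "hdl", "tchol",
)

_LAB_CODE_MAP = {"hba1c": "HBA1C", "ldl": "LDL", "hdl": "HDL", "tchol": "TCHOL", "bmi": "BMI"}

#: Codes (any class-map SGLT2i ingredient works; kept config-free here)
_SGLT2I_CODES = {"empagliflozin", "canagliflozin", "dapagliflozin",
                 "ertugliflozin", "bexagliflozin", "sotagliflozin"}


@dataclass
class CovariateSpec:
    """What to assemble: expert variables, counted codes, filter, windows."""

    expert_variables: tuple[str, ...] = EXPERT_VARIABLES
    feature_dictionary: list[dict] = field(default_factory=list)
    prevalence_threshold: float = 0.05
    window_days: int = WINDOW_DAYS
    log1p_counts: bool = False
    race_levels: int = 4
    race_reference: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence_threshold < 1:
            raise ValueError("prevalence_threshold must be in [0, 1)")
        unknown = set(self.expert_variables) - set(EXPERT_VARIABLES)
        if unknown:
            raise ValueError(f"unknown expert variables: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "CovariateSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "expert_variables" in d:
            d["expert_variables"] = tuple(d["expert_variables"])
        return cls(**d)


@dataclass
class CovariateMatrix:
    """Baseline design matrix aligned to the cohort, with audit metadata."""

    patient_ids: list[str]
    columns: list[str]
    X: np.ndarray
    mask: np.ndarray  # True where the pre-imputation entry was missing
    provenance: list[str]  # expert | history_window | recent_window

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.patient_ids), len(self.columns)):
            raise ValueError("matrix shape does not match index/columns")
        if len(self.provenance) != len(self.columns):
            raise ValueError("provenance tag per column required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.patient_ids, columns=self.columns)

    def to_csv(self, path, sidecar_path=None) -> None:
        df = self.to_frame()
        df.index.name = "patient_id"
        df.to_csv(path)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {"columns": self.columns, "provenance": self.provenance,
                     "n_missing_pre_imputation": self.mask.sum(axis=0).tolist()},
                    fh, indent=2,
                )


def _nearest_lab(events: pd.DataFrame, index_day: int, code: str, window_days: int) -> float:
    """Value of the qualifying lab nearest to index in [index-365, index).

    Ties at equal distance resolve to the later file appearance (stable
    order), logged.
    """
    system = events["system"].to_numpy()
    day = events["day"].to_numpy()
    mask = (
        ((system == "LAB") | (system == "DEMOG"))
        & (events["code"].to_numpy() == code)
        & (day >= index_day - window_days)
        & (day < index_day)
    )
    if not mask.any():
        return np.nan
    days_sel = day[mask]
    best_day = days_sel.max()
    tied = np.flatnonzero(days_sel == best_day)
    if len(tied) > 1:
        logger.info("lab %s: %d tied measurements at day %d; using last entered",
                    code, len(tied), best_day)
    return float(events["value"].to_numpy()[mask][tied[-1]])


def assemble_expert_covariates(
    events: pd.DataFrame,
    index_day: int,
    spec: CovariateSpec,
    episodes: list[MedicationEpisode] | None = None,
) -> dict[str, float]:
    """Assemble one patient's expert-variable row (NaN marks missing).

    Durations are in years ((index - first relevant code day) / 365.25);
    labs and BMI use nearest-within-a-year retrieval; history flags are any
    strictly pre-index occurrence; race is one-hot against a reference
    level.
    """
    row: dict[str, float] = {}
    want = set(spec.expert_variables)
    demog = events[events["system"] == "DEMOG"]

    def demog_value(code: str) -> float:
        sub = demog[demog["code"] == code]
        return float(sub["value"].iloc[0]) if not sub.empty else np.nan

    if "age" in want:
        birth = demog[demog["code"] == "BIRTH_DATE"]
        row["age"] = (index_day - float(birth["day"].iloc[0])) / 365.25 if not birth.empty else np.nan
    if "sex" in want:
        row["sex"] = demog_value("SEX")
    if "race" in want:
        race = demog_value("RACE")
        for lv in range(spec.race_levels):
            if lv == spec.race_reference:
                continue
            row[f"race_{lv}"] = np.nan if np.isnan(race) else float(race == lv)
    if "ethnicity" in want:
        row["ethnicity"] = demog_value("ETHNICITY")
    if "residence" in want:
        row["residence"] = demog_value("RESIDENCE")
    for var in ("bmi", "hba1c", "ldl", "hdl", "tchol"):
        if var in want:
            row[var] = _nearest_lab(events, index_day, _LAB_CODE_MAP[var], spec.window_days)
    if "t2d_duration" in want:
        t2d = events[(events["system"] == "DIAG") & (events["code"] == "T2D")
                     & (events["day"] < index_day)]
        row["t2d_duration"] = (index_day - float(t2d["day"].min())) / 365.25 if not t2d.empty else np.nan
    if "metformin_duration" in want:
        init = [e.initiation_day for e in (episodes or []) if e.drug_class == "metformin"]
        row["metformin_duration"] = (index_day - min(init)) / 365.25 if init else np.nan
    if "prior_hf" in want:
        hf = events[(events["system"] == "DIAG") & (events["code"] == "HF")
                    & (events["day"] < index_day)]
        row["prior_hf"] = float(not hf.empty)
    if "prior_sglt2i" in want:
        sglt = events[(events["system"] == "MED") & (events["code"].isin(_SGLT2I_CODES))
                      & (events["day"] < index_day)]
        row["prior_sglt2i"] = float(not sglt.empty)
    return row


def count_window_features(
    events: pd.DataFrame, index_day: int, spec: CovariateSpec
) -> dict[str, int]:
    """Count dictionary codes in the history and recent pre-index windows."""
    if not spec.feature_dictionary:
        raise ValueError("feature dictionary is empty")
    row: dict[str, int] = {}
    w = spec.window_days
    system = events["system"].to_numpy()
    code = events["code"].to_numpy()
    day = events["day"].to_numpy()
    for entry in spec.feature_dictionary:
        days = day[(system == entry["system"]) & (code == entry["code"])]
        key = f"{entry['system']}:{entry['code']}"
        row[f"{key}:history"] = int(np.sum(days < index_day - w))
        row[f"{key}:recent"] = int(np.sum((days >= index_day - w) & (days < index_day)))
    return row


def min_presence_count(n_patients: int, threshold: float) -> int:
    """Smallest patient presence count that survives the prevalence filter."""
    return math.ceil(threshold * n_patients)


def prevalence_filter(
    counts: pd.DataFrame, threshold: float, n_patients: int | None = None
) -> list[str]:
    """Columns present (count > 0) in at least ceil(threshold * n) patients."""
    n = len(counts) if n_patients is None else n_patients
    cut = min_presence_count(n, threshold)
    presence = (counts > 0).sum(axis=0)
    return [c for c in counts.columns if presence[c] >= cut]


def impute_missing(X: np.ndarray, columns: list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing entries column-wise on the pooled cohort.

    Returns (imputed matrix, missingness mask).  A column with no complete
    case is a hard error naming the column.
    """
    X = np.asarray(X, dtype=float)
    mask = np.isnan(X)
    out = X.copy()
    for j in range(X.shape[1]):
        col_missing = mask[:, j]
        if col_missing.all():
            name = columns[j] if columns else f"column {j}"
            raise ValueError(f"cannot impute {name!r}: no complete case")
        if col_missing.any():
            out[col_missing, j] = X[~col_missing, j].mean()
    return out, mask


def build_covariate_matrix(
    events: pd.DataFrame,
    cohort: pd.DataFrame,
    spec: CovariateSpec,
    episodes_by_patient: dict[str, list[MedicationEpisode]] | None = None,
    classes=None,
) -> CovariateMatrix:
    """Assemble the full baseline design matrix for an eligible cohort.

    Expert columns come first, then windowed count columns that survive the
    prevalence filter (computed over this cohort).  Missing expert values
    are mean-imputed; the pre-imputation mask is preserved.  Medication
    episodes (for the metformin-duration variable) can be passed in or
    detected on the fly from a drug-class map.
    """
    from ehrcausal.cohort import detect_medication_episodes

    by_patient = dict(tuple(events.groupby("patient_id", sort=False)))
    expert_rows, count_rows = [], []
    for _, rec in cohort.iterrows():
        pid = rec["patient_id"]
        grp = by_patient.get(pid)
        if grp is None:
            raise KeyError(f"cohort patient {pid!r} absent from event stream")
        if episodes_by_patient is not None:
            eps = episodes_by_patient.get(pid)
        elif classes is not None:
            eps = detect_medication_episodes(grp, classes)
        else:
            eps = None
        expert_rows.append(assemble_expert_covariates(grp, int(rec["index_day"]), spec, eps))
        if spec.feature_dictionary:
            count_rows.append(count_window_features(grp, int(rec["index_day"]), spec))

    expert_df = pd.DataFrame(expert_rows, index=cohort["patient_id"].tolist())
    frames = [expert_df]
    provenance = ["expert"] * expert_df.shape[1]
    if count_rows:
        counts_df = pd.DataFrame(count_rows, index=cohort["patient_id"].tolist())
        kept = prevalence_filter(counts_df, spec.prevalence_threshold)
        counts_df = counts_df[kept]
        if spec.log1p_counts:
            counts_df = np.log1p(counts_df)
        frames.append(counts_df)
        provenance += [
            "history_window" if c.endswith(":history") else "recent_window" for c in kept
        ]
    full = pd.concat(frames, axis=1)
    X, mask = impute_missing(full.to_numpy(dtype=float), list(full.columns))
    return CovariateMatrix(
        patient_ids=list(full.index),
        columns=list(full.columns),
        X=X,
        mask=mask,
        provenance=provenance,
    )
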