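"""Shared event-stream model and IO.

A patient record is a long-format stream of dated, system-qualified coded
events.  The on-disk dialect is a UTF-8 CSV with header
``patient_id,date,system,code,value``; ``date`` is ISO-8601 (YYYY-MM-DD) and
``value`` is empty when inapplicable.  Parquet with the identical schema is
accepted transparently.

Internally dates are converted to integer day offsets from :data:`EPOCH`;
all interval arithmetic is done in whole days.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Anchor for integer day offsets (day 0).
EPOCH = _dt.date(2000, 1, 1)

#: Recognised event systems.
SYSTEMS = frozenset(
    {"DIAG", "MED", "LAB", "PROC", "NOTE_CUI", "ENCOUNTER", "DEMOG", "DEATH", "HF_HOSP"}
)

#: Plausible calendar range for event dates.
DATE_MIN = _dt.date(1900, 1, 1)
DATE_MAX = _dt.date(2100, 1, 1)

EVENT_COLUMNS = ["patient_id", "date", "system", "code", "value"]

#: Drug classes that define the comparator arms.
INTERVENTION_CLASSES = ("insulin", "sulfonylureas", "DPP4i", "GLP1RA")

#: All classes a class map may declare.
KNOWN_CLASSES = INTERVENTION_CLASSES + ("metformin", "SGLT2i", "thiazolidinediones")


def date_to_days(d: _dt.date | str) -> int:
    """Convert a calendar date (or ISO string) to a day offset from EPOCH."""
    if isinstance(d, str):
        d = _dt.date.fromisoformat(d)
    return (d - EPOCH).days


def days_to_date(days: int) -> _dt.date:
    """Inverse of :func:`date_to_days`."""
    return EPOCH + _dt.timedelta(days=int(days))


def _validate_events(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event stream missing columns: {missing}")
    bad_systems = set(df["system"].unique()) - SYSTEMS
    if bad_systems:
        raise ValueError(f"unknown event systems: {sorted(bad_systems)}")
    dates = pd.to_datetime(df["date"], format="%Y-%m-%d").dt.date
    out_of_range = (dates < DATE_MIN) | (dates > DATE_MAX)
    if out_of_range.any():
        raise ValueError(
            f"{int(out_of_range.sum())} event dates outside plausible range "
            f"[{DATE_MIN}, {DATE_MAX}]"
        )
    out = df.copy()
    out["day"] = [(d - EPOCH).days for d in dates]
    out["value"] = pd.to_numeric(out["value"], errors="coerce")
    return out[["patient_id", "day", "system", "code", "value"]]


def read_events_csv(path) -> pd.DataFrame:
    """Read an event stream (CSV or Parquet) into the internal day-offset frame.

    Returns a frame with columns ``patient_id, day, system, code, value``
    where ``day`` is an integer offset from :data:`EPOCH`.
    """
    path = str(path)
    if path.endswith(".parquet"):
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path, dtype={"patient_id": str, "code": str}, keep_default_na=False,
                         na_values=[""])
        df["code"] = df["code"].astype(str)
    return _validate_events(df)


def write_events_csv(df: pd.DataFrame, path) -> None:
    """Write an internal event frame back to the CSV dialect (ISO dates)."""
    out = df.copy()
    if "day" in out.columns and "date" not in out.columns:
        out["date"] = [days_to_date(d).isoformat() for d in out["day"]]
        out = out.drop(columns=["day"])
    out = out[EVENT_COLUMNS]
    out.to_csv(path, index=False)


@dataclass
class DrugClassMap:
    """Mapping from drug class name to its set of ingredient-level codes.

    Ingredient codes must be disjoint across classes; combination products
    are represented upstream by emitting one code per constituent ingredient.
    """

    classes: dict[str, set] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.classes = {k: set(v) for k, v in self.classes.items()}
        unknown = set(self.classes) - set(KNOWN_CLASSES)
        if unknown:
            raise ValueError(f"unknown drug classes: {sorted(unknown)}")
        seen: dict[str, str] = {}
        for cls, codes in self.classes.items():
            for code in codes:
                if code in seen:
                    raise ValueError(
                        f"ingredient {code!r} appears in both {seen[code]!r} and {cls!r}"
                    )
                seen[code] = cls

    def class_of(self, code: str) -> str | None:
        for cls, codes in self.classes.items():
            if code in codes:
                return cls
        return None

    @classmethod
    def from_yaml(cls, path) -> "DrugClassMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "classes" not in raw:
            raise ValueError(f"{path}: expected a top-level 'classes' mapping")
        return cls(classes={k: set(v) for k, v in raw["classes"].items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"classes": {k: sorted(v) for k, v in self.classes.items()}}, fh)


def default_class_map() -> DrugClassMap:
    """Ingredient-level class map for the seven antidiabetic classes."""
    return DrugClassMap(
        classes={
            "metformin": {"metformin"},
            "insulin": {"insulin"},
            "sulfonylureas": {"chlorpropamide", "glyburide", "glipizide", "glimepiride", "tolbutamide"},
            "DPP4i": {"linagliptin", "alogliptin", "saxagliptin", "sitagliptin"},
            "GLP1RA": {"dulaglutide", "lixisenatide", "albiglutide", "exenatide", "liraglutide", "semaglutide"},
            "SGLT2i": {"empagliflozin", "canagliflozin", "dapagliflozin", "ertugliflozin", "bexagliflozin", "sotagliflozin"},
            "thiazolidinediones": {"pioglitazone", "rosiglitazone"},
        }
    )
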