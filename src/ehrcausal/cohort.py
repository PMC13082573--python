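"""New-user active-comparator cohort construction from a coded event stream.

Stages, applied per patient:

1. medication-episode detection — a drug ingredient counts as an actual
   treatment only if two of its medication codes occur 30 to 180 days apart
   (inclusive); the initiation date is the first code of the earliest
   qualifying pair;
2. index/arm assignment — the earliest initiation among the four
   second-line intervention classes sets the index date and study group;
3. eligibility — age strictly over 18 at index, metformin initiation
   strictly before index, at least one encounter more than 365 days before
   index and one more than 30 days after index (all strict comparisons);
4. outcome derivation — composite of first post-index HF hospitalization or
   death, censored at the last recorded encounter;
5. switch flagging — initiation of a different intervention class within
   the follow-up horizon, for the per-protocol sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from ehrcausal.events import DrugClassMap, INTERVENTION_CLASSES, days_to_date

logger = logging.getLogger(__name__)

#: Default horizon: 5 years including one leap day.
DEFAULT_TAU_DAYS = 1826

PAIR_GAP_MIN = 30
PAIR_GAP_MAX = 180


@dataclass(frozen=True)
class MedicationEpisode:
    patient_id: str
    ingredient: str
    drug_class: str
    initiation_day: int


@dataclass
class CohortRecord:
    """One eligible patient's analysis row.

    ``follow_days`` is time from index to the first of (HF hospitalization,
    death, last encounter); ``event`` is 1 when the composite outcome
    occurred at that time.  ``status_known`` indicates whether the
    fixed-horizon outcome is determined (event by tau, or follow-up past
    tau); ``outcome_by_tau`` is only meaningful when ``status_known`` is 1.
    """

    patient_id: str
    index_day: int
    arm: int
    drug_class: str
    follow_days: int
    event: int
    censored_at_last_encounter: bool
    outcome_by_tau: int
    status_known: int
    switched: bool
    tau_days: int

    def __post_init__(self) -> None:
        if self.follow_days < 0:
            raise ValueError("negative follow-up")
        if self.event == 1 and self.censored_at_last_encounter:
            raise ValueError("event and censoring are mutually exclusive")


def detect_medication_episodes(events: pd.DataFrame, classes: DrugClassMap) -> list[MedicationEpisode]:
    """Detect qualifying medication episodes for one patient.

    Scans all ordered pairs of same-ingredient MED event days; a pair whose
    gap d satisfies 30 <= d <= 180 establishes an episode, initiated at the
    first code of the earliest qualifying pair.  One episode per
    (patient, ingredient).  Input order is irrelevant.
    """
    system = events["system"].to_numpy()
    med_mask = system == "MED"
    codes = events["code"].to_numpy()[med_mask]
    days = events["day"].to_numpy()[med_mask]
    pids = events["patient_id"].to_numpy()[med_mask]
    episodes: list[MedicationEpisode] = []
    for pid in sorted(set(pids)):
        pmask = pids == pid
        for code in sorted(set(codes[pmask])):
            cls = classes.class_of(code)
            if cls is None:
                logger.warning("patient %s: MED code %r not in class map; ignored", pid, code)
                continue
            init = _earliest_qualifying_pair(np.sort(days[pmask & (codes == code)]))
            if init is not None:
                episodes.append(MedicationEpisode(str(pid), code, cls, int(init)))
    return episodes


def _earliest_qualifying_pair(days: np.ndarray) -> int | None:
    """First-code day of the earliest pair with gap in [30, 180], else None."""
    # all ordered pairs; days sorted ascending so the first hit is earliest
    for i in range(len(days)):
        gaps = days[i + 1:] - days[i]
        if np.any((gaps >= PAIR_GAP_MIN) & (gaps <= PAIR_GAP_MAX)):
            return int(days[i])
    return None


def assign_index_and_arm(
    episodes: list[MedicationEpisode], comparison: tuple[str, str]
) -> tuple[int, int, str] | tuple[None, None, str]:
    """Assign index day and arm from the earliest intervention-class episode.

    ``comparison`` is an ordered (arm-1 class, arm-0 class) pair.  Returns
    ``(index_day, arm, drug_class)`` or ``(None, None, reason)`` when no
    assignment is possible: no intervention episode, ambiguous same-day
    initiation of two classes, or a group outside the requested comparison.
    """
    for cls in comparison:
        if cls not in INTERVENTION_CLASSES:
            raise ValueError(f"{cls!r} is not an intervention class")
    interventions = [e for e in episodes if e.drug_class in INTERVENTION_CLASSES]
    if not interventions:
        return None, None, "no_intervention_episode"
    first_day = min(e.initiation_day for e in interventions)
    first_classes = {e.drug_class for e in interventions if e.initiation_day == first_day}
    if len(first_classes) > 1:
        return None, None, "ambiguous_combination_initiation"
    cls = first_classes.pop()
    if cls not in comparison:
        return None, None, "class_not_in_comparison"
    return first_day, int(cls == comparison[0]), cls


# eligibility reasons, in report/attrition order
ELIGIBILITY_REASONS = ("unknown_age", "age_not_over_18", "no_prior_metformin",
                      "no_established_care", "no_maintained_care")


def apply_eligibility(
    events: pd.DataFrame, episodes: list[MedicationEpisode], index_day: int
) -> tuple[bool, list[str]]:
    """Apply the four eligibility criteria; all comparisons strict.

    Age is computed from the DEMOG BIRTH_DATE event (its date is the birth
    date) and must strictly exceed 18 years at index; a metformin episode
    must initiate strictly before index; at least one encounter must occur
    more than 365 days before index and one more than 30 days after.
    """
    reasons: list[str] = []
    system = events["system"].to_numpy()
    code = events["code"].to_numpy()
    day = events["day"].to_numpy()
    birth = day[(system == "DEMOG") & (code == "BIRTH_DATE")]
    if birth.size == 0:
        reasons.append("unknown_age")
    else:
        age_years = (index_day - int(birth[0])) / 365.25
        if not age_years > 18:
            reasons.append("age_not_over_18")
    if not any(e.drug_class == "metformin" and e.initiation_day < index_day for e in episodes):
        reasons.append("no_prior_metformin")
    enc_days = day[system == "ENCOUNTER"]
    if not np.any(enc_days < index_day - 365):
        reasons.append("no_established_care")
    if not np.any(enc_days > index_day + 30):
        reasons.append("no_maintained_care")
    return (not reasons), reasons


def derive_outcome(
    events: pd.DataFrame, index_day: int, tau_days: int = DEFAULT_TAU_DAYS
) -> tuple[int, int, bool, int, int]:
    """Derive the composite outcome for an eligible patient.

    Returns ``(follow_days, event, censored_at_last_encounter,
    outcome_by_tau, status_known)``.  The event time is the first of HF
    hospitalization after index or death; censoring time is the last
    encounter.  The fixed-horizon status is known when the event occurred
    by tau or follow-up extends to tau.
    """
    system = events["system"].to_numpy()
    day = events["day"].to_numpy()
    hf = day[(system == "HF_HOSP") & (day > index_day)]
    death = day[system == "DEATH"]
    candidates = []
    if hf.size:
        candidates.append(int(hf.min()))
    if death.size:
        candidates.append(int(death.min()))
    t_event = min(candidates) if candidates else None
    enc = day[system == "ENCOUNTER"]
    if enc.size == 0 or int(enc.max()) < index_day:
        raise ValueError("last encounter precedes index; eligibility contract violated")
    t_cens = int(enc.max())
    if t_event is not None and t_event <= t_cens:
        follow, event, censored = t_event - index_day, 1, False
    else:
        follow, event, censored = t_cens - index_day, 0, True
    outcome_by_tau = int(event == 1 and follow <= tau_days)
    status_known = int(outcome_by_tau == 1 or follow >= tau_days)
    return follow, event, censored, outcome_by_tau, status_known


def flag_switchers(
    episodes: list[MedicationEpisode], index_day: int, drug_class: str,
    tau_days: int = DEFAULT_TAU_DAYS,
) -> bool:
    """True iff another intervention class initiates in (index, index+tau]."""
    return any(
        e.drug_class in INTERVENTION_CLASSES
        and e.drug_class != drug_class
        and index_day < e.initiation_day <= index_day + tau_days
        for e in episodes
    )


def build_cohort(
    events: pd.DataFrame,
    classes: DrugClassMap,
    comparison: tuple[str, str],
    tau_days: int = DEFAULT_TAU_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full cohort construction over a multi-patient event frame.

    Returns ``(cohort, exclusions)``: one row per eligible patient
    (CohortRecord fields) and one row per excluded patient with its
    first-failure ``exclusion_reason``.
    """
    records: list[dict] = []
    exclusions: list[dict] = []
    for pid, grp in events.groupby("patient_id", sort=True):
        episodes = detect_medication_episodes(grp, classes)
        index_day, arm, cls = assign_index_and_arm(episodes, comparison)
        if index_day is None:
            exclusions.append({"patient_id": str(pid), "exclusion_reason": cls})
            continue
        eligible, reasons = apply_eligibility(grp, episodes, index_day)
        if not eligible:
            # first-failure attribution, in eligibility-rule order
            exclusions.append({"patient_id": str(pid), "exclusion_reason": reasons[0]})
            continue
        follow, event, censored, y_tau, known = derive_outcome(grp, index_day, tau_days)
        rec = CohortRecord(
            patient_id=str(pid),
            index_day=int(index_day),
            arm=int(arm),
            drug_class=cls,
            follow_days=int(follow),
            event=int(event),
            censored_at_last_encounter=censored,
            outcome_by_tau=y_tau,
            status_known=known,
            switched=flag_switchers(episodes, index_day, cls, tau_days),
            tau_days=int(tau_days),
        )
        records.append(asdict(rec))
    cohort = pd.DataFrame(records, columns=[f.name for f in CohortRecord.__dataclass_fields__.values()])
    excl = pd.DataFrame(exclusions, columns=["patient_id", "exclusion_reason"])
    return cohort, excl


def write_cohort_csv(cohort: pd.DataFrame, exclusions: pd.DataFrame, path) -> None:
    """Write cohort + exclusions as one CSV with an ``exclusion_reason`` column."""
    a = cohort.copy()
    a["exclusion_reason"] = ""
    a["index_date"] = [days_to_date(d).isoformat() for d in a["index_day"]]
    b = exclusions.copy()
    b["exclusion_reason"] = b["exclusion_reason"].astype(str)
    out = pd.concat([a, b], ignore_index=True)
    out.to_csv(path, index=False)
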