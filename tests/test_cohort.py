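"""Cohort construction: pairing rule, index/arm, eligibility, outcome, switching."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehrcausal.cohort import (
    apply_eligibility,
    assign_index_and_arm,
    build_cohort,
    derive_outcome,
    detect_medication_episodes,
    flag_switchers,
)
from ehrcausal.events import default_class_map

from conftest import basic_patient, ev, events_frame

COMPARISON = ("insulin", "sulfonylureas")


def med_events(days, pid="p", code="glipizide"):
    return events_frame([ev(pid, d, "MED", code) for d in days])


def brute_force_initiation(days):
    """Independent oracle: scan every ordered pair, earliest qualifying start."""
    qualifying = [
        (a, b) for a, b in itertools.combinations(sorted(days), 2) if 30 <= b - a <= 180
    ]
    return min(q[0] for q in qualifying) if qualifying else None


class TestEpisodeDetection:
    def test_simple_pair(self, class_map):
        eps = detect_medication_episodes(med_events([10, 80]), class_map)
        assert len(eps) == 1
        assert eps[0].initiation_day == 10
        assert eps[0].drug_class == "sulfonylureas"

    def test_gap_too_short(self, class_map):
        assert detect_medication_episodes(med_events([10, 20]), class_map) == []

    def test_nonconsecutive_pair(self, class_map):
        # (0,200) and (0,260) exceed 180; (200,260) qualifies
        eps = detect_medication_episodes(med_events([0, 200, 260]), class_map)
        assert len(eps) == 1
        assert eps[0].initiation_day == 200
        assert brute_force_initiation([0, 200, 260]) == 200

    def test_unknown_code_ignored(self, class_map, caplog):
        with caplog.at_level("WARNING"):
            eps = detect_medication_episodes(med_events([10, 80], code="aspirin"), class_map)
        assert eps == []
        assert "aspirin" in caplog.text

    @given(st.lists(st.integers(0, 400), min_size=1, max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, days):
        cm = default_class_map()
        eps = detect_medication_episodes(med_events(days), cm)
        expected = brute_force_initiation(days)
        got = eps[0].initiation_day if eps else None
        assert got == expected

    @given(st.permutations(list(range(6))))
    @settings(max_examples=25, deadline=None)
    def test_order_insensitive(self, perm):
        cm = default_class_map()
        days = [0, 45, 100, 290, 300, 500]
        shuffled = [days[i] for i in perm]
        assert detect_medication_episodes(med_events(shuffled), cm) == \
            detect_medication_episodes(med_events(days), cm)


class TestIndexAssignment:
    def test_earliest_wins(self, class_map):
        rows = med_events([500, 560]).values.tolist() + \
            med_events([900, 960], code="insulin").values.tolist()
        eps = detect_medication_episodes(events_frame(rows), class_map)
        index_day, arm, cls = assign_index_and_arm(eps, COMPARISON)
        assert (index_day, arm, cls) == (500, 0, "sulfonylureas")

    def test_non_intervention_class_gives_no_assignment(self, class_map):
        eps = detect_medication_episodes(med_events([100, 160], code="empagliflozin"), class_map)
        index_day, arm, reason = assign_index_and_arm(eps, COMPARISON)
        assert index_day is None
        assert reason == "no_intervention_episode"

    def test_same_day_two_classes_ambiguous(self, class_map):
        rows = med_events([500, 560], code="insulin").values.tolist() + \
            med_events([500, 570], code="sitagliptin").values.tolist()
        eps = detect_medication_episodes(events_frame(rows), class_map)
        _, _, reason = assign_index_and_arm(eps, ("insulin", "DPP4i"))
        assert reason == "ambiguous_combination_initiation"

    def test_class_outside_comparison_excluded(self, class_map):
        eps = detect_medication_episodes(med_events([500, 560], code="sitagliptin"), class_map)
        _, _, reason = assign_index_and_arm(eps, COMPARISON)
        assert reason == "class_not_in_comparison"

    def test_invalid_comparison_class(self, class_map):
        with pytest.raises(ValueError, match="not an intervention class"):
            assign_index_and_arm([], ("insulin", "SGLT2i"))


class TestEligibility:
    def run(self, rows, class_map, index_day=2000):
        df = events_frame(rows)
        eps = detect_medication_episodes(df, class_map)
        return apply_eligibility(df, eps, index_day)

    def test_all_criteria_met(self, class_map):
        ok, reasons = self.run(basic_patient("p"), class_map)
        assert ok and reasons == []

    def test_established_care_boundary_fails(self, class_map):
        # encounter at exactly index-365 does not satisfy the strict rule
        rows = basic_patient("p", encounters=(2000 - 365, 2031))
        ok, reasons = self.run(rows, class_map)
        assert not ok and reasons == ["no_established_care"]

    def test_maintained_care_boundary_fails(self, class_map):
        rows = basic_patient("p", encounters=(1600, 2030))
        ok, reasons = self.run(rows, class_map)
        assert not ok and reasons == ["no_maintained_care"]

    def test_age_boundary(self, class_map):
        # 6574 days / 365.25 < 18 years exactly fails; 6575 passes
        ok, reasons = self.run(basic_patient("p", birth_offset=6574), class_map)
        assert not ok and reasons == ["age_not_over_18"]
        ok, _ = self.run(basic_patient("p", birth_offset=6575), class_map)
        assert ok

    def test_missing_birth_date(self, class_map):
        rows = [r for r in basic_patient("p") if r[3] != "BIRTH_DATE"]
        ok, reasons = self.run(rows, class_map)
        assert not ok and reasons == ["unknown_age"]

    def test_metformin_on_index_day_fails(self, class_map):
        rows = basic_patient("p", met_day=2000)
        ok, reasons = self.run(rows, class_map)
        assert not ok and reasons == ["no_prior_metformin"]

    def test_monotone_in_encounters(self, class_map):
        # adding encounters never turns an eligible patient ineligible
        rows = basic_patient("p")
        ok, _ = self.run(rows, class_map)
        assert ok
        for extra_day in (100, 1998, 2001, 5000):
            ok2, _ = self.run(rows + [ev("p", extra_day, "ENCOUNTER", "ENC")], class_map)
            assert ok2


class TestOutcome:
    def frame(self, encounters, extra=()):
        rows = [ev("p", d, "ENCOUNTER", "ENC") for d in encounters] + list(extra)
        return events_frame(rows)

    def test_event_before_censoring(self):
        df = self.frame([1634, 2031, 2900], [ev("p", 2400, "HF_HOSP", "HF_HOSP")])
        T, d, cens, y, known = derive_outcome(df, 2000, 1826)
        assert (T, d, cens, y, known) == (400, 1, False, 1, 1)

    def test_censored_before_tau(self):
        df = self.frame([1634, 2031, 3000])
        T, d, cens, y, known = derive_outcome(df, 2000, 1826)
        assert (T, d, cens, y, known) == (1000, 0, True, 0, 0)

    def test_death_after_tau_known_negative(self):
        # composite event occurs, but past the horizon: status known, outcome 0
        df = self.frame([1634, 2031, 4000], [ev("p", 4000, "DEATH", "DEATH")])
        T, d, cens, y, known = derive_outcome(df, 2000, 1826)
        assert (T, d, cens, y, known) == (2000, 1, False, 0, 1)

    def test_event_after_last_encounter_is_censored(self):
        df = self.frame([1634, 2031, 2500], [ev("p", 2600, "HF_HOSP", "HF_HOSP")])
        T, d, cens, y, known = derive_outcome(df, 2000, 1826)
        assert (T, d, cens) == (500, 0, True)

    def test_last_encounter_before_index_raises(self):
        df = self.frame([1634, 1900])
        with pytest.raises(ValueError, match="precedes index"):
            derive_outcome(df, 2000, 1826)


class TestSwitchers:
    def episodes(self, rows, class_map):
        return detect_medication_episodes(events_frame(rows), class_map)

    def test_switch_detected(self, class_map):
        rows = med_events([2600, 2660], code="insulin").values.tolist()
        eps = self.episodes(rows, class_map)
        assert flag_switchers(eps, 2000, "sulfonylureas", 1826)

    def test_metformin_continuation_not_switch(self, class_map):
        rows = med_events([2600, 2660], code="metformin").values.tolist()
        eps = self.episodes(rows, class_map)
        assert not flag_switchers(eps, 2000, "sulfonylureas", 1826)

    def test_post_index_pair_rule(self, class_map):
        # DPP4i codes at index+100 and index+150 satisfy the pairing rule
        rows = med_events([2100, 2150], code="sitagliptin").values.tolist()
        eps = self.episodes(rows, class_map)
        assert flag_switchers(eps, 2000, "GLP1RA", 1826)

    def test_switch_outside_horizon_ignored(self, class_map):
        rows = med_events([2000 + 1827, 2000 + 1890], code="insulin").values.tolist()
        eps = self.episodes(rows, class_map)
        assert not flag_switchers(eps, 2000, "sulfonylureas", 1826)


def twelve_patient_fixture():
    """Hand-built fixture exercising every eligibility rule and boundary."""
    rows = []
    rows += basic_patient("P01", extra=[ev("P01", 2400, "HF_HOSP", "HF_HOSP")])
    rows += basic_patient("P02", encounters=(1635, 2040))  # exactly index-365
    rows += basic_patient("P03", encounters=(1600, 2030))  # exactly index+30
    rows += basic_patient("P04", birth_offset=6574)  # age exactly under the line
    rows += basic_patient("P05", birth_offset=6575, encounters=(1634, 2031, 3000))
    rows += [r for r in basic_patient("P06") if r[3] != "BIRTH_DATE"]
    # P07: single metformin code, no qualifying pair
    rows += [r for r in basic_patient("P07")
             if not (r[3] == "metformin" and r[1] == 1560)]
    rows += basic_patient("P08", met_day=2000)  # metformin initiates on index day
    # P09: metformin codes 10 days apart
    p09 = basic_patient("P09", met_day=1500)
    rows += [ev("P09", 1510, "MED", "metformin") if r[1] == 1560 and r[3] == "metformin" else r
             for r in p09]
    # P10: intervention codes never form a pair
    p10 = basic_patient("P10")
    rows += [r for r in p10 if not (r[3] == "glipizide" and r[1] == 2060)]
    rows += [ev("P10", 2010, "MED", "glipizide")]
    # P11: two classes initiate the same day
    rows += basic_patient("P11", extra=[ev("P11", 2000, "MED", "insulin"),
                                        ev("P11", 2070, "MED", "insulin")])
    rows += basic_patient("P12", ingredient="insulin",
                          encounters=(1634, 2031, 4000),
                          extra=[ev("P12", 4000, "DEATH", "DEATH")])
    rows += basic_patient("P13", ingredient="sitagliptin")
    return events_frame(rows)


class TestBuildCohort:
    def test_twelve_patient_fixture(self, class_map):
        cohort, excl = build_cohort(twelve_patient_fixture(), class_map, COMPARISON, 1826)
        assert sorted(cohort["patient_id"]) == ["P01", "P05", "P12"]
        expected_reasons = {
            "P02": "no_established_care",
            "P03": "no_maintained_care",
            "P04": "age_not_over_18",
            "P06": "unknown_age",
            "P07": "no_prior_metformin",
            "P08": "no_prior_metformin",
            "P09": "no_prior_metformin",
            "P10": "no_intervention_episode",
            "P11": "ambiguous_combination_initiation",
            "P13": "class_not_in_comparison",
        }
        got = dict(zip(excl["patient_id"], excl["exclusion_reason"]))
        assert got == expected_reasons
        rec = cohort.set_index("patient_id")
        assert rec.loc["P01", "arm"] == 0
        assert rec.loc["P01", "follow_days"] == 400
        assert rec.loc["P01", "event"] == 1
        assert rec.loc["P12", "arm"] == 1
        assert rec.loc["P12", "follow_days"] == 2000
        assert rec.loc["P12", "event"] == 1
        assert rec.loc["P12", "outcome_by_tau"] == 0
        assert rec.loc["P12", "status_known"] == 1
        assert rec.loc["P05", "event"] == 0

    def test_attrition_accounting(self, class_map):
        events = twelve_patient_fixture()
        cohort, excl = build_cohort(events, class_map, COMPARISON, 1826)
        assert len(cohort) + len(excl) == events["patient_id"].nunique()
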