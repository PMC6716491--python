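import datetime as dt

import numpy as np
import pytest

from asthma_triggers.attribution import (
    BETWEEN_SEASONS,
    MAJOR_TRIGGER_LABELS,
    ConditionNeverHoldsError,
    ContributorCounts,
    MajorTriggerResult,
    TriggerCondition,
    adherence,
    assign_season,
    cohort_summary,
    conditional_probability,
    contributor_day_counts,
    default_conditions,
    major_trigger,
    probability_table,
)
from asthma_triggers.records import ValidationError
from conftest import make_flags, make_status

TRIGGERS4 = ("pollen", "pm25", "ozone", "temperature")


def random_day_table(rng, n_days=None):
    """Random (statuses, exposures) pair with day-level flags."""
    n_days = n_days or int(rng.integers(5, 91))
    statuses, exposures = [], []
    for i in range(n_days):
        answered = rng.random() < 0.8
        statuses.append(make_status(
            i, answered=answered,
            symptoms=tuple(s for s in ("cough", "wheeze")
                           if rng.random() < 0.4),
            rescue=bool(rng.random() < 0.3),
            awakening=bool(rng.random() < 0.2),
            limitation=bool(rng.random() < 0.2),
            controller=int(rng.integers(0, 3))))
        exposures.append(make_flags(
            i, **{t: bool(rng.random() < 0.5) for t in TRIGGERS4}))
    return statuses, exposures


class TestConditionalProbability:
    def test_count_ratio(self):
        statuses = [make_status(i, symptoms=("cough",) if i < 4 else ())
                    for i in range(10)]
        exposures = [make_flags(i, pm25=True) for i in range(10)]
        cell = conditional_probability(statuses, exposures, "cough",
                                       TriggerCondition("pm25",
                                                        {"pm25": True}))
        assert (cell.numerator, cell.denominator) == (4, 10)
        assert cell.probability == 0.4

    def test_outcome_never_occurring_gives_zero(self):
        statuses = [make_status(i) for i in range(6)]
        exposures = [make_flags(i, pollen=True) for i in range(6)]
        cell = conditional_probability(statuses, exposures, "wheeze",
                                       TriggerCondition("pollen",
                                                        {"pollen": True}))
        assert cell.probability == 0.0

    def test_condition_never_holding_is_an_error(self):
        statuses = [make_status(0)]
        exposures = [make_flags(0, pm25=False)]
        with pytest.raises(ConditionNeverHoldsError):
            conditional_probability(statuses, exposures, "cough",
                                    TriggerCondition("pm25", {"pm25": True}))

    def test_matches_double_loop_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        outcomes = ("cough", "wheeze", "activity_limitation",
                    "nighttime_awakenings", "rescue_medication_intake")
        for _ in range(60):
            statuses, exposures = random_day_table(rng)
            for trigger in TRIGGERS4[:2]:
                for required in (True, False):
                    condition = TriggerCondition("c", {trigger: required})
                    for outcome in outcomes:
                        num = den = 0
                        for s, e in zip(statuses, exposures):
                            if not s.answered:
                                continue
                            if e.effective[trigger] != required:
                                continue
                            den += 1
                            value = {
                                "activity_limitation": s.activity_limitation,
                                "nighttime_awakenings":
                                    s.nighttime_awakening,
                                "rescue_medication_intake": s.rescue_taken,
                            }.get(outcome, s.symptom_any.get(outcome, False))
                            num += bool(value)
                        if den == 0:
                            with pytest.raises(ConditionNeverHoldsError):
                                conditional_probability(
                                    statuses, exposures, outcome, condition)
                            continue
                        cell = conditional_probability(
                            statuses, exposures, outcome, condition)
                        assert (cell.numerator, cell.denominator) == (num,
                                                                      den)

    def test_law_of_total_count(self):
        rng = np.random.default_rng(3)
        statuses, exposures = random_day_table(rng, 60)
        pos = conditional_probability(statuses, exposures, "cough",
                                      TriggerCondition("c", {"pm25": True}))
        neg = conditional_probability(statuses, exposures, "cough",
                                      TriggerCondition("c", {"pm25": False}))
        answered = sum(1 for s in statuses if s.answered)
        assert pos.denominator + neg.denominator == answered

    def test_exclusion_invariance(self):
        rng = np.random.default_rng(9)
        statuses, exposures = random_day_table(rng, 50)
        kept = [s for s in statuses if s.answered]
        condition = TriggerCondition("c", {"pollen": True})
        a = conditional_probability(statuses, exposures, "cough", condition)
        b = conditional_probability(kept, exposures, "cough", condition)
        assert a == b
        assert contributor_day_counts(statuses, exposures).per_trigger == \
            contributor_day_counts(kept, exposures).per_trigger
        assert adherence(statuses) == adherence(kept)


class TestProbabilityTable:
    def test_two_condition_layout(self):
        statuses = [make_status(i, symptoms=("cough",) if i % 3 == 0 else ())
                    for i in range(20)]
        exposures = [make_flags(i, pollen=i >= 10, pm25=True)
                     for i in range(20)]
        conditions = default_conditions(exposures, statuses)
        table = probability_table(statuses, exposures, conditions)
        assert [c.name for c in table.conditions] == ["pollen and pm25",
                                                      "no pollen and pm25"]
        assert table.outcomes == (
            "cough", "wheeze", "chest_tightness", "activity_limitation",
            "nighttime_awakenings", "rescue_medication_intake")

    def test_single_constant_condition_layout(self):
        statuses = [make_status(i) for i in range(10)]
        exposures = [make_flags(i, pollen=False, pm25=True, ozone=False)
                     for i in range(10)]
        conditions = default_conditions(exposures, statuses)
        assert [c.name for c in conditions] == ["pm25"]

    def test_cells_match_conditional_probability(self):
        rng = np.random.default_rng(17)
        statuses, exposures = random_day_table(rng, 70)
        conditions = [TriggerCondition("a", {"pollen": True}),
                      TriggerCondition("b", {"pollen": False, "pm25": True})]
        table = probability_table(statuses, exposures, conditions)
        for (outcome, name), cell in table.cells.items():
            condition = next(c for c in conditions if c.name == name)
            assert cell == conditional_probability(statuses, exposures,
                                                   outcome, condition)


class TestContributorCounts:
    def test_no_episode_days_gives_zero_counts(self):
        statuses = [make_status(i) for i in range(10)]
        exposures = [make_flags(i, pm25=True) for i in range(10)]
        counts = contributor_day_counts(statuses, exposures)
        assert counts.episode_days == 0
        assert all(v == 0 for v in counts.per_trigger.values())

    def test_trigger_unhealthy_every_day(self):
        statuses = [make_status(i, rescue=i < 7) for i in range(10)]
        exposures = [make_flags(i, pm25=True) for i in range(10)]
        counts = contributor_day_counts(statuses, exposures)
        assert counts.episode_days == 7
        assert counts.per_trigger["pm25"] == 7

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            statuses, exposures = random_day_table(rng)
            counts = contributor_day_counts(statuses, exposures)
            expected = {t: 0 for t in TRIGGERS4}
            episode_days = both = 0
            for s, e in zip(statuses, exposures):
                if not (s.answered and s.episode):
                    continue
                episode_days += 1
                for t in TRIGGERS4:
                    expected[t] += e.effective[t]
                both += e.effective["pollen"] and e.effective["pm25"]
            assert counts.episode_days == episode_days
            assert counts.per_trigger == expected
            assert counts.pollen_pm25_both == both

    def test_window_consistency_with_conditional_probability(self):
        rng = np.random.default_rng(31)
        statuses, exposures = random_day_table(rng, 80)
        counts = contributor_day_counts(statuses, exposures)
        # denominator of P(. | pm25) = answered days with pm25 effective;
        # the contributor count for pm25 ranges over the episode subset
        cell = conditional_probability(statuses, exposures, "cough",
                                       TriggerCondition("c", {"pm25": True}))
        episode_days_with_pm25 = sum(
            1 for s, e in zip(statuses, exposures)
            if s.answered and s.episode and e.effective["pm25"])
        assert counts.per_trigger["pm25"] == episode_days_with_pm25
        assert counts.per_trigger["pm25"] <= cell.denominator


def _counts(episode_days, answered=50, both=0, **per_trigger):
    full = {t: per_trigger.get(t, 0) for t in TRIGGERS4}
    return ContributorCounts(answered, episode_days, full, both)


class TestMajorTrigger:
    def test_too_few_episode_days_is_no_symptoms(self):
        result = major_trigger(_counts(0), "P", "winter")
        assert result.label == "no_symptoms"
        result = major_trigger(_counts(4, pm25=4), "P", "winter")
        assert result.label == "no_symptoms"

    def test_clear_argmax(self):
        result = major_trigger(_counts(10, pollen=9, pm25=1, both=1),
                               "P", "spring")
        assert result.label == "pollen"
        assert result.fractions["pollen"] == pytest.approx(0.9)

    def test_joint_pollen_pm25_label(self):
        result = major_trigger(_counts(10, pollen=9, pm25=9, both=9),
                               "P", "spring")
        assert result.label == "pollen_and_pm25"

    def test_joint_label_requires_co_occurrence(self):
        result = major_trigger(_counts(10, pollen=9, pm25=9, both=3),
                               "P", "spring")
        assert result.label in ("pollen", "pm25", "inconclusive")
        assert result.label == "inconclusive"  # exact tie 0.9 vs 0.9

    def test_all_zero_fractions_is_inconclusive(self):
        result = major_trigger(_counts(8), "P", "fall")
        assert result.label == "inconclusive"


class TestAdherence:
    def test_day_level_percentage(self):
        statuses = [make_status(i, controller=1 if i < 25 else 0)
                    for i in range(50)]
        assert adherence(statuses) == pytest.approx(50.0)

    def test_never_taken_is_zero(self):
        statuses = [make_status(i) for i in range(10)]
        assert adherence(statuses) == 0.0

    def test_session_level_mode(self):
        statuses = [make_status(i, controller=1 if i < 30 else 0)
                    for i in range(50)]
        assert adherence(statuses, mode="session") == pytest.approx(30.0)

    def test_no_answered_days_is_an_error(self):
        with pytest.raises(ValidationError):
            adherence([make_status(0, answered=False)])


class TestSeasonsAndSummary:
    def test_single_season_deployment(self):
        statuses = [make_status(i) for i in range(20)]  # January
        assert assign_season(statuses) == "winter"

    def test_straddling_deployment_is_between_seasons(self):
        statuses = [make_status(i) for i in range(31, 91)]  # Feb-Mar 2018
        assert assign_season(statuses) == BETWEEN_SEASONS

    def test_single_patient_summary(self):
        result = MajorTriggerResult("P", "spring", "pollen", {}, 10, 40)
        summary = cohort_summary([result])
        assert summary.rows == [("spring", 1,
                                 {label: (100.0 if label == "pollen" else 0.0)
                                  for label in MAJOR_TRIGGER_LABELS})]

    def test_empty_cohort_gives_empty_summary(self):
        assert cohort_summary([]).rows == []

    def test_matches_tally_oracle(self):
        rng = np.random.default_rng(5)
        seasons = ["spring", "summer", "fall", "winter", BETWEEN_SEASONS]
        results = [
            MajorTriggerResult(
                f"P{i}", seasons[int(rng.integers(0, 5))],
                MAJOR_TRIGGER_LABELS[int(rng.integers(0, 7))], {}, 10, 40)
            for i in range(83)]
        summary = cohort_summary(results)
        assert sum(n for _, n, _ in summary.rows) == 83
        for season, n, percentages in summary.rows:
            members = [r for r in results if r.season == season]
            assert n == len(members)
            for label in MAJOR_TRIGGER_LABELS:
                expected = 100.0 * sum(r.label == label
                                       for r in members) / n
                assert percentages[label] == pytest.approx(expected)
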