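"""Personalized trigger attribution.

The central statistic is the conditional probability

    P(outcome | condition) = #{answered days: condition holds and outcome}
                             / #{answered days: condition holds}

where the condition is a conjunction of boolean literals over the
effective-exposure flags (trigger outside its healthy range on the day or
the previous day) and the outcome is a diary symptom, activity
limitation, a nighttime awakening, or rescue-medication intake. Days the
patient did not answer the questionnaire are excluded from every count,
and a day on which a referenced trigger was not observed contributes to
neither numerator nor denominator.

On top of the per-patient probability profile the module computes
contributor day-counts (episode days on which each trigger was in its
exposure window), a per-patient *major trigger* label, controller-
medication adherence, and the cohort-level per-season label summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .daily import ExposureFlags
from .episodes import DailyStatus
from .io import format_probability
from .records import SEASONS, TRIGGERS, SeasonCalendar, ValidationError

#: Outcome rows of the per-patient probability table, in table order.
DEFAULT_OUTCOMES = (
    "cough",
    "wheeze",
    "chest_tightness",
    "activity_limitation",
    "nighttime_awakenings",
    "rescue_medication_intake",
)

#: Major-trigger labels, in cohort-summary column order.
MAJOR_TRIGGER_LABELS = ("pollen", "pm25", "ozone", "pollen_and_pm25",
                        "temperature", "no_symptoms", "inconclusive")

BETWEEN_SEASONS = "between_seasons"


class ConditionNeverHoldsError(ValidationError):
    """Zero denominator: the condition holds on no answered day."""


@dataclass(frozen=True)
class TriggerCondition:
    """A conjunction of required effective-exposure values.

    ``literals`` maps trigger name to the boolean it must take, e.g.
    ``{"pollen": True, "pm25": True}`` or ``{"pollen": False, "pm25": True}``.
    """

    name: str
    literals: dict[str, bool]

    def __post_init__(self) -> None:
        if not self.literals:
            raise ValidationError("condition needs at least one literal")

    def evaluable(self, flags: ExposureFlags) -> bool:
        return all(t in flags.effective for t in self.literals)

    def holds(self, flags: ExposureFlags) -> bool:
        return all(flags.effective.get(t) == req
                   for t, req in self.literals.items())

    @staticmethod
    def describe(literals: dict[str, bool]) -> str:
        parts = [t if req else f"no {t}" for t, req in literals.items()]
        return " and ".join(parts)


@dataclass(frozen=True)
class ProbabilityCell:
    numerator: int
    denominator: int

    @property
    def probability(self) -> float:
        return self.numerator / self.denominator


@dataclass
class ProbabilityTable:
    """P(outcome | condition) matrix for one patient, with counts."""

    patient_id: str
    outcomes: tuple[str, ...]
    conditions: tuple[TriggerCondition, ...]
    cells: dict[tuple[str, str], ProbabilityCell] = field(default_factory=dict)

    def probability(self, outcome: str, condition_name: str) -> float:
        return self.cells[(outcome, condition_name)].probability


def _outcome_value(status: DailyStatus, outcome: str) -> bool:
    if outcome == "activity_limitation":
        return status.activity_limitation
    if outcome == "nighttime_awakenings":
        return status.nighttime_awakening
    if outcome == "rescue_medication_intake":
        return status.rescue_taken
    if outcome in status.symptom_any or not status.symptom_any:
        return bool(status.symptom_any.get(outcome))
    raise ValidationError(f"unknown outcome {outcome!r}")


def _paired(statuses: list[DailyStatus], exposures: list[ExposureFlags]
            ) -> list[tuple[DailyStatus, ExposureFlags]]:
    by_date = {e.date: e for e in exposures}
    return [(s, by_date[s.date]) for s in statuses
            if s.answered and s.date in by_date]


def conditional_probability(
    statuses: list[DailyStatus],
    exposures: list[ExposureFlags],
    outcome: str,
    condition: TriggerCondition,
) -> ProbabilityCell:
    """The count-ratio statistic over answered days (see module docstring)."""
    num = den = 0
    for status, flags in _paired(statuses, exposures):
        if not (condition.evaluable(flags) and condition.holds(flags)):
            continue
        den += 1
        if _outcome_value(status, outcome):
            num += 1
    if den == 0:
        raise ConditionNeverHoldsError(
            f"condition {condition.name!r} holds on no answered day")
    return ProbabilityCell(num, den)


def probability_table(
    statuses: list[DailyStatus],
    exposures: list[ExposureFlags],
    conditions: list[TriggerCondition],
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES,
) -> ProbabilityTable:
    """One cell per (outcome, condition); cells whose condition never
    holds are omitted rather than emitted with a zero denominator."""
    if not conditions:
        raise ValidationError("conditions must be nonempty")
    if not statuses:
        raise ValidationError("no statuses supplied")
    table = ProbabilityTable(statuses[0].patient_id, tuple(outcomes),
                             tuple(conditions))
    for condition in conditions:
        for outcome in outcomes:
            try:
                cell = conditional_probability(statuses, exposures, outcome,
                                               condition)
            except ConditionNeverHoldsError:
                continue
            table.cells[(outcome, condition.name)] = cell
    return table


def default_conditions(exposures: list[ExposureFlags],
                       statuses: list[DailyStatus] | None = None,
                       triggers: tuple[str, ...] = ("pollen", "pm25", "ozone"),
                       ) -> list[TriggerCondition]:
    """Choose the patient's conditioning set from which triggers vary.

    Over the answered days with exposure data: a trigger never in its
    exposure window is dropped; one always in it appears only as an
    always-true conjunct; triggers that vary are crossed over both values.
    This reproduces the two-column presence/absence layout when exactly one
    trigger varies, and a single all-present column when none does.
    """
    if statuses is not None:
        flags_list = [e for _, e in _paired(statuses, exposures)]
    else:
        flags_list = exposures
    varying, constant_true = [], []
    for t in triggers:
        values = {e.effective[t] for e in flags_list if t in e.effective}
        if values == {True, False}:
            varying.append(t)
        elif values == {True}:
            constant_true.append(t)
    if not varying and not constant_true:
        raise ConditionNeverHoldsError(
            "no trigger is ever in its exposure window for this patient")
    combos: list[dict[str, bool]] = [{}]
    for t in varying:
        combos = [{**c, t: v} for v in (True, False) for c in combos]
    conditions = []
    for combo in combos:
        literals = {t: combo[t] for t in triggers if t in combo}
        literals.update({t: True for t in constant_true})
        conditions.append(TriggerCondition(
            TriggerCondition.describe(literals), literals))
    return conditions


@dataclass(frozen=True)
class ContributorCounts:
    """Episode-day attribution counts for one patient."""

    answered_days: int
    episode_days: int
    per_trigger: dict[str, int]           # episode days with t in window
    pollen_pm25_both: int = 0             # episode days with both in window


def contributor_day_counts(
    statuses: list[DailyStatus],
    exposures: list[ExposureFlags],
    triggers: tuple[str, ...] = TRIGGERS,
) -> ContributorCounts:
    """For each trigger, the number of episode days on which it was in its
    unhealthy range on the day or the previous day."""
    paired = _paired(statuses, exposures)
    answered = sum(1 for s in statuses if s.answered)
    episode_days = sum(1 for s, _ in paired if s.episode)
    counts = {t: 0 for t in triggers}
    both = 0
    for status, flags in paired:
        if not status.episode:
            continue
        for t in triggers:
            if flags.effective.get(t):
                counts[t] += 1
        if flags.effective.get("pollen") and flags.effective.get("pm25"):
            both += 1
    return ContributorCounts(answered, episode_days, counts, both)


@dataclass(frozen=True)
class MajorTriggerResult:
    patient_id: str
    season: str
    label: str
    fractions: dict[str, float]
    episode_day_count: int
    answered_day_count: int


def major_trigger(
    counts: ContributorCounts,
    patient_id: str,
    season: str,
    min_episode_days: int = 5,
    combo_threshold: float = 0.8,
) -> MajorTriggerResult:
    """Label the patient's dominant trigger for the season.

    Fewer than ``min_episode_days`` episode days -> ``no_symptoms`` (too
    few episodes to conclude anything). Otherwise each trigger's fraction
    of episode days is computed; pollen and PM2.5 jointly dominant (each
    fraction and their same-day co-occurrence fraction at or above
    ``combo_threshold``) -> the combined label; else the argmax fraction,
    with ties (including all-zero) -> ``inconclusive``.
    """
    if counts.episode_days < min_episode_days:
        return MajorTriggerResult(patient_id, season, "no_symptoms",
                                  {t: 0.0 for t in counts.per_trigger},
                                  counts.episode_days, counts.answered_days)
    fractions = {t: c / counts.episode_days
                 for t, c in counts.per_trigger.items()}
    both_frac = counts.pollen_pm25_both / counts.episode_days
    if (fractions.get("pollen", 0.0) >= combo_threshold
            and fractions.get("pm25", 0.0) >= combo_threshold
            and both_frac >= combo_threshold):
        label = "pollen_and_pm25"
    else:
        best = max(fractions.values())
        leaders = [t for t, f in fractions.items()
                   if math.isclose(f, best, rel_tol=0.0, abs_tol=1e-12)]
        label = leaders[0] if len(leaders) == 1 and best > 0 else "inconclusive"
    return MajorTriggerResult(patient_id, season, label, fractions,
                              counts.episode_days, counts.answered_days)


def adherence(statuses: list[DailyStatus], mode: str = "day") -> float:
    """Controller-medication adherence as a percentage (full precision).

    ``day`` mode: percent of answered days with at least one controller
    intake. ``session`` mode: percent of the two daily sessions with an
    intake, over answered days.
    """
    answered = [s for s in statuses if s.answered]
    if not answered:
        raise ValidationError("adherence needs at least one answered day")
    if mode == "day":
        return 100.0 * sum(s.controller_sessions >= 1
                           for s in answered) / len(answered)
    if mode == "session":
        return 100.0 * sum(s.controller_sessions
                           for s in answered) / (2 * len(answered))
    raise ValidationError(f"unknown adherence mode {mode!r}")


def assign_season(statuses: list[DailyStatus],
                  calendar: SeasonCalendar | None = None,
                  dominance: float = 0.8) -> str:
    """The season holding >= ``dominance`` of the answered days, else
    ``between_seasons`` (the deployment straddles a calendar boundary)."""
    calendar = calendar or SeasonCalendar()
    answered = [s for s in statuses if s.answered]
    if not answered:
        raise ValidationError("cannot assign a season with no answered days")
    tally: dict[str, int] = {}
    for s in answered:
        season = calendar.season_of(s.date)
        tally[season] = tally.get(season, 0) + 1
    season, n = max(tally.items(), key=lambda kv: kv[1])
    return season if n / len(answered) >= dominance else BETWEEN_SEASONS


@dataclass
class CohortSummary:
    """Per-season patient counts and major-trigger label percentages."""

    rows: list[tuple[str, int, dict[str, float]]]  # (season, n, label -> %)


def cohort_summary(results: list[MajorTriggerResult]) -> CohortSummary:
    """Tally labels per season stratum (each patient counted once)."""
    strata = list(SEASONS) + [BETWEEN_SEASONS]
    by_season: dict[str, list[MajorTriggerResult]] = {s: [] for s in strata}
    for r in results:
        if r.season not in by_season:
            raise ValidationError(f"unknown season stratum {r.season!r}")
        by_season[r.season].append(r)
    rows = []
    for season in strata:
        members = by_season[season]
        if not members:
            continue
        percentages = {
            label: 100.0 * sum(r.label == label for r in members) / len(members)
            for label in MAJOR_TRIGGER_LABELS}
        rows.append((season, len(members), percentages))
    return CohortSummary(rows)


# ------------------------------------------------------------- rendering

def probability_table_to_csv(table: ProbabilityTable, path: str | Path) -> None:
    """Stable-order CSV with 2-decimal probabilities; cells without a
    valid denominator render empty."""
    names = [c.name for c in table.conditions]
    lines = [",".join(["outcome"] + [f"P(outcome | {n})" for n in names])]
    for outcome in table.outcomes:
        cells = []
        for name in names:
            cell = table.cells.get((outcome, name))
            cells.append("" if cell is None
                         else format_probability(cell.probability))
        lines.append(",".join([outcome] + cells))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")


def cohort_summary_to_csv(summary: CohortSummary, path: str | Path) -> None:
    header = ["season", "n"] + list(MAJOR_TRIGGER_LABELS)
    lines = [",".join(header)]
    for season, n, percentages in summary.rows:
        lines.append(",".join(
            [season, str(n)]
            + [str(round(percentages[label])) for label in MAJOR_TRIGGER_LABELS]))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")
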