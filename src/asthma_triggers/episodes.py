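"""Per-day status fusion and composite asthma-episode detection.

An *asthma episode* is a day-level composite: any of the six diary
symptoms, a nighttime awakening, activity limitation, rescue-medication
intake, or a lung-function reading more than one standard deviation below
the patient's own mean (PEF or FEV1, one-sided — only reductions count).

Days without at least one questionnaire response are "unanswered" and
carry no episode flag; downstream statistics exclude them entirely.
"""

from __future__ import annotations

import datetime as dt
import logging
import statistics
from dataclasses import dataclass, field

from .records import (
    LUNG_MEASURES,
    SYMPTOMS,
    DailyReport,
    LungReading,
    PatientDeployment,
    SessionReport,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Episode component labels, in reporting order.
EPISODE_COMPONENTS = tuple(SYMPTOMS) + (
    "nighttime_awakening", "activity_limitation", "rescue",
    "pef_abnormal", "fev1_abnormal",
)


class InsufficientBaselineError(ValidationError):
    """Fewer than two readings: no usable personal lung baseline."""


@dataclass(frozen=True)
class LungBaseline:
    """Per-patient mean and sample SD for one lung measure."""

    patient_id: str
    measure: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.measure not in LUNG_MEASURES:
            raise ValidationError(f"unknown lung measure {self.measure!r}")
        if self.sd < 0:
            raise ValidationError("baseline sd must be >= 0")
        if self.n < 2:
            raise ValidationError("baseline requires n >= 2")


@dataclass
class DailyStatus:
    """All streams for one patient-day fused into a single record."""

    patient_id: str
    date: dt.date
    answered: bool
    symptom_any: dict[str, bool] = field(default_factory=dict)
    nighttime_awakening: bool = False
    activity_limitation: bool = False
    rescue_taken: bool = False
    controller_sessions: int = 0
    lung_abnormal: dict[str, bool] = field(default_factory=dict)
    episode: bool = False
    components: frozenset[str] = frozenset()


def compute_lung_baseline(readings: list[LungReading],
                          measure: str) -> LungBaseline:
    """Mean and sample SD (denominator n-1) over all deployment readings
    of one measure; requires at least two readings."""
    if measure not in LUNG_MEASURES:
        raise ValidationError(f"unknown lung measure {measure!r}")
    values = [getattr(r, measure) for r in readings]
    if len(values) < 2:
        raise InsufficientBaselineError(
            f"need >= 2 {measure} readings for a baseline, got {len(values)}")
    return LungBaseline(
        patient_id=readings[0].patient_id, measure=measure,
        mean=statistics.fmean(values), sd=statistics.stdev(values),
        n=len(values))


def flag_abnormal(value: float, baseline: LungBaseline) -> bool:
    """True iff the value is strictly more than 1 SD below the mean.

    One-sided: elevated values are never abnormal, and a value exactly at
    mean - 1 SD is normal.
    """
    return value < baseline.mean - baseline.sd


def build_daily_status(
    sessions: list[SessionReport],
    daily: list[DailyReport],
    lung: list[LungReading],
    baselines: dict[str, LungBaseline],
    deployment: PatientDeployment,
) -> list[DailyStatus]:
    """Fuse the streams into one status per deployment day.

    A day is *answered* iff at least one session report exists for it;
    lung readings alone do not make a day answered. Session booleans fuse
    by OR, controller intake by session count, and a day's lung measure is
    abnormal iff any of its readings is.
    """
    for rec in [*sessions, *daily, *lung]:
        if rec.patient_id != deployment.patient_id:
            raise ValidationError(
                f"stream record for {rec.patient_id!r} passed with deployment "
                f"of {deployment.patient_id!r}")
    sessions_by_day: dict[dt.date, list[SessionReport]] = {}
    for s in sessions:
        sessions_by_day.setdefault(s.date, []).append(s)
    daily_by_day = {d.date: d for d in daily}
    lung_by_day: dict[dt.date, list[LungReading]] = {}
    for r in lung:
        lung_by_day.setdefault(r.date, []).append(r)

    out = []
    for date in deployment.days():
        day_sessions = sessions_by_day.get(date, [])
        status = DailyStatus(deployment.patient_id, date,
                             answered=bool(day_sessions))
        if not day_sessions:
            out.append(status)
            continue
        status.symptom_any = {
            s: any(r.symptoms[s] for r in day_sessions) for s in SYMPTOMS}
        status.rescue_taken = any(r.rescue_taken for r in day_sessions)
        status.controller_sessions = sum(
            r.controller_taken for r in day_sessions)
        report = daily_by_day.get(date)
        if report is not None:
            status.nighttime_awakening = report.nighttime_awakening
            status.activity_limitation = report.activity_limitation
        status.lung_abnormal = {
            m: any(flag_abnormal(getattr(r, m), baselines[m])
                   for r in lung_by_day.get(date, []))
            for m in LUNG_MEASURES if m in baselines}
        status.episode, status.components = detect_episode(status)
        out.append(status)
    return out


def detect_episode(status: DailyStatus) -> tuple[bool, frozenset[str]]:
    """Evaluate the composite episode rule on one answered day.

    Returns the flag and the set of component labels that held.
    """
    if not status.answered:
        raise ValidationError(
            f"detect_episode called on unanswered day {status.date}")
    components = {s for s in SYMPTOMS if status.symptom_any.get(s)}
    if status.nighttime_awakening:
        components.add("nighttime_awakening")
    if status.activity_limitation:
        components.add("activity_limitation")
    if status.rescue_taken:
        components.add("rescue")
    for measure in LUNG_MEASURES:
        if status.lung_abnormal.get(measure):
            components.add(f"{measure}_abnormal")
    return bool(components), frozenset(components)


def compute_baselines(lung: list[LungReading]) -> dict[str, LungBaseline]:
    """Baselines for both measures; a measure with too few readings is
    dropped (the 1-SD rule is disabled for it) with a logged warning."""
    baselines = {}
    for measure in LUNG_MEASURES:
        try:
            baselines[measure] = compute_lung_baseline(lung, measure)
        except InsufficientBaselineError as exc:
            logger.warning("lung rule disabled for %s: %s", measure, exc)
    return baselines
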