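"""Typed records for every data stream the pipeline consumes or emits.

All dates and times are calendar-local; the analysis operates on calendar
days, so no time-zone handling is attempted. Each record validates its own
invariants at construction time and raises :class:`ValidationError` with a
message naming the offending field.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

#: Environmental parameters, in their native scales: pollen index 0-12,
#: pm2.5 and ozone as air-quality-index points, temperature in deg F,
#: relative humidity in %.
PARAMETERS = ("pollen", "pm25", "ozone", "temperature", "humidity")

#: Candidate asthma triggers (humidity is measured but, like the study it
#: emulates, never attributed as a trigger on its own).
TRIGGERS = ("pollen", "pm25", "ozone", "temperature")

#: The six diary symptoms, asked at each of the two daily sessions.
SYMPTOMS = (
    "cough",
    "wheeze",
    "chest_tightness",
    "hard_fast_breathing",
    "cannot_talk_full_sentences",
    "nose_opens_wide",
)

SESSIONS = ("morning", "evening")
SEASONS = ("spring", "summer", "fall", "winter")
LUNG_MEASURES = ("pef", "fev1")


class ValidationError(ValueError):
    """A record violated one of its declared invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class EnvObservation:
    """One time-stamped outdoor measurement for one region."""

    region_id: str
    timestamp: dt.datetime
    parameter: str
    value: float

    def __post_init__(self) -> None:
        _require(self.parameter in PARAMETERS,
                 f"unknown parameter {self.parameter!r}")
        _require(math.isfinite(self.value),
                 f"non-finite value for {self.parameter}")
        if self.parameter == "pollen":
            _require(0.0 <= self.value <= 12.0,
                     f"pollen index {self.value} outside [0, 12]")
        elif self.parameter == "humidity":
            _require(0.0 <= self.value <= 100.0,
                     f"humidity {self.value} outside [0, 100]")
        elif self.parameter in ("pm25", "ozone"):
            _require(self.value >= 0.0,
                     f"{self.parameter} {self.value} is negative")


@dataclass(frozen=True)
class SessionReport:
    """One diary questionnaire response (symptoms + medications)."""

    patient_id: str
    date: dt.date
    session: str
    symptoms: dict[str, bool]
    rescue_taken: bool
    controller_taken: bool

    def __post_init__(self) -> None:
        _require(self.session in SESSIONS, f"unknown session {self.session!r}")
        missing = [s for s in SYMPTOMS if s not in self.symptoms]
        _require(not missing, f"missing symptom keys: {missing}")
        extra = [s for s in self.symptoms if s not in SYMPTOMS]
        _require(not extra, f"unknown symptom keys: {extra}")


@dataclass(frozen=True)
class DailyReport:
    """Once-daily nighttime-awakening and activity-limitation answers."""

    patient_id: str
    date: dt.date
    nighttime_awakening: bool
    activity_limitation: bool


@dataclass(frozen=True)
class LungReading:
    """Best-of-trials peak-flow (L/min) and FEV1 (L) for one session."""

    patient_id: str
    date: dt.date
    session: str
    pef: float
    fev1: float
    n_trials: int = 3

    def __post_init__(self) -> None:
        _require(self.session in SESSIONS, f"unknown session {self.session!r}")
        _require(self.pef > 0, f"pef {self.pef} must be positive")
        _require(self.fev1 > 0, f"fev1 {self.fev1} must be positive")
        _require(self.n_trials >= 1, "n_trials must be >= 1")


@dataclass(frozen=True)
class PatientDeployment:
    """The monitored interval for one patient, tied to one region."""

    patient_id: str
    region_id: str
    start_date: dt.date
    end_date: dt.date
    planned_duration: str = "one_month"

    def __post_init__(self) -> None:
        _require(self.start_date <= self.end_date,
                 "deployment start_date after end_date")
        _require(self.planned_duration in ("one_month", "three_months"),
                 f"unknown planned_duration {self.planned_duration!r}")

    def days(self) -> list[dt.date]:
        n = (self.end_date - self.start_date).days + 1
        return [self.start_date + dt.timedelta(days=i) for i in range(n)]

    def contains(self, date: dt.date) -> bool:
        return self.start_date <= date <= self.end_date


_MONTH_TO_SEASON = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
}


@dataclass(frozen=True)
class SeasonCalendar:
    """Maps calendar dates to season labels.

    Defaults to meteorological seasons (Mar-May spring, Jun-Aug summer,
    Sep-Nov fall, Dec-Feb winter). Explicit intervals may be supplied as
    ``(label, start_date, end_date)`` triples; they must be disjoint and
    are checked to cover any date they are asked about.
    """

    intervals: tuple[tuple[str, dt.date, dt.date], ...] = field(
        default_factory=tuple)

    def __post_init__(self) -> None:
        spans = sorted(self.intervals, key=lambda iv: iv[1])
        for (label, start, end) in spans:
            _require(label in SEASONS, f"unknown season label {label!r}")
            _require(start <= end, f"season {label} start after end")
        for a, b in zip(spans, spans[1:]):
            _require(a[2] < b[1],
                     f"season intervals {a[0]} and {b[0]} overlap")

    def season_of(self, date: dt.date) -> str:
        for (label, start, end) in self.intervals:
            if start <= date <= end:
                return label
        if self.intervals:
            raise ValidationError(
                f"date {date} outside the configured season calendar")
        return _MONTH_TO_SEASON[date.month]
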