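"""Calendar-day alignment of environmental series and exposure flags.

The analysis works at day granularity: raw observations are reduced to a
per-day maximum for each parameter, each daily maximum is classified
against the parameter's healthy range, and a trigger counts as an
*effective exposure* on a day if it was outside its healthy range that day
or the previous day (a 48-hour window implemented as a calendar-day lag).
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict
from dataclasses import dataclass, field

from .records import EnvObservation, ValidationError

#: Healthy ranges for the index-scaled parameters. Values above the upper
#: bound are unhealthy; boundary values are healthy (the range is the
#: closed healthy interval). Temperature and humidity have no published
#: thresholds and use wide two-sided defaults.
DEFAULT_RANGES: dict[str, "HealthyRange"] = {}


@dataclass(frozen=True)
class HealthyRange:
    """The closed interval of healthy values for one parameter."""

    parameter: str
    low: float
    high: float
    sidedness: str = "above_is_unhealthy"

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValidationError(
                f"range for {self.parameter}: low {self.low} > high {self.high}")
        if self.sidedness not in ("above_is_unhealthy", "two_sided"):
            raise ValidationError(f"unknown sidedness {self.sidedness!r}")


DEFAULT_RANGES.update({
    "pollen": HealthyRange("pollen", 0.0, 2.4),
    "pm25": HealthyRange("pm25", 0.0, 50.0),
    "ozone": HealthyRange("ozone", 0.0, 50.0),
    "temperature": HealthyRange("temperature", 20.0, 90.0, "two_sided"),
    "humidity": HealthyRange("humidity", 20.0, 80.0, "two_sided"),
})


@dataclass(frozen=True)
class DailyEnvironment:
    """Per-calendar-day maxima for one region.

    A parameter with no observation that day is simply absent from
    ``daily_max``; nothing is imputed.
    """

    region_id: str
    date: dt.date
    daily_max: dict[str, float]


@dataclass(frozen=True)
class ExposureFlags:
    """Same-day (``unhealthy``) and lag-windowed (``effective``) flags.

    Both maps only carry parameters observed on the day itself; a trigger
    unobserved on day d has no flag for d even if observed on d-1.
    """

    date: dt.date
    unhealthy: dict[str, bool]
    effective: dict[str, bool] = field(default_factory=dict)


def aggregate_daily(observations: list[EnvObservation]) -> list[DailyEnvironment]:
    """Reduce raw observations to per-day maxima, one record per calendar
    day with any observation, sorted by date. Requires a single region."""
    regions = {o.region_id for o in observations}
    if len(regions) > 1:
        raise ValidationError(f"aggregate_daily expects one region, got {regions}")
    per_day: dict[dt.date, dict[str, float]] = defaultdict(dict)
    for o in observations:
        day = o.timestamp.date()
        cur = per_day[day].get(o.parameter)
        if cur is None or o.value > cur:
            per_day[day][o.parameter] = o.value
    region = regions.pop() if regions else ""
    return [DailyEnvironment(region, day, dict(per_day[day]))
            for day in sorted(per_day)]


def classify_day(value: float, healthy: HealthyRange) -> bool:
    """True iff the value is unhealthy. Boundary values are healthy."""
    if healthy.sidedness == "above_is_unhealthy":
        return value > healthy.high
    return value < healthy.low or value > healthy.high


def classify_daily(
    daily: list[DailyEnvironment],
    ranges: dict[str, HealthyRange] | None = None,
) -> list[tuple[dt.date, dict[str, bool]]]:
    """Classify every observed (day, parameter) against its healthy range."""
    ranges = DEFAULT_RANGES if ranges is None else ranges
    out = []
    for rec in daily:
        flags = {p: classify_day(v, ranges[p])
                 for p, v in rec.daily_max.items() if p in ranges}
        out.append((rec.date, flags))
    return out


def effective_exposure(
    daily_flags: list[tuple[dt.date, dict[str, bool]]],
    lag_days: int = 1,
) -> list[ExposureFlags]:
    """Apply the exposure window: effective on d iff unhealthy on any of
    d, d-1, ..., d-lag_days (default 1, the 48-hour window).

    Days absent from the series (gaps) contribute nothing; a trigger's
    effective flag exists only where its same-day flag does.
    """
    if lag_days < 0:
        raise ValidationError("lag_days must be >= 0")
    dates = [d for d, _ in daily_flags]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValidationError("daily_flags dates must be strictly increasing")
    by_date = dict(daily_flags)
    out = []
    for date, unhealthy in daily_flags:
        effective = {}
        for trigger, flag in unhealthy.items():
            eff = flag
            for k in range(1, lag_days + 1):
                prev = by_date.get(date - dt.timedelta(days=k))
                if prev is not None and prev.get(trigger):
                    eff = True
            effective[trigger] = eff
        out.append(ExposureFlags(date, dict(unhealthy), effective))
    return out


def exposure_series(
    observations: list[EnvObservation],
    ranges: dict[str, HealthyRange] | None = None,
    lag_days: int = 1,
) -> list[ExposureFlags]:
    """Convenience composition: aggregate -> classify -> window."""
    return effective_exposure(
        classify_daily(aggregate_daily(observations), ranges), lag_days)
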