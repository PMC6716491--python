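"""Run configuration: healthy ranges, window length, attribution
thresholds, season calendar, and simulation settings, loadable from a
YAML file whose keys override the defaults."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .daily import DEFAULT_RANGES, HealthyRange
from .records import SeasonCalendar, ValidationError


@dataclass(frozen=True)
class RunConfig:
    ranges: dict[str, HealthyRange] = field(
        default_factory=lambda: dict(DEFAULT_RANGES))
    lag_days: int = 1
    min_episode_days: int = 5
    combo_threshold: float = 0.8
    season_dominance: float = 0.8
    adherence_mode: str = "day"
    calendar: SeasonCalendar = field(default_factory=SeasonCalendar)
    n_patients: int = 83
    deployment_days: int = 30
    beta: float = 3.0

    def __post_init__(self) -> None:
        if self.lag_days < 0:
            raise ValidationError("lag_days must be >= 0")
        if self.min_episode_days < 0:
            raise ValidationError("min_episode_days must be >= 0")
        if not 0.0 <= self.combo_threshold <= 1.0:
            raise ValidationError("combo_threshold must be in [0, 1]")
        if not 0.0 < self.season_dominance <= 1.0:
            raise ValidationError("season_dominance must be in (0, 1]")
        if self.adherence_mode not in ("day", "session"):
            raise ValidationError(
                f"unknown adherence_mode {self.adherence_mode!r}")


def _parse_range(parameter: str, bounds) -> HealthyRange:
    low, high = float(bounds[0]), float(bounds[1])
    sidedness = ("two_sided" if parameter in ("temperature", "humidity")
                 else "above_is_unhealthy")
    return HealthyRange(parameter, low, high, sidedness)


def load_config(path: str | Path | None) -> RunConfig:
    """Build a RunConfig from a YAML file; absent keys keep defaults."""
    config = RunConfig()
    if path is None:
        return config
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "ranges" in raw:
        ranges = dict(config.ranges)
        for parameter, bounds in raw["ranges"].items():
            if parameter not in ranges:
                raise ValidationError(f"unknown range parameter {parameter!r}")
            ranges[parameter] = _parse_range(parameter, bounds)
        config = replace(config, ranges=ranges)
    window = raw.get("window", {})
    if "lag_days" in window:
        config = replace(config, lag_days=int(window["lag_days"]))
    attribution = raw.get("attribution", {})
    for key in ("min_episode_days", "combo_threshold", "season_dominance"):
        if key in attribution:
            cast = int if key == "min_episode_days" else float
            config = replace(config, **{key: cast(attribution[key])})
    if "adherence_mode" in raw:
        config = replace(config, adherence_mode=str(raw["adherence_mode"]))
    if "seasons" in raw:
        intervals = tuple(
            (str(row["label"]), dt.date.fromisoformat(str(row["start"])),
             dt.date.fromisoformat(str(row["end"])))
            for row in raw["seasons"])
        config = replace(config, calendar=SeasonCalendar(intervals))
    simulate = raw.get("simulate", {})
    for key, cast in (("n_patients", int), ("deployment_days", int),
                      ("beta", float)):
        if key in simulate:
            config = replace(config, **{key: cast(simulate[key])})
    return config
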