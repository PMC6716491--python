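"""Readers and writers for the delimited-text stream formats.

Five per-cohort / per-patient CSV files are understood:

``env.csv``
    ``region_id,timestamp,parameter,value`` with ISO-8601 timestamps.
``sessions.csv``
    one row per diary session with 0/1 symptom and medication flags.
``daily.csv``
    once-daily nighttime-awakening / activity-limitation answers.
``lung.csv``
    per-session best-of-trials PEF and FEV1.
``deployment.csv``
    a single row describing the patient's monitored interval.

Writers produce deterministic bytes for identical input: fixed column
order, ``\n`` line endings, probabilities formatted to 2 decimals (full
precision is kept in memory; only rendering rounds).
"""

from __future__ import annotations

import datetime as dt
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .records import (
    PARAMETERS,
    SYMPTOMS,
    DailyReport,
    EnvObservation,
    LungReading,
    PatientDeployment,
    SessionReport,
    ValidationError,
)


class ParseError(ValueError):
    """A stream file could not be parsed; the message names the line."""


ENV_COLUMNS = ["region_id", "timestamp", "parameter", "value"]
SESSION_COLUMNS = (["patient_id", "date", "session"] + list(SYMPTOMS)
                   + ["rescue_taken", "controller_taken"])
DAILY_COLUMNS = ["patient_id", "date", "nighttime_awakening",
                 "activity_limitation"]
LUNG_COLUMNS = ["patient_id", "date", "session", "pef", "fev1", "n_trials"]
DEPLOYMENT_COLUMNS = ["patient_id", "region_id", "start_date", "end_date",
                      "planned_duration"]

PATIENT_FILES = {
    "sessions": "sessions.csv",
    "daily": "daily.csv",
    "lung": "lung.csv",
    "deployment": "deployment.csv",
}


def _read_table(path: Path, columns: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"missing stream file: {path}")
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: {exc}") from exc
    if list(frame.columns) != list(columns):
        raise ParseError(
            f"{path}: header {list(frame.columns)} != expected {list(columns)}")
    return frame


def _line(row_index: int) -> int:
    # +2: one for the header line, one for 1-based numbering
    return row_index + 2


def _parse_bool(text: str, path: Path, i: int, col: str) -> bool:
    if text == "0":
        return False
    if text == "1":
        return True
    raise ParseError(f"{path} line {_line(i)}: column {col!r} must be 0/1, "
                     f"got {text!r}")


def _parse_date(text: str, path: Path, i: int) -> dt.date:
    try:
        return dt.date.fromisoformat(text)
    except ValueError as exc:
        raise ParseError(f"{path} line {_line(i)}: bad date {text!r}") from exc


def read_env(path: str | Path) -> list[EnvObservation]:
    """Read an environmental series; returns records sorted by
    (region_id, parameter, timestamp). Rows out of order are accepted."""
    path = Path(path)
    frame = _read_table(path, ENV_COLUMNS)
    out: list[EnvObservation] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        if row.parameter not in PARAMETERS:
            raise ValidationError(
                f"{path} line {_line(i)}: unknown parameter {row.parameter!r}")
        try:
            ts = dt.datetime.fromisoformat(row.timestamp)
            value = float(row.value)
        except ValueError as exc:
            raise ParseError(f"{path} line {_line(i)}: {exc}") from exc
        try:
            out.append(EnvObservation(row.region_id, ts, row.parameter, value))
        except ValidationError as exc:
            raise ValidationError(f"{path} line {_line(i)}: {exc}") from exc
    out.sort(key=lambda o: (o.region_id, o.parameter, o.timestamp))
    return out


def read_sessions(path: str | Path) -> list[SessionReport]:
    path = Path(path)
    frame = _read_table(path, SESSION_COLUMNS)
    out: list[SessionReport] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        rec = row._asdict()
        date = _parse_date(rec["date"], path, i)
        symptoms = {s: _parse_bool(rec[s], path, i, s) for s in SYMPTOMS}
        try:
            out.append(SessionReport(
                patient_id=rec["patient_id"], date=date,
                session=rec["session"], symptoms=symptoms,
                rescue_taken=_parse_bool(rec["rescue_taken"], path, i,
                                         "rescue_taken"),
                controller_taken=_parse_bool(rec["controller_taken"], path, i,
                                             "controller_taken")))
        except ValidationError as exc:
            raise ValidationError(f"{path} line {_line(i)}: {exc}") from exc
    _check_unique(((r.patient_id, r.date, r.session) for r in out), path,
                  "(patient, date, session)")
    return out


def read_daily(path: str | Path) -> list[DailyReport]:
    path = Path(path)
    frame = _read_table(path, DAILY_COLUMNS)
    out = []
    for i, row in enumerate(frame.itertuples(index=False)):
        out.append(DailyReport(
            patient_id=row.patient_id,
            date=_parse_date(row.date, path, i),
            nighttime_awakening=_parse_bool(row.nighttime_awakening, path, i,
                                            "nighttime_awakening"),
            activity_limitation=_parse_bool(row.activity_limitation, path, i,
                                            "activity_limitation")))
    _check_unique(((r.patient_id, r.date) for r in out), path,
                  "(patient, date)")
    return out


def read_lung(path: str | Path) -> list[LungReading]:
    path = Path(path)
    frame = _read_table(path, LUNG_COLUMNS)
    out = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            out.append(LungReading(
                patient_id=row.patient_id,
                date=_parse_date(row.date, path, i),
                session=row.session, pef=float(row.pef),
                fev1=float(row.fev1), n_trials=int(row.n_trials)))
        except (ValueError, ValidationError) as exc:
            raise type(exc)(f"{path} line {_line(i)}: {exc}") from exc
    _check_unique(((r.patient_id, r.date, r.session) for r in out), path,
                  "(patient, date, session)")
    return out


def read_deployment(path: str | Path) -> PatientDeployment:
    path = Path(path)
    frame = _read_table(path, DEPLOYMENT_COLUMNS)
    if len(frame) != 1:
        raise ParseError(f"{path}: expected exactly one deployment row, "
                         f"got {len(frame)}")
    row = next(frame.itertuples(index=False))
    return PatientDeployment(
        patient_id=row.patient_id, region_id=row.region_id,
        start_date=_parse_date(row.start_date, path, 0),
        end_date=_parse_date(row.end_date, path, 0),
        planned_duration=row.planned_duration)


def _check_unique(keys: Iterable[tuple], path: Path, label: str) -> None:
    dup = [k for k, c in Counter(keys).items() if c > 1]
    if dup:
        raise ValidationError(f"{path}: duplicate {label} records: {dup[:3]}")


def read_patient_streams(
    directory: str | Path,
) -> tuple[list[SessionReport], list[DailyReport], list[LungReading],
           PatientDeployment]:
    """Read the four per-patient stream files from one directory.

    All records must carry the deployment's patient_id and fall inside its
    [start_date, end_date] window; duplicates are an error.
    """
    directory = Path(directory)
    deployment = read_deployment(directory / PATIENT_FILES["deployment"])
    sessions = read_sessions(directory / PATIENT_FILES["sessions"])
    daily = read_daily(directory / PATIENT_FILES["daily"])
    lung = read_lung(directory / PATIENT_FILES["lung"])
    for rec in [*sessions, *daily, *lung]:
        if rec.patient_id != deployment.patient_id:
            raise ValidationError(
                f"{directory}: record for {rec.patient_id!r} in streams of "
                f"patient {deployment.patient_id!r}")
        if not deployment.contains(rec.date):
            raise ValidationError(
                f"{directory}: record on {rec.date} outside deployment window "
                f"[{deployment.start_date}, {deployment.end_date}]")
    return sessions, daily, lung, deployment


# ---------------------------------------------------------------- writers

def _bool(v: bool) -> str:
    return "1" if v else "0"


def _write_lines(path: Path, header: Sequence[str],
                 rows: Iterable[Sequence[str]]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [",".join(header)]
    lines.extend(",".join(r) for r in rows)
    path.write_text("\n".join(lines) + "\n")


def write_env(observations: Sequence[EnvObservation], path: str | Path) -> None:
    rows = sorted(observations,
                  key=lambda o: (o.region_id, o.parameter, o.timestamp))
    _write_lines(Path(path), ENV_COLUMNS,
                 ([o.region_id, o.timestamp.isoformat(timespec="minutes"),
                   o.parameter, repr(o.value)] for o in rows))


def write_sessions(reports: Sequence[SessionReport], path: str | Path) -> None:
    rows = sorted(reports, key=lambda r: (r.date, r.session))
    _write_lines(Path(path), SESSION_COLUMNS,
                 ([r.patient_id, r.date.isoformat(), r.session]
                  + [_bool(r.symptoms[s]) for s in SYMPTOMS]
                  + [_bool(r.rescue_taken), _bool(r.controller_taken)]
                  for r in rows))


def write_daily(reports: Sequence[DailyReport], path: str | Path) -> None:
    rows = sorted(reports, key=lambda r: r.date)
    _write_lines(Path(path), DAILY_COLUMNS,
                 ([r.patient_id, r.date.isoformat(),
                   _bool(r.nighttime_awakening), _bool(r.activity_limitation)]
                  for r in rows))


def write_lung(readings: Sequence[LungReading], path: str | Path) -> None:
    rows = sorted(readings, key=lambda r: (r.date, r.session))
    _write_lines(Path(path), LUNG_COLUMNS,
                 ([r.patient_id, r.date.isoformat(), r.session,
                   repr(r.pef), repr(r.fev1), str(r.n_trials)]
                  for r in rows))


def write_deployment(deployment: PatientDeployment, path: str | Path) -> None:
    _write_lines(Path(path), DEPLOYMENT_COLUMNS,
                 [[deployment.patient_id, deployment.region_id,
                   deployment.start_date.isoformat(),
                   deployment.end_date.isoformat(),
                   deployment.planned_duration]])


def write_patient_streams(sessions, daily, lung, deployment,
                          directory: str | Path) -> None:
    directory = Path(directory)
    write_sessions(sessions, directory / PATIENT_FILES["sessions"])
    write_daily(daily, directory / PATIENT_FILES["daily"])
    write_lung(lung, directory / PATIENT_FILES["lung"])
    write_deployment(deployment, directory / PATIENT_FILES["deployment"])


def format_probability(p: float) -> str:
    """Render a probability to 2 decimals (the tables' convention)."""
    return f"{p:.2f}"
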