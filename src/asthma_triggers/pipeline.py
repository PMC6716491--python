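"""End-to-end orchestration: raw cohort directory -> output tables.

Expected input layout (what the cohort simulator writes):

    <in>/env/<region_id>.csv
    <in>/patients/<patient_id>/{sessions,daily,lung,deployment}.csv

Outputs, all deterministic for identical inputs and config:

    <out>/status_<patient>.csv
    <out>/probability_table_<patient>.csv
    <out>/major_triggers.csv
    <out>/adherence.csv
    <out>/cohort_summary.csv
    <out>/run.log

A failure in one patient is logged and skips only that patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from . import io as tio
from .attribution import (
    ContributorCounts,
    MajorTriggerResult,
    ProbabilityTable,
    adherence,
    assign_season,
    cohort_summary,
    cohort_summary_to_csv,
    contributor_day_counts,
    default_conditions,
    major_trigger,
    probability_table,
    probability_table_to_csv,
)
from .config import RunConfig
from .daily import ExposureFlags, exposure_series
from .episodes import (
    EPISODE_COMPONENTS,
    DailyStatus,
    build_daily_status,
    compute_baselines,
)
from .records import TRIGGERS

logger = logging.getLogger(__name__)


@dataclass
class PatientResult:
    patient_id: str
    season: str
    statuses: list[DailyStatus]
    exposures: list[ExposureFlags]
    table: ProbabilityTable | None
    counts: ContributorCounts
    result: MajorTriggerResult
    adherence_pct: float


def analyze_patient(patient_dir: Path, env_dir: Path,
                    config: RunConfig) -> PatientResult:
    """The per-patient pipeline: read -> align -> episodes -> attribution."""
    sessions, daily, lung, deployment = tio.read_patient_streams(patient_dir)
    env = tio.read_env(env_dir / f"{deployment.region_id}.csv")
    exposures = exposure_series(env, config.ranges, config.lag_days)
    baselines = compute_baselines(lung)
    statuses = build_daily_status(sessions, daily, lung, baselines,
                                  deployment)
    season = assign_season(statuses, config.calendar, config.season_dominance)
    counts = contributor_day_counts(statuses, exposures)
    result = major_trigger(counts, deployment.patient_id, season,
                           config.min_episode_days, config.combo_threshold)
    try:
        conditions = default_conditions(exposures, statuses)
        table = probability_table(statuses, exposures, conditions)
    except Exception as exc:
        logger.warning("%s: no probability table (%s)",
                       deployment.patient_id, exc)
        table = None
    return PatientResult(
        deployment.patient_id, season, statuses, exposures, table, counts,
        result, adherence(statuses, config.adherence_mode))


def _write_status(statuses: list[DailyStatus], path: Path) -> None:
    header = ["patient_id", "date", "answered", "episode", "components",
              "rescue_taken", "controller_sessions", "nighttime_awakening",
              "activity_limitation"]
    lines = [",".join(header)]
    for s in statuses:
        components = ";".join(c for c in EPISODE_COMPONENTS
                              if c in s.components)
        lines.append(",".join([
            s.patient_id, s.date.isoformat(), str(int(s.answered)),
            str(int(s.episode)), components, str(int(s.rescue_taken)),
            str(s.controller_sessions), str(int(s.nighttime_awakening)),
            str(int(s.activity_limitation))]))
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(input_dir: str | Path, output_dir: str | Path,
                 config: RunConfig | None = None,
                 ) -> tuple[list[PatientResult], list[str]]:
    """Process every patient directory; returns (results, failed ids)."""
    config = config or RunConfig()
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    log_path = output_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    root = logging.getLogger("asthma_triggers")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    saved_propagate = root.propagate
    root.propagate = False  # per-patient narrative goes to run.log only

    results: list[PatientResult] = []
    failures: list[str] = []
    patient_dirs = sorted((input_dir / "patients").iterdir())
    try:
        for patient_dir in patient_dirs:
            if not patient_dir.is_dir():
                continue
            try:
                res = analyze_patient(patient_dir, input_dir / "env", config)
            except Exception as exc:
                failures.append(patient_dir.name)
                logger.error("patient %s failed at analysis stage: %s",
                             patient_dir.name, exc)
                continue
            results.append(res)
            logger.info(
                "%s: %d answered days, %d episode days, contributors %s, "
                "adherence %d%%, label %s",
                res.patient_id, res.counts.answered_days,
                res.counts.episode_days,
                {t: res.counts.per_trigger[t] for t in TRIGGERS},
                round(res.adherence_pct), res.result.label)
            _write_status(res.statuses,
                          output_dir / f"status_{res.patient_id}.csv")
            if res.table is not None:
                probability_table_to_csv(
                    res.table,
                    output_dir / f"probability_table_{res.patient_id}.csv")
    finally:
        root.removeHandler(handler)
        root.propagate = saved_propagate
        handler.close()

    _write_major_triggers(results, output_dir / "major_triggers.csv")
    _write_adherence(results, output_dir / "adherence.csv")
    cohort_summary_to_csv(cohort_summary([r.result for r in results]),
                          output_dir / "cohort_summary.csv")
    return results, failures


def _write_major_triggers(results: list[PatientResult], path: Path) -> None:
    header = ["patient_id", "season", "label", "episode_days",
              "answered_days"] + [f"fraction_{t}" for t in TRIGGERS]
    lines = [",".join(header)]
    for r in sorted(results, key=lambda r: r.patient_id):
        lines.append(",".join(
            [r.patient_id, r.season, r.result.label,
             str(r.result.episode_day_count), str(r.result.answered_day_count)]
            + [f"{r.result.fractions.get(t, 0.0):.4f}" for t in TRIGGERS]))
    path.write_text("\n".join(lines) + "\n")


def _write_adherence(results: list[PatientResult], path: Path) -> None:
    lines = ["patient_id,adherence_pct"]
    for r in sorted(results, key=lambda r: r.patient_id):
        lines.append(f"{r.patient_id},{round(r.adherence_pct)}")
    path.write_text("\n".join(lines) + "\n")


def render_report(result: PatientResult) -> str:
    """Human-readable per-patient narrative, mirroring the CSV outputs."""
    counts = result.counts
    lines = [
        f"Patient {result.patient_id} ({result.season})",
        "=" * 40,
        f"Answered days: {counts.answered_days}",
        f"Asthma episode days: {counts.episode_days}",
    ]
    component_days: dict[str, int] = {}
    for s in result.statuses:
        if s.answered:
            for c in s.components:
                component_days[c] = component_days.get(c, 0) + 1
    if component_days:
        lines.append("Episode component day counts:")
        for c in EPISODE_COMPONENTS:
            if c in component_days:
                lines.append(f"  {c}: {component_days[c]}")
    else:
        lines.append("No asthma episodes recorded.")
    lines.append("Contributor day counts (trigger in unhealthy range on the "
                 "day or the previous day):")
    for t in TRIGGERS:
        lines.append(f"  {t}: {counts.per_trigger[t]} of "
                     f"{counts.episode_days} episode days")
    lines.append(f"Controller adherence: {round(result.adherence_pct)}%")
    if result.table is not None:
        lines.append("Probability of outcome given trigger condition:")
        names = [c.name for c in result.table.conditions]
        lines.append("  outcome | " + " | ".join(names))
        for outcome in result.table.outcomes:
            cells = []
            for name in names:
                cell = result.table.cells.get((outcome, name))
                cells.append("--" if cell is None
                             else tio.format_probability(cell.probability))
            lines.append(f"  {outcome} | " + " | ".join(cells))
    lines.append(f"Major trigger: {result.result.label}")
    return "\n".join(lines) + "\n"
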