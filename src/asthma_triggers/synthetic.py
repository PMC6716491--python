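"""Synthetic cohort generator.

Every downstream stage of the pipeline is exercised against simulated
data with the statistical structure the analysis assumes:

* outdoor parameters follow an AR(1) process at the daily level with a
  fixed (deterministic) sinusoidal diurnal shape, sampled hourly except
  pollen, which is reported every 12 hours;
* each patient carries a logistic symptom model — on an answered day d,
  symptom s occurs with probability
  ``logistic(alpha_s + sum_t beta_t * X_t(d))`` where ``X_t(d)`` is the
  effective-exposure flag (trigger outside its healthy range on d or
  d-1) computed by the same code the analysis pipeline uses;
* rescue intake is drawn only on symptomatic days, controller intake at
  the patient's adherence rate, and whole days go unanswered with
  probability ``1 - response_rate``;
* lung function is Gaussian around the patient's personal baseline with
  a shared within-day state (the two sessions measure the same airway
  caliber, AR(1)-correlated across days) and a fixed downward shift, in
  SD units, on symptomatic days.

Random streams are split per patient and per stream from the master
seed, so adding a patient to a cohort never perturbs the others.
"""

from __future__ import annotations

import datetime as dt
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from . import io as tio
from .daily import DEFAULT_RANGES, HealthyRange, exposure_series
from .records import (
    SYMPTOMS,
    DailyReport,
    EnvObservation,
    LungReading,
    PatientDeployment,
    SessionReport,
    ValidationError,
)

#: Outcomes the logistic model generates: the six diary symptoms plus the
#: two once-daily answers.
OUTCOMES = tuple(SYMPTOMS) + ("nighttime_awakening", "activity_limitation")

POLLEN_HOURS = (6, 18)  # 12-hourly collection
DIURNAL_PEAK_HOUR = 15  # afternoon maximum for the sinusoidal shape


def _entropy(*parts: int | str) -> list[int]:
    return [p if isinstance(p, int)
            else zlib.crc32(p.encode()) & 0x7FFFFFFF
            for p in parts]


def _rng(seed: int, *parts: int | str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(_entropy(seed, *parts)))


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@dataclass(frozen=True)
class ParamModel:
    """Daily-level AR(1) marginal model for one parameter."""

    mean: float
    amplitude: float
    ar_coef: float
    innovation_sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar_coef < 1.0:
            raise ValidationError("ar_coef must be in [0, 1)")
        if self.innovation_sd < 0:
            raise ValidationError("innovation_sd must be >= 0")


@dataclass(frozen=True)
class EnvScenario:
    """One season's environmental regime."""

    season: str
    days: int
    start_date: dt.date
    params: dict[str, ParamModel]
    pollen_active: bool = True

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValidationError("scenario days must be >= 1")


@dataclass(frozen=True)
class PatientProfile:
    """Ground-truth generative model for one patient.

    ``baseline_logodds`` maps each outcome to alpha (log-odds on an
    unexposed day; ``-inf`` disables the outcome); ``susceptibility``
    maps trigger names to the nonnegative log-odds increment beta applied
    when the trigger's effective-exposure flag is on (``+inf`` forces the
    outcome on exposed days). ``lung_drop_sd`` is the downward shift of
    both lung measures, in SD units, on days with any diary symptom.
    """

    baseline_logodds: dict[str, float]
    susceptibility: dict[str, float]
    rescue_propensity: float
    controller_adherence: float
    response_rate: float
    pef_mean: float = 320.0
    pef_sd: float = 30.0
    fev1_mean: float = 2.0
    fev1_sd: float = 0.25
    lung_drop_sd: float = 2.0
    lung_day_ar: float = 0.6
    lung_within_day_weight: float = 0.6

    def __post_init__(self) -> None:
        for name, p in (("rescue_propensity", self.rescue_propensity),
                        ("controller_adherence", self.controller_adherence),
                        ("response_rate", self.response_rate)):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.pef_sd <= 0 or self.fev1_sd <= 0:
            raise ValidationError("lung SDs must be > 0")
        for t, beta in self.susceptibility.items():
            if beta < 0:
                raise ValidationError(f"susceptibility[{t}] must be >= 0")
        unknown = set(self.baseline_logodds) - set(OUTCOMES)
        if unknown:
            raise ValidationError(f"unknown outcomes {sorted(unknown)}")


def simulate_environment(scenario: EnvScenario, seed: int,
                         region_id: str = "R0") -> list[EnvObservation]:
    """Generate the scenario's observation stream.

    Hourly pm2.5/ozone/temperature/humidity and 12-hourly pollen over
    ``scenario.days`` calendar days; identical seed, identical output.
    """
    out: list[EnvObservation] = []
    for parameter, model in sorted(scenario.params.items()):
        rng = _rng(seed, scenario.season, parameter)
        # stationary AR(1) deviations at the daily level
        if model.ar_coef > 0 and model.innovation_sd > 0:
            stat_sd = model.innovation_sd / math.sqrt(1 - model.ar_coef**2)
        else:
            stat_sd = model.innovation_sd
        x = rng.normal(0.0, stat_sd) if stat_sd > 0 else 0.0
        hours = (POLLEN_HOURS if parameter == "pollen"
                 else tuple(range(24)))
        for day_index in range(scenario.days):
            date = scenario.start_date + dt.timedelta(days=day_index)
            if day_index > 0:
                x = (model.ar_coef * x
                     + (rng.normal(0.0, model.innovation_sd)
                        if model.innovation_sd > 0 else 0.0))
            for hour in hours:
                value = (model.mean + x + model.amplitude
                         * math.sin(2 * math.pi * (hour - DIURNAL_PEAK_HOUR
                                                   + 6) / 24.0))
                if parameter == "pollen":
                    value = 0.0 if not scenario.pollen_active else value
                    value = min(max(value, 0.0), 12.0)
                elif parameter == "humidity":
                    value = min(max(value, 0.0), 100.0)
                elif parameter in ("pm25", "ozone"):
                    value = max(value, 0.0)
                out.append(EnvObservation(
                    region_id, dt.datetime.combine(date, dt.time(hour)),
                    parameter, value))
    out.sort(key=lambda o: (o.region_id, o.parameter, o.timestamp))
    return out


def _check_env_coverage(env: list[EnvObservation],
                        deployment: PatientDeployment) -> None:
    window = [o.timestamp for o in env
              if deployment.start_date <= o.timestamp.date()
              <= deployment.end_date]
    if not window:
        raise ValidationError("env does not cover the deployment window")
    window.sort()
    if window[0].date() != deployment.start_date:
        raise ValidationError("env missing the deployment start date")
    if window[-1].date() != deployment.end_date:
        raise ValidationError("env missing the deployment end date")
    for a, b in zip(window, window[1:]):
        if b - a > dt.timedelta(hours=24):
            raise ValidationError(
                f"env gap > 24 h inside deployment window: {a} -> {b}")


def _outcome_probability(profile: PatientProfile, outcome: str,
                         exposed: dict[str, bool]) -> float:
    x = profile.baseline_logodds.get(outcome, -math.inf)
    for trigger, beta in profile.susceptibility.items():
        if exposed.get(trigger):
            x = x + beta  # only on-flag terms: avoids 0 * inf
    return _sigmoid(x)


def simulate_patient(
    profile: PatientProfile,
    env: list[EnvObservation],
    deployment: PatientDeployment,
    seed: int,
    ranges: dict[str, HealthyRange] | None = None,
    lag_days: int = 1,
) -> tuple[list[SessionReport], list[DailyReport], list[LungReading]]:
    """Draw one patient's diary, daily, and lung streams.

    The effective-exposure flags entering the logistic model are computed
    with the analysis pipeline's own aggregation/classification/window
    code, on the same environmental series the pipeline will later see.
    """
    _check_env_coverage(env, deployment)
    region_env = [o for o in env if o.region_id == deployment.region_id]
    flags = {e.date: e for e in exposure_series(
        region_env, ranges or DEFAULT_RANGES, lag_days)}

    response_rng = _rng(seed, deployment.patient_id, "response")
    outcome_rng = _rng(seed, deployment.patient_id, "outcomes")
    med_rng = _rng(seed, deployment.patient_id, "medication")
    lung_rng = _rng(seed, deployment.patient_id, "lung")

    sessions: list[SessionReport] = []
    daily: list[DailyReport] = []
    lung: list[LungReading] = []
    w = profile.lung_within_day_weight
    phi = profile.lung_day_ar
    day_state = lung_rng.normal()
    for date in deployment.days():
        # fixed draw counts per day keep streams aligned across profiles
        answered = response_rng.random() < profile.response_rate
        exposed = flags[date].effective if date in flags else {}
        occur = {o: outcome_rng.random()
                 < _outcome_probability(profile, o, exposed)
                 for o in OUTCOMES}
        symptomatic = any(occur[s] for s in SYMPTOMS)
        rescue_draw, controller_draw = med_rng.random(size=2)
        rescue = symptomatic and rescue_draw < profile.rescue_propensity
        controller = bool(controller_draw < profile.controller_adherence)
        day_state = phi * day_state + math.sqrt(1 - phi**2) * lung_rng.normal()
        session_z = (math.sqrt(w) * day_state
                     + math.sqrt(1 - w) * lung_rng.normal(size=2))
        if not answered:
            continue
        for session, z in zip(("morning", "evening"), session_z):
            sessions.append(SessionReport(
                deployment.patient_id, date, session,
                {s: occur[s] for s in SYMPTOMS}, rescue, controller))
            shift = float(z) - profile.lung_drop_sd * symptomatic
            lung.append(LungReading(
                deployment.patient_id, date, session,
                pef=max(profile.pef_mean + profile.pef_sd * shift, 1.0),
                fev1=max(profile.fev1_mean + profile.fev1_sd * shift, 0.05),
                n_trials=3))
        daily.append(DailyReport(deployment.patient_id, date,
                                 occur["nighttime_awakening"],
                                 occur["activity_limitation"]))
    return sessions, daily, lung


# -------------------------------------------------------- cohort presets

def _pm(mean, amplitude, ar, sd) -> ParamModel:
    return ParamModel(mean, amplitude, ar, sd)


#: Seasonal regimes: winter has no pollen and elevated pm2.5; spring and
#: fall have pollen frequently above its healthy band; summer has higher
#: ozone and mostly sparse pollen.
SEASON_SCENARIOS: dict[str, dict] = {
    "winter": dict(pollen_active=False, params={
        "pollen": _pm(0.0, 0.0, 0.0, 0.0),
        "pm25": _pm(40.0, 6.0, 0.6, 8.0),
        "ozone": _pm(25.0, 5.0, 0.6, 6.0),
        "temperature": _pm(35.0, 8.0, 0.7, 4.0),
        "humidity": _pm(60.0, 10.0, 0.6, 8.0)}),
    "spring": dict(pollen_active=True, params={
        "pollen": _pm(3.0, 0.8, 0.6, 1.2),
        "pm25": _pm(35.0, 6.0, 0.6, 8.0),
        "ozone": _pm(30.0, 6.0, 0.6, 6.0),
        "temperature": _pm(60.0, 10.0, 0.6, 5.0),
        "humidity": _pm(55.0, 10.0, 0.6, 8.0)}),
    "summer": dict(pollen_active=True, params={
        "pollen": _pm(1.2, 0.4, 0.6, 0.8),
        "pm25": _pm(38.0, 6.0, 0.6, 8.0),
        "ozone": _pm(40.0, 7.0, 0.6, 7.0),
        "temperature": _pm(82.0, 6.0, 0.6, 4.0),
        "humidity": _pm(60.0, 15.0, 0.6, 8.0)}),
    "fall": dict(pollen_active=True, params={
        "pollen": _pm(2.6, 0.8, 0.6, 1.2),
        "pm25": _pm(38.0, 6.0, 0.6, 8.0),
        "ozone": _pm(28.0, 5.0, 0.6, 6.0),
        "temperature": _pm(55.0, 10.0, 0.6, 5.0),
        "humidity": _pm(60.0, 10.0, 0.6, 8.0)}),
}

#: Environmental spans in an exemplar year; long enough for 90-day
#: deployments plus per-patient start offsets and the exposure lag.
SEASON_ENV_START = {
    "winter": dt.date(2017, 12, 5),
    "spring": dt.date(2018, 3, 5),
    "summer": dt.date(2018, 6, 5),
    "fall": dt.date(2018, 9, 5),
    "between": dt.date(2018, 1, 20),
}

#: Cohort season mix mirroring the per-season patient counts of the
#: study population this generator emulates (16/6/14/23/24 of 83).
DEFAULT_SEASON_MIX = {"spring": 16, "summer": 6, "fall": 14,
                      "winter": 23, "between": 24}

#: Baseline per-day outcome rates on unexposed days.
BASELINE_SYMPTOM_RATE = 0.05
BASELINE_DAILY_RATE = 0.02
DEFAULT_BETA = 3.0

#: Season-conditional planted-trigger prevalences for the default mix.
SEASON_TRIGGER_WEIGHTS = {
    "spring": (("pollen", 0.65), ("pm25", 0.25), ("none", 0.10)),
    "summer": (("ozone", 0.35), ("pm25", 0.35), ("none", 0.30)),
    "fall": (("pollen", 0.40), ("pm25", 0.30), ("none", 0.30)),
    "winter": (("pm25", 0.80), ("none", 0.20)),
    "between": (("pollen_and_pm25", 0.35), ("pm25", 0.15), ("none", 0.50)),
}


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def default_profile(planted_trigger: str = "none",
                    beta: float = DEFAULT_BETA) -> PatientProfile:
    """A study-typical patient with one planted susceptibility.

    ``planted_trigger`` is a trigger name, ``pollen_and_pm25`` for joint
    susceptibility, or ``none``.
    """
    susceptibility: dict[str, float] = {}
    if planted_trigger == "pollen_and_pm25":
        susceptibility = {"pollen": beta, "pm25": beta}
    elif planted_trigger != "none":
        susceptibility = {planted_trigger: beta}
    alphas = {s: _logit(BASELINE_SYMPTOM_RATE) for s in SYMPTOMS}
    alphas.update({o: _logit(BASELINE_DAILY_RATE)
                   for o in ("nighttime_awakening", "activity_limitation")})
    return PatientProfile(
        baseline_logodds=alphas, susceptibility=susceptibility,
        rescue_propensity=0.6, controller_adherence=0.5, response_rate=0.85)


def season_scenario(season: str, days: int) -> list[EnvScenario]:
    """The scenario segments for one season stratum.

    ``between`` straddles the winter/spring boundary: winter parameters
    (pollen absent) through February, spring parameters from March 1 —
    the presence/absence split the personalized analysis exploits.
    """
    start = SEASON_ENV_START[season]
    if season != "between":
        return [EnvScenario(season=season, days=days, start_date=start,
                            **SEASON_SCENARIOS[season])]
    boundary = dt.date(2018, 3, 1)
    winter_days = (boundary - start).days
    return [
        EnvScenario(season="winter", days=winter_days, start_date=start,
                    **SEASON_SCENARIOS["winter"]),
        EnvScenario(season="spring", days=days - winter_days,
                    start_date=boundary, **SEASON_SCENARIOS["spring"]),
    ]


def season_environment(season: str, days: int, seed: int,
                       region_id: str) -> list[EnvObservation]:
    obs: list[EnvObservation] = []
    for segment in season_scenario(season, days):
        obs.extend(simulate_environment(segment, seed, region_id))
    obs.sort(key=lambda o: (o.region_id, o.parameter, o.timestamp))
    return obs


@dataclass
class CohortSpec:
    """Study conditions for one simulated cohort."""

    n_patients: int = 83
    season_mix: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SEASON_MIX))
    deployment_days: int = 30
    between_deployment_days: int = 90  # cross-season patients run 3 months
    beta: float = DEFAULT_BETA
    profile_sampler: Callable[[str, float], PatientProfile] | None = None
    trigger_weights: dict[str, tuple[tuple[str, float], ...]] | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")


def _pick_weighted(rng: np.random.Generator,
                   weighted: tuple[tuple[str, float], ...]) -> str:
    names = [n for n, _ in weighted]
    weights = np.array([w for _, w in weighted], dtype=float)
    return names[rng.choice(len(names), p=weights / weights.sum())]


def simulate_cohort(spec: CohortSpec, seed: int,
                    out_dir: str | Path) -> Path:
    """Write a full cohort in the pipeline's on-disk formats.

    Layout: ``env/<region>.csv`` (one region per season stratum),
    ``patients/<patient_id>/{sessions,daily,lung,deployment}.csv``, and
    ``manifest.csv`` recording each patient's planted trigger — the
    ground truth for recovery experiments.
    """
    out_dir = Path(out_dir)
    season_cycle = [s for s, n in spec.season_mix.items() for _ in range(n)]
    env_days = {s: (spec.between_deployment_days if s == "between"
                    else spec.deployment_days) + 14
                for s in spec.season_mix}
    environments = {
        s: season_environment(s, env_days[s], seed, f"R_{s}")
        for s in spec.season_mix if spec.season_mix[s] > 0}
    for season, obs in environments.items():
        tio.write_env(obs, out_dir / "env" / f"R_{season}.csv")

    trigger_weights = spec.trigger_weights or SEASON_TRIGGER_WEIGHTS
    manifest = ["patient_id,planted_trigger,beta,season"]
    for i in range(spec.n_patients):
        patient_id = f"P{i + 1:03d}"
        rng = _rng(seed, patient_id, "design")
        season = season_cycle[i % len(season_cycle)]
        trigger = _pick_weighted(rng, trigger_weights[season])
        beta = 0.0 if trigger == "none" else spec.beta
        if spec.profile_sampler is not None:
            profile = spec.profile_sampler(trigger, beta)
        else:
            profile = default_profile(trigger, beta)
        days = (spec.between_deployment_days if season == "between"
                else spec.deployment_days)
        offset = int(rng.integers(1, 8))  # leave room for the lag day
        start = SEASON_ENV_START[season] + dt.timedelta(days=offset)
        deployment = PatientDeployment(
            patient_id, f"R_{season}", start,
            start + dt.timedelta(days=days - 1),
            "three_months" if days > 45 else "one_month")
        streams = simulate_patient(profile, environments[season],
                                   deployment, seed)
        tio.write_patient_streams(*streams, deployment,
                                  out_dir / "patients" / patient_id)
        manifest.append(f"{patient_id},{trigger},{beta},{season}")
    (out_dir / "manifest.csv").write_text("\n".join(manifest) + "\n")
    return out_dir


def recovery_cohort(n_patients: int, beta: float, seed: int,
                    out_dir: str | Path,
                    deployment_days: int = 60) -> Path:
    """The planted-trigger recovery experiment.

    Patients alternate between a winter deployment with pm2.5 planted and
    a spring deployment with pollen planted, each trigger being the
    dominant seasonal exposure, so the manifest label is recoverable from
    co-occurrence when the planted effect is real.
    """
    spec = CohortSpec(
        n_patients=n_patients,
        season_mix={"winter": 1, "spring": 1},
        deployment_days=deployment_days,
        beta=beta,
        trigger_weights={
            "winter": (("pm25", 1.0),),
            "spring": (("pollen", 1.0),),
        })
    return simulate_cohort(spec, seed, out_dir)
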