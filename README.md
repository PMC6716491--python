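# asthma-triggers

Personalized asthma-trigger attribution from patient-generated health
data (mHealth diaries, home spirometry) and outdoor environmental
series.

Pediatric asthma is heterogeneous: the exposure that precedes one
child's symptoms (pollen, fine particulate matter, ozone, temperature)
may be irrelevant for another. This package implements a day-level
co-occurrence analysis for cohorts monitored with twice-daily
symptom/medication questionnaires, once-daily nighttime-awakening and
activity-limitation questions, twice-daily peak-flow/FEV1 readings, and
outdoor measurements collected hourly (PM2.5, ozone, temperature,
humidity) or every 12 hours (pollen index). It is aimed at
mHealth/epidemiology researchers who need a tested, reproducible
reference implementation of this analysis — including a synthetic
cohort generator, since real deployments of this kind are rarely
publishable as raw data.

## Method

All streams are aligned to calendar days.

* **Exposure.** For each parameter the daily maximum is compared with
  its healthy range (pollen index 0–2.4; PM2.5 and ozone 0–50 AQI
  points; two-sided configurable bands for temperature and humidity;
  boundary values are healthy). A trigger *t* is an **effective
  exposure** on day *d* if it was outside its healthy range on *d* or
  on *d − 1* — a 48-hour window motivated by late-phase asthmatic
  responses.
* **Episodes.** A day the questionnaire was answered is an **asthma
  episode** if any of: one of the six diary symptoms (cough, wheeze,
  chest tightness, hard and fast breathing, cannot talk in full
  sentences, nose opens wide), nighttime awakening, activity
  limitation, rescue-medication intake, or a PEF or FEV1 reading more
  than 1 SD below the patient's own deployment mean (strict, one-sided:
  x < μ − σ). Unanswered days are excluded from every statistic.
* **Attribution.** The per-patient profile is the matrix of
  conditional probabilities

  P(outcome | C) = #{answered days: C holds and outcome} /
  #{answered days: C holds},

  where each condition C is a conjunction of effective-exposure
  literals (e.g. "pollen and PM2.5", "no pollen and PM2.5") chosen from
  the triggers that actually varied during the deployment. Contributor
  day-counts (episode days with *t* in its exposure window), a
  per-season **major-trigger label** (argmax of per-trigger episode-day
  fractions, with a combined pollen-and-PM2.5 label when both dominate
  jointly, `no_symptoms` below a minimum episode count, and
  `inconclusive` on ties), controller adherence (% of answered days
  with an intake), and a cohort-level per-season label summary complete
  the outputs.

The synthetic generator plants ground truth: AR(1) seasonal
environments with deterministic diurnal shape, and patients whose
symptoms are Bernoulli with log-odds α_s + Σ_t β_t·X_t(d), where
X_t(d) is the same effective-exposure flag the pipeline computes.
Planted susceptibilities are recorded in a manifest, so label-recovery
experiments have an exact oracle.

## Worked example

```
$ asthma-triggers simulate --out demo/cohort --seed 4 --n-patients 2
$ asthma-triggers run --in demo/cohort --out demo/results
$ asthma-triggers report --in demo/cohort --patient P001
Patient P001 (spring)
========================================
Answered days: 26
Asthma episode days: 26
...
Contributor day counts (trigger in unhealthy range on the day or the previous day):
  pollen: 26 of 26 episode days
  pm25: 11 of 26 episode days
  ozone: 0 of 26 episode days
  temperature: 0 of 26 episode days
Controller adherence: 58%
Probability of outcome given trigger condition:
  outcome | pm25 and pollen | no pm25 and pollen
  cough | 0.55 | 0.67
  wheeze | 0.73 | 0.53
  ...
Major trigger: pollen
```

Patient P001 was simulated with a planted pollen susceptibility
(β = 3) in a spring environment; pollen was in its unhealthy range in
the 48-hour window of all 26 episode days, so the pipeline labels the
patient's major trigger `pollen`, matching the manifest. The
probability table conditions on PM2.5 (which varied) with pollen as an
always-present conjunct — the same presence/absence layout a clinician
would read for a real deployment. `demo/results/` additionally contains
per-day status files, `major_triggers.csv`, `adherence.csv`, and the
per-season `cohort_summary.csv`.

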