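# Methods

## Day-level model

The analysis is deliberately non-parametric and day-granular: every
stream is reduced to calendar days, and the only statistic is a
conditional relative frequency. No causal claim is made — the output
quantifies co-occurrence between threshold exceedances and a composite
symptom outcome, which is how the underlying monitoring methodology is
used clinically.

**Exposure classification.** Daily maxima are compared against closed
healthy intervals; a value equal to an endpoint is healthy. Pollen,
PM2.5, and ozone use `above_is_unhealthy` (their healthy ranges start
at 0, so a "below" violation cannot occur); temperature and humidity
are two-sided with configurable bands (defaults 20–90 °F and 20–80 %),
because no published thresholds exist for them at this granularity.
The 48-hour exposure window is implemented as a calendar-day lag:
trigger *t* is effective on *d* iff it was unhealthy on *d* or *d − 1*.
`window.lag_days` is configurable (0 disables carryover; larger values
support sensitivity analyses). A day missing from the environmental
series contributes nothing — no imputation.

**Pollen's two 12-hourly readings** are reduced by the same daily-max
rule as the hourly parameters; with at most two readings per day this
is the natural analogue and keeps one code path.

**Episodes.** `episode = any(symptoms) ∨ awakening ∨ limitation ∨
rescue ∨ lung_abnormal`. The lung rule uses the patient's own
deployment mean and sample SD (denominator n − 1) over *all* readings,
including episode days; excluding symptomatic days would require the
episode labels the rule itself helps define. The contamination widens
the SD, which in practice concentrates lung-abnormal flags on genuinely
depressed (symptomatic) days. The inequality is strict and one-sided:
x < μ − σ; elevated values are never abnormal. A measure with fewer
than two readings disables the rule for that patient (logged warning).
A day counts as *answered* only if at least one questionnaire session
was returned; lung readings alone do not answer a day. Controller
adherence is day-level by default (≥ 1 intake), with a `session` mode
(x/2 per day) behind a config switch.

**Conditioning sets.** Per patient, the conditions default to the
cross-product over triggers whose effective-exposure flag took both
values during the deployment, with always-exposed triggers appended as
positive conjuncts and never-exposed triggers dropped. This reproduces
the two-column presence/absence profile when exactly one trigger
varies, and a single all-present column when none does. A condition
that never holds on an answered day yields no cell (zero denominators
are never emitted). Days on which a referenced trigger was unobserved
enter neither numerator nor denominator.

**Major trigger.** With fewer than `min_episode_days` (default 5)
episode days the label is `no_symptoms` — too few events to conclude
anything. Otherwise f_t = (episode days with t effective)/(episode
days); if f_pollen, f_pm25, and their same-day co-occurrence fraction
all reach `combo_threshold` (default 0.8) the label is
`pollen_and_pm25`; otherwise the unique argmax, or `inconclusive` on a
tie (including all-zero). A deployment is assigned to the season
holding ≥ 80 % of its answered days, else to a `between_seasons`
stratum. Reported percentages and probabilities are rounded (integers,
2 decimals) only at rendering; full precision is kept internally.

## Synthetic cohort

The generator emulates the monitored-cohort setting: per-season AR(1)
environments (winter: pollen absent, PM2.5 frequently above 50; spring
and fall: pollen frequently above 2.4; summer: elevated ozone; a
`between` stratum switches winter → spring at March 1, reproducing the
pollen absence/presence split that makes two-condition profiles
informative). Within-day structure is a deterministic sinusoid peaking
mid-afternoon — only daily maxima matter downstream, so its role is
realism. Values are clipped to their scales (pollen 0–12, humidity
0–100, PM2.5/ozone ≥ 0).

Patients are logistic: baseline per-day outcome rates of 0.05 for the
six symptoms and 0.02 for awakening/limitation on unexposed days, a
planted log-odds increment β = 3 by default on the susceptible
trigger(s), rescue propensity 0.6 given any symptom, controller
adherence 0.5, response rate 0.85, and lung baselines PEF 320 ± 30
L/min, FEV1 2.0 ± 0.25 L with a 2-SD drop on symptomatic days. Lung
readings share a day-level state (AR(1) coefficient 0.6 across days,
within-day weight 0.6), reflecting that airway caliber is a day-scale
quantity; each session's PEF and FEV1 derive from the same standardized
deviate, as both come from the same expiratory maneuver. Marginally
every reading is Gaussian around baseline, so under a no-symptom
profile the 1-SD rule flags readings at the Φ(−1) ≈ 0.159 tail rate —
a property the tests verify. Default deployments are 30 days (90 for
the between-seasons stratum), with the season mix 16/6/14/23/24
matching the cohort composition the generator emulates.

Randomness is split with `numpy` seed sequences keyed by (master seed,
patient id, stream), so cohorts are bit-reproducible and adding a
patient never perturbs existing ones.

**What the generator does not emulate:** reporting biases (symptom
over-/under-reporting), within-day symptom timing, device measurement
error beyond Gaussian noise, indoor air quality, activity/sleep
covariates, and heavy-tailed or skewed lung-function distributions.
Passing recovery tests therefore show the pipeline's correctness under
its own assumptions, not field validity of the co-occurrence method.

## Numerical and degenerate-input choices

* Probabilities are exact integer ratios; no smoothing.
* Ties in the argmax are detected at absolute tolerance 1e−12.
* α = −∞ and β = +∞ are honored exactly (probability 0/1); β terms are
  summed only over active flags so 0 · ∞ never arises.
* Duplicate (patient, date, session) records, records outside the
  deployment window, and malformed rows are hard errors naming the file
  and line; one corrupt patient aborts only that patient in a cohort
  run.
* Writers emit deterministic bytes (sorted rows, `repr` floats for
  lossless round-trips, LF endings).

## Known limitations

* **The method cannot abstain under ambient exposure.** Because
  attribution is pure co-occurrence, a patient with no true trigger
  susceptibility who lives through a high-PM2.5 season and has episode
  days from any source — including the guaranteed Gaussian-tail rate of
  the 1-SD lung rule, ≈ 0.16 per reading — will still receive that
  season's dominant trigger as a label once the minimum episode count
  is reached. Null-cohort experiments (β = 0) make this visible:
  abstention (`no_symptoms`/`inconclusive`) is rare. Interpreting
  labels causally is therefore unsupported; they summarize exposure
  context.
* The 1-SD lung rule is scale-invariant, so its null firing rate is a
  property of the noise distribution, not of device precision.
* Season assignment by answered-day dominance can differ from intended
  recruitment season for sparse responders.
* The probability tables condition on window-level exposure (day or
  previous day); same-day-only conditioning is available by setting
  `window.lag_days: 0`.
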