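import datetime as dt

import pytest

from asthma_triggers.daily import ExposureFlags
from asthma_triggers.episodes import DailyStatus, detect_episode
from asthma_triggers.records import SYMPTOMS
from asthma_triggers.synthetic import CohortSpec, simulate_cohort

D0 = dt.date(2018, 1, 1)


def make_status(day_index=0, answered=True, symptoms=(), rescue=False,
                awakening=False, limitation=False, controller=0,
                pef_abnormal=False, fev1_abnormal=False,
                patient_id="P") -> DailyStatus:
    status = DailyStatus(
        patient_id=patient_id, date=D0 + dt.timedelta(days=day_index),
        answered=answered)
    if not answered:
        return status
    status.symptom_any = {s: s in symptoms for s in SYMPTOMS}
    status.rescue_taken = rescue
    status.nighttime_awakening = awakening
    status.activity_limitation = limitation
    status.controller_sessions = controller
    status.lung_abnormal = {"pef": pef_abnormal, "fev1": fev1_abnormal}
    status.episode, status.components = detect_episode(status)
    return status


def make_flags(day_index=0, **effective) -> ExposureFlags:
    return ExposureFlags(D0 + dt.timedelta(days=day_index),
                         unhealthy=dict(effective),
                         effective=dict(effective))


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 6-patient cohort across winter, spring, and a straddling
    deployment, written in the on-disk input formats."""
    out = tmp_path_factory.mktemp("cohort") / "data"
    spec = CohortSpec(n_patients=6,
                      season_mix={"winter": 1, "spring": 1, "between": 1},
                      deployment_days=25)
    simulate_cohort(spec, seed=11, out_dir=out)
    return out
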