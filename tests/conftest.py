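import datetime as dt

import pytest

from telestress import (CohortSpec, ExperimentConfig, WorkShiftRecord,
                        compute_teleworking_rate, default_registry,
                        generate_cohort)
from telestress.features import (build_instances, build_labels,
                                 build_weekly_features, infer_study_start)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_cohort():
    """A 25-participant, 12-week synthetic cohort with the default planted
    effects; large enough for a full neighborhood cluster (pool of 24 < 20
    is not triggered because cluster_size is lowered where needed)."""
    return generate_cohort(CohortSpec(n_participants=25, n_weeks=12, seed=7))


@pytest.fixture(scope="session")
def small_cohort_prepared(small_cohort, registry):
    """(instances_by_participant, profiles) for the small cohort."""
    start = infer_study_start(small_cohort.participants)
    instances, profiles = {}, {}
    for p in small_cohort.participants:
        feats = build_weekly_features(p, registry, start, 12)
        instances[p.participant_id] = build_instances(feats, build_labels(p))
        profiles[p.participant_id] = compute_teleworking_rate(
            p.shifts, p.participant_id)
    return instances, profiles


def make_shift(pid="P1", date=dt.date(2022, 1, 17), wfh=False, absent=False,
               actual_start=540.0, actual_end=1050.0):
    if absent:
        actual_start = actual_end = None
    return WorkShiftRecord(
        participant_id=pid, date=date, scheduled_start=540.0,
        scheduled_end=1050.0, scheduled_hours=8.0, wfh=wfh, absent=absent,
        actual_start=actual_start, actual_end=actual_end)
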