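import numpy as np
import pytest

from fvcjoint import (
    JointDataset,
    SubjectData,
    SubjectRecord,
    VisitRecord,
    SimulationConfig,
    simulate_dataset,
)


def make_subject(
    subject_id="S1",
    arm=0,
    ata=0,
    baseline=70.0,
    event_time=1.0,
    event=0,
    times=(),
    fvc=(),
):
    return SubjectData(
        subject_id=subject_id,
        arm=arm,
        ata_positive=ata,
        baseline_fvc_pct=baseline,
        event_time_years=event_time,
        event_indicator=event,
        times_years=np.asarray(times, dtype=float),
        fvc=np.asarray(fvc, dtype=float),
    )


def make_dataset(subjects, endpoint="all_cause", period="52w"):
    return JointDataset(subjects=list(subjects), endpoint=endpoint, period=period)


@pytest.fixture
def toy_raw_tables(tmp_path):
    """Two subjects, four visits, one hospitalisation, written as CSVs."""
    subjects = tmp_path / "subjects.csv"
    visits = tmp_path / "visits.csv"
    events = tmp_path / "hosp_events.csv"
    subjects.write_text(
        "subject_id,arm,ata_positive,baseline_fvc_pct,followup_end_days,death_day\n"
        "A,1,0,72.5,392,\n"
        "B,0,1,65.0,392,250\n"
    )
    visits.write_text(
        "subject_id,visit_week,fvc_pct,on_treatment\n"
        "A,0,72.0,1\n"
        "A,2,71.5,1\n"
        "B,0,64.0,1\n"
        "B,24,63.0,1\n"
    )
    events.write_text("subject_id,event_day,category\nA,30,all_cause\n")
    return str(subjects), str(visits), str(events)


@pytest.fixture(scope="session")
def small_trial():
    """A simulated 150-subject trial shared by the slower model tests."""
    cfg = SimulationConfig(n_subjects=150)
    dataset, truth = simulate_dataset(cfg, seed=20260101 % (2**31))
    return cfg, dataset, truth
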