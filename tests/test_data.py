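"""Raw-table parsing, endpoint derivation and measurement filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fvcjoint import (
    DAYS_PER_YEAR,
    WEEK52_CAP_DAYS,
    SchemaError,
    SubjectRecord,
    ValidationError,
    VisitRecord,
    build_joint_dataset,
    derive_endpoint,
    filter_on_treatment,
    read_tables,
    write_tables,
)


class TestReadTables:
    def test_toy_csv_parses_into_typed_records(self, toy_raw_tables):
        subjects, visits = read_tables(*toy_raw_tables)
        assert len(subjects) == 2
        assert len(visits) == 4
        a = next(s for s in subjects if s.subject_id == "A")
        assert a.hospitalisation_events == [(30.0, "all_cause")]
        assert a.death_day is None
        b = next(s for s in subjects if s.subject_id == "B")
        assert b.death_day == 250.0

    def test_missing_fvc_is_kept_as_missing(self, tmp_path, toy_raw_tables):
        subjects_csv, _, events_csv = toy_raw_tables
        visits_csv = tmp_path / "v.csv"
        visits_csv.write_text(
            "subject_id,visit_week,fvc_pct,on_treatment\nA,2,,1\nA,4,70.0,1\n"
        )
        _, visits = read_tables(subjects_csv, str(visits_csv), events_csv)
        assert visits[0].fvc_pct is None
        # and the missing measurement is dropped by the filter
        t, y = filter_on_treatment(visits, event_time_years=1.0)
        assert len(t) == 1 and y[0] == 70.0

    def test_negative_visit_week_names_the_row(self, tmp_path, toy_raw_tables):
        subjects_csv, _, events_csv = toy_raw_tables
        visits_csv = tmp_path / "v.csv"
        visits_csv.write_text("subject_id,visit_week,fvc_pct,on_treatment\nA,-2,70,1\n")
        with pytest.raises(ValidationError, match="row 2"):
            read_tables(subjects_csv, str(visits_csv), events_csv)

    def test_missing_mandatory_column_is_schema_error(self, tmp_path, toy_raw_tables):
        _, visits_csv, events_csv = toy_raw_tables
        bad = tmp_path / "s.csv"
        bad.write_text("subject_id,arm\nA,1\n")
        with pytest.raises(SchemaError, match="mandatory column"):
            read_tables(str(bad), visits_csv, events_csv)

    def test_duplicate_subject_week_pair_rejected(self, tmp_path, toy_raw_tables):
        subjects_csv, _, events_csv = toy_raw_tables
        visits_csv = tmp_path / "v.csv"
        visits_csv.write_text(
            "subject_id,visit_week,fvc_pct,on_treatment\nA,2,70,1\nA,2,71,1\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_tables(subjects_csv, str(visits_csv), events_csv)

    def test_round_trip_preserves_records(self, tmp_path, toy_raw_tables):
        subjects, visits = read_tables(*toy_raw_tables)
        paths = (tmp_path / "s.csv", tmp_path / "v.csv", tmp_path / "e.csv")
        write_tables(subjects, visits, *map(str, paths))
        subjects2, visits2 = read_tables(str(paths[0]), str(paths[1]), str(paths[2]))
        assert subjects == subjects2
        assert visits == visits2


def _subject(events=(), death=None, followup=392.0):
    return SubjectRecord(
        subject_id="X",
        arm=1,
        ata_positive=0,
        baseline_fvc_pct=70.0,
        followup_end_days=followup,
        hospitalisation_events=list(events),
        death_day=death,
    )


class TestDeriveEndpoint:
    def test_event_inside_window(self):
        s = _subject(events=[(30.0, "all_cause")])
        assert derive_endpoint(s) == (30.0 / DAYS_PER_YEAR, 1)

    def test_event_after_followup_window_is_censored(self):
        # a hospitalisation 40 days beyond the end of the 28-day window
        s = _subject(events=[(392.0 + 40.0, "all_cause")])
        t, d = derive_endpoint(s)
        assert d == 0
        assert t == pytest.approx(392.0 / DAYS_PER_YEAR)

    def test_composite_takes_earlier_of_death_and_hospitalisation(self):
        s = _subject(events=[(150.0, "all_cause")], death=100.0)
        assert derive_endpoint(s) == (100.0 / DAYS_PER_YEAR, 1)

    def test_52w_cap_is_392_days(self):
        s = _subject(events=[(500.0, "all_cause")], followup=728.0)
        t52, d52 = derive_endpoint(s, period="52w")
        tw, dw = derive_endpoint(s, period="whole")
        assert (d52, dw) == (0, 1)
        assert t52 == pytest.approx(WEEK52_CAP_DAYS / DAYS_PER_YEAR)
        assert tw == pytest.approx(500.0 / DAYS_PER_YEAR)

    def test_category_matching(self):
        s = _subject(events=[(60.0, "ssc_related")])
        # an ssc-related hospitalisation is also an all-cause one
        assert derive_endpoint(s, endpoint="all_cause")[1] == 1
        assert derive_endpoint(s, endpoint="ssc_related")[1] == 1
        assert derive_endpoint(s, endpoint="icu")[1] == 0

    def test_day_zero_event_gets_positive_time(self):
        s = _subject(events=[(0.0, "all_cause")])
        t, d = derive_endpoint(s)
        assert d == 1 and t == pytest.approx(0.5 / DAYS_PER_YEAR)

    @given(
        days=st.lists(st.floats(0, 800), max_size=4),
        death=st.one_of(st.none(), st.floats(0, 800)),
    )
    @settings(max_examples=100, deadline=None)
    def test_idempotent_and_order_independent(self, days, death):
        events = [(d, "all_cause") for d in days]
        s1 = _subject(events=events, death=death)
        s2 = _subject(events=list(reversed(events)), death=death)
        r1 = derive_endpoint(s1)
        assert r1 == derive_endpoint(s1) == derive_endpoint(s2)
        # whole-trial window can only add events and extend censoring
        t52, d52 = derive_endpoint(s1, period="52w")
        tw, dw = derive_endpoint(s1, period="whole")
        assert dw >= d52
        assert tw >= t52 - 1e-12


class TestFilterOnTreatment:
    def test_keeps_only_measurements_before_event(self):
        visits = [
            VisitRecord("X", w, 70.0 - w / 10, 1) for w in (2.0, 24.0, 52.0)
        ]
        t, y = filter_on_treatment(visits, event_time_years=30 * 7 / DAYS_PER_YEAR)
        assert len(t) == 2
        assert np.allclose(t, np.array([2.0, 24.0]) * 7 / DAYS_PER_YEAR)

    def test_off_treatment_visit_dropped_regardless_of_timing(self):
        visits = [VisitRecord("X", 12.0, 68.0, 0)]
        t, _ = filter_on_treatment(visits, event_time_years=2.0)
        assert len(t) == 0

    def test_baseline_week_excluded_from_response(self):
        visits = [VisitRecord("X", 0.0, 70.0, 1), VisitRecord("X", 2.0, 69.0, 1)]
        t, y = filter_on_treatment(visits, event_time_years=2.0)
        assert len(t) == 1 and y[0] == 69.0

    def test_no_retained_visits_is_allowed(self):
        t, y = filter_on_treatment([], event_time_years=1.0)
        assert len(t) == 0 and len(y) == 0


class TestBuildJointDataset:
    def _records(self):
        subs, visits = [], []
        for i in range(5):
            events = [(100.0, "all_cause")] if i < 2 else []
            subs.append(
                SubjectRecord(
                    subject_id=f"P{i}",
                    arm=i % 2,
                    ata_positive=i // 3,
                    baseline_fvc_pct=70.0,
                    followup_end_days=392.0,
                    hospitalisation_events=events,
                )
            )
            visits.append(VisitRecord(f"P{i}", 2.0, 70.0, 1))
        return subs, visits

    def test_counts_match_event_rows(self):
        subs, visits = self._records()
        ds = build_joint_dataset(subs, visits)
        assert ds.summary() == {
            "endpoint": "all_cause",
            "period": "52w",
            "n": 5,
            "n_events": 2,
            "event_pct": 40.0,
            "unfittable": False,
        }

    def test_zero_event_endpoint_flagged_unfittable(self):
        subs, visits = self._records()
        ds = build_joint_dataset(subs, visits, endpoint="ventilation")
        assert ds.n_events == 0 and ds.unfittable

    def test_whole_trial_event_count_dominates_52w(self, small_trial):
        cfg, _, truth = small_trial
        import dataclasses

        from fvcjoint import simulate_trial

        cfg_whole = dataclasses.replace(cfg, period="whole")
        subs, visits, _ = simulate_trial(cfg_whole, truth.seed)
        ds52 = build_joint_dataset(subs, visits, period="52w")
        dsw = build_joint_dataset(subs, visits, period="whole")
        assert dsw.n_events >= ds52.n_events
        for a, b in zip(ds52.subjects, dsw.subjects):
            assert b.event_time_years >= a.event_time_years - 1e-12

    def test_retained_times_precede_event_times(self, small_trial):
        _, ds, _ = small_trial
        for s in ds.subjects:
            assert np.all(s.times_years < s.event_time_years)
            assert s.event_time_years > 0
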