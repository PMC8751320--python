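"""Domain types, CSV readers/writers and analysis-dataset construction.

The raw inputs are three tables: one row per subject (treatment arm,
anti-topoisomerase antibody status, baseline FVC% predicted, end of the
follow-up window, optional day of death), one row per hospitalisation
event (day and category), and one row per spirometry visit (week and
FVC% predicted).  From these the analysis dataset is derived by

* composing each hospitalisation endpoint with death into a composite
  "first event" time, counting only events inside the treatment period
  plus a 28-day window, and
* retaining only on-treatment FVC measurements taken strictly before the
  composite event (or censoring) time.

Times are carried in years (days / 365.25) so that trajectory slopes read
as annual rates of change in FVC% predicted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25
WEEKS_TO_YEARS = 7.0 / DAYS_PER_YEAR

#: hospitalisation categories; ``all_cause`` matches any hospitalisation row,
#: the others match rows tagged with that exact category.
HOSP_CATEGORIES = ("all_cause", "ssc_related", "er_or_icu", "icu", "ventilation")

#: 52-week analysis cap: treatment visits through week 52 plus the 28-day
#: post-treatment event window.
WEEK52_CAP_DAYS = 52 * 7 + 28

_SUBJECT_COLUMNS = (
    "subject_id",
    "arm",
    "ata_positive",
    "baseline_fvc_pct",
    "followup_end_days",
    "death_day",
)
_EVENT_COLUMNS = ("subject_id", "event_day", "category")
_VISIT_COLUMNS = ("subject_id", "visit_week", "fvc_pct", "on_treatment")


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


class ValidationError(ValueError):
    """Rows fail type or range checks; the message names the rows."""


class UnfittableEndpointError(RuntimeError):
    """Too few events for a stable model fit on this endpoint."""


@dataclass
class SubjectRecord:
    """One trial participant: covariates and outcome bookkeeping.

    ``followup_end_days`` is the end of the event-observation window
    (treatment stop plus 28 days), taken as given input.  Hospitalisation
    events are ``(day, category)`` pairs with categories from
    :data:`HOSP_CATEGORIES`.
    """

    subject_id: str
    arm: int
    ata_positive: int
    baseline_fvc_pct: float
    followup_end_days: float
    hospitalisation_events: list[tuple[float, str]] = field(default_factory=list)
    death_day: float | None = None

    def __post_init__(self) -> None:
        if not self.followup_end_days > 0:
            raise ValidationError(
                f"subject {self.subject_id!r}: followup_end_days must be > 0"
            )
        if not self.baseline_fvc_pct > 0:
            raise ValidationError(
                f"subject {self.subject_id!r}: baseline_fvc_pct must be > 0"
            )
        for day, cat in self.hospitalisation_events:
            if day < 0:
                raise ValidationError(
                    f"subject {self.subject_id!r}: event day {day} < 0"
                )
            if cat not in HOSP_CATEGORIES:
                raise ValidationError(
                    f"subject {self.subject_id!r}: unknown event category {cat!r}"
                )
        if self.death_day is not None and self.death_day < 0:
            raise ValidationError(f"subject {self.subject_id!r}: death_day < 0")


@dataclass
class VisitRecord:
    """One spirometry visit.  ``fvc_pct`` may be None (missing measurement)."""

    subject_id: str
    visit_week: float
    fvc_pct: float | None
    on_treatment: int = 1

    def __post_init__(self) -> None:
        if self.visit_week < 0:
            raise ValidationError(
                f"subject {self.subject_id!r}: visit_week {self.visit_week} < 0"
            )
        if self.fvc_pct is not None and not self.fvc_pct > 0:
            raise ValidationError(
                f"subject {self.subject_id!r}: fvc_pct must be > 0 if present"
            )


@dataclass
class SubjectData:
    """Endpoint-derived, filtered record of one subject in a JointDataset."""

    subject_id: str
    arm: int
    ata_positive: int
    baseline_fvc_pct: float
    event_time_years: float
    event_indicator: int
    times_years: np.ndarray
    fvc: np.ndarray


@dataclass
class JointDataset:
    """Validated analysis dataset for one endpoint and analysis period.

    Every subject appears exactly once; subjects without any retained FVC
    measurement still contribute survival information.
    """

    subjects: list[SubjectData]
    endpoint: str
    period: str

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def n_events(self) -> int:
        return sum(s.event_indicator for s in self.subjects)

    @property
    def event_fraction(self) -> float:
        return self.n_events / self.n if self.n else float("nan")

    @property
    def unfittable(self) -> bool:
        """True when the endpoint has no events at all (no hazard is estimable)."""
        return self.n_events == 0

    def event_times(self, uncensored_only: bool = True) -> np.ndarray:
        ts = [
            s.event_time_years
            for s in self.subjects
            if s.event_indicator or not uncensored_only
        ]
        return np.asarray(ts, dtype=float)

    def summary(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "period": self.period,
            "n": self.n,
            "n_events": self.n_events,
            "event_pct": round(100.0 * self.event_fraction, 1) if self.n else None,
            "unfittable": self.unfittable,
        }


def _require_columns(df: pd.DataFrame, required: Sequence[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing mandatory column(s) {missing}")


def read_tables(
    subjects_csv: str,
    visits_csv: str,
    events_csv: str | None = None,
) -> tuple[list[SubjectRecord], list[VisitRecord]]:
    """Read and validate the raw trial tables.

    Parameters
    ----------
    subjects_csv, visits_csv, events_csv
        Paths to UTF-8 CSV files with header rows.  ``events_csv`` holds the
        hospitalisation events; if omitted, subjects carry no events.

    Returns
    -------
    (subjects, visits)
        Typed records; hospitalisation events are attached to their subject.

    Raises
    ------
    SchemaError
        if a mandatory column is absent.
    ValidationError
        if a row fails a type or range check (the message cites row numbers)
        or a ``(subject_id, visit_week)`` pair is duplicated.
    """
    sdf = pd.read_csv(subjects_csv, dtype={"subject_id": str})
    _require_columns(sdf, _SUBJECT_COLUMNS[:-1], "subjects table")
    if "death_day" not in sdf.columns:
        sdf["death_day"] = np.nan

    events_by_subject: dict[str, list[tuple[float, str]]] = {}
    if events_csv is not None:
        edf = pd.read_csv(events_csv, dtype={"subject_id": str})
        _require_columns(edf, _EVENT_COLUMNS, "events table")
        for rownum, row in enumerate(edf.itertuples(index=False), start=2):
            if pd.isna(row.event_day) or row.event_day < 0:
                raise ValidationError(
                    f"events table row {rownum}: invalid event_day {row.event_day!r}"
                )
            events_by_subject.setdefault(row.subject_id, []).append(
                (float(row.event_day), str(row.category))
            )

    subjects: list[SubjectRecord] = []
    seen_ids: set[str] = set()
    for rownum, row in enumerate(sdf.itertuples(index=False), start=2):
        if row.subject_id in seen_ids:
            raise ValidationError(
                f"subjects table row {rownum}: duplicate subject_id {row.subject_id!r}"
            )
        seen_ids.add(row.subject_id)
        try:
            subjects.append(
                SubjectRecord(
                    subject_id=row.subject_id,
                    arm=int(row.arm),
                    ata_positive=int(row.ata_positive),
                    baseline_fvc_pct=float(row.baseline_fvc_pct),
                    followup_end_days=float(row.followup_end_days),
                    hospitalisation_events=events_by_subject.get(row.subject_id, []),
                    death_day=None if pd.isna(row.death_day) else float(row.death_day),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"subjects table row {rownum}: {exc}") from exc

    vdf = pd.read_csv(visits_csv, dtype={"subject_id": str})
    _require_columns(vdf, ("subject_id", "visit_week"), "visits table")
    if "on_treatment" not in vdf.columns:
        vdf["on_treatment"] = 1
    if "fvc_pct" not in vdf.columns:
        raise SchemaError("visits table: missing mandatory column(s) ['fvc_pct']")
    dup = vdf.duplicated(subset=["subject_id", "visit_week"])
    if dup.any():
        rows = [int(i) + 2 for i in vdf.index[dup][:5]]
        raise ValidationError(
            f"visits table: duplicate (subject_id, visit_week) at row(s) {rows}"
        )

    visits: list[VisitRecord] = []
    for rownum, row in enumerate(vdf.itertuples(index=False), start=2):
        try:
            visits.append(
                VisitRecord(
                    subject_id=row.subject_id,
                    visit_week=float(row.visit_week),
                    fvc_pct=None if pd.isna(row.fvc_pct) else float(row.fvc_pct),
                    on_treatment=int(row.on_treatment),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"visits table row {rownum}: {exc}") from exc

    return subjects, visits


def write_tables(
    subjects: Iterable[SubjectRecord],
    visits: Iterable[VisitRecord],
    subjects_csv: str,
    visits_csv: str,
    events_csv: str | None = None,
) -> None:
    """Write records back to the three-CSV layout accepted by read_tables."""
    srows, erows = [], []
    for s in subjects:
        srows.append(
            {
                "subject_id": s.subject_id,
                "arm": s.arm,
                "ata_positive": s.ata_positive,
                "baseline_fvc_pct": s.baseline_fvc_pct,
                "followup_end_days": s.followup_end_days,
                "death_day": s.death_day if s.death_day is not None else "",
            }
        )
        for day, cat in s.hospitalisation_events:
            erows.append({"subject_id": s.subject_id, "event_day": day, "category": cat})
    pd.DataFrame(srows, columns=list(_SUBJECT_COLUMNS)).to_csv(subjects_csv, index=False)
    vrows = [
        {
            "subject_id": v.subject_id,
            "visit_week": v.visit_week,
            "fvc_pct": v.fvc_pct if v.fvc_pct is not None else "",
            "on_treatment": v.on_treatment,
        }
        for v in visits
    ]
    pd.DataFrame(vrows, columns=list(_VISIT_COLUMNS)).to_csv(visits_csv, index=False)
    if events_csv is not None:
        pd.DataFrame(erows, columns=list(_EVENT_COLUMNS)).to_csv(events_csv, index=False)


def _matches_endpoint(category: str, endpoint: str) -> bool:
    # every hospitalisation is an all-cause hospitalisation
    return endpoint == "all_cause" or category == endpoint


def derive_endpoint(
    subject: SubjectRecord,
    endpoint: str = "all_cause",
    period: str = "52w",
) -> tuple[float, int]:
    """Composite first-event time for one subject.

    The event time is the minimum of the first qualifying hospitalisation day
    and the day of death, provided it falls within the observation window
    (treatment period plus 28 days, additionally capped at 392 days for the
    52-week analysis); otherwise the subject is censored at the cap.
    Event days beyond ``followup_end_days`` never qualify.

    Returns ``(event_time_years, event_indicator)`` with time in years and
    a strictly positive event time (a day-0 event is shifted to half a day).
    """
    if endpoint not in HOSP_CATEGORIES:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    if period not in ("52w", "whole"):
        raise ValueError(f"unknown period {period!r}; expected '52w' or 'whole'")

    cap_days = subject.followup_end_days
    if period == "52w":
        cap_days = min(cap_days, WEEK52_CAP_DAYS)

    candidates = [
        day
        for day, cat in subject.hospitalisation_events
        if _matches_endpoint(cat, endpoint) and day <= subject.followup_end_days
    ]
    if subject.death_day is not None and subject.death_day <= subject.followup_end_days:
        candidates.append(subject.death_day)

    if candidates and min(candidates) <= cap_days:
        day = max(min(candidates), 0.5)  # keep event_time strictly positive
        return day / DAYS_PER_YEAR, 1
    return cap_days / DAYS_PER_YEAR, 0


def filter_on_treatment(
    visits: Iterable[VisitRecord],
    event_time_years: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Retain the longitudinal response pairs for one subject.

    Keeps on-treatment visits with a non-missing FVC taken strictly before
    the event/censoring time.  The week-0 (baseline) measurement is excluded
    from the response vector: baseline FVC enters the model as a covariate
    only.
    """
    t, y = [], []
    for v in visits:
        if not v.on_treatment or v.fvc_pct is None or v.visit_week <= 0:
            continue
        ty = v.visit_week * WEEKS_TO_YEARS
        if ty < event_time_years:
            t.append(ty)
            y.append(v.fvc_pct)
    order = np.argsort(t, kind="stable")
    return np.asarray(t, dtype=float)[order], np.asarray(y, dtype=float)[order]


def build_joint_dataset(
    subjects: Sequence[SubjectRecord],
    visits: Sequence[VisitRecord],
    endpoint: str = "all_cause",
    period: str = "52w",
) -> JointDataset:
    """Apply endpoint derivation and measurement filtering to every subject."""
    visits_by_subject: dict[str, list[VisitRecord]] = {}
    for v in visits:
        visits_by_subject.setdefault(v.subject_id, []).append(v)

    out: list[SubjectData] = []
    for s in subjects:
        time_years, indicator = derive_endpoint(s, endpoint=endpoint, period=period)
        tt, yy = filter_on_treatment(visits_by_subject.get(s.subject_id, []), time_years)
        out.append(
            SubjectData(
                subject_id=s.subject_id,
                arm=s.arm,
                ata_positive=s.ata_positive,
                baseline_fvc_pct=s.baseline_fvc_pct,
                event_time_years=time_years,
                event_indicator=indicator,
                times_years=tt,
                fvc=yy,
            )
        )
    return JointDataset(subjects=out, endpoint=endpoint, period=period)
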