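"""Cohort selection and five-year outcome labeling.

Inclusion: at least one index-code (default ICD-10 I20, angina) diagnosis on
an inpatient or emergency encounter inside the admission window; the index
admission is the earliest qualifying one.  Exclusion: any prior-history
event (default MI / stroke / heart failure) strictly before the index date,
and patients whose qualifying encounters are all outpatient.

Labeling: outcome 1 iff a composite event (death, MI, stroke, heart
failure) occurs strictly after the index date and within the follow-up
horizon (default 1826 days, i.e. five years at 365.25 days/year); else 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .errors import ConsistencyError
from .synthetic import EmrTables

logger = logging.getLogger(__name__)

DEFAULT_EVENT_TYPES = frozenset({"death", "MI", "stroke", "heart_failure"})


@dataclass(frozen=True)
class CohortCriteria:
    """Inclusion/exclusion filters and the follow-up horizon."""

    index_code: str = "I20"
    allowed_encounters: frozenset = frozenset({"inpatient", "emergency"})
    window_start: date = date(2000, 1, 1)
    window_end: date = date(2016, 12, 31)
    exclusion_history: frozenset = frozenset({"MI", "stroke", "heart_failure"})
    event_types: frozenset = DEFAULT_EVENT_TYPES
    horizon_days: int = 1826

    def __post_init__(self) -> None:
        if self.horizon_days <= 0:
            raise ValueError("horizon_days must be positive")
        if not self.index_code:
            raise ValueError("index_code must be non-empty")


def _coerce_dates(frame: pd.DataFrame, col: str, table: str) -> pd.DataFrame:
    """Parse a date column; malformed rows are dropped with a log line."""
    parsed = pd.to_datetime(frame[col], errors="coerce")
    bad = parsed.isna() & frame[col].notna()
    if bad.any():
        logger.warning("dropping %d %s rows with malformed %s", int(bad.sum()), table, col)
    out = frame.copy()
    out[col] = parsed
    return out[parsed.notna()]


def _latest_before_index(
    records: pd.DataFrame, index_dates: pd.Series, name_col: str, date_col: str, prefix: str
) -> pd.DataFrame:
    """Wide frame of the latest value per (patient, measure) at or before index."""
    if records.empty:
        return pd.DataFrame(index=index_dates.index)
    merged = records.merge(index_dates.rename("index_date"), left_on="patient_id", right_index=True)
    merged = merged[merged[date_col] <= merged["index_date"]]
    if merged.empty:
        return pd.DataFrame(index=index_dates.index)
    merged = merged.sort_values([date_col], kind="stable")
    latest = merged.groupby(["patient_id", name_col])["value"].last().unstack(name_col)
    latest.columns = [f"{prefix}_{c}" for c in latest.columns]
    return latest


def select_cohort(tables: EmrTables, criteria: CohortCriteria = CohortCriteria()) -> pd.DataFrame:
    """Apply the inclusion/exclusion flow; returns an unlabeled cohort table.

    One row per included patient with ``index_date``, demographics and
    latest-before-index summaries of every auxiliary table.  An empty person
    table yields an empty cohort, not an error.
    """
    cols = [
        "patient_id",
        "index_date",
        "sex",
        "age_at_index",
    ]
    if tables.person.empty:
        return pd.DataFrame(columns=cols)

    diag = _coerce_dates(tables.diagnosis, "diagnosis_date", "diagnosis")
    qualifying = diag[
        diag["icd10_code"].astype(str).str.startswith(criteria.index_code)
        & diag["encounter_type"].isin(criteria.allowed_encounters)
        & (diag["diagnosis_date"] >= pd.Timestamp(criteria.window_start))
        & (diag["diagnosis_date"] <= pd.Timestamp(criteria.window_end))
    ]
    if qualifying.empty:
        return pd.DataFrame(columns=cols)
    index_date = qualifying.groupby("patient_id")["diagnosis_date"].min()

    # prior-history exclusion: any listed event strictly before index
    events = _coerce_dates(tables.events, "event_date", "events")
    prior = events[events["event_type"].isin(criteria.exclusion_history)].merge(
        index_date.rename("index_date"), left_on="patient_id", right_index=True
    )
    excluded = set(prior.loc[prior["event_date"] < prior["index_date"], "patient_id"])
    index_date = index_date[~index_date.index.isin(excluded)]
    if index_date.empty:
        return pd.DataFrame(columns=cols)

    cohort = index_date.rename("index_date").to_frame()
    person = tables.person.set_index("patient_id")
    cohort["sex"] = person["sex"]
    birth = pd.to_datetime(person["birth_date"])
    cohort["age_at_index"] = (
        (cohort["index_date"] - birth.loc[cohort.index]).dt.days / 365.25
    ).round(2)

    # latest-before-index summaries from the measurement panels
    for table, name_col, date_col, prefix in [
        (tables.laboratory, "test_name", "date", "lab"),
        (tables.echocardiography, "measure_name", "date", "echo"),
        (tables.physical, "measure_name", "date", "phys"),
    ]:
        coerced = _coerce_dates(table, date_col, prefix) if not table.empty else table
        wide = _latest_before_index(coerced, cohort["index_date"], name_col, date_col, prefix)
        cohort = cohort.join(wide)

    smoke = tables.smoke.groupby("patient_id")["smoking_level"].max()
    cohort["smoke_level"] = smoke

    cohort["n_medications"] = tables.medication.groupby("patient_id").size()
    cohort["n_visits"] = tables.visit.groupby("patient_id").size()
    cohort["n_surgeries"] = tables.surgery.groupby("patient_id").size()
    cohort["n_diagnoses"] = tables.diagnosis.groupby("patient_id")["icd10_code"].nunique()
    for col in ["n_medications", "n_visits", "n_surgeries", "n_diagnoses"]:
        cohort[col] = cohort[col].fillna(0).astype(int)

    cohort = cohort.reset_index().rename(columns={"index": "patient_id"})
    if "patient_id" not in cohort.columns:  # groupby index name already set
        cohort = cohort.rename(columns={cohort.columns[0]: "patient_id"})
    return cohort.sort_values("patient_id", kind="stable").reset_index(drop=True)


def label_outcome(
    cohort: pd.DataFrame,
    events: pd.DataFrame,
    horizon_days: int = 1826,
    event_types=DEFAULT_EVENT_TYPES,
) -> pd.DataFrame:
    """Attach the binary composite outcome to a cohort table.

    ``outcome`` is 1 iff a listed event falls strictly after the index date
    and within ``horizon_days`` of it.  A listed event strictly *before* the
    index date of an included patient indicates broken upstream filtering
    and raises :class:`ConsistencyError`.
    """
    labeled = cohort.copy()
    if labeled.empty:
        labeled["outcome"] = pd.Series(dtype=int)
        return labeled
    ev = _coerce_dates(events, "event_date", "events")
    ev = ev[ev["event_type"].isin(event_types)]
    merged = ev.merge(labeled[["patient_id", "index_date"]], on="patient_id")
    if not merged.empty:
        before = merged["event_date"] < merged["index_date"]
        if before.any():
            bad = sorted(merged.loc[before, "patient_id"].unique())[:5]
            raise ConsistencyError(
                f"follow-up events predate the index admission for patients {bad}; "
                "these patients should have been excluded upstream"
            )
        delta = (merged["event_date"] - merged["index_date"]).dt.days
        hit = merged.loc[(delta > 0) & (delta <= horizon_days), "patient_id"].unique()
    else:
        hit = []
    labeled["outcome"] = labeled["patient_id"].isin(set(hit)).astype(int)
    return labeled
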