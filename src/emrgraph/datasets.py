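"""Small hand-written demo datasets (synthetic, built in code).

``journey_demo_tables`` returns a five-patient EMR bundle used throughout
the documentation and round-trip tests.  Patient 107411 is the worked
example: an angina admission with a hypertension diagnosis, a blood
laboratory value of 94.0, an echocardiography measurement of -1.0, a
physical measurement of 53.55, smoking level 1, statin medication, a
diagnostic-ultrasound procedure, and a composite event at age 67.
"""

from __future__ import annotations

import pandas as pd

from .synthetic import EmrTables

JOURNEY_PATIENT_ID = 107411


def journey_demo_tables() -> EmrTables:
    """Five synthetic patients; 107411 carries the documented journey."""

    def d(s: str) -> pd.Timestamp:
        return pd.Timestamp(s)

    person = pd.DataFrame(
        {
            "patient_id": [107411, 107412, 107413, 107414, 107415],
            "sex": ["M", "F", "M", "F", "M"],
            "birth_date": [d("1943-03-15"), d("1950-06-01"), d("1962-09-20"), d("1948-01-10"), d("1955-11-05")],
        }
    )
    # 107411: index angina admission 2008-05-10, aged 65 at index
    diagnosis = pd.DataFrame(
        {
            "patient_id": [107411, 107411, 107412, 107413, 107414, 107415, 107415],
            "icd10_code": ["I20", "I10", "I20", "I20", "I20", "I20", "E11"],
            "diagnosis_name": [
                "angina",
                "hypertension",
                "angina",
                "angina",
                "angina",
                "angina",
                "type 2 diabetes",
            ],
            "diagnosis_date": [
                d("2008-05-10"),
                d("2008-05-10"),
                d("2006-03-02"),
                d("2010-07-15"),
                d("2005-01-20"),
                d("2012-04-11"),
                d("2012-04-11"),
            ],
            "encounter_type": ["inpatient", "inpatient", "inpatient", "emergency", "inpatient", "inpatient", "outpatient"],
        }
    )
    laboratory = pd.DataFrame(
        {
            "patient_id": [107411, 107412, 107413, 107414, 107415],
            "test_name": ["blood", "blood", "blood", "blood", "blood"],
            "value": [94.0, 88.5, 101.2, 92.3, 97.8],
            "date": [d("2008-05-01"), d("2006-02-20"), d("2010-07-01"), d("2005-01-05"), d("2012-04-01")],
        }
    )
    echocardiography = pd.DataFrame(
        {
            "patient_id": [107411, 107412, 107414],
            "measure_name": ["gls", "ef", "ef"],
            "value": [-1.0, 60.2, 55.1],
            "date": [d("2008-05-02"), d("2006-02-21"), d("2005-01-06")],
        }
    )
    physical = pd.DataFrame(
        {
            "patient_id": [107411, 107412, 107413, 107415],
            "measure_name": ["weight", "weight", "sbp", "sbp"],
            "value": [53.55, 61.2, 135.0, 128.0],
            "date": [d("2008-05-03"), d("2006-02-22"), d("2010-07-02"), d("2012-04-02")],
        }
    )
    medication = pd.DataFrame(
        {
            "patient_id": [107411, 107412, 107413, 107415],
            "drug_name": ["statin", "aspirin", "statin", "statin"],
            "start_date": [d("2008-05-11"), d("2006-03-03"), d("2010-07-16"), d("2012-04-12")],
        }
    )
    surgery = pd.DataFrame(
        {
            "patient_id": [107411],
            "procedure_name": ["diagnostic ultrasound"],
            "date": [d("2008-05-09")],
        }
    )
    visit = pd.DataFrame(
        {
            "patient_id": [107411, 107411, 107412, 107413, 107414, 107415],
            "visit_date": [d("2008-05-10"), d("2010-06-20"), d("2006-03-02"), d("2010-07-15"), d("2005-01-20"), d("2012-04-11")],
            "encounter_type": ["inpatient", "outpatient", "inpatient", "emergency", "inpatient", "inpatient"],
            "age_at_visit": [65.2, 67.3, 55.8, 47.8, 57.0, 56.4],
        }
    )
    smoke = pd.DataFrame(
        {
            "patient_id": [107411, 107412, 107413, 107414, 107415],
            "smoking_level": [1, 0, 2, 0, 3],
        }
    )
    # 107411 suffers a composite event on 2010-06-20, aged 67, within 5 years
    events = pd.DataFrame(
        {
            "patient_id": [107411, 107413],
            "event_type": ["MI", "heart_failure"],
            "event_date": [d("2010-06-20"), d("2016-09-01")],
        }
    )
    tables = EmrTables(
        person=person,
        diagnosis=diagnosis,
        laboratory=laboratory,
        echocardiography=echocardiography,
        physical=physical,
        medication=medication,
        surgery=surgery,
        visit=visit,
        smoke=smoke,
        events=events,
    )
    tables.validate()
    return tables
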