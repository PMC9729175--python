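"""Synthetic EMR table generator.

Real cardiology EMR extracts of the kind this package targets are gated
behind institutional review, so the package ships a generator that emulates
their statistical and structural shape: an angina (ICD-10 I20) admission
cohort with inpatient / emergency-room index encounters inside a 2000-2016
window, eight auxiliary record tables per patient, and a binary five-year
composite event outcome (death, myocardial infarction, stroke, heart
failure) with roughly one positive per eleven negatives whose risk rises
with age.

The outcome mechanism is logistic in age and a handful of latent clinical
measurements (systolic blood pressure, a blood laboratory value, glucose,
ejection fraction, smoking level).  The intercept is calibrated numerically
so that, *among patients that survive the downstream cohort filters*, the
expected event prevalence equals ``event_prevalence``.  Patients destined to
be removed by the filters (outpatient-only encounters, prior exclusion
events) are generated too, so that cohort selection has real work to do.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ConfigError, ConsistencyError

#: canonical column sets, also used for empty tables and CSV round-trips
TABLE_COLUMNS: dict[str, list[str]] = {
    "person": ["patient_id", "sex", "birth_date"],
    "diagnosis": [
        "patient_id",
        "icd10_code",
        "diagnosis_name",
        "diagnosis_date",
        "encounter_type",
    ],
    "laboratory": ["patient_id", "test_name", "value", "date"],
    "echocardiography": ["patient_id", "measure_name", "value", "date"],
    "physical": ["patient_id", "measure_name", "value", "date"],
    "medication": ["patient_id", "drug_name", "start_date"],
    "surgery": ["patient_id", "procedure_name", "date"],
    "visit": ["patient_id", "visit_date", "encounter_type", "age_at_visit"],
    "smoke": ["patient_id", "smoking_level"],
    "events": ["patient_id", "event_type", "event_date"],
}

AUX_TABLES = [
    "diagnosis",
    "laboratory",
    "echocardiography",
    "physical",
    "medication",
    "surgery",
    "visit",
    "smoke",
    "events",
]

EVENT_TYPES = ["death", "MI", "stroke", "heart_failure"]
EXCLUSION_EVENT_TYPES = ["MI", "stroke", "heart_failure"]
ENCOUNTER_TYPES = ["inpatient", "emergency", "outpatient"]

# (mean, sd) of each continuous measurement panel
LAB_TESTS = {"blood": (90.0, 15.0), "glucose": (105.0, 25.0), "creatinine": (1.0, 0.25), "ldl": (120.0, 30.0)}
ECHO_MEASURES = {"ef": (58.0, 8.0), "gls": (-18.0, 3.0), "lvedd": (50.0, 6.0)}
PHYSICAL_MEASURES = {"weight": (68.0, 12.0), "height": (165.0, 9.0), "sbp": (128.0, 17.0), "dbp": (78.0, 11.0)}

MEDICATIONS = {
    "statin": 0.55,
    "aspirin": 0.50,
    "beta_blocker": 0.35,
    "ace_inhibitor": 0.30,
    "nitrate": 0.25,
    "clopidogrel": 0.20,
}
SURGERIES = ["diagnostic ultrasound", "pci", "cabg", "valve repair"]

DIAGNOSIS_NAMES = {
    "I20": "angina",
    "I10": "hypertension",
    "E11": "type 2 diabetes",
    "I25": "chronic ischaemic heart disease",
    "E78": "dyslipidaemia",
    "I48": "atrial fibrillation",
    "N18": "chronic kidney disease",
    "J45": "asthma",
    "I65": "carotid stenosis",
    "K21": "reflux disease",
}


def _diagnosis_code_pool() -> tuple[list[str], np.ndarray]:
    """A fixed pool of ~190 three-character ICD-10 codes with Zipf weights.

    The named comorbidities above get the largest weights; the long tail is
    filled with synthetic letter+digit codes so that the downstream
    "top-146 + other" diagnosis feature bucketing is exercised.
    """
    codes = list(DIAGNOSIS_NAMES)
    codes.remove("I20")  # index diagnosis handled separately
    for letter in "ABCDEFGHIJKLMN":
        for num in range(10, 23):
            code = f"{letter}{num}"
            if code not in DIAGNOSIS_NAMES:
                codes.append(code)
    codes = codes[:190]
    weights = 1.0 / np.arange(1, len(codes) + 1) ** 1.1
    return codes, weights / weights.sum()


@dataclass(frozen=True)
class RiskParams:
    """Parameters of the logistic event-risk model.

    ``intercept + age_effect * (age - age_center) + coefs . covariates`` is
    the linear predictor; the event probability is its logistic transform.
    """

    intercept: float = 0.0
    age_effect: float = 0.08
    age_center: float = 62.0
    coefs: tuple[float, ...] = ()


def risk_score(age, covariates, params: RiskParams):
    """Event probability for a patient of ``age`` with standardized covariates.

    Strictly increasing in ``age`` whenever ``params.age_effect > 0``.
    Accepts scalars or aligned arrays.
    """
    age = np.asarray(age, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    coefs = np.asarray(params.coefs, dtype=float)
    if coefs.size == 0:
        contrib = 0.0
    else:
        contrib = cov @ coefs
    lp = params.intercept + params.age_effect * (age - params.age_center) + contrib
    return expit(lp)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic EMR generator.

    Defaults encode the study conditions the generator emulates: a 2000-2016
    admission window, composite-event prevalence of 1/12 among patients that
    pass the cohort filters (so negatives outnumber positives more than
    tenfold), and a positive age effect so that event-positive patients are
    older on average.
    """

    n_patients: int = 1000
    seed: int = 0
    window_start: date = date(2000, 1, 1)
    window_end: date = date(2016, 12, 31)
    event_prevalence: float = 1.0 / 12.0
    age_effect: float = 0.08  # log-odds per year of age
    signal_scale: float = 1.0  # multiplies the covariate effects (not age)
    fraction_outpatient_only: float = 0.15
    fraction_prior_event: float = 0.10
    mean_extra_diagnoses: float = 3.0
    mean_extra_visits: float = 2.0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if not 0.0 < self.event_prevalence < 1.0:
            raise ConfigError("event_prevalence must lie in (0, 1)")
        if self.window_start >= self.window_end:
            raise ConfigError("admission window start must precede its end")
        if not 0.0 <= self.fraction_outpatient_only < 1.0:
            raise ConfigError("fraction_outpatient_only must lie in [0, 1)")
        if not 0.0 <= self.fraction_prior_event < 1.0:
            raise ConfigError("fraction_prior_event must lie in [0, 1)")
        if self.fraction_outpatient_only + self.fraction_prior_event >= 1.0:
            raise ConfigError("filter fractions must leave room for an eligible cohort")


@dataclass
class EmrTables:
    """Bundle of the ten EMR-style record tables.

    ``person`` is the universe of patients; every other table references it
    through ``patient_id``.  Dates are pandas datetimes in memory and
    ISO-8601 strings on disk.
    """

    person: pd.DataFrame
    diagnosis: pd.DataFrame
    laboratory: pd.DataFrame
    echocardiography: pd.DataFrame
    physical: pd.DataFrame
    medication: pd.DataFrame
    surgery: pd.DataFrame
    visit: pd.DataFrame
    smoke: pd.DataFrame
    events: pd.DataFrame

    @classmethod
    def empty(cls) -> "EmrTables":
        return cls(**{name: pd.DataFrame(columns=cols) for name, cols in TABLE_COLUMNS.items()})

    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    def validate(self) -> None:
        """Check column sets and referential integrity of patient IDs."""
        known = set(self.person["patient_id"])
        for name, frame in self.tables().items():
            missing_cols = set(TABLE_COLUMNS[name]) - set(frame.columns)
            if missing_cols:
                raise ConsistencyError(f"table {name!r} lacks columns {sorted(missing_cols)}")
            if name == "person":
                if frame["patient_id"].duplicated().any():
                    raise ConsistencyError("duplicate patient_id in person table")
                continue
            orphans = set(frame["patient_id"]) - known
            if orphans:
                raise ConsistencyError(
                    f"table {name!r} references unknown patients, e.g. {sorted(orphans)[:3]}"
                )

    def restrict(self, patient_ids) -> "EmrTables":
        """Sub-tables containing only the given patients."""
        keep = set(patient_ids)
        return EmrTables(
            **{
                name: frame[frame["patient_id"].isin(keep)].reset_index(drop=True)
                for name, frame in self.tables().items()
            }
        )

    def to_csv_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, frame in self.tables().items():
            out = frame.copy()
            for col in out.columns:
                if pd.api.types.is_datetime64_any_dtype(out[col]):
                    out[col] = out[col].dt.strftime("%Y-%m-%d")
            out.to_csv(outdir / f"{name}.csv", index=False)

    @classmethod
    def from_csv_dir(cls, indir) -> "EmrTables":
        indir = Path(indir)
        frames = {}
        date_cols = {
            "person": ["birth_date"],
            "diagnosis": ["diagnosis_date"],
            "laboratory": ["date"],
            "echocardiography": ["date"],
            "physical": ["date"],
            "medication": ["start_date"],
            "surgery": ["date"],
            "visit": ["visit_date"],
            "smoke": [],
            "events": ["event_date"],
        }
        for name, cols in TABLE_COLUMNS.items():
            frame = pd.read_csv(indir / f"{name}.csv")
            if frame.empty:
                frame = pd.DataFrame(columns=cols)
            for col in date_cols[name]:
                if col in frame.columns:
                    frame[col] = pd.to_datetime(frame[col])
            frames[name] = frame
        return cls(**frames)


def _dates_from_offsets(base: np.ndarray, offset_days: np.ndarray) -> pd.Series:
    return pd.Series(base + offset_days.astype("timedelta64[D]"))


def generate_emr(config: GeneratorConfig) -> EmrTables:
    """Generate the full table bundle for ``config.n_patients`` patients.

    Deterministic given ``config.seed``.  Every patient has at least one
    visit; an ``1 - fraction_outpatient_only - fraction_prior_event``
    fraction carries an I20 inpatient/ER admission inside the window and a
    clean prior history, and only those patients enter the prevalence
    calibration of the outcome model.
    """
    n = config.n_patients
    if n == 0:
        return EmrTables.empty()

    rng = np.random.default_rng(config.seed)
    pid = np.arange(100000, 100000 + n, dtype=np.int64)

    # ---- patient-level latents -------------------------------------------
    group = rng.choice(
        3,
        size=n,
        p=[
            config.fraction_outpatient_only,
            config.fraction_prior_event,
            1.0 - config.fraction_outpatient_only - config.fraction_prior_event,
        ],
    )  # 0 = outpatient-only, 1 = prior exclusion event, 2 = eligible
    eligible = group == 2

    window_start = np.datetime64(config.window_start, "D")
    window_days = int(
        (np.datetime64(config.window_end, "D") - window_start) / np.timedelta64(1, "D")
    )
    index_offset = rng.integers(0, window_days + 1, size=n)
    index_date = window_start + index_offset.astype("timedelta64[D]")

    age = np.clip(rng.normal(62.0, 11.0, size=n), 30.0, 90.0)
    birth_date = index_date - np.round(age * 365.25).astype("timedelta64[D]")
    sex = np.where(rng.random(n) < 0.45, "F", "M")

    # latent clinical measurements (emitted below, some rows masked missing)
    lab_vals = {t: rng.normal(m, s, size=n) for t, (m, s) in LAB_TESTS.items()}
    echo_vals = {t: rng.normal(m, s, size=n) for t, (m, s) in ECHO_MEASURES.items()}
    phys_vals = {t: rng.normal(m, s, size=n) for t, (m, s) in PHYSICAL_MEASURES.items()}
    smoke_level = rng.choice(4, size=n, p=[0.5, 0.2, 0.2, 0.1])

    # ---- outcome model ----------------------------------------------------
    s = config.signal_scale

    def z(vals, key, table):
        mean, sd = table[key]
        return (vals[key] - mean) / sd

    lp = (
        config.age_effect * (age - 62.0)
        + s * 0.35 * z(phys_vals, "sbp", PHYSICAL_MEASURES)
        + s * 0.30 * z(lab_vals, "blood", LAB_TESTS)
        + s * 0.25 * z(lab_vals, "glucose", LAB_TESTS)
        - s * 0.35 * z(echo_vals, "ef", ECHO_MEASURES)
        + s * 0.25 * smoke_level
    )
    lp_eligible = lp[eligible] if eligible.any() else lp

    def prevalence_gap(intercept: float) -> float:
        return float(expit(intercept + lp_eligible).mean() - config.event_prevalence)

    intercept = brentq(prevalence_gap, -30.0, 30.0)
    p_event = expit(intercept + lp)
    outcome = rng.random(n) < p_event

    # ---- person ----------------------------------------------------------
    person = pd.DataFrame(
        {"patient_id": pid, "sex": sex, "birth_date": pd.Series(birth_date)}
    )

    # ---- diagnosis -------------------------------------------------------
    index_encounter = np.where(group == 0, "outpatient", np.where(rng.random(n) < 0.5, "inpatient", "emergency"))
    code_pool, code_weights = _diagnosis_code_pool()
    n_extra = rng.poisson(config.mean_extra_diagnoses, size=n)
    owner = np.repeat(np.arange(n), n_extra)
    extra_codes = rng.choice(len(code_pool), size=owner.size, p=code_weights)
    extra_offsets = rng.integers(-730, 1, size=owner.size)
    diagnosis = pd.DataFrame(
        {
            "patient_id": np.concatenate([pid, pid[owner]]),
            "icd10_code": np.concatenate(
                [np.full(n, "I20"), np.asarray(code_pool, dtype=object)[extra_codes]]
            ),
            "diagnosis_date": pd.Series(
                np.concatenate([index_date, index_date[owner] + extra_offsets.astype("timedelta64[D]")])
            ),
            "encounter_type": np.concatenate(
                [
                    index_encounter,
                    np.asarray(ENCOUNTER_TYPES, dtype=object)[rng.choice(3, size=owner.size)],
                ]
            ),
        }
    )
    diagnosis["diagnosis_name"] = (
        diagnosis["icd10_code"].map(DIAGNOSIS_NAMES).fillna("unspecified condition")
    )
    diagnosis = diagnosis[TABLE_COLUMNS["diagnosis"]]

    # ---- measurement panels ---------------------------------------------
    def panel_frame(values: dict[str, np.ndarray], name_col: str, presence: float) -> pd.DataFrame:
        parts = []
        for test, vals in values.items():
            present = rng.random(n) < presence
            offs = rng.integers(0, 366, size=int(present.sum()))
            parts.append(
                pd.DataFrame(
                    {
                        "patient_id": pid[present],
                        name_col: test,
                        "value": np.round(vals[present], 2),
                        "date": _dates_from_offsets(index_date[present], -offs),
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)

    laboratory = panel_frame(lab_vals, "test_name", 0.92)
    echocardiography = panel_frame(echo_vals, "measure_name", 0.85)
    physical = panel_frame(phys_vals, "measure_name", 0.95)

    # ---- medication ------------------------------------------------------
    med_parts = []
    for drug, prob in MEDICATIONS.items():
        on_drug = rng.random(n) < prob
        offs = rng.integers(0, 731, size=int(on_drug.sum()))
        med_parts.append(
            pd.DataFrame(
                {
                    "patient_id": pid[on_drug],
                    "drug_name": drug,
                    "start_date": _dates_from_offsets(index_date[on_drug], -offs),
                }
            )
        )
    medication = pd.concat(med_parts, ignore_index=True)

    # ---- surgery ---------------------------------------------------------
    had_surgery = rng.random(n) < 0.30
    n_surg = int(had_surgery.sum())
    surgery = pd.DataFrame(
        {
            "patient_id": pid[had_surgery],
            "procedure_name": np.asarray(SURGERIES, dtype=object)[
                rng.choice(len(SURGERIES), size=n_surg, p=[0.5, 0.25, 0.15, 0.1])
            ],
            "date": _dates_from_offsets(index_date[had_surgery], -rng.integers(0, 181, size=n_surg)),
        }
    )

    # ---- visit -----------------------------------------------------------
    n_extra_visits = rng.poisson(config.mean_extra_visits, size=n)
    vowner = np.repeat(np.arange(n), n_extra_visits)
    voffs = rng.integers(-365, 366, size=vowner.size)
    visit_dates = np.concatenate([index_date, index_date[vowner] + voffs.astype("timedelta64[D]")])
    visit_owner = np.concatenate([np.arange(n), vowner])
    visit = pd.DataFrame(
        {
            "patient_id": pid[visit_owner],
            "visit_date": pd.Series(visit_dates),
            "encounter_type": np.concatenate(
                [
                    index_encounter,
                    np.asarray(ENCOUNTER_TYPES, dtype=object)[rng.choice(3, size=vowner.size)],
                ]
            ),
            "age_at_visit": np.round(
                age[visit_owner]
                + (visit_dates - index_date[visit_owner]) / np.timedelta64(365, "D"),
                1,
            ),
        }
    )

    smoke = pd.DataFrame({"patient_id": pid, "smoking_level": smoke_level})

    # ---- events ----------------------------------------------------------
    event_parts = []
    prior = group == 1
    n_prior = int(prior.sum())
    if n_prior:
        event_parts.append(
            pd.DataFrame(
                {
                    "patient_id": pid[prior],
                    "event_type": np.asarray(EXCLUSION_EVENT_TYPES, dtype=object)[
                        rng.choice(3, size=n_prior)
                    ],
                    "event_date": _dates_from_offsets(
                        index_date[prior], -rng.integers(30, 3651, size=n_prior)
                    ),
                }
            )
        )
    # follow-up events: positives inside the 5-year horizon, a fraction of
    # negatives beyond it (so late events beyond the horizon exist)
    pos = outcome
    n_pos = int(pos.sum())
    if n_pos:
        event_parts.append(
            pd.DataFrame(
                {
                    "patient_id": pid[pos],
                    "event_type": np.asarray(EVENT_TYPES, dtype=object)[rng.choice(4, size=n_pos)],
                    "event_date": _dates_from_offsets(
                        index_date[pos], rng.integers(1, 1827, size=n_pos)
                    ),
                }
            )
        )
    late = (~outcome) & (rng.random(n) < 0.20)
    n_late = int(late.sum())
    if n_late:
        event_parts.append(
            pd.DataFrame(
                {
                    "patient_id": pid[late],
                    "event_type": np.asarray(EVENT_TYPES, dtype=object)[rng.choice(4, size=n_late)],
                    "event_date": _dates_from_offsets(
                        index_date[late], rng.integers(1827, 2923, size=n_late)
                    ),
                }
            )
        )
    events = (
        pd.concat(event_parts, ignore_index=True)
        if event_parts
        else pd.DataFrame(columns=TABLE_COLUMNS["events"])
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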