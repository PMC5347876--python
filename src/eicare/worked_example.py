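"""A fully worked individual case, embedded for demos and self-checks.

The patient is diagnosed with a CD4 count of 420 cells/uL and a viral load
of 4.0 log10 copies/mL, re-attends 4 months later with CD4 fallen to 370,
re-attends after a further 5 months and starts ART, is seen again 3 months
later, and once more after 1 month, by which time her CD4 is back to 420
and her viral load undetectable.  Over an 18-month horizon the algorithm
labels months 3, 4, 9 and 12 out of care: EIC = 14/18 = 77.8%.
"""

from __future__ import annotations

from datetime import date as Date, timedelta
from pathlib import Path

from .classifier import RuleConfig, classify_months, patient_eic
from .cohort import (
    LabMeasurement,
    MonthClassification,
    PatientRecord,
    TherapyEvent,
    VisitEvent,
)
from .episodes import build_episodes, month_start_day

ENTRY = Date(2004, 1, 15)
FOLLOW_UP_MONTHS = 18


def _day(m: int) -> Date:
    """Date of the first day of algorithm month ``m`` after entry."""
    return ENTRY + timedelta(days=month_start_day(m))


def worked_example_patient() -> PatientRecord:
    """Construct the embedded case as a :class:`PatientRecord` with care
    episodes at months 0, 4, 9, 12 and 13."""
    rec = PatientRecord(
        patient_id="example-001",
        gender="female",
        birth_date=Date(1974, 6, 15),
        ethnicity="black_african",
        acquisition="heterosexual",
        clinic_id="clinic-A",
        hiv_diagnosis_date=ENTRY,
        admin_end_date=_day(FOLLOW_UP_MONTHS),
    )
    rec.labs = [
        LabMeasurement(_day(0), "cd4", 420.0),
        LabMeasurement(_day(0), "viral_load", 10_000.0),  # 4.0 log10 copies/mL
        LabMeasurement(_day(4), "cd4", 370.0),
        LabMeasurement(_day(12), "haemoglobin", 13.2),
        LabMeasurement(_day(13), "cd4", 420.0),
        LabMeasurement(_day(13), "viral_load", 50.0, below_detection=True),
    ]
    rec.therapy = [TherapyEvent(_day(9), "start")]
    rec.visits = [
        VisitEvent(m.date, {"cd4": "cd4", "viral_load": "viral_load", "haemoglobin": "haemoglobin"}[m.kind])
        for m in rec.labs
    ] + [VisitEvent(_day(9), "art_start")]
    rec.sort_events()
    return rec


def run_worked_example(config: RuleConfig | None = None) -> tuple[list[MonthClassification], float]:
    """Classify the embedded case over its 18-month horizon."""
    patient = worked_example_patient()
    episodes = build_episodes(patient)
    cls = classify_months(
        episodes, FOLLOW_UP_MONTHS, config, patient_id=patient.patient_id
    )
    return cls, patient_eic(cls)


def write_worked_example_csvs(out_dir: str | Path) -> dict[str, Path]:
    """Write the embedded case as the four cohort CSVs (a one-patient
    cohort fixture)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = worked_example_patient()
    paths = {
        "visits": out / "visits.csv",
        "labs": out / "labs.csv",
        "therapy": out / "therapy.csv",
        "demographics": out / "demographics.csv",
    }
    with open(paths["visits"], "w") as fh:
        fh.write("patient_id,date,source\n")
        # lab/therapy rows imply attendance on load; only non-lab markers here
    with open(paths["labs"], "w") as fh:
        fh.write("patient_id,date,kind,value,below_detection\n")
        for m in rec.labs:
            fh.write(
                f"{rec.patient_id},{m.date.isoformat()},{m.kind},"
                f"{m.value:g},{int(m.below_detection)}\n"
            )
    with open(paths["therapy"], "w") as fh:
        fh.write("patient_id,date,kind\n")
        for t in rec.therapy:
            fh.write(f"{rec.patient_id},{t.date.isoformat()},{t.kind}\n")
    with open(paths["demographics"], "w") as fh:
        fh.write(
            "patient_id,gender,birth_date,ethnicity,acquisition,clinic_id,"
            "hiv_diagnosis_date,aids_diagnosis_date,admin_end_date\n"
        )
        fh.write(
            f"{rec.patient_id},{rec.gender},{rec.birth_date.isoformat()},"
            f"{rec.ethnicity},{rec.acquisition},{rec.clinic_id},"
            f"{rec.hiv_diagnosis_date.isoformat()},,"
            f"{rec.admin_end_date.isoformat()}\n"
        )
    return paths
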