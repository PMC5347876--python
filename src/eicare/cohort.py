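"""Domain types and delimited-text I/O for longitudinal HIV cohort data.

The data model mirrors what routine clinical HIV cohorts collect: dated
laboratory measurements (CD4 count, viral load, haemoglobin), antiretroviral
therapy (ART) start and regimen-switch dates, clinic visits and per-patient
demographics.  Where explicit appointment data are unavailable, laboratory
and therapy dates double as surrogate markers of clinic attendance, so every
lab/therapy row also contributes an attendance event.

Input files are plain CSV:

* ``visits.csv``        -- ``patient_id,date,source``
* ``labs.csv``          -- ``patient_id,date,kind,value,below_detection``
* ``therapy.csv``       -- ``patient_id,date,kind``
* ``demographics.csv``  -- ``patient_id,gender,birth_date,ethnicity,
  acquisition,clinic_id,hiv_diagnosis_date,aids_diagnosis_date,admin_end_date``

Dates are ISO 8601 (``YYYY-MM-DD``).  Viral loads reported below the
detection limit ("<50") are stored as the bound with ``below_detection=1``;
threshold rules then compare the stored value, so "<50" satisfies
"<= 50 copies/mL" and the strict "< 50" test used in blip detection.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path

import pandas as pd

GENDERS = ("male", "female", "other_unknown")
ETHNICITIES = ("white", "black_african", "other", "unknown")
ACQUISITIONS = ("msm", "heterosexual", "idu", "other_unknown")
LAB_KINDS = ("cd4", "viral_load", "haemoglobin")
THERAPY_KINDS = ("start", "switch")
VISIT_SOURCES = (
    "clinic_visit",
    "cd4",
    "viral_load",
    "haemoglobin",
    "art_start",
    "art_switch",
)

_LAB_TO_SOURCE = {"cd4": "cd4", "viral_load": "viral_load", "haemoglobin": "haemoglobin"}
_THERAPY_TO_SOURCE = {"start": "art_start", "switch": "art_switch"}


@dataclass(frozen=True)
class VisitEvent:
    """One attendance marker: a dated event whose ``source`` names which
    record type implied the attendance."""

    date: Date
    source: str


@dataclass(frozen=True)
class LabMeasurement:
    date: Date
    kind: str
    value: float
    below_detection: bool = False


@dataclass(frozen=True)
class TherapyEvent:
    date: Date
    kind: str  # "start" or "switch"


@dataclass
class PatientRecord:
    """One patient's demographics plus dated clinical event streams.

    Event lists are kept sorted ascending by (date, source/kind) so that
    downstream grouping is deterministic.
    """

    patient_id: str
    gender: str
    birth_date: Date
    ethnicity: str
    acquisition: str
    clinic_id: str
    hiv_diagnosis_date: Date
    aids_diagnosis_date: Date | None = None
    admin_end_date: Date | None = None
    visits: list[VisitEvent] = field(default_factory=list)
    labs: list[LabMeasurement] = field(default_factory=list)
    therapy: list[TherapyEvent] = field(default_factory=list)

    def sort_events(self) -> None:
        self.visits.sort(key=lambda v: (v.date, v.source))
        self.labs.sort(key=lambda m: (m.date, m.kind, m.value))
        self.therapy.sort(key=lambda t: (t.date, t.kind))

    @property
    def attendance_dates(self) -> list[Date]:
        """Sorted distinct dates on which any attendance marker occurred."""
        return sorted({v.date for v in self.visits})

    @property
    def entry_date(self) -> Date:
        """Study entry: the first attendance marker date."""
        dates = self.attendance_dates
        if not dates:
            raise ValueError(f"patient {self.patient_id} has no attendance markers")
        return dates[0]

    def art_start_date(self) -> Date | None:
        for ev in self.therapy:
            if ev.kind == "start":
                return ev.date
        return None


@dataclass(frozen=True)
class MonthClassification:
    """Label for one follow-up month.

    ``anchor_episode_month`` is the month index of the care episode whose
    expectation window covers (or fails to cover) this month.
    """

    patient_id: str
    month_index: int
    label: str  # "in_care" | "out_of_care"
    anchor_episode_month: int


@dataclass(frozen=True)
class RowError:
    """One rejected or suspect input row; ``line`` is the 1-based file line
    number (header = line 1)."""

    file: str
    line: int
    message: str


@dataclass
class LoadResult:
    patients: list[PatientRecord]
    n_excluded_single_attendance: int
    errors: list[RowError] = field(default_factory=list)


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _parse_date(raw: str) -> Date:
    return Date.fromisoformat(raw.strip())


def _parse_opt_date(raw: str) -> Date | None:
    raw = raw.strip()
    return None if raw == "" else Date.fromisoformat(raw)


def load_cohort(
    visits_path: str | Path,
    labs_path: str | Path,
    therapy_path: str | Path,
    demographics_path: str | Path,
) -> LoadResult:
    """Load and merge the four cohort files into :class:`PatientRecord` s.

    One record per ``patient_id`` in the demographics file.  Lab and therapy
    rows also contribute attendance events.  Patients with fewer than two
    distinct attendance dates are excluded (the measure needs at least one
    inter-episode gap) and counted in the result.  Malformed rows are
    reported with file line numbers and skipped; suspect-but-usable rows
    (e.g. a lab dated before HIV diagnosis) are flagged and kept.
    """
    errors: list[RowError] = []

    demo = _read_csv(demographics_path)
    _require_columns(
        demo,
        (
            "patient_id",
            "gender",
            "birth_date",
            "ethnicity",
            "acquisition",
            "clinic_id",
            "hiv_diagnosis_date",
            "aids_diagnosis_date",
            "admin_end_date",
        ),
        str(demographics_path),
    )
    patients: dict[str, PatientRecord] = {}
    for idx, row in demo.iterrows():
        line = int(idx) + 2
        pid = row["patient_id"].strip()
        try:
            gender = row["gender"].strip()
            ethnicity = row["ethnicity"].strip()
            acquisition = row["acquisition"].strip()
            for value, domain, name in (
                (gender, GENDERS, "gender"),
                (ethnicity, ETHNICITIES, "ethnicity"),
                (acquisition, ACQUISITIONS, "acquisition"),
            ):
                if value not in domain:
                    raise ValueError(f"unknown {name} {value!r}")
            rec = PatientRecord(
                patient_id=pid,
                gender=gender,
                birth_date=_parse_birth_date(row["birth_date"]),
                ethnicity=ethnicity,
                acquisition=acquisition,
                clinic_id=row["clinic_id"].strip(),
                hiv_diagnosis_date=_parse_date(row["hiv_diagnosis_date"]),
                aids_diagnosis_date=_parse_opt_date(row["aids_diagnosis_date"]),
                admin_end_date=_parse_opt_date(row["admin_end_date"]),
            )
        except ValueError as exc:
            errors.append(RowError(str(demographics_path), line, str(exc)))
            continue
        if (
            rec.aids_diagnosis_date is not None
            and rec.aids_diagnosis_date < rec.hiv_diagnosis_date
        ):
            errors.append(
                RowError(
                    str(demographics_path),
                    line,
                    f"patient {pid}: AIDS diagnosis precedes HIV diagnosis",
                )
            )
        patients[pid] = rec

    def _patient(pid: str, path: str, line: int) -> PatientRecord | None:
        rec = patients.get(pid)
        if rec is None:
            errors.append(RowError(path, line, f"unknown patient_id {pid!r}"))
        return rec

    visits = _read_csv(visits_path)
    _require_columns(visits, ("patient_id", "date", "source"), str(visits_path))
    for idx, row in visits.iterrows():
        line = int(idx) + 2
        rec = _patient(row["patient_id"].strip(), str(visits_path), line)
        if rec is None:
            continue
        try:
            d = _parse_date(row["date"])
            source = row["source"].strip()
            if source not in VISIT_SOURCES:
                raise ValueError(f"unknown source {source!r}")
        except ValueError as exc:
            errors.append(RowError(str(visits_path), line, str(exc)))
            continue
        rec.visits.append(VisitEvent(d, source))

    labs = _read_csv(labs_path)
    _require_columns(
        labs, ("patient_id", "date", "kind", "value", "below_detection"), str(labs_path)
    )
    for idx, row in labs.iterrows():
        line = int(idx) + 2
        rec = _patient(row["patient_id"].strip(), str(labs_path), line)
        if rec is None:
            continue
        try:
            d = _parse_date(row["date"])
            kind = row["kind"].strip()
            if kind not in LAB_KINDS:
                raise ValueError(f"unknown lab kind {kind!r}")
            value = float(row["value"])
            if value < 0:
                raise ValueError(f"negative lab value {value}")
            below = row["below_detection"].strip() in ("1", "true", "True")
        except ValueError as exc:
            errors.append(RowError(str(labs_path), line, str(exc)))
            continue
        if d < rec.hiv_diagnosis_date:
            errors.append(
                RowError(
                    str(labs_path),
                    line,
                    f"patient {rec.patient_id}: lab dated before HIV diagnosis (kept)",
                )
            )
        rec.labs.append(LabMeasurement(d, kind, value, below))
        rec.visits.append(VisitEvent(d, _LAB_TO_SOURCE[kind]))

    therapy = _read_csv(therapy_path)
    _require_columns(therapy, ("patient_id", "date", "kind"), str(therapy_path))
    for idx, row in therapy.iterrows():
        line = int(idx) + 2
        rec = _patient(row["patient_id"].strip(), str(therapy_path), line)
        if rec is None:
            continue
        try:
            d = _parse_date(row["date"])
            kind = row["kind"].strip()
            if kind not in THERAPY_KINDS:
                raise ValueError(f"unknown therapy kind {kind!r}")
        except ValueError as exc:
            errors.append(RowError(str(therapy_path), line, str(exc)))
            continue
        if d < rec.hiv_diagnosis_date:
            errors.append(
                RowError(
                    str(therapy_path),
                    line,
                    f"patient {rec.patient_id}: therapy dated before HIV diagnosis (kept)",
                )
            )
        rec.therapy.append(TherapyEvent(d, kind))
        rec.visits.append(VisitEvent(d, _THERAPY_TO_SOURCE[kind]))

    kept: list[PatientRecord] = []
    n_excluded = 0
    for rec in patients.values():
        rec.sort_events()
        _validate_therapy(rec, errors)
        if len(rec.attendance_dates) < 2:
            n_excluded += 1
            continue
        kept.append(rec)
    kept.sort(key=lambda r: r.patient_id)
    return LoadResult(kept, n_excluded, errors)


def _parse_birth_date(raw: str) -> Date:
    """Accept YYYY-MM-DD or month-precision YYYY-MM (imputed to day 15)."""
    raw = raw.strip()
    if len(raw) == 7:  # YYYY-MM
        return Date.fromisoformat(raw + "-15")
    return Date.fromisoformat(raw)


def _validate_therapy(rec: PatientRecord, errors: list[RowError]) -> None:
    """Enforce: at most one ART start; switches after start; a switch on the
    start date is collapsed into the start."""
    starts = [t for t in rec.therapy if t.kind == "start"]
    if len(starts) > 1:
        errors.append(
            RowError(
                "<therapy>",
                0,
                f"patient {rec.patient_id}: multiple ART starts; keeping earliest",
            )
        )
        keep = starts[0]
        rec.therapy = [t for t in rec.therapy if t.kind != "start" or t is keep]
    start = rec.art_start_date()
    if start is not None:
        cleaned = []
        for t in rec.therapy:
            if t.kind == "switch" and t.date <= start:
                if t.date < start:
                    errors.append(
                        RowError(
                            "<therapy>",
                            0,
                            f"patient {rec.patient_id}: switch before ART start dropped",
                        )
                    )
                continue  # same-date switch folded into the start
            cleaned.append(t)
        rec.therapy = cleaned


# ---------------------------------------------------------------------------
# classification I/O

_CLASSIFICATION_COLUMNS = ["patient_id", "month_index", "label", "anchor_episode_month"]


def write_month_classifications(
    rows: "list[MonthClassification] | pd.DataFrame", path: str | Path
) -> None:
    """Write month classifications (or any person-month DataFrame) as CSV
    with a stable column order; round-trips losslessly through
    :func:`read_month_classifications`."""
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(
            [dataclasses.asdict(r) for r in rows], columns=_CLASSIFICATION_COLUMNS
        )
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write classifications to {path}: {exc}") from exc


def read_month_classifications(path: str | Path) -> list[MonthClassification]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, tuple(_CLASSIFICATION_COLUMNS), str(path))
    return [
        MonthClassification(
            patient_id=str(r.patient_id),
            month_index=int(r.month_index),
            label=str(r.label),
            anchor_episode_month=int(r.anchor_episode_month),
        )
        for r in df.itertuples()
    ]
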