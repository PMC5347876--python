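"""Seeded synthetic-cohort simulator with known ground-truth engagement.

Each simulated patient follows simple parametric clinical dynamics — linear
CD4 decline while untreated, linear recovery on ART, a log10 viral-load
set-point that decays to suppression after ART start, occasional blips once
suppressed — chosen to be just rich enough to drive every branch of the
scheduling rule table; realism beyond that is a non-goal.

Visits are scheduled *by the rule engine itself* applied to the true
clinical state: after each attended visit the next one is due within the
expected interval, and a stochastic delay process (probability ``p_delay``
of attending late, with a geometric or fixed number of extra months)
injects disengagement.  Because the schedule and the delays are known, the
true in/out-of-care label of every follow-up month is known by
construction, which makes the full classification pipeline testable end to
end: with every lab observed and no delays, the classifier must reproduce
the ground truth exactly.

Lab values recorded at attended visits are the values used for scheduling;
observation probabilities below 1 withhold values from the emitted files
only (for carry-forward ablation experiments).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from datetime import date as Date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifier import RuleConfig, classify_months, expected_interval
from .cohort import LabMeasurement, PatientRecord, TherapyEvent, VisitEvent
from .episodes import CareEpisode, build_episodes, month_start_day

_LOG10_DETECT = np.log10(50.0)


@dataclass
class SimulationParams:
    """Generator settings (cohort composition, clinical dynamics, attendance
    process).  Units: CD4 in cells/uL, viral load in log10 copies/mL where
    noted, rates per year, months are 30.4-day algorithm months."""

    n_patients: int = 200
    seed: int = 0
    entry_start: Date = Date(2000, 1, 1)
    entry_end: Date = Date(2009, 12, 31)
    horizon_months: int = 60          # administrative follow-up horizon

    baseline_cd4_mean: float = 520.0
    baseline_cd4_sd: float = 180.0
    cd4_decline_per_year: float = 60.0    # untreated decline, patient mean
    cd4_decline_sd: float = 25.0          # patient-level spread
    cd4_recovery_per_year: float = 100.0  # on-ART recovery
    cd4_ceiling: float = 900.0
    cd4_noise_sd: float = 40.0            # per-measurement noise

    vl_setpoint_log10_mean: float = 4.5
    vl_setpoint_log10_sd: float = 0.7
    vl_noise_log10_sd: float = 0.15
    suppress_months: float = 5.0          # time from ART start to suppression
    blip_prob: float = 0.08               # per suppressed visit, after >= 2

    art_cd4_threshold: float = 350.0      # eligible to start ART at/below
    art_start_prob: float = 0.7           # per eligible visit
    switch_prob: float = 0.05             # new combination per on-ART visit
    aids_prob: float = 0.3                # per visit with measured CD4 < 200

    p_delay: float = 0.25                 # probability a visit is late
    p_delay_untreated: float | None = None  # optional per-status overrides
    p_delay_treated: float | None = None
    delay_kind: str = "geometric"         # "geometric" | "fixed"
    delay_geom_p: float = 0.5             # extra months ~ Geometric(p), mean 1/p
    delay_fixed_months: int = 2

    cd4_obs_prob: float = 1.0             # emission (not scheduling) ablation
    vl_obs_prob: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p_delay", "blip_prob", "art_start_prob", "switch_prob",
                     "aids_prob", "cd4_obs_prob", "vl_obs_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.horizon_months < 2:
            raise ValueError("horizon_months must be >= 2 (shorter than any interval)")
        if self.delay_kind not in ("geometric", "fixed"):
            raise ValueError(f"delay_kind must be 'geometric' or 'fixed', got {self.delay_kind!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        for key in ("entry_start", "entry_end"):
            if key in data and isinstance(data[key], str):
                data[key] = Date.fromisoformat(data[key])
        return cls(**data)


@dataclass
class GroundTruth:
    """True attendance schedule and month labels, by construction.

    ``schedule`` has one row per attended visit: patient_id, episode_month,
    interval (expected months to next visit), scheduled_month and
    actual_month of the next visit (NA after the final visit).  ``labels``
    has one row per follow-up month up to each patient's last visit:
    patient_id, month_index, in_care (0/1).
    """

    schedule: pd.DataFrame
    labels: pd.DataFrame

    def labels_for(self, patient_id: str) -> dict[int, int]:
        sub = self.labels[self.labels["patient_id"] == patient_id]
        return dict(zip(sub["month_index"].astype(int), sub["in_care"].astype(int)))


@dataclass
class SimulatedCohort:
    patients: list[PatientRecord]
    ground_truth: GroundTruth
    params: SimulationParams

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit the four cohort CSVs plus ground_truth.csv and schedule.csv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {name: out / f"{name}.csv" for name in
                 ("visits", "labs", "therapy", "demographics", "ground_truth", "schedule")}
        with open(paths["visits"], "w") as fh:
            fh.write("patient_id,date,source\n")
        with open(paths["labs"], "w") as fh:
            fh.write("patient_id,date,kind,value,below_detection\n")
            for p in self.patients:
                for m in p.labs:
                    fh.write(f"{p.patient_id},{m.date.isoformat()},{m.kind},"
                             f"{m.value:g},{int(m.below_detection)}\n")
        with open(paths["therapy"], "w") as fh:
            fh.write("patient_id,date,kind\n")
            for p in self.patients:
                for t in p.therapy:
                    fh.write(f"{p.patient_id},{t.date.isoformat()},{t.kind}\n")
        with open(paths["demographics"], "w") as fh:
            fh.write("patient_id,gender,birth_date,ethnicity,acquisition,clinic_id,"
                     "hiv_diagnosis_date,aids_diagnosis_date,admin_end_date\n")
            for p in self.patients:
                aids = p.aids_diagnosis_date.isoformat() if p.aids_diagnosis_date else ""
                fh.write(f"{p.patient_id},{p.gender},{p.birth_date.isoformat()},"
                         f"{p.ethnicity},{p.acquisition},{p.clinic_id},"
                         f"{p.hiv_diagnosis_date.isoformat()},{aids},"
                         f"{p.admin_end_date.isoformat()}\n")
        self.ground_truth.labels.to_csv(paths["ground_truth"], index=False)
        self.ground_truth.schedule.to_csv(paths["schedule"], index=False)
        return paths


def _truth_labels(visit_months: list[int], intervals: list[int]) -> list[tuple[int, int]]:
    """Month labels implied by the schedule alone: after a visit at month m
    with expected interval N, months m+1..m+N are in care and any further
    months before the next visit are out of care.  Censored at last visit."""
    out: list[tuple[int, int]] = []
    for (m, n), nxt in zip(zip(visit_months, intervals), visit_months[1:]):
        for month in range(m + 1, nxt + 1):
            out.append((month, int(month <= m + n)))
    return out


def simulate_cohort(params: SimulationParams | None = None) -> SimulatedCohort:
    """Generate a cohort; deterministic given ``params.seed``."""
    p = params or SimulationParams()
    root = np.random.SeedSequence([p.seed & 0x7FFFFFFF, 0x51C0])
    demo_rng = np.random.default_rng(root.spawn(1)[0])
    patient_seeds = root.spawn(p.n_patients)

    entry_span = (p.entry_end - p.entry_start).days
    if entry_span < 0:
        raise ValueError("entry_end precedes entry_start")

    patients: list[PatientRecord] = []
    sched_rows: list[dict] = []
    label_rows: list[dict] = []
    cfg = RuleConfig()

    for i in range(p.n_patients):
        rng = np.random.default_rng(patient_seeds[i])
        pid = f"sim-{i:05d}"
        entry = p.entry_start + timedelta(days=int(demo_rng.integers(0, entry_span + 1)))
        rec = PatientRecord(
            patient_id=pid,
            gender=str(demo_rng.choice(["male", "female"], p=[0.72, 0.28])),
            birth_date=Date(int(demo_rng.integers(1950, 1986)),
                            int(demo_rng.integers(1, 13)), 15),
            ethnicity=str(demo_rng.choice(
                ["white", "black_african", "other", "unknown"],
                p=[0.53, 0.29, 0.09, 0.09])),
            acquisition=str(demo_rng.choice(
                ["msm", "heterosexual", "idu", "other_unknown"],
                p=[0.50, 0.39, 0.03, 0.08])),
            clinic_id=f"clinic-{int(demo_rng.integers(1, 6))}",
            hiv_diagnosis_date=entry,
            admin_end_date=entry + timedelta(days=month_start_day(p.horizon_months)),
        )

        baseline = max(80.0, rng.normal(p.baseline_cd4_mean, p.baseline_cd4_sd))
        decline = max(5.0, rng.normal(p.cd4_decline_per_year, p.cd4_decline_sd))
        setpoint = max(2.0, rng.normal(p.vl_setpoint_log10_mean, p.vl_setpoint_log10_sd))

        art_month: int | None = None
        cd4_at_art: float = baseline
        prev_cd4: float | None = None
        prev_vl: tuple[float, bool] | None = None  # (value, below_detection)
        n_suppressed = 0
        aids_month: int | None = None
        visit_months: list[int] = []
        intervals: list[int] = []

        m = 0
        while m <= p.horizon_months:
            years = m * 30.4 / 365.25
            if art_month is None:
                cd4_true = baseline - decline * years
            else:
                on_art_years = (m - art_month) * 30.4 / 365.25
                cd4_true = min(p.cd4_ceiling,
                               cd4_at_art + p.cd4_recovery_per_year * on_art_years)
            cd4 = float(max(10.0, round(cd4_true + rng.normal(0.0, p.cd4_noise_sd))))

            # ART start decision precedes this month's VL only in bookkeeping:
            # the virological effect begins after the start visit (t = 0).
            started_now = False
            if art_month is None and cd4 <= p.art_cd4_threshold and rng.random() < p.art_start_prob:
                art_month = m
                cd4_at_art = cd4_true
                started_now = True

            if art_month is None or m == art_month:
                vl_log = setpoint + rng.normal(0.0, p.vl_noise_log10_sd)
                vl, below = float(max(51.0, round(10 ** vl_log))), False
            else:
                t = m - art_month
                decayed = setpoint - (setpoint - 1.4) * min(1.0, t / p.suppress_months)
                decayed += rng.normal(0.0, p.vl_noise_log10_sd)
                if decayed < _LOG10_DETECT:
                    if n_suppressed >= 2 and rng.random() < p.blip_prob:
                        vl, below = float(rng.integers(51, 201)), False
                    else:
                        vl, below = 50.0, True
                        n_suppressed += 1
                else:
                    vl, below = float(round(10 ** decayed)), False

            switched_now = (art_month is not None and m > art_month
                            and rng.random() < p.switch_prob)
            if aids_month is None and cd4 < 200 and rng.random() < p.aids_prob:
                aids_month = m

            visit_date = entry + timedelta(days=month_start_day(m))
            blip = (50 < vl <= 200 and not below
                    and prev_vl is not None
                    and (prev_vl[0] < 50 or (prev_vl[1] and prev_vl[0] <= 50)))
            ep = CareEpisode(
                month_index=m,
                episode_date=visit_date,
                lowest_cd4=cd4,
                cd4_drop=(prev_cd4 - cd4) if prev_cd4 is not None else None,
                highest_vl=vl,
                vl_below_detection=below,
                vl_is_blip=blip,
                on_art=art_month is not None and art_month <= m,
                started_art_this_episode=started_now,
                started_new_combination_this_episode=switched_now,
                within_one_month_of_diagnosis=(visit_date - entry).days * 5 <= 152,
                aids_event_this_episode=aids_month == m,
            )
            interval = expected_interval(ep, cfg).months

            # record the visit
            rec.labs.append(LabMeasurement(visit_date, "haemoglobin",
                                           float(round(rng.normal(13.5, 1.2), 1))))
            rec.visits.append(VisitEvent(visit_date, "haemoglobin"))
            if rng.random() < p.cd4_obs_prob:
                rec.labs.append(LabMeasurement(visit_date, "cd4", cd4))
                rec.visits.append(VisitEvent(visit_date, "cd4"))
            if rng.random() < p.vl_obs_prob:
                rec.labs.append(LabMeasurement(visit_date, "viral_load", vl, below))
                rec.visits.append(VisitEvent(visit_date, "viral_load"))
            if started_now:
                rec.therapy.append(TherapyEvent(visit_date, "start"))
                rec.visits.append(VisitEvent(visit_date, "art_start"))
            if switched_now:
                rec.therapy.append(TherapyEvent(visit_date, "switch"))
                rec.visits.append(VisitEvent(visit_date, "art_switch"))
            if aids_month == m:
                rec.aids_diagnosis_date = visit_date

            prev_cd4, prev_vl = cd4, (vl, below)
            visit_months.append(m)
            intervals.append(interval)

            # schedule the next visit, possibly late
            scheduled = m + interval
            pd_eff = p.p_delay
            if ep.on_art and p.p_delay_treated is not None:
                pd_eff = p.p_delay_treated
            elif not ep.on_art and p.p_delay_untreated is not None:
                pd_eff = p.p_delay_untreated
            extra = 0
            if rng.random() < pd_eff:
                extra = (p.delay_fixed_months if p.delay_kind == "fixed"
                         else int(rng.geometric(p.delay_geom_p)))
            nxt = scheduled + extra
            sched_rows.append({
                "patient_id": pid, "episode_month": m, "interval": interval,
                "scheduled_month": scheduled,
                "actual_month": nxt if nxt <= p.horizon_months else pd.NA,
            })
            if nxt > p.horizon_months:
                break
            m = nxt

        rec.sort_events()
        patients.append(rec)
        for month, in_care in _truth_labels(visit_months, intervals):
            label_rows.append({"patient_id": pid, "month_index": month, "in_care": in_care})

    schedule = pd.DataFrame(
        sched_rows,
        columns=["patient_id", "episode_month", "interval", "scheduled_month", "actual_month"],
    )
    labels = pd.DataFrame(label_rows, columns=["patient_id", "month_index", "in_care"])
    return SimulatedCohort(patients, GroundTruth(schedule, labels), p)


@dataclass
class RecoveryReport:
    """Per-month agreement between classifier output and ground truth."""

    n_months: int
    n_agree: int
    disagreements: pd.DataFrame  # patient_id, month_index, truth, predicted, anchor

    @property
    def agreement(self) -> float:
        return self.n_agree / self.n_months if self.n_months else 1.0


def classification_recovery(
    patients: list[PatientRecord],
    ground_truth: GroundTruth,
    config: RuleConfig | None = None,
) -> RecoveryReport:
    """Re-derive labels from the emitted cohort and compare with truth.

    With every lab observed the pipeline (episode grouping + rule engine +
    month classifier) must reproduce the generator's schedule exactly; with
    labs withheld, disagreements trace to carry-forward state differences.
    """
    n_months = n_agree = 0
    rows = []
    for p in patients:
        truth = ground_truth.labels_for(p.patient_id)
        if len(p.attendance_dates) < 2:
            continue
        cls = classify_months(build_episodes(p), config=config, patient_id=p.patient_id)
        pred = {c.month_index: c for c in cls}
        for month in sorted(set(truth) | set(pred)):
            n_months += 1
            t = truth.get(month)
            c = pred.get(month)
            pl = None if c is None else int(c.label == "in_care")
            if t is not None and pl is not None and t == pl:
                n_agree += 1
            else:
                rows.append({
                    "patient_id": p.patient_id, "month_index": month,
                    "truth": t, "predicted": pl,
                    "anchor_episode_month": None if c is None else c.anchor_episode_month,
                })
    disagreements = pd.DataFrame(
        rows, columns=["patient_id", "month_index", "truth", "predicted",
                       "anchor_episode_month"])
    return RecoveryReport(n_months, n_agree, disagreements)


def simulate_correlated_binary(
    n_patients: int,
    n_months: int,
    baseline_p: float,
    odds_ratio: float,
    kappa: float,
    seed: int,
) -> pd.DataFrame:
    """Person-month outcomes with an exact marginal odds ratio for a binary
    patient-level covariate, and exchangeable within-patient correlation.

    Patient i in group x has monthly success probability drawn from a Beta
    distribution with mean p_x, where odds(p_1)/odds(p_0) = ``odds_ratio``;
    Beta mixing is mean-preserving, so the *marginal* month-level odds ratio
    equals ``odds_ratio`` exactly — the estimand of a population-averaged
    (GEE) logistic model.  Intraclass correlation is 1/(1 + kappa).
    """
    if not 0 < baseline_p < 1:
        raise ValueError("baseline_p must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xB1A5]))
    odds0 = baseline_p / (1 - baseline_p)
    p1 = odds0 * odds_ratio / (1 + odds0 * odds_ratio)
    rows = []
    for i in range(n_patients):
        x = i % 2
        p_x = p1 if x else baseline_p
        p_i = rng.beta(kappa * p_x, kappa * (1 - p_x))
        y = rng.random(n_months) < p_i
        for mth, yi in enumerate(y, start=1):
            rows.append({"patient_id": f"p{i:04d}", "month_index": mth,
                         "in_care": int(yi), "exposed": "yes" if x else "no"})
    return pd.DataFrame(rows)
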