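"""Person-month table, stratified summaries and the GEE association model."""

from datetime import date as Date, timedelta

import numpy as np
import pandas as pd
import pytest

from eicare.analytics import (
    FACTOR_LEVELS,
    fit_association_model,
    person_month_table,
    stratified_proportions,
)
from eicare.classifier import classify_months
from eicare.cohort import MonthClassification, PatientRecord, LabMeasurement, VisitEvent
from eicare.episodes import build_episodes, month_start_day
from eicare.simulate import (
    SimulationParams,
    simulate_cohort,
    simulate_correlated_binary,
)
from eicare.worked_example import worked_example_patient

ENTRY = Date(2004, 1, 15)


def _classified_worked_example():
    patient = worked_example_patient()
    cls = classify_months(build_episodes(patient), 18, patient_id=patient.patient_id)
    return [patient], cls


def test_worked_example_covariates_are_time_updated():
    patients, cls = _classified_worked_example()
    table = person_month_table(patients, cls)
    assert len(table) == 18
    by_month = table.set_index("month_index")
    # CD4 history 420 then 370: both fall in the >=350 group throughout
    assert by_month.loc[1, "nadir_cd4_group"] == ">=350"
    assert by_month.loc[5, "nadir_cd4_group"] == ">=350"
    assert by_month.loc[5, "current_cd4_group"] == ">=350"
    assert by_month.loc[14, "current_cd4_group"] == ">=350"  # 420 again at month 13
    assert by_month.loc[1, "calendar_period"] == "2004-2007"
    assert by_month.loc[1, "time_in_study_group"] == "<1y"
    assert by_month.loc[1, "on_art"] == "no"
    assert by_month.loc[10, "on_art"] == "yes"  # ART started at the month-9 episode


def test_age_group_crosses_boundary_mid_follow_up():
    patient = worked_example_patient()
    # age 44.95 at the month-1 midpoint -> crosses 45 during follow-up
    midpoint1 = ENTRY + timedelta(days=0.5 * 30.4)
    patient.birth_date = midpoint1 - timedelta(days=round(44.95 * 365.25))
    cls = classify_months(build_episodes(patient), 18, patient_id=patient.patient_id)
    table = person_month_table([patient], cls).set_index("month_index")
    assert table.loc[1, "age_group"] == "25-45"
    assert table.loc[12, "age_group"] == ">45"


def test_months_before_first_cd4_have_missing_cd4_groups():
    rec = PatientRecord(
        patient_id="p1", gender="male", birth_date=Date(1970, 1, 1),
        ethnicity="white", acquisition="msm", clinic_id="c1",
        hiv_diagnosis_date=ENTRY,
    )
    rec.labs = [LabMeasurement(ENTRY + timedelta(days=month_start_day(5)), "cd4", 300.0)]
    rec.visits = [VisitEvent(ENTRY, "clinic_visit"),
                  VisitEvent(rec.labs[0].date, "cd4")]
    rec.sort_events()
    cls = classify_months(build_episodes(rec), follow_up_end_month=8, patient_id="p1")
    table = person_month_table([rec], cls).set_index("month_index")
    assert pd.isna(table.loc[1, "nadir_cd4_group"])
    # the month-5 measurement falls after that month's midpoint, so it first
    # counts at month 6
    assert pd.isna(table.loc[5, "current_cd4_group"])
    assert table.loc[6, "current_cd4_group"] == "200-349"


def test_stratified_proportions_partition_person_months():
    cohort = simulate_cohort(SimulationParams(n_patients=40, seed=5, horizon_months=48))
    cls = []
    for p in cohort.patients:
        cls.extend(classify_months(build_episodes(p), patient_id=p.patient_id))
    table = person_month_table(cohort.patients, cls)
    for factor in ("gender", "age_group", "time_in_study_group", "clinic_id"):
        strat = stratified_proportions(table, factor)
        assert strat["person_months"].sum() == table[factor].notna().sum()
    # invariant to patient ordering
    reordered = table.sample(frac=1.0, random_state=0)
    a = stratified_proportions(table, "gender")
    b = stratified_proportions(reordered, "gender")
    pd.testing.assert_frame_equal(a, b)


def test_stratified_proportions_reports_empty_levels_and_rejects_unknown_factor():
    patients, cls = _classified_worked_example()
    table = person_month_table(patients, cls)
    strat = stratified_proportions(table, "gender").set_index("level")
    assert strat.loc["female", "person_months"] == 18
    assert strat.loc["female", "percent_in_care"] == pytest.approx(100 * 14 / 18, abs=0.05)
    assert strat.loc["male", "person_months"] == 0
    with pytest.raises(ValueError, match="age_group"):
        stratified_proportions(table, "shoe_size")


def test_delayed_untreated_patients_show_lower_on_art_engagement():
    params = SimulationParams(
        n_patients=120, seed=9, horizon_months=48,
        p_delay_treated=0.0, p_delay_untreated=0.8,
        delay_kind="fixed", delay_fixed_months=2,
    )
    cohort = simulate_cohort(params)
    cls = []
    for p in cohort.patients:
        cls.extend(classify_months(build_episodes(p), patient_id=p.patient_id))
    table = person_month_table(cohort.patients, cls)
    strat = stratified_proportions(table, "on_art").set_index("level")
    assert strat.loc["yes", "percent_in_care"] > strat.loc["no", "percent_in_care"]


def test_unadjusted_gee_matches_closed_form_two_by_two_odds_ratio():
    # equal cluster sizes, cluster-constant binary covariate: the GEE point
    # estimate must equal the crude odds ratio of the aggregated 2x2 table
    df = simulate_correlated_binary(
        n_patients=60, n_months=12, baseline_p=0.6, odds_ratio=2.0, kappa=8.0, seed=21
    )
    res = fit_association_model(df, ["exposed"])
    est = res.table.set_index("level").loc["yes", "or"]
    counts = df.groupby("exposed")["in_care"].agg(["sum", "size"])
    a, n1 = counts.loc["yes", "sum"], counts.loc["yes", "size"]
    b, n0 = counts.loc["no", "sum"], counts.loc["no", "size"]
    crude = (a / (n1 - a)) / (b / (n0 - b))
    assert est == pytest.approx(crude, rel=1e-4)


def test_reference_levels_carry_odds_ratio_exactly_one():
    df = simulate_correlated_binary(
        n_patients=40, n_months=10, baseline_p=0.6, odds_ratio=1.5, kappa=8.0, seed=3
    )
    res = fit_association_model(df, ["exposed"])
    ref = res.table[res.table["reference"]]
    assert list(ref["level"]) == ["no"]
    assert (ref["or"] == 1.0).all()
    nonref = res.table[~res.table["reference"]]
    assert ((nonref["ci_low"] <= nonref["or"]) & (nonref["or"] <= nonref["ci_high"])).all()


def test_model_validation_errors():
    df = simulate_correlated_binary(
        n_patients=10, n_months=6, baseline_p=0.6, odds_ratio=1.0, kappa=8.0, seed=4
    )
    with pytest.raises(ValueError, match="unknown covariate"):
        fit_association_model(df, ["haircut"])
    single = df[df["patient_id"] == "p0000"]
    with pytest.raises(ValueError, match="2 patients"):
        fit_association_model(single, ["exposed"])
    df_const = df.assign(exposed="no")
    with pytest.raises(ValueError, match="fewer than 2 observed levels"):
        fit_association_model(df_const, ["exposed"])


def test_adjusted_model_on_synthetic_cohort_produces_full_table():
    cohort = simulate_cohort(SimulationParams(n_patients=120, seed=13, horizon_months=60))
    cls = []
    for p in cohort.patients:
        cls.extend(classify_months(build_episodes(p), patient_id=p.patient_id))
    table = person_month_table(cohort.patients, cls)
    covs = ["gender", "on_art", "nadir_cd4_group", "time_in_study_group"]
    res = fit_association_model(table, covs, adjust=True)
    assert res.adjusted
    assert set(res.table["factor"]) >= set(covs)
    assert np.isfinite(res.table.loc[~res.table["reference"], "or"]).all()
    assert res.n_patients > 100


def test_null_covariate_confidence_interval_covers_one_at_nominal_rate():
    # type-I calibration at small scale: independent covariate, ~95% CIs
    hits = 0
    n_rep = 40
    for rep in range(n_rep):
        df = simulate_correlated_binary(
            n_patients=40, n_months=12, baseline_p=0.7, odds_ratio=1.0,
            kappa=8.0, seed=1000 + rep,
        )
        t = fit_association_model(df, ["exposed"]).table.set_index("level")
        hits += t.loc["yes", "ci_low"] <= 1.0 <= t.loc["yes", "ci_high"]
    assert hits >= int(0.85 * n_rep)
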