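"""Person-month analysis: time-updated covariates, stratified engagement
proportions and the month-level association model.

Each classified follow-up month becomes one analysis row carrying the
patient's covariates evaluated at that month's midpoint (entry date plus
(m - 0.5) x 30.4 days): age group, ART status, nadir and current CD4 group,
calendar period and time in study.  Stratified summaries report person-month
counts and percent in care per level.  Associations are estimated with
month-level logistic regression fitted by generalized estimating equations
(GEE) with an exchangeable working correlation and robust (sandwich)
standard errors, accounting for the repeated months within each patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import timedelta

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import MonthClassification, PatientRecord
from .episodes import MONTH_DAYS

log = logging.getLogger(__name__)

AGE_GROUPS = ("<25", "25-45", ">45")
CD4_GROUPS = ("<200", "200-349", ">=350")
CALENDAR_PERIODS = ("2000-2003", "2004-2007", "2008-2012")
TIME_IN_STUDY_GROUPS = ("<1y", "1-5y", "5-10y", ">10y")

#: Covariates available to summaries and models, with their level sets
#: (None = free-form, e.g. clinic) in display order.
FACTOR_LEVELS: dict[str, tuple[str, ...] | None] = {
    "gender": ("male", "female", "other_unknown"),
    "age_group": AGE_GROUPS,
    "ethnicity": ("white", "black_african", "other", "unknown"),
    "acquisition": ("msm", "heterosexual", "idu", "other_unknown"),
    "on_art": ("no", "yes"),
    "nadir_cd4_group": CD4_GROUPS,
    "current_cd4_group": CD4_GROUPS,
    "calendar_period": CALENDAR_PERIODS,
    "time_in_study_group": TIME_IN_STUDY_GROUPS,
    "clinic_id": None,
}

#: Reference level per covariate for the association model.
REFERENCE_LEVELS = {
    "gender": "female",
    "age_group": ">45",
    "ethnicity": "white",
    "acquisition": "msm",
    "on_art": "no",
    "nadir_cd4_group": ">=350",
    "current_cd4_group": ">=350",
    "calendar_period": "2004-2007",
    "time_in_study_group": ">10y",
}


def _age_group(years: float) -> str:
    if years < 25:
        return "<25"
    if years <= 45:
        return "25-45"
    return ">45"


def _cd4_group(value: float) -> str:
    if value < 200:
        return "<200"
    if value < 350:
        return "200-349"
    return ">=350"


def _calendar_period(year: int) -> str | None:
    if 2000 <= year <= 2003:
        return "2000-2003"
    if 2004 <= year <= 2007:
        return "2004-2007"
    if 2008 <= year <= 2012:
        return "2008-2012"
    return None


def _time_in_study_group(years: float) -> str:
    if years < 1:
        return "<1y"
    if years <= 5:
        return "1-5y"
    if years <= 10:
        return "5-10y"
    return ">10y"


def person_month_table(
    patients: list[PatientRecord],
    classifications: list[MonthClassification],
) -> pd.DataFrame:
    """Build the person-month analysis table.

    One row per classified month with time-updated covariates evaluated at
    the month midpoint; covariates that cannot be evaluated (no CD4 measured
    yet, midpoint outside the calendar windows) are missing (NA).
    """
    by_patient = {p.patient_id: p for p in patients}
    cls_by_patient: dict[str, list[MonthClassification]] = {}
    for c in classifications:
        cls_by_patient.setdefault(c.patient_id, []).append(c)

    rows = []
    for pid, cls in cls_by_patient.items():
        p = by_patient.get(pid)
        if p is None:
            raise ValueError(f"classifications refer to unknown patient {pid!r}")
        entry = p.entry_date
        art_start = p.art_start_date()
        cd4s = [(m.date, m.value) for m in p.labs if m.kind == "cd4"]
        for c in sorted(cls, key=lambda c: c.month_index):
            mid = entry + timedelta(days=(c.month_index - 0.5) * MONTH_DAYS)
            age = (mid - p.birth_date).days / 365.25
            seen = [v for d, v in cd4s if d <= mid]
            nadir = min(seen) if seen else None
            current = seen[-1] if seen else None
            rows.append(
                {
                    "patient_id": pid,
                    "month_index": c.month_index,
                    "in_care": int(c.label == "in_care"),
                    "gender": p.gender,
                    "age_group": _age_group(age),
                    "ethnicity": p.ethnicity,
                    "acquisition": p.acquisition,
                    "on_art": "yes" if art_start is not None and art_start <= mid else "no",
                    "nadir_cd4_group": _cd4_group(nadir) if nadir is not None else pd.NA,
                    "current_cd4_group": _cd4_group(current) if current is not None else pd.NA,
                    "calendar_period": _calendar_period(mid.year) or pd.NA,
                    "time_in_study_group": _time_in_study_group(
                        (c.month_index - 0.5) * MONTH_DAYS / 365.25
                    ),
                    "clinic_id": p.clinic_id,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "month_index",
            "in_care",
            "gender",
            "age_group",
            "ethnicity",
            "acquisition",
            "on_art",
            "nadir_cd4_group",
            "current_cd4_group",
            "calendar_period",
            "time_in_study_group",
            "clinic_id",
        ],
    )


def stratified_proportions(rows: pd.DataFrame, factor: str) -> pd.DataFrame:
    """Person-month counts and percent in care by level of ``factor``.

    Levels defined for the factor but unobserved are reported with count 0;
    months with a missing factor value are excluded from that factor's table.
    """
    if factor not in FACTOR_LEVELS:
        raise ValueError(
            f"unknown factor {factor!r}; valid factors: {sorted(FACTOR_LEVELS)}"
        )
    levels = FACTOR_LEVELS[factor]
    sub = rows.dropna(subset=[factor])
    grouped = sub.groupby(factor, observed=True)["in_care"].agg(["size", "mean"])
    if levels is None:
        levels = tuple(sorted(grouped.index))
    out = []
    for level in levels:
        if level in grouped.index:
            n = int(grouped.loc[level, "size"])
            pct = 100.0 * float(grouped.loc[level, "mean"])
        else:
            n, pct = 0, float("nan")
        out.append({"factor": factor, "level": level, "person_months": n, "percent_in_care": pct})
    return pd.DataFrame(out)


@dataclass
class AssociationResult:
    """Odds ratios for being in care in any particular month.

    ``table`` has one row per covariate level: factor, level, or, ci_low,
    ci_high, p, reference (bool).  Reference levels carry OR exactly 1.
    """

    table: pd.DataFrame
    n_rows: int
    n_patients: int
    n_dropped_missing: int
    correlation_structure: str = "exchangeable"
    adjusted: bool = False


def fit_association_model(
    rows: pd.DataFrame,
    covariates: list[str],
    adjust: bool = False,
    include_clinic: bool = True,
) -> AssociationResult:
    """Fit the month-level logistic association model with GEE.

    ``adjust=False`` fits one single-covariate model per entry in
    ``covariates``; ``adjust=True`` fits one model containing them all
    (plus clinic when available and ``include_clinic``).  Robust standard
    errors account for within-patient clustering.  Months missing any
    modelled covariate are dropped (counted in the result); separation or
    non-convergence raises rather than returning silent output.
    """
    for cov in covariates:
        if cov not in rows.columns:
            raise ValueError(
                f"unknown covariate {cov!r}; available columns: {sorted(rows.columns)}"
            )
    if rows["patient_id"].nunique() < 2:
        raise ValueError("association model requires rows from at least 2 patients")

    model_covs = list(covariates)
    if adjust and include_clinic and rows["clinic_id"].nunique() > 1:
        if "clinic_id" not in model_covs:
            model_covs.append("clinic_id")

    def _fit(covs: list[str]) -> tuple[pd.DataFrame, int, int, int]:
        sub = rows.dropna(subset=covs).copy()
        n_dropped = len(rows) - len(sub)
        if n_dropped:
            log.info("dropped %d person-months with missing covariates", n_dropped)
        terms = []
        for cov in covs:
            observed = set(sub[cov].unique())
            if len(observed) < 2:
                raise ValueError(f"covariate {cov!r} has fewer than 2 observed levels")
            ref = REFERENCE_LEVELS.get(cov)
            if ref not in observed:
                ref = sorted(observed)[0]
            terms.append(f"C({cov}, Treatment({ref!r}))")
        formula = "in_care ~ " + " + ".join(terms)
        model = sm.GEE.from_formula(
            formula,
            groups="patient_id",
            data=sub,
            family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        try:
            res = model.fit()
        except Exception as exc:  # pragma: no cover - surfaced, not swallowed
            raise RuntimeError(f"GEE fit failed: {exc}") from exc
        if not np.all(np.isfinite(res.bse)) or np.any(res.bse > 1e3):
            raise RuntimeError(
                "GEE fit unstable (non-finite or exploding standard errors); "
                "check for separation or empty strata"
            )
        params, ci, pvals = res.params, res.conf_int(), res.pvalues
        recs = []
        for cov in covs:
            observed = set(sub[cov].unique())
            ref = REFERENCE_LEVELS.get(cov)
            if ref not in observed:
                ref = sorted(observed)[0]
            order = FACTOR_LEVELS.get(cov) or tuple(sorted(observed))
            for level in order:
                if level not in observed:
                    continue
                if level == ref:
                    recs.append(
                        {
                            "factor": cov,
                            "level": level,
                            "or": 1.0,
                            "ci_low": np.nan,
                            "ci_high": np.nan,
                            "p": np.nan,
                            "reference": True,
                        }
                    )
                    continue
                name = f"C({cov}, Treatment({ref!r}))[T.{level}]"
                recs.append(
                    {
                        "factor": cov,
                        "level": level,
                        "or": float(np.exp(params[name])),
                        "ci_low": float(np.exp(ci.loc[name, 0])),
                        "ci_high": float(np.exp(ci.loc[name, 1])),
                        "p": float(pvals[name]),
                        "reference": False,
                    }
                )
        return pd.DataFrame(recs), len(sub), sub["patient_id"].nunique(), n_dropped

    if adjust:
        table, n_rows, n_patients, n_dropped = _fit(model_covs)
    else:
        parts, n_rows, n_patients, n_dropped = [], 0, 0, 0
        for cov in covariates:
            t, nr, npat, nd = _fit([cov])
            parts.append(t)
            n_rows, n_patients, n_dropped = max(n_rows, nr), max(n_patients, npat), n_dropped + nd
        table = pd.concat(parts, ignore_index=True)

    return AssociationResult(
        table=table,
        n_rows=n_rows,
        n_patients=n_patients,
        n_dropped_missing=n_dropped,
        adjusted=adjust,
    )
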