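"""New-user inception cohort construction.

Builds the cohort of adult starters of one of the five antihypertensive
monotherapy classes from raw dispensing records: index-date detection with a
730-day washout, exclusion of patients with acute-cardiovascular / secondary
hypertension drug use around the index, follow-up end determination
(study end, 3780-day cap, first acute-CV drug, end of last exposure supply,
or change of the initial monotherapy — whichever comes first), and derivation
of the categorical risk-factor covariates (age band, sex, nine comorbidity
drug flags within 180 days, calendar period of the index date).

Conventions: day 0 is the index date; supply intervals are half-open
``[day, day + days_supply)``; ages are completed years at the index date.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classmap import ClassMap, DEFAULT_CLASS_MAP, is_valid_atc

log = logging.getLogger(__name__)

LOOKBACK_DAYS = 730
POST_INDEX_EXCLUSION_DAYS = 90
MAX_FOLLOWUP_DAYS = 3780
COVARIATE_WINDOW_DAYS = 180
MIN_AGE = 18

CENSOR_REASONS = (
    "study_end",
    "max_3780",
    "acute_cv_drug",
    "last_exposure_supply_end",
    "regimen_change",
)

AGE_BANDS = ("young", "middle", "older")
CALENDAR_PERIODS = ("1996-2000", "2000-2010", "2010-2020")
COMORBIDITY_NAMES = (
    "diabetes", "ra", "asthma_copd", "antiepileptics", "antiparkinson",
    "psycholeptics", "psychoanaleptics", "addictive_disorders",
    "antineoplastics",
)


def validate_dispensings(disp: pd.DataFrame) -> pd.DataFrame:
    """Check schema, coerce dates, and reject invalid rows loudly."""
    required = {"patient_id", "dispense_date", "atc_code", "days_supply"}
    missing = required - set(disp.columns)
    if missing:
        raise ValueError(f"dispensing table missing columns: {sorted(missing)}")
    out = disp.copy()
    out["dispense_date"] = pd.to_datetime(out["dispense_date"])
    out["days_supply"] = out["days_supply"].astype(int)
    bad_supply = out["days_supply"] < 1
    if bad_supply.any():
        raise ValueError(
            f"{int(bad_supply.sum())} dispensings with days_supply < 1 "
            f"(first at row {out.index[bad_supply][0]})"
        )
    bad_atc = ~out["atc_code"].astype(str).map(is_valid_atc)
    if bad_atc.any():
        raise ValueError(
            f"{int(bad_atc.sum())} dispensings with malformed ATC codes "
            f"(e.g. {out.loc[bad_atc, 'atc_code'].iloc[0]!r})"
        )
    return out.sort_values(["patient_id", "dispense_date"], kind="mergesort")


def completed_years(birth: pd.Timestamp, at: pd.Timestamp) -> int:
    """Age in completed years at *at*."""
    years = at.year - birth.year
    if (at.month, at.day) < (birth.month, birth.day):
        years -= 1
    return years


def identify_index(
    disp: pd.DataFrame,
    class_map: ClassMap = DEFAULT_CLASS_MAP,
    lookback_days: int = LOOKBACK_DAYS,
    window_start: pd.Timestamp | str | None = None,
) -> pd.DataFrame:
    """Candidate index events: first exposure dispensing per patient.

    The candidate is the patient's first exposure-class dispensing at/after
    ``window_start`` (if given).  A patient is rejected when any exposure
    dispensing falls in the ``lookback_days`` before the candidate (not a
    starter) or when two distinct exposure classes are dispensed on the
    candidate day (not monotherapy).

    Returns columns ``patient_id, index_date, index_class``.
    """
    if disp.empty:
        return pd.DataFrame(columns=["patient_id", "index_date", "index_class"])
    disp = validate_dispensings(disp)
    expo = disp.assign(
        drug_class=disp["atc_code"].map(class_map.exposure_class_of)
    ).dropna(subset=["drug_class"])
    if window_start is not None:
        window_start = pd.Timestamp(window_start)

    rows = []
    for pid, grp in expo.groupby("patient_id", sort=True):
        cand = grp if window_start is None else grp[grp["dispense_date"] >= window_start]
        if cand.empty:
            continue
        index_date = cand["dispense_date"].iloc[0]
        prior = grp["dispense_date"]
        washout_lo = index_date - pd.Timedelta(days=lookback_days)
        if ((prior >= washout_lo) & (prior < index_date)).any():
            continue  # not a starter
        day0 = cand[cand["dispense_date"] == index_date]
        classes = sorted(day0["drug_class"].unique())
        if len(classes) != 1:
            continue  # >=2 classes on the index day: not monotherapy
        rows.append((pid, index_date, classes[0]))
    return pd.DataFrame(rows, columns=["patient_id", "index_date", "index_class"])


def apply_exclusions(
    candidates: pd.DataFrame,
    disp: pd.DataFrame,
    patients: pd.DataFrame,
    class_map: ClassMap = DEFAULT_CLASS_MAP,
    lookback_days: int = LOOKBACK_DAYS,
    post_window: int = POST_INDEX_EXCLUSION_DAYS,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop candidates with exclusion-drug use around the index, or aged < 18.

    The exclusion window is ``[index - lookback_days, index + post_window]``
    (both ends inclusive).  Returns the retained cohort and a count of
    removals by reason.
    """
    disp = validate_dispensings(disp)
    pat = patients.set_index("patient_id")
    excl_disp = disp[disp["atc_code"].astype(str).map(class_map.is_exclusion)]
    excl_by_pid = {pid: grp["dispense_date"].to_numpy() for pid, grp in excl_disp.groupby("patient_id")}

    flow = {"candidates": len(candidates), "excluded_drug_window": 0,
            "excluded_underage": 0, "excluded_missing_patient": 0}
    keep = []
    for row in candidates.itertuples(index=False):
        dates = excl_by_pid.get(row.patient_id)
        if dates is not None:
            lo = row.index_date - pd.Timedelta(days=lookback_days)
            hi = row.index_date + pd.Timedelta(days=post_window)
            if ((dates >= lo.to_datetime64()) & (dates <= hi.to_datetime64())).any():
                flow["excluded_drug_window"] += 1
                continue
        if row.patient_id not in pat.index:
            flow["excluded_missing_patient"] += 1
            log.warning("patient %s absent from patient table; rejected", row.patient_id)
            continue
        birth = pd.Timestamp(pat.loc[row.patient_id, "birth_date"])
        if completed_years(birth, row.index_date) < MIN_AGE:
            flow["excluded_underage"] += 1
            continue
        keep.append(row)
    cohort = pd.DataFrame(keep, columns=candidates.columns)
    flow["retained"] = len(cohort)
    return cohort, flow


def determine_followup_end(
    cohort: pd.DataFrame,
    disp: pd.DataFrame,
    class_map: ClassMap = DEFAULT_CLASS_MAP,
    study_end: pd.Timestamp | str = "2020-12-31",
    max_days: int = MAX_FOLLOWUP_DAYS,
    exposure_end_rule: str = "supply_end",
) -> pd.DataFrame:
    """Attach ``followup_end_day`` and ``censor_reason`` to each cohort entry.

    Follow-up ends at the earliest of: the study end, the ``max_days`` cap,
    the first acute-cardiovascular drug dispensing after index, the end of
    supply of the last dispensing of the index class (or its dispensing date
    when ``exposure_end_rule='dispense_date'``), and the first dispensing of
    a different exposure class or FDC (regimen change).  Ties are broken in
    that order.
    """
    if exposure_end_rule not in ("supply_end", "dispense_date"):
        raise ValueError("exposure_end_rule must be 'supply_end' or 'dispense_date'")
    study_end = pd.Timestamp(study_end)
    disp = validate_dispensings(disp)
    by_pid = dict(tuple(disp.groupby("patient_id")))

    ends, reasons = [], []
    for row in cohort.itertuples(index=False):
        grp = by_pid.get(row.patient_id)
        day = (grp["dispense_date"] - row.index_date).dt.days
        atc = grp["atc_code"].astype(str)
        drug_class = atc.map(class_map.exposure_class_of)

        candidates: dict[str, float] = {
            # study_end day itself is still observed: exclusive end = +1
            "study_end": (study_end - row.index_date).days + 1,
            "max_3780": max_days,
        }
        acute = day[(day > 0) & atc.map(class_map.is_acute_cv)]
        if not acute.empty:
            candidates["acute_cv_drug"] = int(acute.min())
        own = grp[(drug_class == row.index_class).to_numpy()]
        own_days = (own["dispense_date"] - row.index_date).dt.days
        if exposure_end_rule == "supply_end":
            candidates["last_exposure_supply_end"] = int(
                (own_days + own["days_supply"]).max()
            )
        else:
            candidates["last_exposure_supply_end"] = int(max(own_days.max(), 1))
        change = day[
            (day > 0)
            & (
                ((drug_class.notna()) & (drug_class != row.index_class))
                | atc.map(class_map.is_fdc)
            ).to_numpy()
        ]
        if not change.empty:
            candidates["regimen_change"] = int(change.min())

        best_reason = min(
            candidates,
            key=lambda r: (candidates[r], CENSOR_REASONS.index(r)),
        )
        ends.append(int(candidates[best_reason]))
        reasons.append(best_reason)

    out = cohort.copy()
    out["followup_end_day"] = ends
    out["censor_reason"] = reasons
    if (out["followup_end_day"] <= 0).any():
        raise ValueError("non-positive follow-up; index dates must precede study end")
    return out


def age_band(age_years: int) -> str:
    if age_years < 40:
        return "young"
    if age_years < 70:
        return "middle"
    return "older"


def calendar_period(index_date: pd.Timestamp) -> str:
    """Half-open calendar bins [1996, 2000), [2000, 2010), [2010, 2021)."""
    y = index_date.year
    if y < 2000:
        return "1996-2000"
    if y < 2010:
        return "2000-2010"
    return "2010-2020"


def assign_covariates(
    cohort: pd.DataFrame,
    disp: pd.DataFrame,
    patients: pd.DataFrame,
    class_map: ClassMap = DEFAULT_CLASS_MAP,
    window: int = COVARIATE_WINDOW_DAYS,
) -> pd.DataFrame:
    """Derive the categorical risk-factor table.

    Comorbidity flags are true iff >=1 dispensing of the matching drug group
    falls within ``[index, index + window]`` days (inclusive).  Records with
    a missing birth date or sex are rejected with a logged reason.
    """
    disp = validate_dispensings(disp)
    pat = patients.set_index("patient_id")
    com = disp.assign(group=disp["atc_code"].map(class_map.comorbidity_group_of)).dropna(
        subset=["group"]
    )
    com_by_pid = dict(tuple(com.groupby("patient_id")))

    rows = []
    for row in cohort.itertuples(index=False):
        if row.patient_id not in pat.index:
            log.warning("patient %s absent from patient table; rejected", row.patient_id)
            continue
        prec = pat.loc[row.patient_id]
        if pd.isna(prec.get("birth_date")) or pd.isna(prec.get("sex")):
            log.warning("patient %s missing birth date or sex; rejected", row.patient_id)
            continue
        rec = row._asdict()
        age = completed_years(pd.Timestamp(prec["birth_date"]), row.index_date)
        rec["age"] = age
        rec["age_band"] = age_band(age)
        rec["sex"] = str(prec["sex"])
        rec["calendar_period"] = calendar_period(row.index_date)
        grp = com_by_pid.get(row.patient_id)
        flagged: set[str] = set()
        if grp is not None:
            offs = (grp["dispense_date"] - row.index_date).dt.days
            inwin = grp[(offs >= 0) & (offs <= window)]
            flagged = set(inwin["group"])
        for name in COMORBIDITY_NAMES:
            rec[name] = name in flagged
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class CohortResult:
    cohort: pd.DataFrame
    flow: dict[str, int]


def build_cohort(
    disp: pd.DataFrame,
    patients: pd.DataFrame,
    class_map: ClassMap = DEFAULT_CLASS_MAP,
    study_end: pd.Timestamp | str = "2020-12-31",
    lookback_days: int = LOOKBACK_DAYS,
    post_window: int = POST_INDEX_EXCLUSION_DAYS,
    window_start: pd.Timestamp | str | None = None,
) -> CohortResult:
    """Run the full cohort chain and return the covariate-annotated cohort."""
    candidates = identify_index(disp, class_map, lookback_days, window_start)
    retained, flow = apply_exclusions(
        candidates, disp, patients, class_map, lookback_days, post_window
    )
    with_end = determine_followup_end(retained, disp, class_map, study_end)
    full = assign_covariates(with_end, disp, patients, class_map)
    flow["with_covariates"] = len(full)
    return CohortResult(cohort=full, flow=flow)


def persistent_subcohort(cohort: pd.DataFrame, years: int) -> pd.DataFrame:
    """Patients still on the original monotherapy beyond ``years`` treatment years."""
    return cohort[cohort["followup_end_day"] > 360 * years]


def long_record_subcohort(
    cohort: pd.DataFrame, disp: pd.DataFrame, min_days: int = 1080
) -> pd.DataFrame:
    """Patients whose dispensing history (any drug) extends past ``min_days``."""
    disp = validate_dispensings(disp)
    last = disp.groupby("patient_id")["dispense_date"].max()
    idx = cohort.set_index("patient_id").index
    span = (last.reindex(idx) - cohort.set_index("patient_id")["index_date"]).dt.days
    return cohort[(span > min_days).to_numpy()]
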