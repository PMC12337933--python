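"""DataFrame-level orchestration over the per-patient primitives.

Bridges the raw dispensing table and the cohort to the interval/PDC/pattern
machinery: per-patient coverage timelines of the index class, the annual and
overall adherence tables, per-patient pattern profiles, and the class-by-target
switch/add-on matrices.
"""

from __future__ import annotations

import pandas as pd

from .classmap import ClassMap, DEFAULT_CLASS_MAP
from .cohort import validate_dispensings
from .coverage import annual_pdc, binarize_adherence, covered_intervals, overall_pdc
from .patterns import GAP_DAYS, SWITCH_WINDOW, classify_patient

MAX_OBSERVE_DAYS = 3780


def _per_patient_dispensings(
    cohort: pd.DataFrame, disp: pd.DataFrame, class_map: ClassMap
) -> dict[object, tuple[list[tuple[int, int]], list[int], list[tuple[int, str]]]]:
    """For each cohort patient: index-class (day, supply), same-class days,
    and other-exposure/FDC (day, target) lists, as offsets from index."""
    disp = validate_dispensings(disp)
    by_pid = dict(tuple(disp.groupby("patient_id")))
    out = {}
    for row in cohort.itertuples(index=False):
        grp = by_pid.get(row.patient_id)
        if grp is None:
            out[row.patient_id] = ([], [], [])
            continue
        days = (grp["dispense_date"] - row.index_date).dt.days
        atc = grp["atc_code"].astype(str)
        cls = atc.map(class_map.exposure_class_of)
        own_mask = ((cls == row.index_class) & (days >= 0)).to_numpy()
        own = [
            (int(d), int(s))
            for d, s in zip(days[own_mask], grp["days_supply"].to_numpy()[own_mask])
        ]
        other_mask = (
            (days > 0)
            & (((cls.notna()) & (cls != row.index_class)) | atc.map(class_map.is_fdc))
        ).to_numpy()
        others = [
            (int(d), "fdc" if class_map.is_fdc(a) else str(c))
            for d, a, c in zip(days[other_mask], atc[other_mask], cls[other_mask])
        ]
        out[row.patient_id] = (own, [d for d, _ in own], sorted(others))
    return out


def pattern_observation_end(
    cohort: pd.DataFrame, study_end: pd.Timestamp | str, max_days: int = MAX_OBSERVE_DAYS
) -> pd.Series:
    """Observation horizon for pattern scanning: min(study end + 1, 3780).

    Deliberately not the supply-censored follow-up end — a post-supply gap
    could never be observed under that rule and nobody could discontinue.
    """
    study_end = pd.Timestamp(study_end)
    days = (study_end - pd.to_datetime(cohort["index_date"])).dt.days + 1
    return days.clip(upper=max_days).rename("observe_end")


def adherence_tables(
    cohort: pd.DataFrame,
    disp: pd.DataFrame,
    class_map: ClassMap = DEFAULT_CLASS_MAP,
    policy: str = "carryover",
    max_years: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient-per-year and overall PDC tables.

    Annual rows are emitted only for evaluable years (follow-up covering the
    whole 360-day window).  Returns ``(annual, overall)`` frames.
    """
    per = _per_patient_dispensings(cohort, disp, class_map)
    annual_rows, overall_rows = [], []
    for row in cohort.itertuples(index=False):
        own, _, _ = per[row.patient_id]
        intervals = covered_intervals(own, policy)
        end = int(row.followup_end_day)
        for k in range(1, max_years + 1):
            pdc = annual_pdc(intervals, k, followup_end_day=end)
            if pdc is None:
                break
            annual_rows.append(
                (row.patient_id, k, pdc, binarize_adherence(pdc) == "high")
            )
        opdc = overall_pdc(intervals, end)
        overall_rows.append(
            (row.patient_id, end, opdc, binarize_adherence(opdc) == "high")
        )
    annual = pd.DataFrame(
        annual_rows, columns=["patient_id", "year", "pdc", "high_adherence"]
    )
    overall = pd.DataFrame(
        overall_rows, columns=["patient_id", "followup_end_day", "pdc", "high_adherence"]
    )
    return annual, overall


def classify_cohort(
    cohort: pd.DataFrame,
    disp: pd.DataFrame,
    class_map: ClassMap = DEFAULT_CLASS_MAP,
    study_end: pd.Timestamp | str = "2020-12-31",
    policy: str = "carryover",
    gap_days: int = GAP_DAYS,
    window: int = SWITCH_WINDOW,
) -> pd.DataFrame:
    """Pattern profile per cohort patient (one row each)."""
    per = _per_patient_dispensings(cohort, disp, class_map)
    observe = pattern_observation_end(cohort, study_end)
    rows = []
    for (row, obs_end) in zip(cohort.itertuples(index=False), observe):
        own, same_days, others = per[row.patient_id]
        intervals = covered_intervals(own, policy)
        prof = classify_patient(
            row.patient_id, intervals, same_days, others, int(obs_end), gap_days, window
        )
        rows.append(
            {
                "patient_id": prof.patient_id,
                "index_class": row.index_class,
                "continuation": prof.continuation,
                "disc_day": prof.discontinuation_day,
                "switch_day": prof.switch_day,
                "switch_target": prof.switch_target,
                "addon_day": prof.addon_day,
                "addon_target": prof.addon_target,
            }
        )
    return pd.DataFrame(rows)


def pattern_rates(profiles: pd.DataFrame) -> pd.DataFrame:
    """Non-exclusive pattern percentages by index class (rows can sum > 100%)."""
    out = []
    for cls, grp in profiles.groupby("index_class"):
        n = len(grp)
        out.append(
            {
                "index_class": cls,
                "n": n,
                "continuation_pct": 100 * grp["continuation"].mean(),
                "discontinuation_pct": 100 * grp["disc_day"].notna().mean(),
                "switch_pct": 100 * grp["switch_day"].notna().mean(),
                "addon_pct": 100 * grp["addon_day"].notna().mean(),
            }
        )
    return pd.DataFrame(out)


def switch_addon_matrices(
    profiles: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class-by-target count matrices for switch and add-on events."""
    switch = pd.crosstab(profiles["index_class"], profiles["switch_target"])
    addon = pd.crosstab(profiles["index_class"], profiles["addon_target"])
    return switch, addon
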