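"""New-user cohort construction: index, exclusions, follow-up end, covariates."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_dispensings, make_patients
from oracles import scan_followup_end
from rxadherence.classmap import DEFAULT_CLASS_MAP, ClassMap
from rxadherence.cohort import (
    apply_exclusions,
    assign_covariates,
    build_cohort,
    determine_followup_end,
    identify_index,
    long_record_subcohort,
    persistent_subcohort,
)
from rxadherence.simulate import SimulationConfig, simulate_population


class TestClassMap:
    def test_exposure_lookup(self):
        cm = DEFAULT_CLASS_MAP
        assert cm.exposure_class_of("C09AA02") == "acei"
        assert cm.exposure_class_of("C03AA03") == "thiazide"
        assert cm.exposure_class_of("C08CA01") == "ccb"
        assert cm.exposure_class_of("A10BA02") is None

    def test_fdc_and_comorbidity(self):
        cm = DEFAULT_CLASS_MAP
        assert cm.is_fdc("C09BA02")
        assert cm.comorbidity_group_of("A10BA02") == "diabetes"
        assert cm.comorbidity_group_of("N05BA01") == "psycholeptics"

    def test_requires_all_five_classes(self):
        with pytest.raises(ValueError):
            ClassMap(exposure_classes={"acei": ("C09A",)})


class TestIdentifyIndex:
    def test_first_dispensing_is_index(self):
        disp = make_dispensings([("p1", "2005-03-01", "C09AA02", 90)])
        out = identify_index(disp)
        assert len(out) == 1
        assert out.iloc[0]["index_class"] == "acei"
        assert out.iloc[0]["index_date"] == pd.Timestamp("2005-03-01")

    def test_prior_exposure_within_lookback_blocks_index(self):
        # C07A 400 days before the in-window candidate: not a starter
        disp = make_dispensings(
            [("p1", "2004-01-27", "C07AB02", 30), ("p1", "2005-03-01", "C09AA02", 90)]
        )
        out = identify_index(disp, window_start="2005-01-01")
        assert out.empty

    def test_prior_exposure_outside_lookback_allows_index(self):
        disp = make_dispensings(
            [("p1", "2002-01-01", "C07AB02", 30), ("p1", "2005-03-01", "C09AA02", 90)]
        )
        out = identify_index(disp, window_start="2005-01-01")
        assert len(out) == 1

    def test_two_classes_on_index_day_rejected(self):
        disp = make_dispensings(
            [("p1", "2005-03-01", "C09AA02", 90), ("p1", "2005-03-01", "C03AA03", 30)]
        )
        assert identify_index(disp).empty

    def test_empty_input(self):
        assert identify_index(make_dispensings([])).empty


class TestExclusions:
    @staticmethod
    def _setup(extra_rows, birth="1960-05-05"):
        disp = make_dispensings(
            [("p1", "2005-03-01", "C09AA02", 90)] + extra_rows
        )
        patients = make_patients([("p1", birth, "F")])
        cand = identify_index(disp)
        return apply_exclusions(cand, disp, patients)

    def test_exclusion_drug_at_30_days_post_index(self):
        cohort, flow = self._setup([("p1", "2005-03-31", "C01AA05", 30)])
        assert cohort.empty and flow["excluded_drug_window"] == 1

    def test_exclusion_drug_at_91_days_retained(self):
        cohort, _ = self._setup([("p1", "2005-05-31", "C01AA05", 30)])
        assert len(cohort) == 1

    def test_underage_excluded(self):
        cohort, flow = self._setup([], birth="1988-01-01")
        assert cohort.empty and flow["excluded_underage"] == 1

    def test_age_18_retained(self):
        cohort, _ = self._setup([], birth="1987-03-01")
        assert len(cohort) == 1

    def test_idempotent(self):
        disp = make_dispensings(
            [("p1", "2005-03-01", "C09AA02", 90), ("p1", "2005-05-31", "C01AA05", 30)]
        )
        patients = make_patients([("p1", "1960-05-05", "F")])
        cand = identify_index(disp)
        cohort, _ = apply_exclusions(cand, disp, patients)
        again, flow = apply_exclusions(cohort, disp, patients)
        pd.testing.assert_frame_equal(cohort, again)
        assert flow["excluded_drug_window"] == 0


class TestFollowupEnd:
    def test_study_end_censor(self):
        disp = make_dispensings(
            [("p1", "2019-06-01", "C09AA02", 90), ("p1", "2020-11-01", "C09AA02", 600)]
        )
        cohort = identify_index(disp)
        out = determine_followup_end(cohort, disp, study_end="2020-12-31")
        assert out.iloc[0]["censor_reason"] == "study_end"
        assert out.iloc[0]["followup_end_day"] == (
            pd.Timestamp("2020-12-31") - pd.Timestamp("2019-06-01")
        ).days + 1

    def test_ten_year_cap(self):
        rows = [("p1", pd.Timestamp("1996-01-01") + pd.Timedelta(days=90 * k), "C09AA02", 91)
                for k in range(50)]
        disp = make_dispensings(rows)
        cohort = identify_index(disp)
        out = determine_followup_end(cohort, disp, study_end="2020-12-31")
        assert out.iloc[0]["followup_end_day"] == 3780
        assert out.iloc[0]["censor_reason"] == "max_3780"

    def test_last_supply_end(self):
        disp = make_dispensings(
            [
                ("p1", "2005-01-01", "C09AA02", 90),
                ("p1", "2005-09-28", "C09AA02", 90),  # day 270, ends day 360
            ]
        )
        cohort = identify_index(disp)
        out = determine_followup_end(cohort, disp, study_end="2020-12-31")
        assert out.iloc[0]["followup_end_day"] == 360
        assert out.iloc[0]["censor_reason"] == "last_exposure_supply_end"

    def test_regimen_change_censor(self):
        disp = make_dispensings(
            [
                ("p1", "2005-01-01", "C09AA02", 300),
                ("p1", "2005-05-01", "C08CA01", 90),  # day 120 regimen change
            ]
        )
        cohort = identify_index(disp)
        out = determine_followup_end(cohort, disp, study_end="2020-12-31")
        assert out.iloc[0]["followup_end_day"] == 120
        assert out.iloc[0]["censor_reason"] == "regimen_change"

    def test_matches_day_scan_oracle_on_synthetic_patients(self):
        cfg = SimulationConfig(n_patients=200, seed=9)
        patients, disp, _ = simulate_population(cfg)
        cohort = identify_index(disp)
        out = determine_followup_end(cohort, disp, study_end="2020-12-31")
        cm = DEFAULT_CLASS_MAP
        merged = disp.merge(out, on="patient_id")
        merged["day"] = (merged["dispense_date"] - merged["index_date"]).dt.days
        for pid, grp in merged.groupby("patient_id"):
            row = out[out["patient_id"] == pid].iloc[0]
            own = grp[grp["atc_code"].map(cm.exposure_class_of) == row["index_class"]]
            others = grp[
                grp["atc_code"].map(
                    lambda a: (cm.exposure_class_of(a) not in (None, row["index_class"]))
                    or cm.is_fdc(a)
                )
            ]
            end, reason = scan_followup_end(
                study_end_day=(pd.Timestamp("2020-12-31") - row["index_date"]).days + 1,
                max_days=3780,
                acute_days=grp[grp["atc_code"].map(cm.is_acute_cv)]["day"],
                own_supply_ends=(own["day"] + own["days_supply"]).tolist(),
                change_days=others["day"].tolist(),
            )
            assert (end, reason) == (
                row["followup_end_day"], row["censor_reason"]
            ), pid

    def test_subcohorts_nested(self):
        cfg = SimulationConfig(n_patients=300, seed=5)
        patients, disp, _ = simulate_population(cfg)
        res = build_cohort(disp, patients)
        sizes = []
        for k in range(1, 6):
            sub = persistent_subcohort(res.cohort, k)
            sizes.append(set(sub["patient_id"]))
        for a, b in zip(sizes[1:], sizes[:-1]):
            assert a <= b
        long3 = long_record_subcohort(res.cohort, disp, 1080)
        assert set(long3["patient_id"]) <= set(res.cohort["patient_id"])


class TestCovariates:
    @staticmethod
    def _cohort_with(extra_rows, birth="1950-06-15"):
        disp = make_dispensings(
            [("p1", "2005-03-01", "C09AA02", 90)] + extra_rows
        )
        patients = make_patients([("p1", birth, "M")])
        cohort = identify_index(disp)
        cohort = determine_followup_end(cohort, disp, study_end="2020-12-31")
        return assign_covariates(cohort, disp, patients)

    def test_comorbidity_inside_window(self):
        out = self._cohort_with([("p1", "2005-06-09", "A10BA02", 30)])  # +100
        assert bool(out.iloc[0]["diabetes"])

    def test_comorbidity_outside_window(self):
        out = self._cohort_with([("p1", "2005-09-17", "A10BA02", 30)])  # +200
        assert not bool(out.iloc[0]["diabetes"])

    @pytest.mark.parametrize(
        "birth, band", [("1935-01-01", "older"), ("1936-01-01", "middle"),
                        ("1966-01-01", "young")]
    )
    def test_age_bands_at_boundary(self, birth, band):
        # index 2005-03-01: ages 70, 69 and 39 completed years
        out = self._cohort_with([], birth=birth)
        assert out.iloc[0]["age_band"] == band

    def test_calendar_period(self):
        out = self._cohort_with([])
        assert out.iloc[0]["calendar_period"] == "2000-2010"

    def test_missing_sex_rejected(self):
        disp = make_dispensings([("p1", "2005-03-01", "C09AA02", 90)])
        patients = pd.DataFrame(
            {"patient_id": ["p1"], "birth_date": ["1950-01-01"], "sex": [None]}
        )
        cohort = identify_index(disp)
        cohort = determine_followup_end(cohort, disp, study_end="2020-12-31")
        out = assign_covariates(cohort, disp, patients)
        assert out.empty
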