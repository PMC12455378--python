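"""Encounter identification, exclusion cascade, outcome and covariates."""

import datetime as dt

import pandas as pd
import pytest

from salpnet.cohort import (
    AttritionReport,
    apply_eligibility,
    assign_index_dates,
    build_cohort,
    classify_outcome,
    derive_covariates,
    identify_sterilization_encounters,
)

T2 = (dt.date(2020, 1, 1), dt.date(2023, 1, 1))
T1 = (dt.date(2017, 1, 1), dt.date(2020, 1, 1))


def claim(enrollee, physician, date, setting, system, code, specialty="obgyn", hrr="HRR00"):
    return {
        "enrollee_id": enrollee,
        "physician_id": physician,
        "specialty": specialty,
        "service_date": date,
        "setting": setting,
        "code_system": system,
        "code": code,
        "hrr_id": hrr,
    }


def enrolled(enrollee, start="2019-01-01", end="2023-01-01"):
    return {"enrollee_id": enrollee, "start_date": start, "end_date": end}


def attrs(enrollee, birth_year=1990, region="South", sdi="25-50", metro=True):
    return {
        "enrollee_id": enrollee,
        "birth_year": birth_year,
        "region": region,
        "sdi_class": sdi,
        "metro": metro,
    }


class TestIdentify:
    def test_outpatient_salpingectomy_with_sterilization_dx_is_interval(self, codes):
        claims = pd.DataFrame(
            [
                claim("E1", "P1", "2021-05-10", "outpatient", "CPT", "58661"),
                claim("E1", "P1", "2021-05-10", "outpatient", "ICD10DX", "Z30.2"),
            ]
        )
        cand, rejects = identify_sterilization_encounters(claims, codes, "T2", T2)
        assert len(cand) == 1 and rejects.empty
        assert cand.iloc[0]["setting_class"] == "interval"
        assert cand.iloc[0]["surgeon_id"] == "P1"

    def test_ectopic_diagnosis_disqualifies(self, codes):
        claims = pd.DataFrame(
            [
                claim("E1", "P1", "2021-05-10", "outpatient", "CPT", "58661"),
                claim("E1", "P1", "2021-05-10", "outpatient", "ICD10DX", "Z30.2"),
                claim("E1", "P1", "2021-05-10", "outpatient", "ICD10DX", "O00.90"),
            ]
        )
        cand, _ = identify_sterilization_encounters(claims, codes, "T2", T2)
        assert cand.empty

    def test_inpatient_with_delivery_is_postpartum(self, codes):
        claims = pd.DataFrame(
            [
                claim("E1", "P1", "2021-05-10", "inpatient", "ICD10PCS", "0UT74ZZ"),
                claim("E1", "P1", "2021-05-10", "inpatient", "ICD10PCS", "10D00Z1"),
                claim("E1", "P1", "2021-05-10", "inpatient", "ICD10DX", "Z30.2"),
            ]
        )
        cand, _ = identify_sterilization_encounters(claims, codes, "T2", T2)
        assert len(cand) == 1
        assert cand.iloc[0]["setting_class"] == "postpartum"

    def test_inpatient_without_delivery_goes_to_rejects(self, codes):
        claims = pd.DataFrame(
            [
                claim("E1", "P1", "2021-05-10", "inpatient", "ICD10PCS", "0UL74ZZ"),
                claim("E1", "P1", "2021-05-10", "inpatient", "ICD10DX", "Z30.2"),
            ]
        )
        cand, rejects = identify_sterilization_encounters(claims, codes, "T2", T2)
        assert cand.empty and len(rejects) == 1
        assert "delivery" in rejects.iloc[0]["reason"]

    def test_missing_sterilization_dx_not_candidate(self, codes):
        claims = pd.DataFrame(
            [claim("E1", "P1", "2021-05-10", "outpatient", "CPT", "58661")]
        )
        cand, _ = identify_sterilization_encounters(claims, codes, "T2", T2)
        assert cand.empty

    def test_surgeon_tie_broken_by_interaction_days(self, codes):
        claims = pd.DataFrame(
            [
                claim("E1", "P2", "2021-05-10", "outpatient", "CPT", "58661"),
                claim("E1", "P1", "2021-05-10", "outpatient", "CPT", "58661"),
                claim("E1", "P1", "2021-05-10", "outpatient", "ICD10DX", "Z30.2"),
                # P1 has more history with the patient
                claim("E1", "P1", "2021-01-03", "outpatient", "CPT", "99213"),
                claim("E1", "P1", "2021-02-03", "outpatient", "CPT", "99213"),
            ]
        )
        cand, _ = identify_sterilization_encounters(claims, codes, "T2", T2)
        assert cand.iloc[0]["surgeon_id"] == "P1"

    def test_consecutive_inpatient_dates_form_one_admission(self, codes):
        claims = pd.DataFrame(
            [
                claim("E1", "P1", "2021-05-10", "inpatient", "ICD10PCS", "10D00Z1"),
                claim("E1", "P1", "2021-05-11", "inpatient", "ICD10PCS", "0UT74ZZ"),
                claim("E1", "P1", "2021-05-11", "inpatient", "ICD10DX", "Z30.2"),
            ]
        )
        cand, _ = identify_sterilization_encounters(claims, codes, "T2", T2)
        assert len(cand) == 1
        assert cand.iloc[0]["setting_class"] == "postpartum"


def _candidate_world(codes, birth_year=1990, extra_claims=(), enrollment=None):
    claims = [
        claim("E1", "P1", "2021-05-10", "outpatient", "CPT", "58661"),
        claim("E1", "P1", "2021-05-10", "outpatient", "ICD10DX", "Z30.2"),
        *extra_claims,
    ]
    claims = pd.DataFrame(claims)
    enrollment = pd.DataFrame(enrollment if enrollment is not None else [enrolled("E1")])
    attributes = pd.DataFrame([attrs("E1", birth_year=birth_year)])
    cand, _ = identify_sterilization_encounters(claims, codes, "T2", T2)
    return apply_eligibility(cand, enrollment, claims, attributes, codes)


class TestEligibility:
    def test_clean_record_is_retained(self, codes):
        eligible, report = _candidate_world(codes)
        assert len(eligible) == 1
        frame = report.to_frame()
        assert (frame["n_after"].iloc[:-1].to_numpy() == frame["n_before"].iloc[1:].to_numpy()).all()

    def test_age_52_excluded(self, codes):
        eligible, report = _candidate_world(codes, birth_year=1969)
        assert eligible.empty
        frame = report.to_frame().set_index("filter_name")
        assert frame.loc["age_18_49", "n_removed"] == 1

    def test_hysterectomy_three_months_prior_excluded(self, codes):
        eligible, report = _candidate_world(
            codes,
            extra_claims=[claim("E1", "P9", "2021-02-10", "outpatient", "ICD10DX", "Z90.710")],
        )
        assert eligible.empty
        frame = report.to_frame().set_index("filter_name")
        assert frame.loc["exclusion_surgical_history", "n_removed"] == 1

    def test_prior_salpingectomy_excluded_but_not_same_day(self, codes):
        # a salpingectomy 100 days earlier excludes
        eligible, _ = _candidate_world(
            codes,
            extra_claims=[claim("E1", "P9", "2021-01-30", "outpatient", "CPT", "58700")],
        )
        assert eligible.empty
        # the index encounter's own code does not self-exclude
        eligible, _ = _candidate_world(codes)
        assert len(eligible) == 1

    def test_missing_enrollment_counted_separately(self, codes):
        eligible, report = _candidate_world(codes, enrollment=[])
        assert eligible.empty
        frame = report.to_frame().set_index("filter_name")
        assert frame.loc["missing_enrollment", "n_removed"] == 1

    def test_coverage_gap_excluded(self, codes):
        eligible, report = _candidate_world(
            codes,
            enrollment=[
                enrolled("E1", "2019-01-01", "2021-01-01"),
                enrolled("E1", "2021-01-05", "2023-01-01"),  # 4-day gap inside look-back
            ],
        )
        assert eligible.empty
        frame = report.to_frame().set_index("filter_name")
        assert frame.loc["continuous_coverage_12mo", "n_removed"] == 1

    def test_abutting_spans_are_continuous(self, codes):
        eligible, _ = _candidate_world(
            codes,
            enrollment=[
                enrolled("E1", "2019-01-01", "2021-01-01"),
                enrolled("E1", "2021-01-01", "2023-01-01"),
            ],
        )
        assert len(eligible) == 1

    def test_implausible_specialty_excluded(self, codes):
        claims = pd.DataFrame(
            [
                claim("E1", "P1", "2021-05-10", "outpatient", "CPT", "58661", specialty="primary_care"),
                claim("E1", "P1", "2021-05-10", "outpatient", "ICD10DX", "Z30.2", specialty="primary_care"),
            ]
        )
        cand, _ = identify_sterilization_encounters(claims, codes, "T2", T2)
        eligible, report = apply_eligibility(
            cand, pd.DataFrame([enrolled("E1")]), claims, pd.DataFrame([attrs("E1")]), codes
        )
        assert eligible.empty
        assert report.to_frame().set_index("filter_name").loc["surgeon_specialty", "n_removed"] == 1

    def test_attrition_telescoping_enforced(self):
        report = AttritionReport()
        report.add("a", 10, 8)
        with pytest.raises(ValueError):
            report.add("b", 9, 9)


class TestOutcome:
    def test_interval_any_salpingectomy_true(self, codes):
        assert classify_outcome(frozenset({"58700", "Z30.2"}), "interval", codes)

    def test_postpartum_ligation_only_false(self, codes):
        assert not classify_outcome(frozenset({"0UL74ZZ", "Z30.2", "10D00Z1"}), "postpartum", codes)

    def test_concurrent_oophorectomy_negates(self, codes):
        assert not classify_outcome(
            frozenset({"0UT74ZZ", "0UT20ZZ", "Z30.2", "10D00Z1"}), "postpartum", codes
        )

    def test_postpartum_requires_pcs_complete_codes(self, codes):
        # a CPT-only salpingectomy cannot qualify a postpartum encounter
        assert not classify_outcome(frozenset({"58661", "Z30.2", "10D00Z1"}), "postpartum", codes)
        assert classify_outcome(frozenset({"0UT50ZZ", "Z30.2", "10D00Z1"}), "postpartum", codes)

    def test_unknown_setting_asserts(self, codes):
        with pytest.raises(AssertionError):
            classify_outcome(frozenset(), "inpatient", codes)


class TestIndexDates:
    def _tables(self):
        attributes = pd.DataFrame(
            [attrs("E1", 1990), attrs("E2", 1985), attrs("E3", 1950)]
        )
        enrollment = pd.DataFrame(
            [enrolled(e, "2015-01-01", "2023-01-01") for e in ("E1", "E2", "E3")]
        )
        t1_cand = pd.DataFrame(
            [{"enrollee_id": "E1", "date": dt.date(2018, 5, 1)}]
        )
        return attributes, enrollment, t1_cand

    def test_sterilized_enrollee_keeps_procedure_date(self):
        attributes, enrollment, t1_cand = self._tables()
        idx = assign_index_dates(attributes, enrollment, t1_cand, T1, seed=0)
        assert idx.set_index("enrollee_id").loc["E1", "index_date"] == "2018-05-01"

    def test_random_dates_deterministic_and_inside_t1(self):
        attributes, enrollment, t1_cand = self._tables()
        a = assign_index_dates(attributes, enrollment, t1_cand, T1, seed=3)
        b = assign_index_dates(attributes, enrollment, t1_cand, T1, seed=3)
        pd.testing.assert_frame_equal(a, b)
        d = dt.date.fromisoformat(a.set_index("enrollee_id").loc["E2", "index_date"])
        assert T1[0] <= d < T1[1]

    def test_age_above_64_not_in_sample(self):
        attributes, enrollment, t1_cand = self._tables()
        idx = assign_index_dates(attributes, enrollment, t1_cand, T1, seed=0)
        assert not idx.set_index("enrollee_id").loc["E3", "in_sharing_sample"]
        assert idx.set_index("enrollee_id").loc["E1", "in_sharing_sample"]


class TestCovariates:
    def _eligible(self, codes, extra_claims=(), birth_year=1988):
        claims = [
            claim("E1", "P1", "2021-05-10", "outpatient", "CPT", "58661"),
            claim("E1", "P1", "2021-05-10", "outpatient", "ICD10DX", "Z30.2"),
            *extra_claims,
        ]
        claims = pd.DataFrame(claims)
        attributes = pd.DataFrame([attrs("E1", birth_year=birth_year)])
        cand, _ = identify_sterilization_encounters(claims, codes, "T2", T2)
        eligible, _ = apply_eligibility(
            cand, pd.DataFrame([enrolled("E1")]), claims, attributes, codes
        )
        return derive_covariates(eligible, claims, attributes, codes)

    def test_age_band_boundary(self, codes):
        cov = self._eligible(codes, birth_year=1988)  # age 33 at mid-2021
        assert cov.iloc[0]["age_band"] == "30-34"

    def test_no_bmi_code_maps_to_under_25(self, codes):
        cov = self._eligible(codes)
        assert cov.iloc[0]["bmi_class"] == "<25"
        assert not cov.iloc[0]["smoking"]

    def test_bmi_code_in_window_classifies(self, codes):
        cov = self._eligible(
            codes,
            extra_claims=[claim("E1", "P9", "2021-01-15", "outpatient", "ICD10DX", "Z68.35")],
        )
        assert cov.iloc[0]["bmi_class"] == "30-39"

    def test_two_elixhauser_groups_give_two_plus(self, codes):
        cov = self._eligible(
            codes,
            extra_claims=[
                claim("E1", "P9", "2021-01-15", "outpatient", "ICD10DX", "I10"),
                claim("E1", "P9", "2021-02-15", "outpatient", "ICD10DX", "E11.9"),
            ],
        )
        assert cov.iloc[0]["elixhauser_class"] == ">=2"

    def test_postpartum_mode_of_delivery_from_codes(self, codes):
        claims = pd.DataFrame(
            [
                claim("E1", "P1", "2021-05-10", "inpatient", "ICD10PCS", "0UT74ZZ"),
                claim("E1", "P1", "2021-05-10", "inpatient", "ICD10PCS", "10D00Z1"),
                claim("E1", "P1", "2021-05-10", "inpatient", "ICD10DX", "Z30.2"),
            ]
        )
        attributes = pd.DataFrame([attrs("E1")])
        cand, _ = identify_sterilization_encounters(claims, codes, "T2", T2)
        eligible, _ = apply_eligibility(
            cand, pd.DataFrame([enrolled("E1")]), claims, attributes, codes
        )
        cov = derive_covariates(eligible, claims, attributes, codes)
        assert cov.iloc[0]["mode_of_delivery"] == "cesarean"
        assert cov.iloc[0]["year"] == 2021


class TestEndToEnd:
    def test_world_cohort_outcome_matches_ground_truth(self, world, codes):
        """Claims-level cohort reconstruction agrees with the generator."""
        cfg = world.config
        cohort, report, rejects = build_cohort(
            world.claims, world.enrollment, world.attributes, codes, "T2", cfg.t2_span
        )
        assert rejects.empty
        truth = world.ground_truth.encounters
        t2 = truth[(truth["era"] == "T2") & ~truth["excluded_by_design"]]
        merged = cohort.merge(
            t2, left_on=["enrollee_id"], right_on=["enrollee_id"], suffixes=("", "_gt")
        )
        # most design-eligible encounters survive the cascade (dropout may
        # remove a few) and every survivor's outcome/setting agrees exactly
        assert len(merged) > 0.9 * len(t2)
        assert (merged["os_flag"] == merged["os_flag_gt"]).all()
        assert (merged["setting_class"] == merged["setting_class_gt"]).all()
        # no design-excluded encounter survives
        bad = cohort.merge(
            truth[truth["excluded_by_design"]], on="enrollee_id", how="inner"
        )
        assert bad.empty

    def test_attrition_telescopes_on_world(self, world, codes):
        _, report, _ = build_cohort(
            world.claims, world.enrollment, world.attributes, codes, "T2", world.config.t2_span
        )
        frame = report.to_frame()
        assert (
            frame["n_after"].iloc[:-1].to_numpy() == frame["n_before"].iloc[1:].to_numpy()
        ).all()
        assert (frame["n_before"] - frame["n_removed"] == frame["n_after"]).all()
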