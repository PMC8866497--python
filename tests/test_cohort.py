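"""Cohort rules and the structured covariate block."""

import dataclasses

import numpy as np
import pytest

import textconfound as tc


class TestAssignTreatmentGroup:
    def test_single_record(self, simple_records):
        assert tc.assign_treatment_group(simple_records[0], "prostate").group == "surgery"

    def test_earlier_start_wins(self, simple_records):
        # radiation day 10 before surgery day 40
        assert tc.assign_treatment_group(simple_records[2], "prostate").group == "radiation"

    def test_no_treatment_prostate_is_monitoring(self, simple_records):
        assert tc.assign_treatment_group(simple_records[3], "prostate").group == "monitoring"

    def test_no_treatment_nsclc_excluded(self, simple_records):
        assert tc.assign_treatment_group(simple_records[3], "nsclc").group is None

    def test_tie_raises_with_patient_id(self, simple_records):
        rec = dataclasses.replace(
            simple_records[0],
            treatment_records=[("surgery", 30.0), ("radiation", 30.0)],
        )
        with pytest.raises(ValueError, match="A"):
            tc.assign_treatment_group(rec, "prostate")


class TestFilterCohort:
    def test_six_month_landmark(self, simple_records):
        kept = tc.filter_cohort(simple_records, "prostate", require_note=False)
        ids = {r.patient_id for r in kept}
        assert "E" not in ids  # survival 120 < 183
        assert "A" in ids  # survival 400

    def test_boundary_inclusive(self, simple_records):
        rec = dataclasses.replace(simple_records[0], survival_days=183.0)
        assert tc.filter_cohort([rec], "prostate", require_note=False) == [rec]

    def test_note_window_requirement(self, simple_records):
        kept = tc.filter_cohort(simple_records, "prostate", require_note=True)
        ids = {r.patient_id for r in kept}
        assert "F" not in ids  # only note at day 130 > 140 - 60 window start
        assert "A" in ids

    def test_monotone_in_patients(self, simple_records):
        base = tc.filter_cohort(simple_records[:4], "prostate")
        more = tc.filter_cohort(simple_records, "prostate")
        assert {r.patient_id for r in base} <= {r.patient_id for r in more}


class TestBucketAge:
    @pytest.mark.parametrize(
        "age, label, index",
        [(30, "<=49", 0), (49, "<=49", 0), (50, "50-54", 1), (64, "60-64", 3),
         (84, "80-84", 7), (85, ">=85", 8), (97, ">=85", 8)],
    )
    def test_buckets(self, age, label, index):
        assert tc.bucket_age(age) == label
        assert tc.age_bucket_index(age) == index

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            tc.bucket_age(-1)


class TestEncodeStructured:
    def test_prostate_has_nine_columns(self, simple_records):
        mat = tc.encode_structured(simple_records, "prostate")
        assert len(mat.structured_columns()) == 9
        assert set(mat.column_names) == {
            "struct:patient_age", "struct:race_white", "struct:race_api",
            "struct:race_black", "struct:hispanic", "struct:clinical_stage",
            "struct:diagnosis_year", "struct:tumor_grade", "struct:grade_unknown",
        }

    def test_nsclc_has_seven_columns(self, simple_records):
        mat = tc.encode_structured(simple_records, "nsclc")
        assert len(mat.structured_columns()) == 7
        assert "struct:male" in mat.column_names
        assert "struct:tumor_grade" not in mat.column_names
        assert "struct:clinical_stage" not in mat.column_names

    def test_grade_median_imputation_flagged(self, simple_records):
        mat = tc.encode_structured(simple_records, "prostate").to_dataframe()
        # observed grades 2,1,3,2,4 -> median 2; patient D missing
        assert mat.loc["D", "struct:tumor_grade"] == 2
        assert mat.loc["D", "struct:grade_unknown"] == 1
        assert mat.loc["A", "struct:grade_unknown"] == 0

    def test_unknown_race_all_zero(self, simple_records):
        mat = tc.encode_structured(simple_records, "prostate").to_dataframe()
        race_cols = ["struct:race_white", "struct:race_api", "struct:race_black"]
        assert mat.loc["D", race_cols].sum() == 0

    def test_all_grades_missing_rejected(self, simple_records):
        records = [
            dataclasses.replace(r, tumor_grade=None) for r in simple_records
        ]
        with pytest.raises(ValueError, match="median"):
            tc.encode_structured(records, "prostate")


class TestImputeClinicalStage:
    def _records(self, n, stage_fn, missing_idx):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(n):
            path = int(rng.integers(1, 5))
            recs.append(
                tc.PatientRecord(
                    f"p{i}", float(rng.integers(50, 85)), "male", "white",
                    "non-hispanic", 2010 + i % 8, 400.0, 0,
                    clinical_stage=None if i in missing_idx else stage_fn(path),
                    pathological_stage=path, tumor_grade=1 + path % 4,
                )
            )
        return recs

    def test_constant_training_labels(self):
        recs = self._records(30, lambda p: 2, missing_idx={5, 6})
        out = tc.impute_clinical_stage(recs, seed=1)
        assert out[5].clinical_stage == 2 and out[6].clinical_stage == 2

    def test_recovers_deterministic_rule(self):
        # clinical stage is an exact function of pathological stage
        recs = self._records(120, lambda p: p, missing_idx=set(range(0, 120, 7)))
        out = tc.impute_clinical_stage(recs, seed=3)
        for rec in out:
            assert rec.clinical_stage == rec.pathological_stage

    def test_deterministic_given_seed(self):
        recs = self._records(60, lambda p: max(1, p - 1), missing_idx={1, 9, 17})
        a = tc.impute_clinical_stage(recs, seed=11)
        b = tc.impute_clinical_stage(recs, seed=11)
        assert [r.clinical_stage for r in a] == [r.clinical_stage for r in b]

    def test_no_training_data_rejected(self):
        recs = self._records(10, lambda p: None, missing_idx=set(range(10)))
        with pytest.raises(ValueError):
            tc.impute_clinical_stage(recs)


class TestScaleCovariates:
    def test_two_point_column(self):
        mat = tc.CovariateMatrix(["a", "b"], ["struct:x"], np.array([[1.0], [3.0]]))
        scaled = tc.scale_covariates(mat)
        np.testing.assert_allclose(
            scaled.values.ravel(), [-1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12
        )

    def test_constant_column_zeroed_with_warning(self):
        mat = tc.CovariateMatrix(
            ["a", "b", "c"], ["struct:x"], np.array([[2.0], [2.0], [2.0]])
        )
        with pytest.warns(UserWarning, match="constant"):
            scaled = tc.scale_covariates(mat)
        assert np.all(scaled.values == 0)

    def test_idempotent_on_standardized_column(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std(ddof=1)
        mat = tc.CovariateMatrix(
            [f"p{i}" for i in range(50)], ["struct:x"], x[:, None]
        )
        scaled = tc.scale_covariates(mat)
        np.testing.assert_allclose(scaled.values, mat.values, atol=1e-12)
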