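"""Analysis-cohort construction and the structured covariate block.

Implements the cohort rules of the retrospective treatment comparison:
first-treatment group assignment (surgery / radiation / active monitoring),
a six-month survival landmark against immortal-time bias, the pre-treatment
note requirement, age bucketing, one-hot race/ethnicity encoding, median
grade imputation with an indicator, random-forest clinical-stage imputation
from pathological stage, and z-score standardization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .matrix import STRUCT_PREFIX, CovariateMatrix
from .textproc import NoteDocument, window_notes

logger = logging.getLogger(__name__)

Disease = Literal["prostate", "nsclc"]

#: pre-treatment note window, in days, per disease (2 months / 1 month)
NOTE_WINDOW_DAYS: dict[str, int] = {"prostate": 60, "nsclc": 30}

#: six-month survival landmark, in days
MIN_SURVIVAL_DAYS = 183


@dataclass
class PatientRecord:
    """One patient's structured fields, notes, treatments and outcome."""

    patient_id: str
    age: float
    gender: str  # "male" / "female"
    race: str  # "white" / "black" / "api" / "unknown"
    ethnicity: str  # "hispanic" / "non-hispanic" / "unknown"
    diagnosis_year: int
    survival_days: float
    event: int
    clinical_stage: Optional[int] = None  # ordinal I-IV -> 1-4
    pathological_stage: Optional[int] = None
    tumor_grade: Optional[int] = None  # ordinal 1-4
    treatment_records: list[tuple[str, float]] = field(default_factory=list)
    notes: list[NoteDocument] = field(default_factory=list)
    stage_missing_flag: bool = False

    def __post_init__(self) -> None:
        if self.survival_days <= 0:
            raise ValueError(f"{self.patient_id}: survival_days must be > 0")
        if self.event not in (0, 1):
            raise ValueError(f"{self.patient_id}: event must be 0 or 1")
        for modality, start in self.treatment_records:
            if start < 0:
                raise ValueError(f"{self.patient_id}: treatment start_day < 0")
            if modality not in ("surgery", "radiation"):
                raise ValueError(f"{self.patient_id}: unknown modality {modality!r}")

    def treatment_start(self) -> Optional[float]:
        if not self.treatment_records:
            return None
        return min(start for _, start in self.treatment_records)


@dataclass
class TreatmentAssignment:
    """Treatment-group label; ``group`` is None for excluded patients."""

    patient_id: str
    group: Optional[str]  # "surgery" / "radiation" / "monitoring" / None
    W: Optional[int] = None  # defined only inside a named two-group comparison


def assign_treatment_group(record: PatientRecord, disease: Disease) -> TreatmentAssignment:
    """Assign by the first treatment received; no treatment means monitoring
    (prostate) or exclusion (NSCLC).  Equal surgery/radiation start days have
    no defined rule and raise."""
    recs = record.treatment_records
    modalities = {m for m, _ in recs}
    if not recs:
        group = "monitoring" if disease == "prostate" else None
        return TreatmentAssignment(record.patient_id, group)
    if modalities == {"surgery"}:
        return TreatmentAssignment(record.patient_id, "surgery")
    if modalities == {"radiation"}:
        return TreatmentAssignment(record.patient_id, "radiation")
    first_surgery = min(s for m, s in recs if m == "surgery")
    first_radiation = min(s for m, s in recs if m == "radiation")
    if first_surgery == first_radiation:
        raise ValueError(
            f"patient {record.patient_id}: surgery and radiation start on the "
            f"same day ({first_surgery}); no assignment rule for ties"
        )
    group = "surgery" if first_surgery < first_radiation else "radiation"
    return TreatmentAssignment(record.patient_id, group)


def filter_cohort(
    records: Sequence[PatientRecord],
    disease: Disease,
    min_survival_days: float = MIN_SURVIVAL_DAYS,
    require_note: bool = True,
) -> list[PatientRecord]:
    """Apply the survival landmark and pre-treatment note requirement.

    Patients must survive at least ``min_survival_days`` past diagnosis
    (inclusive).  With ``require_note``, treated patients need at least one
    note inside the pre-treatment window for the disease; monitoring
    patients (no treatment date) need at least one note of any date.
    """
    if min_survival_days <= 0:
        raise ValueError("min_survival_days must be > 0")
    window = NOTE_WINDOW_DAYS[disease]
    kept = []
    for rec in records:
        if rec.survival_days < min_survival_days:
            continue
        if require_note:
            start = rec.treatment_start()
            usable = rec.notes if start is None else window_notes(rec.notes, start, window)
            if not usable:
                continue
        kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# age buckets

_AGE_EDGES = list(range(50, 90, 5))  # 50, 55, ..., 85


def bucket_age(age: float) -> str:
    """Bucket age as <=49, 5-year bands 50-84, and >=85."""
    if age < 0:
        raise ValueError("age must be >= 0")
    if age <= 49:
        return "<=49"
    if age >= 85:
        return ">=85"
    lo = 50 + 5 * int((age - 50) // 5)
    return f"{lo}-{lo + 4}"


def age_bucket_index(age: float) -> int:
    """Ordinal index of the age bucket (<=49 -> 0, ..., >=85 -> 8)."""
    if age < 0:
        raise ValueError("age must be >= 0")
    if age <= 49:
        return 0
    if age >= 85:
        return 8
    return 1 + int((age - 50) // 5)


# ---------------------------------------------------------------------------
# structured encoding

_RACE_LEVELS = ("white", "api", "black")


def encode_structured(records: Sequence[PatientRecord], disease: Disease) -> CovariateMatrix:
    """Build the structured covariate block.

    Prostate: patient_age, race_white/api/black, hispanic, clinical_stage,
    diagnosis_year, tumor_grade, grade_unknown (9 columns).  NSCLC: the
    stage column is dropped (the cohort is restricted to clinical stage I)
    and gender is added, giving 7 columns.  Unknown race or ethnicity
    contributes all-zero indicators; unknown grade is imputed with the
    median observed grade and flagged.
    """
    if not records:
        raise ValueError("no records to encode")
    n = len(records)
    cols: dict[str, np.ndarray] = {}
    cols["patient_age"] = np.array([age_bucket_index(r.age) for r in records], float)
    if disease == "nsclc":
        cols["male"] = np.array([1.0 if r.gender == "male" else 0.0 for r in records])
    for level in _RACE_LEVELS:
        cols[f"race_{level}"] = np.array([1.0 if r.race == level else 0.0 for r in records])
    cols["hispanic"] = np.array([1.0 if r.ethnicity == "hispanic" else 0.0 for r in records])
    if disease == "prostate":
        stages = np.array(
            [r.clinical_stage if r.clinical_stage is not None else np.nan for r in records]
        )
        if np.isnan(stages).any():
            missing = [records[i].patient_id for i in np.flatnonzero(np.isnan(stages))]
            raise ValueError(
                f"clinical stage missing for {missing[:5]}; run impute_clinical_stage first"
            )
        cols["clinical_stage"] = stages
    cols["diagnosis_year"] = np.array([float(r.diagnosis_year) for r in records])
    if disease == "prostate":
        grades = np.array(
            [r.tumor_grade if r.tumor_grade is not None else np.nan for r in records]
        )
        observed = grades[~np.isnan(grades)]
        if observed.size == 0:
            raise ValueError("all tumor grades missing; median undefined")
        median = float(np.median(observed))
        unknown = np.isnan(grades).astype(float)
        grades = np.where(np.isnan(grades), median, grades)
        cols["tumor_grade"] = grades
        cols["grade_unknown"] = unknown

    names = [STRUCT_PREFIX + c for c in cols]
    values = np.column_stack([cols[c] for c in cols]) if cols else np.empty((n, 0))
    return CovariateMatrix([r.patient_id for r in records], names, values)


def impute_clinical_stage(
    records: Sequence[PatientRecord], seed: int = 0
) -> list[PatientRecord]:
    """Impute missing clinical stage with a random forest.

    The model is trained on patients with both stages observed, using age
    bucket, pathological stage, diagnosis year and tumor grade; it predicts
    the clinical stage of patients missing it but having a pathological
    stage.  Patients missing both stages are flagged and left missing.
    """
    train = [r for r in records if r.clinical_stage is not None and r.pathological_stage is not None]
    if not train:
        raise ValueError("no records with both clinical and pathological stage")

    grades = [r.tumor_grade for r in records if r.tumor_grade is not None]
    grade_fill = float(np.median(grades)) if grades else 0.0

    def _features(r: PatientRecord) -> list[float]:
        return [
            float(age_bucket_index(r.age)),
            float(r.pathological_stage),  # type: ignore[arg-type]
            float(r.diagnosis_year),
            float(r.tumor_grade) if r.tumor_grade is not None else grade_fill,
        ]

    clf = RandomForestClassifier(n_estimators=100, random_state=seed)
    clf.fit([_features(r) for r in train], [r.clinical_stage for r in train])

    out: list[PatientRecord] = []
    for r in records:
        if r.clinical_stage is not None:
            out.append(r)
        elif r.pathological_stage is not None:
            pred = int(clf.predict([_features(r)])[0])
            out.append(replace(r, clinical_stage=pred))
        else:
            out.append(replace(r, stage_missing_flag=True))
    return out


def scale_covariates(matrix: CovariateMatrix) -> CovariateMatrix:
    """Z-score each column (sample SD, ddof=1); constant columns become 0."""
    if matrix.n_patients < 2:
        raise ValueError("need at least 2 rows to standardize")
    values = matrix.values.copy()
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        names = [matrix.column_names[j] for j in np.flatnonzero(constant)]
        warnings.warn(f"constant columns set to 0: {names}", stacklevel=2)
        logger.warning("constant columns set to 0: %s", names)
    sd_safe = np.where(constant, 1.0, sd)
    values = (values - mean) / sd_safe
    values[:, constant] = 0.0
    return CovariateMatrix(list(matrix.patient_ids), list(matrix.column_names), values)
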