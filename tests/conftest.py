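import logging
import warnings

import numpy as np
import pytest

import textconfound as tc

logging.getLogger("textconfound").setLevel(logging.ERROR)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning, module="lifelines")
        warnings.filterwarnings("ignore", message=".*convergence.*")
        yield


@pytest.fixture(scope="session")
def confounded_cohort():
    """n=1000 cohort with two planted text confounders and true HR = 1."""
    config = tc.SimulationConfig(n_patients=1000, seed=42)
    records, manifest = tc.generate_cohort(config)
    return config, records, manifest


@pytest.fixture()
def toy_text_config():
    return tc.TextFeatureConfig(
        entity_dictionary=frozenset(
            {"bladder", "obstruction", "history", "urothelial", "carcinoma", "smoking"}
        ),
        top_k=10,
    )


@pytest.fixture()
def simple_records():
    """Six hand-built prostate patients covering the cohort rules."""
    def note(pid, day, text="HISTORY: Patient reports ongoing bladder symptoms."):
        return tc.NoteDocument(pid, day, text)

    return [
        tc.PatientRecord(
            "A", 64, "male", "white", "non-hispanic", 2010, 400, 1,
            clinical_stage=2, pathological_stage=2, tumor_grade=2,
            treatment_records=[("surgery", 100.0)], notes=[note("A", 10.0)],
        ),
        tc.PatientRecord(
            "B", 71, "male", "api", "hispanic", 2012, 900, 0,
            clinical_stage=1, pathological_stage=2, tumor_grade=1,
            treatment_records=[("radiation", 120.0)], notes=[note("B", 30.0)],
        ),
        tc.PatientRecord(
            "C", 55, "male", "black", "non-hispanic", 2011, 250, 1,
            clinical_stage=3, pathological_stage=3, tumor_grade=3,
            treatment_records=[("radiation", 10.0), ("surgery", 40.0)],
            notes=[note("C", 5.0)],
        ),
        tc.PatientRecord(
            "D", 48, "male", "unknown", "unknown", 2009, 1200, 0,
            clinical_stage=2, pathological_stage=2, tumor_grade=None,
            treatment_records=[], notes=[note("D", 200.0)],
        ),
        tc.PatientRecord(
            "E", 83, "male", "white", "non-hispanic", 2015, 120, 1,
            clinical_stage=2, pathological_stage=3, tumor_grade=2,
            treatment_records=[("surgery", 90.0)], notes=[note("E", 20.0)],
        ),
        tc.PatientRecord(
            "F", 67, "male", "white", "non-hispanic", 2014, 700, 1,
            clinical_stage=4, pathological_stage=4, tumor_grade=4,
            treatment_records=[("surgery", 140.0)],
            notes=[note("F", 130.0)],  # inside the 60-day exclusion window
        ),
    ]


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
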