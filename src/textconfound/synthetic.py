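"""Synthetic EMR cohorts with known ground truth.

Generates patients whose treatment assignment follows a logistic model and
whose survival follows an exponential proportional-hazards model, both
driven by latent binary "condition" indicators that are also written into
free-text notes.  A term with positive treatment log-odds and positive
log-hazard is therefore a genuine text-borne confounder, and the manifest
records everything needed to score downstream recovery: latent indicators,
true propensities, and the true treatment log hazard ratio.

Notes are sentence-templated English: boilerplate head/tail sentences,
clinical field labels, one affirmative sentence per active condition, plus
optional short negated mentions of *inactive* conditions ("No history of
smoking.") that the downstream negation filter must discard.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import PatientRecord
from .textproc import NoteDocument

#: default vocabulary of candidate note terms (conditions / findings)
DEFAULT_VOCAB = (
    "bladder", "urothelial", "carcinoma", "obstruction", "copd", "smoking",
    "diabetes", "hypertension", "anemia", "fatigue", "dyspnea", "cough",
    "hematuria", "nocturia", "lesion", "nodule", "biopsy", "psa",
    "frailty", "dementia", "arthritis", "obesity", "insomnia", "edema",
    "neuropathy",
)


@dataclass(frozen=True)
class TermEffect:
    """Effects of one latent condition term.

    ``gamma_t`` is its treatment log-odds effect, ``gamma_y`` its log-hazard
    effect, and ``prevalence`` the Bernoulli rate of the latent indicator.
    A term with nonzero ``gamma_t`` *and* ``gamma_y`` is a planted confounder.
    """

    gamma_t: float
    gamma_y: float
    prevalence: float = 0.35


@dataclass(frozen=True)
class StructuredEffect:
    """Treatment log-odds / log-hazard effects of a structured covariate."""

    gamma_t: float
    gamma_y: float


@dataclass
class SimulationConfig:
    """Generative conditions for one synthetic cohort."""

    n_patients: int = 1000
    vocab: tuple[str, ...] = DEFAULT_VOCAB
    confounder_terms: Mapping[str, TermEffect] = field(
        default_factory=lambda: {
            "bladder": TermEffect(1.0, 1.0),
            "copd": TermEffect(1.0, 1.0, prevalence=0.30),
        }
    )
    structured_effects: Mapping[str, StructuredEffect] = field(
        default_factory=lambda: {
            "age": StructuredEffect(0.3, 0.5),
            "stage": StructuredEffect(0.2, 0.3),
        }
    )
    treatment_intercept: float = 0.0
    baseline_hazard_rate: float = 1.0 / 2000.0  # events per day
    true_treatment_loghr: float = 0.0
    censoring_rate: float = 0.2
    noise_term_rate: float = 2.0
    negated_mention_rate: float = 0.3
    seed: int = 0
    disease: str = "prostate"
    notes_per_patient: int = 3
    treatment_start_range: tuple[int, int] = (90, 150)
    note_window_days: int = 60

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("invalid config: n_patients must be >= 1")
        unknown = set(self.confounder_terms) - set(self.vocab)
        if unknown:
            raise ValueError(
                f"invalid config: confounder_terms not in vocab: {sorted(unknown)}"
            )
        if not (0.0 <= self.censoring_rate <= 1.0):
            raise ValueError("invalid config: censoring_rate must lie in [0, 1]")
        if self.baseline_hazard_rate <= 0:
            raise ValueError("invalid config: baseline_hazard_rate must be > 0")
        if not (0.0 <= self.negated_mention_rate <= 1.0):
            raise ValueError("invalid config: negated_mention_rate must lie in [0, 1]")
        for name, eff in self.structured_effects.items():
            if name not in ("age", "stage", "grade"):
                raise ValueError(f"invalid config: unknown structured effect {name!r}")


@dataclass
class GroundTruthManifest:
    """Oracle record of the generative process for one cohort."""

    patient_ids: list[str]
    confounder_names: list[str]
    term_indicators: np.ndarray = field(repr=False)  # n x n_terms, {0,1}
    true_propensity: np.ndarray = field(repr=False)  # in (0,1)
    true_treatment_loghr: float = 0.0
    W: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    survival_days: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    event: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    structured: Optional[pd.DataFrame] = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not (np.all(self.true_propensity > 0) and np.all(self.true_propensity < 1)):
            raise ValueError("true propensity must lie strictly inside (0, 1)")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "patient_ids": self.patient_ids,
            "confounder_names": self.confounder_names,
            "term_indicators": self.term_indicators.astype(int).tolist(),
            "true_propensity": self.true_propensity.tolist(),
            "true_treatment_loghr": self.true_treatment_loghr,
            "W": self.W.astype(int).tolist(),
            "survival_days": self.survival_days.tolist(),
            "event": self.event.astype(int).tolist(),
            "structured": None if self.structured is None else self.structured.to_dict("list"),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            patient_ids=d["patient_ids"],
            confounder_names=d["confounder_names"],
            term_indicators=np.asarray(d["term_indicators"], float),
            true_propensity=np.asarray(d["true_propensity"], float),
            true_treatment_loghr=d["true_treatment_loghr"],
            W=np.asarray(d["W"], int),
            survival_days=np.asarray(d["survival_days"], float),
            event=np.asarray(d["event"], int),
            structured=None if d["structured"] is None else pd.DataFrame(d["structured"]),
        )


# ---------------------------------------------------------------------------
# note rendering

_BOILER_HEAD = (
    "Example Medical Center, Oncology Clinic.",
    "Seen in consultation by John Smith, M.D.",
)
_BOILER_TAIL = (
    "Return to clinic as scheduled.",
    "Electronically signed by John Smith, M.D.",
)

_AFFIRMATIVE_TEMPLATES = (
    "Patient reports ongoing {term} symptoms.",
    "Assessment significant for {term} on review.",
    "Findings consistent with {term} were discussed.",
)


def render_note(
    active_terms: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator,
    inactive_terms: Sequence[str] = (),
) -> str:
    """Render one note for a patient's active latent terms.

    Every active term appears in at least one affirmative sentence.  With
    probability ``negated_mention_rate`` a short negated sentence about an
    inactive term is added; the downstream negation filter must remove it.
    Boilerplate head/tail sentences and a field label exercise the
    boilerplate-stripping stage.
    """
    body: list[str] = []
    for term in active_terms:
        template = _AFFIRMATIVE_TEMPLATES[int(rng.integers(len(_AFFIRMATIVE_TEMPLATES)))]
        body.append(template.format(term=term))
    n_noise = int(rng.poisson(config.noise_term_rate))
    noise_pool = [t for t in config.vocab if t not in config.confounder_terms]
    for _ in range(n_noise):
        term = noise_pool[int(rng.integers(len(noise_pool)))]
        template = _AFFIRMATIVE_TEMPLATES[int(rng.integers(len(_AFFIRMATIVE_TEMPLATES)))]
        body.append(template.format(term=term))
    if inactive_terms and rng.random() < config.negated_mention_rate:
        term = inactive_terms[int(rng.integers(len(inactive_terms)))]
        body.append(f"No history of {term}.")
    if not body:
        body.append("Patient doing well overall today.")
    sentences = list(_BOILER_HEAD) + ["HISTORY: " + " ".join(body)] + list(_BOILER_TAIL)
    return " ".join(sentences)


# ---------------------------------------------------------------------------
# cohort generation


def _solve_censoring_rate(lambdas: np.ndarray, target: float) -> float:
    """Rate c of independent exponential censoring with P(C < T) = target."""

    def frac_censored(c: float) -> float:
        return float(np.mean(c / (c + lambdas))) - target

    return float(brentq(frac_censored, 1e-12, 1e6, xtol=1e-14))


def _draw_structured(n: int, rng: np.random.Generator, disease: str) -> pd.DataFrame:
    age = np.clip(rng.normal(68.0, 8.0, n), 40.0, 95.0)
    race = rng.choice(["white", "api", "black", "unknown"], n, p=[0.65, 0.12, 0.04, 0.19])
    ethnicity = rng.choice(
        ["hispanic", "non-hispanic", "unknown"], n, p=[0.06, 0.88, 0.06]
    )
    stage = rng.choice([1, 2, 3, 4], n, p=[0.30, 0.55, 0.10, 0.05])
    # pathological stage tends to sit one level above clinical stage
    path_stage = np.minimum(4, stage + (rng.random(n) < 0.3).astype(int))
    grade = rng.choice([1, 2, 3, 4], n, p=[0.25, 0.40, 0.30, 0.05]).astype(float)
    year = rng.integers(2008, 2018, n)
    # real registries are incomplete: mask some grades and clinical stages,
    # keeping the unmasked truth for the generative hazard/treatment models
    stage_true = stage.astype(float)
    grade_true = grade.copy()
    grade[rng.random(n) < 0.05] = np.nan
    stage = stage.astype(float)
    stage[rng.random(n) < 0.10] = np.nan
    if disease == "nsclc":
        gender = rng.choice(["male", "female"], n, p=[0.47, 0.53])
    else:
        gender = np.repeat("male", n)
    return pd.DataFrame(
        {
            "age": age,
            "gender": gender,
            "race": race,
            "ethnicity": ethnicity,
            "clinical_stage": stage,
            "clinical_stage_true": stage_true,
            "pathological_stage": path_stage,
            "tumor_grade": grade,
            "tumor_grade_true": grade_true,
            "diagnosis_year": year,
        }
    )


def _structured_design(struct: pd.DataFrame) -> dict[str, np.ndarray]:
    """Centered/scaled structured covariates entering the generative models."""
    return {
        "age": (struct["age"].to_numpy() - 68.0) / 8.0,
        "stage": struct["clinical_stage_true"].to_numpy() - 2.0,
        "grade": struct["tumor_grade_true"].to_numpy() - 2.0,
    }


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[PatientRecord], GroundTruthManifest]:
    """Simulate one cohort of patients with notes and a ground-truth manifest.

    Treatment is Bernoulli(sigmoid(eta)) with eta the sum of the intercept,
    structured effects, and gamma_t-weighted latent term indicators; the
    treated arm receives surgery, the control arm radiation.  Survival is
    exponential with hazard ``baseline * exp(gamma_y . Z + structured +
    b_w W)``; censoring is independent exponential with its rate solved to
    hit ``censoring_rate``.  Fixed seed gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    struct = _draw_structured(n, rng, config.disease)
    design = _structured_design(struct)

    conf_names = list(config.confounder_terms)
    prevalences = np.array([config.confounder_terms[t].prevalence for t in conf_names])
    Z = (rng.random((n, len(conf_names))) < prevalences).astype(float)

    gamma_t = np.array([config.confounder_terms[t].gamma_t for t in conf_names])
    gamma_y = np.array([config.confounder_terms[t].gamma_y for t in conf_names])

    eta_t = np.full(n, config.treatment_intercept)
    log_hazard = np.log(config.baseline_hazard_rate) * np.ones(n)
    for name, eff in config.structured_effects.items():
        eta_t += eff.gamma_t * design[name]
        log_hazard += eff.gamma_y * design[name]
    eta_t += Z @ gamma_t
    log_hazard += Z @ gamma_y

    propensity = expit(eta_t)
    W = (rng.random(n) < propensity).astype(int)
    log_hazard += config.true_treatment_loghr * W

    lambdas = np.exp(log_hazard)
    T = rng.exponential(1.0 / lambdas)
    if config.censoring_rate > 0:
        c = _solve_censoring_rate(lambdas, config.censoring_rate)
        C = rng.exponential(1.0 / c, n)
        survival = np.minimum(T, C)
        event = (T <= C).astype(int)
    else:
        survival = T
        event = np.ones(n, int)
    survival_days = np.maximum(1, np.ceil(survival)).astype(int)

    lo, hi = config.treatment_start_range
    starts = rng.integers(lo, hi + 1, n)

    records: list[PatientRecord] = []
    patient_ids = [f"P{i:05d}" for i in range(n)]
    for i, pid in enumerate(patient_ids):
        active = [conf_names[j] for j in range(len(conf_names)) if Z[i, j] == 1]
        inactive = [t for t in conf_names if t not in active]
        notes: list[NoteDocument] = []
        # first note guaranteed inside the usable pre-treatment region
        usable_end = max(1, int(starts[i]) - config.note_window_days)
        first_day = int(rng.integers(0, usable_end))
        note_days = [first_day] + [
            int(rng.integers(0, int(starts[i]) + 1))
            for _ in range(config.notes_per_patient - 1)
        ]
        for day in note_days:
            text = render_note(active, config, rng, inactive_terms=inactive)
            notes.append(NoteDocument(pid, float(day), text))
        modality = "surgery" if W[i] == 1 else "radiation"
        records.append(
            PatientRecord(
                patient_id=pid,
                age=float(struct["age"][i]),
                gender=str(struct["gender"][i]),
                race=str(struct["race"][i]),
                ethnicity=str(struct["ethnicity"][i]),
                diagnosis_year=int(struct["diagnosis_year"][i]),
                survival_days=float(survival_days[i]),
                event=int(event[i]),
                clinical_stage=(
                    None if np.isnan(struct["clinical_stage"][i])
                    else int(struct["clinical_stage"][i])
                ),
                pathological_stage=int(struct["pathological_stage"][i]),
                tumor_grade=(
                    None if np.isnan(struct["tumor_grade"][i])
                    else int(struct["tumor_grade"][i])
                ),
                treatment_records=[(modality, float(starts[i]))],
                notes=notes,
            )
        )

    manifest = GroundTruthManifest(
        patient_ids=patient_ids,
        confounder_names=conf_names,
        term_indicators=Z,
        true_propensity=propensity,
        true_treatment_loghr=config.true_treatment_loghr,
        W=W,
        survival_days=survival_days.astype(float),
        event=event,
        structured=struct,
    )
    return records, manifest


def oracle_marginal_hr(
    manifest: GroundTruthManifest, adjustment_set: Sequence[str] = ()
) -> float:
    """Cox HR for treatment adjusting for ground-truth latent indicators.

    Fits on the *latent* term indicators named in ``adjustment_set`` (not on
    text-derived covariates), providing the best-achievable reference that
    text featurization and selection are compared against.
    """
    from .survival import fit_cox  # local import to avoid a cycle

    if len(manifest.patient_ids) == 0:
        raise ValueError("empty cohort")
    unknown = set(adjustment_set) - set(manifest.confounder_names)
    if unknown:
        raise KeyError(f"terms not in manifest: {sorted(unknown)}")
    cols = {}
    for term in adjustment_set:
        j = manifest.confounder_names.index(term)
        cols[term] = manifest.term_indicators[:, j]
    X = pd.DataFrame(cols, index=manifest.patient_ids) if cols else None
    model = fit_cox(
        X,
        manifest.W,
        (manifest.survival_days, manifest.event),
    )
    return float(np.exp(model.coefficients["W"]))


# ---------------------------------------------------------------------------
# on-disk format

PATIENT_TABLE_COLUMNS = [
    "patient_id", "age", "gender", "race", "ethnicity", "clinical_stage",
    "pathological_stage", "tumor_grade", "diagnosis_year", "treatment",
    "treatment_start_day", "survival_days", "event",
]


def write_cohort(
    records: Sequence[PatientRecord],
    manifest: Optional[GroundTruthManifest],
    outdir: str | Path,
) -> None:
    """Write one UTF-8 text file per note, a patient TSV, and the manifest."""
    outdir = Path(outdir)
    notes_dir = outdir / "notes"
    notes_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    note_rows = []
    for rec in records:
        treatment = rec.treatment_records[0] if rec.treatment_records else ("", "")
        rows.append(
            [
                rec.patient_id, rec.age, rec.gender, rec.race, rec.ethnicity,
                rec.clinical_stage, rec.pathological_stage, rec.tumor_grade,
                rec.diagnosis_year, treatment[0], treatment[1],
                rec.survival_days, rec.event,
            ]
        )
        for k, note in enumerate(rec.notes):
            path = notes_dir / f"{rec.patient_id}_{k}.txt"
            path.write_text(note.text, encoding="utf-8")
            note_rows.append([rec.patient_id, note.date, str(path.relative_to(outdir))])
    pd.DataFrame(rows, columns=PATIENT_TABLE_COLUMNS).to_csv(
        outdir / "patients.tsv", sep="\t", index=False
    )
    pd.DataFrame(note_rows, columns=["patient_id", "date", "path"]).to_csv(
        outdir / "notes.tsv", sep="\t", index=False
    )
    if manifest is not None:
        manifest.to_json(outdir / "manifest.json")


def read_cohort(indir: str | Path) -> list[PatientRecord]:
    """Read a cohort directory written by :func:`write_cohort`."""
    indir = Path(indir)
    patients = pd.read_csv(indir / "patients.tsv", sep="\t")
    notes = pd.read_csv(indir / "notes.tsv", sep="\t")
    notes_by_pid: dict[str, list[NoteDocument]] = {}
    for _, row in notes.iterrows():
        text = (indir / row["path"]).read_text(encoding="utf-8")
        notes_by_pid.setdefault(str(row["patient_id"]), []).append(
            NoteDocument(str(row["patient_id"]), float(row["date"]), text)
        )
    records = []
    for _, row in patients.iterrows():
        pid = str(row["patient_id"])
        treatments = []
        if isinstance(row["treatment"], str) and row["treatment"]:
            treatments = [(row["treatment"], float(row["treatment_start_day"]))]
        records.append(
            PatientRecord(
                patient_id=pid,
                age=float(row["age"]),
                gender=str(row["gender"]),
                race=str(row["race"]),
                ethnicity=str(row["ethnicity"]),
                diagnosis_year=int(row["diagnosis_year"]),
                survival_days=float(row["survival_days"]),
                event=int(row["event"]),
                clinical_stage=None if pd.isna(row["clinical_stage"]) else int(row["clinical_stage"]),
                pathological_stage=None if pd.isna(row["pathological_stage"]) else int(row["pathological_stage"]),
                tumor_grade=None if pd.isna(row["tumor_grade"]) else int(row["tumor_grade"]),
                treatment_records=treatments,
                notes=notes_by_pid.get(pid, []),
            )
        )
    return records
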