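"""End-to-end orchestration and ΔHR reporting.

Runs cohort build -> note featurization -> dual-Lasso selection -> three
estimators x three covariate sets (structured, intersect, struct+intersect)
and summarizes each adjusted estimate by its shift relative to the
structured-only baseline of the same estimator: ``ΔHR = |baseline HR -
adjusted HR|``, as a percentage of the baseline HR, labelled "toward
equipoise" when the adjusted estimate moves closer to HR = 1.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    NOTE_WINDOW_DAYS,
    MIN_SURVIVAL_DAYS,
    PatientRecord,
    assign_treatment_group,
    encode_structured,
    filter_cohort,
    impute_clinical_stage,
    scale_covariates,
)
from .matrix import CovariateMatrix, concat_blocks
from .selection import (
    SelectionResult,
    fit_outcome_lasso_cox,
    fit_treatment_lasso,
    refit_unpenalized_outcome,
    refit_unpenalized_treatment,
    select_confounders,
)
from .survival import (
    HREstimate,
    PropensityFit,
    covariate_hr_table,
    estimate_propensity,
    hr_iptw,
    hr_matching,
    hr_multicoxph,
    select_propensity_model,
)
from .synthetic import GroundTruthManifest, SimulationConfig, generate_cohort, read_cohort
from .textproc import TextFeatureConfig, featurize_notes, window_notes

logger = logging.getLogger(__name__)

ESTIMATORS = ("matching", "iptw", "multi.coxph")
COVARIATE_SETS = ("structured", "intersect", "struct+intersect")
REPORT_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# ΔHR arithmetic


@dataclass(frozen=True)
class DeltaHR:
    """Shift of an adjusted HR relative to its baseline."""

    delta: float
    percent: float
    direction: str  # "toward equipoise" / "away from equipoise"


def delta_hr(baseline_hr: float, adjusted_hr: float) -> DeltaHR:
    """ΔHR = |baseline - adjusted|, as a percentage of the baseline.

    Values are rounded to the displayed precision (2 decimals for the
    delta, 1 for the percentage); the shift is "toward equipoise" when the
    adjusted estimate is closer to 1 than the baseline.
    """
    if baseline_hr <= 0 or adjusted_hr <= 0:
        raise ValueError("hazard ratios must be positive")
    delta = abs(baseline_hr - adjusted_hr)
    percent = 100.0 * delta / baseline_hr
    direction = (
        "toward equipoise"
        if abs(adjusted_hr - 1.0) < abs(baseline_hr - 1.0)
        else "away from equipoise"
    )
    return DeltaHR(round(delta, 2), round(percent, 1), direction)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Configuration of one comparison run."""

    simulation: Optional[SimulationConfig] = None
    input_dir: Optional[str] = None
    disease: str = "prostate"
    comparison: tuple[str, str] = ("surgery", "radiation")  # (treated, control)
    policy: str = "lambda.1se"
    folds: int = 10
    seed: int = 0
    min_survival_days: float = MIN_SURVIVAL_DAYS
    top_k: int = 100
    ngram_max: int = 1
    max_document_frequency: float = 0.7
    entity_dictionary: Optional[tuple[str, ...]] = None
    learners: tuple[str, ...] = ("logistic", "gradient_boosting", "random_forest")
    cross_fit: bool = True
    outdir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        if sim is not None:
            from .synthetic import StructuredEffect, TermEffect

            if "confounder_terms" in sim:
                sim["confounder_terms"] = {
                    k: TermEffect(*v) for k, v in sim["confounder_terms"].items()
                }
            if "structured_effects" in sim:
                sim["structured_effects"] = {
                    k: StructuredEffect(*v) for k, v in sim["structured_effects"].items()
                }
            if "vocab" in sim:
                sim["vocab"] = tuple(sim["vocab"])
            sim = SimulationConfig(**sim)
        for key in ("comparison", "learners", "entity_dictionary"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)


# ---------------------------------------------------------------------------
# report containers


@dataclass
class ComparisonReport:
    """All HR estimates and ΔHR summaries for one two-group comparison."""

    comparison: str
    estimates: dict[tuple[str, str], Optional[HREstimate]]  # (estimator, set)
    deltas: dict[tuple[str, str], Optional[DeltaHR]]
    selection: SelectionResult
    propensity_learner: dict[str, str]  # covariate set -> chosen learner
    counts: dict = field(default_factory=dict)
    covariate_table: Optional[pd.DataFrame] = field(default=None, repr=False)
    coefficient_table: Optional[pd.DataFrame] = field(default=None, repr=False)

    def baseline(self, estimator: str) -> Optional[HREstimate]:
        return self.estimates.get((estimator, "structured"))

    def to_dict(self) -> dict:
        def est_dict(e: Optional[HREstimate]) -> Optional[dict]:
            if e is None:
                return None
            return {
                "hr": round(e.hr, 6),
                "hr_display": round(e.hr, 2),
                "ci95": [round(e.ci95[0], 6), round(e.ci95[1], 6)],
                "p_value": round(e.p_value, 6),
                "n_used": e.n_used,
            }

        payload = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "comparison": self.comparison,
            "selection": {
                "policy": self.selection.policy,
                "intersection": sorted(self.selection.intersection),
                "treatment_support": sorted(self.selection.treatment_support),
                "outcome_support": sorted(self.selection.outcome_support),
                "diagnostic": self.selection.diagnostic,
            },
            "propensity_learner": self.propensity_learner,
            "counts": self.counts,
            "estimates": {},
        }
        for (estimator, cset), est in sorted(self.estimates.items()):
            entry = est_dict(est)
            d = self.deltas.get((estimator, cset))
            if entry is not None and d is not None:
                entry["delta_hr"] = d.delta
                entry["percent_shift"] = d.percent
                entry["direction"] = d.direction
            payload["estimates"][f"{estimator}|{cset}"] = (
                entry if entry is not None else "not estimated"
            )
        return payload

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# the analysis core


@dataclass
class PreparedComparison:
    """Cohort after group assignment, filtering and featurization."""

    records: list[PatientRecord]
    W: np.ndarray
    durations: np.ndarray
    events: np.ndarray
    covariates: CovariateMatrix  # scaled struct + text blocks
    n_structured: int


def prepare_comparison(
    records: Sequence[PatientRecord], config: PipelineConfig
) -> PreparedComparison:
    """Assign groups, filter the cohort, and build the scaled covariate matrix."""
    treated_group, control_group = config.comparison
    kept: list[PatientRecord] = []
    w_list: list[int] = []
    for rec in records:
        assignment = assign_treatment_group(rec, config.disease)  # type: ignore[arg-type]
        if assignment.group == treated_group:
            kept.append(rec)
            w_list.append(1)
        elif assignment.group == control_group:
            kept.append(rec)
            w_list.append(0)
    w_by_pid = {r.patient_id: w for r, w in zip(kept, w_list)}
    kept = filter_cohort(
        kept, config.disease, config.min_survival_days, require_note=True  # type: ignore[arg-type]
    )
    if not kept:
        raise ValueError("cohort is empty after filtering")
    W = np.array([w_by_pid[r.patient_id] for r in kept], int)

    if config.disease == "prostate" and any(r.clinical_stage is None for r in kept):
        kept = impute_clinical_stage(kept, seed=config.seed)
        kept = [r for r in kept if r.clinical_stage is not None]
        W = np.array([w_by_pid[r.patient_id] for r in kept], int)

    struct = encode_structured(kept, config.disease)  # type: ignore[arg-type]

    window = NOTE_WINDOW_DAYS[config.disease]
    notes_by_pid = {}
    for rec in kept:
        start = rec.treatment_start()
        docs = rec.notes if start is None else window_notes(rec.notes, start, window)
        notes_by_pid[rec.patient_id] = docs
    dictionary = config.entity_dictionary
    if dictionary is None and config.simulation is not None:
        dictionary = tuple(config.simulation.vocab)
    if dictionary is None:
        raise ValueError("entity_dictionary is required when not simulating")
    text_cfg = TextFeatureConfig(
        entity_dictionary=frozenset(dictionary),
        ngram_max=config.ngram_max,
        top_k=config.top_k,
        max_document_frequency=config.max_document_frequency,
    )
    text = featurize_notes(notes_by_pid, text_cfg)

    combined = scale_covariates(concat_blocks([struct, text]))
    durations = np.array([r.survival_days for r in kept], float)
    events = np.array([r.event for r in kept], int)
    return PreparedComparison(
        records=kept,
        W=W,
        durations=durations,
        events=events,
        covariates=combined,
        n_structured=struct.n_columns,
    )


def _covariate_sets(
    prepared: PreparedComparison, selection: SelectionResult
) -> dict[str, list[str]]:
    df = prepared.covariates.to_dataframe()
    nonconstant = set(df.columns[df.std() > 0])

    def _usable(cols: list[str]) -> list[str]:
        dropped = [c for c in cols if c not in nonconstant]
        if dropped:
            logger.info("dropping constant columns from adjustment: %s", dropped)
        return [c for c in cols if c in nonconstant]

    struct_cols = _usable(prepared.covariates.structured_columns())
    inter = _usable(sorted(selection.intersection))
    struct_inter = struct_cols + [c for c in inter if c not in struct_cols]
    return {
        "structured": struct_cols,
        "intersect": inter,
        "struct+intersect": struct_inter,
    }


def estimate_all(
    prepared: PreparedComparison,
    selection: SelectionResult,
    config: PipelineConfig,
) -> tuple[dict[tuple[str, str], Optional[HREstimate]], dict[str, str]]:
    """Run the three estimators on each covariate set."""
    X = prepared.covariates.to_dataframe()
    outcome = (prepared.durations, prepared.events)
    estimates: dict[tuple[str, str], Optional[HREstimate]] = {}
    learners_used: dict[str, str] = {}
    for cset, cols in _covariate_sets(prepared, selection).items():
        if not cols:
            for estimator in ESTIMATORS:
                estimates[(estimator, cset)] = None
            logger.info("covariate set %s is empty; marked not estimated", cset)
            continue
        fits = [
            estimate_propensity(
                X[cols], prepared.W, learner, seed=config.seed, cross_fit=config.cross_fit
            )
            for learner in config.learners
        ]
        best = select_propensity_model(fits)
        learners_used[cset] = best.learner
        estimates[("matching", cset)] = hr_matching(outcome, prepared.W, best, cset)
        estimates[("iptw", cset)] = hr_iptw(outcome, prepared.W, best, cset)
        est, _ = hr_multicoxph(outcome, prepared.W, best, X[cols], cset)
        estimates[("multi.coxph", cset)] = est
    return estimates, learners_used


def analyze_cohort(
    records: Sequence[PatientRecord],
    config: PipelineConfig,
) -> ComparisonReport:
    """Full analysis of one comparison on an in-memory cohort."""
    prepared = prepare_comparison(records, config)
    X = prepared.covariates
    outcome = (prepared.durations, prepared.events)

    tx_path = fit_treatment_lasso(X, prepared.W, folds=config.folds, seed=config.seed)
    out_path = fit_outcome_lasso_cox(X, outcome, folds=config.folds, seed=config.seed)
    selection = select_confounders(
        tx_path,
        out_path,
        policy=config.policy,
        n_events=int(prepared.events.sum()),
        n_structured=prepared.n_structured,
    )

    estimates, learners_used = estimate_all(prepared, selection, config)
    deltas: dict[tuple[str, str], Optional[DeltaHR]] = {}
    for estimator in ESTIMATORS:
        base = estimates.get((estimator, "structured"))
        for cset in COVARIATE_SETS:
            est = estimates.get((estimator, cset))
            if base is None or est is None or cset == "structured":
                deltas[(estimator, cset)] = None
            else:
                deltas[(estimator, cset)] = delta_hr(base.hr, est.hr)

    sets = _covariate_sets(prepared, selection)
    cov_table = None
    coef_table = None
    if sets["struct+intersect"]:
        cov_table = covariate_hr_table(
            X.to_dataframe()[sets["struct+intersect"]],
            prepared.W,
            outcome,
            intersection=selection.intersection,
        )
        refit_cols = sets["struct+intersect"]
        coef_table = pd.DataFrame(
            {
                "treatment_coef": refit_unpenalized_treatment(X, prepared.W, refit_cols),
                "outcome_coef": refit_unpenalized_outcome(X, outcome, refit_cols),
            }
        )

    report = ComparisonReport(
        comparison=f"{config.comparison[0]} vs {config.comparison[1]}",
        estimates=estimates,
        deltas=deltas,
        selection=selection,
        propensity_learner=learners_used,
        counts={
            "n_patients": len(prepared.records),
            "n_treated": int(prepared.W.sum()),
            "n_control": int((1 - prepared.W).sum()),
            "n_events": int(prepared.events.sum()),
            "n_covariates": X.n_columns,
            "n_structured": prepared.n_structured,
            "seed": config.seed,
        },
        covariate_table=cov_table,
        coefficient_table=coef_table,
    )
    return report


def run_pipeline(config: PipelineConfig | str | Path) -> ComparisonReport:
    """Execute the full workflow and write artifacts when an outdir is set."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    if config.simulation is not None:
        sim = replace(config.simulation, seed=config.simulation.seed or config.seed)
        records, _manifest = generate_cohort(sim)
        logger.info("generated synthetic cohort: n=%d", len(records))
    elif config.input_dir is not None:
        records = read_cohort(config.input_dir)
        logger.info("read cohort from %s: n=%d", config.input_dir, len(records))
    else:
        raise ValueError("config must name either a simulation or an input_dir")

    report = analyze_cohort(records, config)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_json(outdir / "report.json")
        report.selection.to_json(outdir / "selection.json")
        if report.covariate_table is not None:
            report.covariate_table.to_csv(outdir / "covariate_hr_table.tsv", sep="\t", index=False)
        if report.coefficient_table is not None:
            report.coefficient_table.to_csv(outdir / "selected_coefficients.tsv", sep="\t")
        try:
            forest_plot(report, outdir / "forest.svg")
        except Exception as exc:  # plotting must never sink the analysis
            logger.warning("forest plot failed: %s", exc)
    return report


# ---------------------------------------------------------------------------
# multi-seed validation harness


def validate_recovery(
    config: PipelineConfig, n_seeds: int, light: bool = True
) -> pd.DataFrame:
    """Across-seed summary of selection recall and log-HR bias per method.

    For each seed a fresh cohort is generated under ``config.simulation``;
    the summary tabulates the recall of planted confounder terms, the
    absolute log-HR bias of every estimator x covariate set, and the
    fraction of seeds where struct+intersect beats structured-only.
    ``light`` restricts propensity estimation to the logistic learner to
    keep many-seed sweeps affordable.
    """
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    if config.simulation is None:
        raise ValueError("validate_recovery requires a simulation config")

    rows = []
    base = config.simulation
    planted = [
        t for t, eff in base.confounder_terms.items()
        if eff.gamma_t != 0 and eff.gamma_y != 0
    ]
    run_cfg = dataclasses.replace(
        config, learners=("logistic",) if light else config.learners
    )
    for s in range(n_seeds):
        sim = replace(base, seed=base.seed + 1000 + s)
        records, manifest = generate_cohort(sim)
        run_cfg = dataclasses.replace(run_cfg, seed=sim.seed)
        report = analyze_cohort(records, run_cfg)
        recovered = {t for t in planted if f"text:{t}" in report.selection.intersection}
        b_w = manifest.true_treatment_loghr
        row = {
            "seed": sim.seed,
            "recall": len(recovered) / len(planted) if planted else np.nan,
        }
        for (estimator, cset), est in report.estimates.items():
            if est is not None:
                row[f"bias|{estimator}|{cset}"] = abs(est.log_hr - b_w)
        rows.append(row)
    summary = pd.DataFrame(rows)
    for estimator in ESTIMATORS:
        a = summary.get(f"bias|{estimator}|struct+intersect")
        b = summary.get(f"bias|{estimator}|structured")
        if a is not None and b is not None:
            summary[f"win|{estimator}"] = (a < b).astype(float)
    return summary


# ---------------------------------------------------------------------------
# forest plot


def forest_plot(report: ComparisonReport, path: str | Path) -> None:
    """Forest plot of all estimates, labelled "HR [CI]; p; ΔHR"."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = [
        (estimator, cset, report.estimates.get((estimator, cset)))
        for estimator in ESTIMATORS
        for cset in COVARIATE_SETS
    ]
    fig, ax = plt.subplots(figsize=(8, 0.5 * len(rows) + 1.5))
    ypos = np.arange(len(rows))[::-1]
    for y, (estimator, cset, est) in zip(ypos, rows):
        label = f"{estimator} / {cset}"
        if est is None:
            ax.text(1.0, y, "not estimated", va="center", fontsize=8, color="gray")
        else:
            d = report.deltas.get((estimator, cset))
            delta_txt = f"; ΔHR {d.delta:.2f}" if d is not None else ""
            ax.errorbar(
                est.hr, y,
                xerr=[[est.hr - est.ci95[0]], [est.ci95[1] - est.hr]],
                fmt="s", color="black", capsize=3,
            )
            ax.text(
                ax.get_xlim()[1], y,
                f"{est.hr:.2f} [{est.ci95[0]:.2f}, {est.ci95[1]:.2f}]; "
                f"p={est.p_value:.3f}{delta_txt}",
                va="center", fontsize=7,
            )
        ax.text(-0.02, y, label, va="center", ha="right", fontsize=8,
                transform=ax.get_yaxis_transform())
    ax.axvline(1.0, color="gray", linestyle="--", linewidth=0.8)
    ax.set_yticks([])
    ax.set_xlabel("Hazard ratio (log scale)")
    ax.set_xscale("log")
    ax.set_title(report.comparison)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
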