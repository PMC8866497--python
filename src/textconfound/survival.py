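"""Propensity-adjusted hazard-ratio estimation.

Three estimators of the treatment hazard ratio, all built on Cox
proportional-hazards regression with robust (sandwich) variance and Efron
tie handling:

* ``matching``  — 1:1 greedy nearest-neighbor propensity matching without
  replacement, then a univariate Cox model on the matched sample;
* ``iptw``      — univariate Cox model weighted by stabilized inverse
  propensity weights ``w = W + (1 - W) e/(1 - e)``, which reweight controls
  to the treated population;
* ``multi.coxph`` — a multivariate Cox model on treatment plus the selected
  covariates, IPTW-weighted, giving a doubly robust estimate.

Propensity scores come from logistic regression, gradient boosting, or a
random forest; the model with the best post-weighting covariate balance
(mean absolute standardized mean difference) subject to adequate overlap is
selected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .matrix import CovariateMatrix

logger = logging.getLogger(__name__)

PROPENSITY_LEARNERS = ("logistic", "gradient_boosting", "random_forest")
#: positivity clip bounds for estimated propensity scores
SCORE_CLIP = (0.01, 0.99)
#: an arm with more than this fraction of clipped scores fails overlap
MAX_CLIP_FRACTION = 0.05


# ---------------------------------------------------------------------------
# Cox model


@dataclass
class CoxModel:
    """Fitted Cox proportional-hazards model (robust variance)."""

    coefficients: pd.Series
    se: pd.Series
    p_values: pd.Series
    ci95: pd.DataFrame  # columns "low", "high" on the HR scale
    variance: pd.DataFrame
    baseline_hazard: pd.DataFrame
    n: int
    n_events: int

    @property
    def hr(self) -> pd.Series:
        return np.exp(self.coefficients)


def _as_dataframe(X, ids=None) -> Optional[pd.DataFrame]:
    if X is None:
        return None
    if isinstance(X, CovariateMatrix):
        return X.to_dataframe()
    return pd.DataFrame(X)


def fit_cox(
    X: Optional[pd.DataFrame | CovariateMatrix],
    W: Optional[np.ndarray],
    outcome: tuple[np.ndarray, np.ndarray],
    weights: Optional[np.ndarray] = None,
) -> CoxModel:
    """Fit a (weighted) Cox PH model of the outcome on [W, X].

    Efron tie handling; robust sandwich variance with weights treated as
    fixed.  ``X`` and ``W`` may each be omitted (e.g., a univariate model on
    the treatment passes ``X=None``).
    """
    durations = np.asarray(outcome[0], float)
    events = np.asarray(outcome[1], int)
    if events.sum() == 0:
        raise ValueError("no events observed; Cox model is undefined")
    if weights is not None and np.any(np.asarray(weights) < 0):
        raise ValueError("weights must be non-negative")

    df = pd.DataFrame({"_duration": durations, "_event": events})
    if W is not None:
        df["W"] = np.asarray(W, float)
    Xdf = _as_dataframe(X)
    if Xdf is not None:
        for c in Xdf.columns:
            df[c] = Xdf[c].to_numpy()
    if weights is not None:
        df["_w"] = np.asarray(weights, float)

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(
                df,
                duration_col="_duration",
                event_col="_event",
                weights_col="_w" if weights is not None else None,
                robust=True,
                fit_options={"precision": 1e-12, "max_steps": 500},
            )
        except Exception as exc:  # lifelines ConvergenceError and friends
            raise RuntimeError(f"Cox model failed to converge: {exc}") from exc

    summary = cph.summary
    return CoxModel(
        coefficients=summary["coef"].copy(),
        se=summary["se(coef)"].copy(),
        p_values=summary["p"].copy(),
        ci95=pd.DataFrame(
            {
                "low": np.exp(summary["coef lower 95%"]),
                "high": np.exp(summary["coef upper 95%"]),
            }
        ),
        variance=cph.variance_matrix_.copy(),
        baseline_hazard=cph.baseline_hazard_.copy(),
        n=len(df),
        n_events=int(events.sum()),
    )


# ---------------------------------------------------------------------------
# propensity estimation


@dataclass
class PropensityFit:
    """Cross-fitted propensity scores with balance/overlap diagnostics."""

    learner: str
    scores: np.ndarray = field(repr=False)
    balance: pd.DataFrame = field(repr=False)  # smd_before / smd_after per covariate
    overlap: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.scores <= 0) or np.any(self.scores >= 1):
            raise ValueError("propensity scores must lie strictly inside (0, 1)")

    @property
    def mean_abs_smd_after(self) -> float:
        return float(self.balance["smd_after"].abs().mean())


def _make_learner(learner: str, seed: int):
    if learner == "logistic":
        return LogisticRegression(max_iter=2000)
    if learner == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if learner == "random_forest":
        return RandomForestClassifier(
            n_estimators=200, min_samples_leaf=10, random_state=seed
        )
    raise ValueError(f"unknown learner {learner!r}; expected one of {PROPENSITY_LEARNERS}")


def _smd(x: np.ndarray, W: np.ndarray, weights: Optional[np.ndarray] = None) -> float:
    """Standardized mean difference between arms, optionally weighted."""
    if weights is None:
        weights = np.ones_like(W, dtype=float)
    wt, wc = weights[W == 1], weights[W == 0]
    xt, xc = x[W == 1], x[W == 0]
    mt = np.average(xt, weights=wt)
    mc = np.average(xc, weights=wc)
    vt = np.average((xt - mt) ** 2, weights=wt)
    vc = np.average((xc - mc) ** 2, weights=wc)
    pooled = np.sqrt((vt + vc) / 2.0)
    if pooled == 0:
        return 0.0
    return float((mt - mc) / pooled)


def estimate_propensity(
    X: pd.DataFrame | CovariateMatrix,
    W: np.ndarray,
    learner: str = "logistic",
    seed: int = 0,
    cross_fit: bool = True,
) -> PropensityFit:
    """Estimate e(X) = P(W=1 | X) with the named learner.

    Scores are cross-fitted (2-fold by default) so that balance diagnostics
    are not flattered by in-sample overfitting, then clipped to
    ``SCORE_CLIP`` for positivity.  Balance is the per-covariate SMD before
    and after stabilized weighting.
    """
    Xdf = _as_dataframe(X)
    W = np.asarray(W, int)
    if len(np.unique(W)) < 2:
        raise ValueError("both treatment arms must be present")
    Xmat = Xdf.to_numpy(float)
    scores = np.empty(len(W), float)
    if cross_fit:
        splitter = StratifiedKFold(n_splits=2, shuffle=True, random_state=seed)
        for train, test in splitter.split(Xmat, W):
            model = _make_learner(learner, seed)
            model.fit(Xmat[train], W[train])
            scores[test] = model.predict_proba(Xmat[test])[:, 1]
    else:
        model = _make_learner(learner, seed)
        model.fit(Xmat, W)
        scores = model.predict_proba(Xmat)[:, 1]

    lo, hi = SCORE_CLIP
    clipped_low = scores < lo
    clipped_high = scores > hi
    scores = np.clip(scores, lo, hi)
    overlap = {
        "clip_fraction_treated": float((clipped_low | clipped_high)[W == 1].mean()),
        "clip_fraction_control": float((clipped_low | clipped_high)[W == 0].mean()),
        "score_mean_treated": float(scores[W == 1].mean()),
        "score_mean_control": float(scores[W == 0].mean()),
    }

    weights = stabilized_weights(scores, W)
    balance = pd.DataFrame(
        {
            "smd_before": [_smd(Xmat[:, j], W) for j in range(Xmat.shape[1])],
            "smd_after": [_smd(Xmat[:, j], W, weights) for j in range(Xmat.shape[1])],
        },
        index=list(Xdf.columns),
    )
    return PropensityFit(learner=learner, scores=scores, balance=balance, overlap=overlap)


def select_propensity_model(fits: Sequence[PropensityFit]) -> PropensityFit:
    """Pick the fit with best post-weighting balance, subject to overlap.

    A fit fails overlap when either arm has more than ``MAX_CLIP_FRACTION``
    of its scores clipped.  Ties in mean |SMD| break by the fixed preference
    order logistic > gradient_boosting > random_forest.
    """
    if not fits:
        raise ValueError("no propensity fits supplied")
    ok = [
        f
        for f in fits
        if max(f.overlap["clip_fraction_treated"], f.overlap["clip_fraction_control"])
        <= MAX_CLIP_FRACTION
    ]
    if not ok:
        raise ValueError(
            "every propensity model fails the overlap check; "
            "revise the covariate set or trimming"
        )
    order = {name: i for i, name in enumerate(PROPENSITY_LEARNERS)}
    best = min(ok, key=lambda f: (round(f.mean_abs_smd_after, 12), order[f.learner]))
    logger.info(
        "selected propensity learner %s (mean |SMD| after = %.4f)",
        best.learner, best.mean_abs_smd_after,
    )
    return best


def stabilized_weights(fit: PropensityFit | np.ndarray, W: np.ndarray) -> np.ndarray:
    """Stabilized IPT weights: treated get 1, controls their propensity odds."""
    scores = fit.scores if isinstance(fit, PropensityFit) else np.asarray(fit, float)
    W = np.asarray(W, int)
    if np.any(scores <= 0) or np.any(scores >= 1):
        raise ValueError("propensity scores must lie strictly inside (0, 1)")
    return W + (1 - W) * scores / (1.0 - scores)


# ---------------------------------------------------------------------------
# matching


def nnm_match(fit: PropensityFit | np.ndarray, W: np.ndarray) -> list[tuple[int, int]]:
    """1:1 greedy nearest-neighbor matching on the propensity score.

    Without replacement; units of the matched-from arm are processed in
    descending score order and each takes the nearest still-available
    partner.  The minority arm is always matched into the majority pool:
    when treated units outnumber controls the roles are swapped, otherwise
    greedy matching would exhaust the pool and retain precisely the
    highest-propensity (most confounded) treated patients.  Returns
    (treated_index, control_index) pairs; unmatched units are dropped
    (their count is logged).
    """
    scores = fit.scores if isinstance(fit, PropensityFit) else np.asarray(fit, float)
    W = np.asarray(W, int)
    treated = np.flatnonzero(W == 1)
    controls = np.flatnonzero(W == 0)
    if treated.size == 0 or controls.size == 0:
        raise ValueError("both arms must be non-empty for matching")
    swap = treated.size > controls.size
    if swap:
        source, pool = controls, treated
        logger.info("nnm_match: treated arm is larger; matching controls into it")
    else:
        source, pool = treated, controls
    order = source[np.argsort(-scores[source], kind="stable")]
    available = list(pool)
    pairs: list[tuple[int, int]] = []
    for s in order:
        if not available:
            break
        dists = np.abs(scores[available] - scores[s])
        j = int(np.argmin(dists))  # ties -> lowest index among available
        partner = int(available.pop(j))
        pairs.append((partner, int(s)) if swap else (int(s), partner))
    n_unmatched = (treated.size - len(pairs)) + (controls.size - len(pairs))
    if n_unmatched:
        logger.info("nnm_match: %d units left unmatched", n_unmatched)
    return pairs


# ---------------------------------------------------------------------------
# HR estimators


@dataclass
class HREstimate:
    """Treatment hazard ratio from one estimator / covariate set."""

    estimator: str  # "matching" / "iptw" / "multi.coxph"
    covariate_set: str  # "structured" / "intersect" / "struct+intersect"
    hr: float
    ci95: tuple[float, float]
    p_value: float
    n_used: int
    log_hr: float = 0.0
    se: float = 0.0

    def __post_init__(self) -> None:
        if not (self.ci95[0] <= self.hr <= self.ci95[1]):
            raise ValueError("HR must lie inside its confidence interval")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")


def _treatment_estimate(
    model: CoxModel, estimator: str, covariate_set: str
) -> HREstimate:
    return HREstimate(
        estimator=estimator,
        covariate_set=covariate_set,
        hr=float(np.exp(model.coefficients["W"])),
        ci95=(float(model.ci95.loc["W", "low"]), float(model.ci95.loc["W", "high"])),
        p_value=float(model.p_values["W"]),
        n_used=model.n,
        log_hr=float(model.coefficients["W"]),
        se=float(model.se["W"]),
    )


def hr_matching(
    outcome: tuple[np.ndarray, np.ndarray],
    W: np.ndarray,
    fit: PropensityFit,
    covariate_set: str = "structured",
    pairs: Optional[list[tuple[int, int]]] = None,
) -> HREstimate:
    """Univariate Cox HR on the 1:1 propensity-matched subsample."""
    if pairs is None:
        pairs = nnm_match(fit, W)
    idx = np.array([i for pair in pairs for i in pair], int)
    durations = np.asarray(outcome[0], float)[idx]
    events = np.asarray(outcome[1], int)[idx]
    if events.sum() == 0:
        raise ValueError("no events in the matched subsample")
    model = fit_cox(None, np.asarray(W)[idx], (durations, events))
    return _treatment_estimate(model, "matching", covariate_set)


def hr_iptw(
    outcome: tuple[np.ndarray, np.ndarray],
    W: np.ndarray,
    fit: PropensityFit,
    covariate_set: str = "structured",
) -> HREstimate:
    """Univariate Cox HR with stabilized inverse propensity weighting."""
    weights = stabilized_weights(fit, W)
    model = fit_cox(None, W, outcome, weights=weights)
    return _treatment_estimate(model, "iptw", covariate_set)


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cols: list[np.ndarray] = [np.ones(len(X))]
        for name in X.columns:
            cand = np.column_stack(cols + [X[name].to_numpy(float)])
            if np.linalg.matrix_rank(cand) == len(cols):
                bad.append(name)
            else:
                cols.append(X[name].to_numpy(float))
        raise ValueError(f"singular design; collinear columns: {bad}")


def hr_multicoxph(
    outcome: tuple[np.ndarray, np.ndarray],
    W: np.ndarray,
    fit: Optional[PropensityFit],
    X: pd.DataFrame | CovariateMatrix,
    covariate_set: str = "struct+intersect",
) -> tuple[HREstimate, CoxModel]:
    """Doubly robust multivariate Cox model: [W, covariates], IPTW-weighted.

    Returns the treatment-row estimate plus the full fitted model (the
    per-covariate rows feed the covariate HR tables).
    """
    Xdf = _as_dataframe(X)
    events = np.asarray(outcome[1], int)
    if Xdf is not None and Xdf.shape[1] > 0:
        _check_full_rank(Xdf)
        if events.sum() < 10 * (Xdf.shape[1] + 1):
            warnings.warn(
                f"{events.sum()} events for {Xdf.shape[1] + 1} model terms violates "
                "the 1-in-10 rule of thumb; estimates may be unstable",
                stacklevel=2,
            )
    weights = stabilized_weights(fit, W) if fit is not None else None
    model = fit_cox(Xdf, W, outcome, weights=weights)
    return _treatment_estimate(model, "multi.coxph", covariate_set), model


def covariate_hr_table(
    X: pd.DataFrame | CovariateMatrix,
    W: np.ndarray,
    outcome: tuple[np.ndarray, np.ndarray],
    intersection: Sequence[str] = (),
) -> pd.DataFrame:
    """Univariate and multivariate per-covariate HR table (unweighted).

    One univariate Cox model per covariate plus one joint multivariate
    model, with Wald 95% CIs and p-values; the treatment row comes first and
    intersection-selected covariates are marked.
    """
    Xdf = _as_dataframe(X)
    rows = []
    uni_w = fit_cox(None, W, outcome)
    multi = fit_cox(Xdf, W, outcome)

    def _row(name: str, uni: CoxModel, label: str) -> dict:
        return {
            "covariate": label,
            "uni_hr": float(np.exp(uni.coefficients[name])),
            "uni_ci_low": float(uni.ci95.loc[name, "low"]),
            "uni_ci_high": float(uni.ci95.loc[name, "high"]),
            "uni_p": float(uni.p_values[name]),
            "multi_hr": float(np.exp(multi.coefficients[label.rstrip('*')])),
            "multi_ci_low": float(multi.ci95.loc[label.rstrip('*'), "low"]),
            "multi_ci_high": float(multi.ci95.loc[label.rstrip('*'), "high"]),
            "multi_p": float(multi.p_values[label.rstrip('*')]),
        }

    rows.append(_row("W", uni_w, "W"))
    for name in Xdf.columns:
        uni = fit_cox(Xdf[[name]], None, outcome)
        label = name + ("*" if name in set(intersection) else "")
        row = _row(name, uni, label)
        rows.append(row)
    return pd.DataFrame(rows)
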