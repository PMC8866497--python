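"""Uncover potential confounders by dual-Lasso support intersection.

Fits an L1 logistic model for treatment and an L1 Cox model for survival
on the same covariate matrix, then intersects their supports at the
lambda.1se penalty. On this cohort the planted terms should be recovered.
"""

import textconfound as tc
from textconfound.pipeline import prepare_comparison

sim = tc.SimulationConfig(n_patients=1000, seed=7)
records, manifest = tc.generate_cohort(sim)
config = tc.PipelineConfig(simulation=sim, seed=7, top_k=25)

prepared = prepare_comparison(records, config)
print(f"analysis cohort: {len(prepared.records)} patients, "
      f"{int(prepared.events.sum())} events, "
      f"{prepared.covariates.n_columns} covariates")

tx = tc.fit_treatment_lasso(prepared.covariates, prepared.W, seed=7)
sv = tc.fit_outcome_lasso_cox(
    prepared.covariates, (prepared.durations, prepared.events), seed=7
)
result = tc.select_confounders(tx, sv, policy="lambda.1se",
                               n_events=int(prepared.events.sum()))

print("treatment support:", sorted(tx.support("lambda.1se")))
print("outcome support:  ", sorted(sv.support("lambda.1se")))
print("intersection:     ", sorted(result.intersection))
print("planted terms:    ", sorted(manifest.confounder_names))
# Covariates in the intersection predict BOTH treatment and survival —
# the operational definition of a potential confounder.
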