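"""Estimate the treatment HR under matching, IPTW, and multi.coxph.

Runs the full pipeline on a confounded synthetic cohort (true HR = 1) and
prints the 3 estimators x 3 covariate sets grid with ΔHR shifts relative
to the structured-only baseline.
"""

import textconfound as tc

config = tc.PipelineConfig(
    simulation=tc.SimulationConfig(n_patients=1000, seed=7),
    seed=7,
    learners=("logistic",),
    top_k=25,
)
report = tc.run_pipeline(config)

print(f"comparison: {report.comparison}")
print(f"intersection: {sorted(report.selection.intersection)}")
print(f"{'estimator':<12} {'covariates':<18} {'HR':>6} {'95% CI':>16} "
      f"{'p':>7} {'ΔHR':>5} {'shift':>7}")
for (estimator, cset), est in sorted(report.estimates.items()):
    if est is None:
        print(f"{estimator:<12} {cset:<18} not estimated")
        continue
    d = report.deltas.get((estimator, cset))
    delta = f"{d.delta:.2f}" if d else "   - "
    pct = f"{d.percent:.1f}%" if d else "    - "
    print(f"{estimator:<12} {cset:<18} {est.hr:6.2f} "
          f"[{est.ci95[0]:5.2f}, {est.ci95[1]:5.2f}] {est.p_value:7.3f} "
          f"{delta:>5} {pct:>7}")
# The structured-only rows are biased away from HR = 1 by the text-borne
# confounders; adding the uncovered terms (struct+intersect) shifts every
# estimator back toward equipoise — the direction of the known truth.
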