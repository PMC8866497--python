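"""Generate a synthetic EMR cohort with planted text-borne confounding.

Two latent conditions ("bladder", "copd") raise both the odds of surgery
and the death hazard; the true treatment effect is null (HR = 1), so any
apparent effect in the raw data is confounding.
"""

import numpy as np

import textconfound as tc

config = tc.SimulationConfig(n_patients=500, seed=1)
records, manifest = tc.generate_cohort(config)

print(f"patients: {len(records)}")
print(f"treated (surgery) fraction: {manifest.W.mean():.3f}")
print(f"event fraction: {manifest.event.mean():.3f} (censoring target 0.20)")
print(f"true treatment HR: {np.exp(manifest.true_treatment_loghr):.2f}")

unadjusted = tc.oracle_marginal_hr(manifest, [])
adjusted = tc.oracle_marginal_hr(manifest, manifest.confounder_names)
print(f"unadjusted Cox HR for treatment: {unadjusted:.2f}  <- inflated by confounding")
print(f"HR adjusted for the latent conditions: {adjusted:.2f}  <- near the truth")

print("\nfirst note of the first patient:\n" + records[0].notes[0].text)
# The affirmative sentences name the patient's active conditions; the
# boilerplate and any short negated sentence are removed downstream.
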