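"""Generate a synthetic primary-care cohort and re-estimate control rates.

Draws a patient-level cohort with the structure of the observed study
population (288 point-of-care vs 1,102 laboratory patients, A1c result
availability 76% vs 36%, right-skewed baseline A1c), then recovers the
per-cycle probability of reaching the glycemic target — the Markov
model's key strategy parameter — by maximum likelihood.
"""

import poccea

config = poccea.reference_config()
cohort = poccea.generate_cohort(config["cohort"])

print("baseline characteristics by group:")
print(poccea.summarize_baseline(cohort).round(3).to_string(index=False))

print("\nper-cycle control-rate estimates (constant-hazard MLE, 95% Wilson CI):")
for group, generating in (("poc", 0.14), ("lab", 0.0738)):
    est = poccea.estimate_control_rate(cohort, group)
    print(
        f"  {group:>3}: p_hat {est.p_hat:.4f} [{est.ci_low:.4f}, {est.ci_high:.4f}]"
        f"  (generating value {generating}, n_used {est.n_used})"
    )
print(
    "\nOnly patients with an available A1c result are assessable; the "
    "estimates recover the generating per-cycle probabilities within "
    "sampling error."
)
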