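"""Probabilistic sensitivity analysis (Monte Carlo) of the reference model.

Draws every uncertain parameter (beta for probabilities, gamma for costs,
sd = 20% of the base value), re-evaluates both strategies 1,000 times, and
prints the 2.5th/97.5th percentile intervals plus the fraction of trials
in which point-of-care testing has positive incremental net monetary
benefit at selected willingness-to-pay values.
"""

import poccea

config = poccea.reference_config()
model = config["model"]
dists = poccea.default_distributions(model, dispersion=0.2)
result = poccea.run_psa(model, dists, n_trials=1000, seed=42)

print("2.5th / 97.5th percentiles over 1,000 trials:")
for _, row in result.percentile_summary.iterrows():
    print(f"  {row['quantity']:>12}: [{row['p2.5']:>10.4f}, {row['p97.5']:>10.4f}]")

print("\nacceptability (fraction of trials with positive incremental NMB):")
acc = result.nmb_acceptance.set_index("wtp")["p_positive_incremental_nmb"]
for wtp in (0.0, 1000.0, 2000.0, 3000.0, 5000.0):
    print(f"  WTP ${wtp:>6,.0f}: {acc.loc[wtp]:.3f}")
print(
    "\nThe intervals quantify parameter uncertainty around the deterministic "
    "base case; acceptability rising with WTP reflects that the "
    "point-of-care strategy buys effectiveness at a cost."
)
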