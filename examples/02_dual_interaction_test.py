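"""Run both interaction-detection methods on one SNP–flux pair.

A cohort of 20,000 with a planted amplification (beta_interaction = 0.3) is
simulated; the script prints the interaction-model estimate, the per-dosage
flux effects, the Welch heterogeneity test, and the weighted dosage slope.
The two approaches estimate the same quantity and should agree closely.
"""

from fluxgei.experiments import simulate_and_test_pair, single_pair_config

config = single_pair_config(n=20000, beta_interaction=0.3, seed=11)
result = simulate_and_test_pair(config)

inter = result.interaction
print("interaction effect size test (5-term stratified Cox):")
print(f"  beta_SNPxFlux = {inter.beta_interaction:+.4f}  "
      f"SE = {inter.se:.4f}  Wald p = {inter.p:.3g}")

dt = result.dosage_test
print("dosage-specific test:")
for i in range(3):
    print(f"  dosage {i}: beta_Flux = {dt.strata.beta[i]:+.4f} "
          f"(SE {dt.strata.se[i]:.4f}, n = {dt.strata.n[i]}, "
          f"events = {dt.strata.events[i]})")
print(f"  Welch ANOVA: F = {dt.F:.2f} on ({dt.df1:.0f}, {dt.df2:.1f}) df, "
      f"p = {dt.p:.3g}")
print(f"  weighted slope = {dt.slope:+.4f}  SE = {dt.slope_se:.4f}")
# Both estimates sit near the planted log-hazard interaction of +0.30 per
# dosage x flux-SD unit; the per-dosage flux effects climb by ~0.30 per
# additional risk allele on top of the planted main effect of 0.10.
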