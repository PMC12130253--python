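# fluxgei

Detection of metabolic reaction fluxes that **buffer** or **amplify** the
effect of disease risk alleles on a time-to-event outcome.

Genome-wide association studies yield thousands of risk variants whose
mechanism is unknown. One route to mechanism is to ask whether the penetrance
of a risk allele depends on the activity of a biochemical reaction: a flux
that strengthens the allele's effect on disease *amplifies* it, one that
weakens it *buffers* it. `fluxgei` implements, as a tested and reusable
library, the dual-test statistical machinery for this question — aimed at
genetic epidemiologists and systems-biology groups working with genetically
predicted organ-specific fluxes and survival phenotypes (e.g. coronary
artery disease onset in population biobanks) — together with a synthetic
cohort generator so every stage can be validated without access to
restricted individual-level data.

## The model

For each SNP–flux pair, two complementary tests with different assumptions
are run and intersected.

**Interaction effect size test.** A stratified Cox proportional-hazards
model with attained age as the timescale:

    h(t) = h0(t) · exp(β_SNP·SNP + β_Flux·Flux + β_SNP²·SNP²
                       + β_Flux²·Flux² + β_SNP:Flux·SNP·Flux)

where `SNP` is the risk-allele dosage in [0, 2] and `Flux` is the
standardized log2 flux, first adjusted by regressing out the dosage (to
block spurious interactions when the genetically predicted flux correlates
with the allele). Genetic principal components are covariates; the model is
stratified by sex and genotyping array. Significance is a two-tailed Wald
test on β_SNP:Flux.

**Dosage-specific test.** Individuals are split by hard-called dosage
(0, 1, 2) and the flux effect is estimated within each group:

    h_SNPᵢ(t) = h0_SNPᵢ(t) · exp(β_Flux,SNPᵢ · Flux)

Heterogeneity of the β_Flux,SNPᵢ across dosage groups is tested with
Welch's ANOVA (the squared standard errors stand in for s²/n), and an
interaction-comparable slope comes from 1/SE²-weighted regression of the
per-dosage effects on dosage.

Both p-value vectors are Benjamini–Hochberg adjusted over the same
post-pruning pair set; a pair is **called** when both FDR values are below
0.05 (borderline below 0.25). Positive β_SNP:Flux = amplification, negative
= buffering. Around the core tests the pipeline provides greedy pruning of
|r| > 0.5 correlated same-organ fluxes, univariate SNP and flux screens,
LD-block definition (single-linkage, friends-of-friends, tree cut 0.4 ⇔
connected components of the R² > 0.6 graph), locus-level aggregation,
per-flux-quartile variant-effect profiles, and cross-cohort replication
comparison.

The Cox partial likelihood (stratified, Efron ties) is maximized by the
package's own vectorized Newton solver, validated in the test suite against
both brute-force maximization of the written-out partial likelihood and an
independent survival library.

## Worked example

`examples/02_dual_interaction_test.py` simulates 20,000 individuals with a
planted amplification of +0.30 log-HR per dosage×flux-SD and runs both
methods:

```
interaction effect size test (5-term stratified Cox):
  beta_SNPxFlux = +0.2885  SE = 0.0235  Wald p = 9.25e-35
dosage-specific test:
  dosage 0: beta_Flux = +0.1133 (SE 0.0231, n = 9699, events = 1874)
  dosage 1: beta_Flux = +0.4030 (SE 0.0221, n = 8538, events = 2080)
  dosage 2: beta_Flux = +0.6735 (SE 0.0449, n = 1763, events = 509)
  Welch ANOVA: F = 77.96 on (2, 5175.7) df, p = 4.38e-34
  weighted slope = +0.2833  SE = 0.0227
```

The per-dosage flux effects climb by ~0.30 per extra risk allele on top of
the planted main effect of 0.10, and both estimators sit within two
standard errors of the truth. `examples/03_run_pipeline.py` runs the full
discovery pipeline on the bundled demo cohort (5,000 individuals, 6 SNPs,
12 reactions, one planted pair) and prints the stage tables: the planted
(rs1, R1) pair is the sole significant call, the pruning log lists the four
correlated fluxes removed before FDR adjustment, and the locus table
aggregates calls over LD blocks. The other examples cover cohort
simulation, quartile profiles and two-cohort replication.

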