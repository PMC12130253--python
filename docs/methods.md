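# Methods

## Statistical model

The package tests, for each SNP–flux pair, whether a reaction flux modulates
the log hazard ratio of a risk allele for a survival outcome on the age
timescale. Two estimators of the same modulation are used and intersected.

The **interaction model** is a stratified Cox proportional-hazards fit with
linear predictor `β_SNP·S + β_Flux·F' + β_SNP²·S² + β_Flux²·F'² +
β_SNP:Flux·S·F'` plus genetic principal components (and, in the sensitivity
variant, BMI, systolic blood pressure, LDL-C, HDL-C and triglycerides),
stratified by sex and genotyping array. `F'` is the flux after ordinary
least-squares removal of its dosage component. The adjustment is a
projection, not a rescaling: residuals are deliberately **not**
re-standardized, so effect sizes stay commensurate across pairs. The
quadratic terms absorb curvature in either margin so that the product term
captures genuinely non-additive structure.

The **dosage-specific test** splits the cohort by hard-called dosage
(nearest integer; ties at .5 round up) and fits the flux effect separately
per group, on the *unadjusted* flux — within a dosage group the dosage is
(nearly) constant, so the adjustment would only shift the intercept.
Heterogeneity across the ≤3 estimates is assessed with Welch's
heteroscedastic ANOVA applied at the estimate level: group "mean" β_i,
with SE_i² standing in for s_i²/n_i, and the group size entering only the
Welch–Satterthwaite degrees-of-freedom correction. This is the only reading
of an estimate-level Welch test that is internally consistent; with two
groups it reduces exactly to the squared Welch t statistic (asserted in the
tests). A 1/SE²-weighted least-squares slope of β_i on dosage i puts the
heterogeneity on the same scale as the interaction coefficient; its SE
comes from the weighted normal equations without residual rescaling,
i.e. the weights are taken as true inverse variances.

A pair is called significant when **both** tests survive Benjamini–Hochberg
adjustment at FDR < 0.05, adjusted over the identical post-pruning pair
set; 0.25 defines the borderline band. The intersection guards against
artefacts specific to either parameterization; because the two estimators
agree extremely tightly on clean simulated data (Pearson r > 0.999 in the
validation suite), the intersection provides robustness against model
misspecification rather than a large reduction in false positives.

## Cox engine

All fits go through one solver: Newton iteration with step halving on the
stratified partial likelihood with the Efron tie correction, relative
log-likelihood tolerance 1e-9, at most 100 iterations. Design columns are
standardized internally for conditioning and results back-transformed
exactly. Per-stratum linear predictors are shifted by their maximum before
exponentiation; the shift cancels identically in the partial likelihood, so
this is a pure overflow guard. When all event times within a stratum are
distinct the gradient and observed information are accumulated with
reverse-cumulative-sum identities (no per-event Python loop), which is what
makes the simulation studies (thousands of fits at n = 10–20k) cheap; tied
event times fall back to an explicit Efron pass. Monotone likelihoods
(perfect separation) plateau rather than converge in the usual sense; a fit
that plateaus with a standardized coefficient above 10 (a log-HR per SD no
real cohort produces) is flagged non-converged, and callers treat
non-convergence as a per-pair failure, never silently. Zero events or a
column constant within every stratum raise immediately. The contract
accepts an entry-age argument so delayed entry can be added later without
interface change, but left truncation is not implemented (see
Limitations).

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
stage by stage, from a single master seed that deterministically spawns
per-stage substreams (genotypes, fluxes, survival, covariates) — identical
configuration and seed give bit-identical cohorts.

*Genotypes.* Two haplotype indicator vectors per individual from a
latent-Gaussian threshold model: latent MVN with the configured inter-SNP
correlation, allele carried when the latent value falls below the
MAF-quantile. Marginally this is exact Hardy–Weinberg; pairwise dosage R²
is tunable but attenuated relative to the latent correlation (latent 0.9 at
MAF 0.3 realizes R² ≈ 0.49; ≈ 0.70 at latent 0.97 — values fixed by
Monte-Carlo before the validation suite was written). MAF must lie in
(0, 0.5].

*Fluxes.* Raw flux = Σ eQTL effect × dosage + correlated Gaussian
background (per-organ correlation matrix), then each column standardized to
mean 0, variance 1 (the convention for log-transformed genetically
predicted fluxes). Standardization is exact to 1e-8 by construction.

*Survival.* Event ages by inverse transform from a per-stratum Weibull
baseline under the exponentiated linear predictor (first-order, quadratic
and interaction terms per configured pair, plus PC effects), with
administrative censoring at a fixed age. Defaults — shape 5, scale 95,
censoring at 70, giving a ~20% event fraction — were chosen once to mimic a
late-onset cardiovascular-disease age-incidence profile. Sex (54% female)
and a two-level array label (10% "B") are drawn independently; optional
cardiometabolic covariates are Gaussians on population-plausible scales
with a configurable correlation to the flux signal, used to exercise the
covariate-sensitivity variant.

What the generator does **not** emulate: real LD panels or haplotype
structure beyond pairwise R²; environment-driven flux variation;
enrolment-conditioned sampling of prevalent cases (no delayed entry — ages
run from birth); genome coordinates. Passing tests therefore demonstrate
the statistical machinery is correct under a proportional-hazards world
with the assumed dependence structure, not that any real-data finding is
reproduced.

## Pipeline conventions and numerical choices

- **Pruning** ranks pairs by max(p_interaction, p_dosage) ascending, keeps
  the reaction of the best-ranked surviving pair and removes every
  same-organ reaction with |r| above 0.5 together with its pairs. The
  threshold applies to |r|: stoichiometric coupling can be negative, and
  sign-blind removal is the conservative choice. Ties in the ranking break
  lexicographically by (reaction, SNP), making the output a pure function
  of its inputs.
- **LD blocks** are connected components of the strict R² > 0.6 graph,
  which for single linkage is exactly the 1−R² tree cut at 0.4; an edge at
  exactly R² = 0.6 does not join. R² is the squared Pearson correlation of
  dosage vectors.
- **Dosage strata** need a minimum of 10 events (configurable) or they are
  flagged absent; the heterogeneity test requires at least two present
  strata. This guards rare-homozygote instability.
- **Quartiles** are assigned by ordinal rank (ties to the lower quartile by
  rank), so quartile sizes differ by at most one; the per-quartile trend
  line is weighted by 1/SE², matching the dosage-slope convention.
- **Replication comparison** restricts to shared pairs, correlates the two
  cohorts' interaction estimates and dosage slopes, reports the same-sign
  fraction, and re-runs BH within the replication pair set only (a pair
  replicates when either test clears the threshold).
- **Batch isolation:** every per-pair failure (monomorphic dosage, sparse
  stratum, non-convergence) is caught, logged and emitted as a NaN row with
  a diagnostic, never aborting a batch.
- The univariate SNP screen defaults to the genome-wide 5e-8 threshold; the
  bundled demo overrides it to 1e-2, the scale-appropriate analogue at
  5,000 individuals, where no realistic effect can reach 5e-8.

## Validation design and problem sizes

The acceptance suite validates: estimator agreement across 500 pairs at
n = 20,000 (r ≥ 0.99); type-I error and p-value uniformity over 1,000 null
cohorts at n = 10,000; recovery and 95% CI coverage of a planted 0.3
interaction over 200 cohorts at n = 20,000; exact equivalence of BH,
pruning, block-finding and small-sample Cox fits against independently
coded oracles; post-pruning and block structural guarantees; intersection
conservativeness; and the end-to-end demo over 20 seeds.
`scripts/acceptance.py` reruns the same studies at moderate sizes (300
pairs at n = 10,000; 500 null replicates at n = 5,000; 100 recovery
replicates; 10 demo seeds) so a complete from-scratch reproduction takes
about a minute.

One caveat the validation itself exposes: with a single true pair among 48
and both tests agreeing at r > 0.999, the both-tests rule at FDR 0.05
retains the single-test false-call rate, so about one run in ten to twenty
produces one spurious significant pair — that is what FDR 0.05 permits, not
a defect; demanding near-zero spurious calls *and* near-perfect estimator
agreement simultaneously is not achievable at these sizes.

## Limitations

- No delayed entry / left truncation: prevalent cases are not modelled, and
  the generator draws ages from birth. The engine interface reserves the
  argument.
- No time-varying covariates, competing risks or penalized fits.
- Welch ANOVA at the estimate level treats per-dosage estimates as
  independent Gaussians with known variances; at very small event counts
  per stratum this is approximate (hence the per-stratum event minimum).
- The gene-annotation filter on reactions is consumed as a boolean input
  attribute; it is never recomputed from metabolic network structure.
- VCF dosage input is out of scope; genotype dosages are consumed as
  delimited text (or in memory).
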