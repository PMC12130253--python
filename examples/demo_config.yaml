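# Demo pipeline configuration (YAML schema for fluxgei.load_config).
#
# sim: the synthetic cohort.
#   n_individuals, seed, n_pcs, censor_age  — scalars
#   snps:        list of {name, maf}; maf in (0, 0.5]
#   ld_corr:     optional inter-SNP latent correlation matrix (unit diagonal, PSD)
#   reactions:   list of {name, organ, gene_annotated (default true)}
#   flux_corr:   optional {organ: correlation matrix} for the flux background
#   eqtl_effects: list of {snp, reaction, effect} — raw-flux shift per dosage
#   true_effects: list of {snp, reaction, beta_snp, beta_flux, beta_snp2,
#                 beta_flux2, beta_interaction} — log-hazard effect sizes
# pipeline: analysis settings.
#   snp_p_threshold, r_threshold, ld_cut, alpha, borderline, min_events, outdir

sim:
  n_individuals: 5000
  seed: 1
  n_pcs: 4
  censor_age: 70.0
  snps:
    - {name: rs1, maf: 0.30}
    - {name: rs2, maf: 0.28}
    - {name: rs3, maf: 0.25}
    - {name: rs4, maf: 0.35}
    - {name: rs5, maf: 0.20}
    - {name: rs6, maf: 0.40}
  reactions:
    - {name: R1, organ: liver}
    - {name: R2, organ: liver}
    - {name: R3, organ: liver}
    - {name: R4, organ: liver}
    - {name: R5, organ: liver}
    - {name: R6, organ: liver}
    - {name: R7, organ: heart}
    - {name: R8, organ: heart}
    - {name: R9, organ: heart}
    - {name: R10, organ: heart}
    - {name: R11, organ: heart}
    - {name: R12, organ: heart}
  flux_corr:
    liver:
      - [1.0, 0.8, 0.0, 0.0, 0.0, 0.0]
      - [0.8, 1.0, 0.0, 0.0, 0.0, 0.0]
      - [0.0, 0.0, 1.0, 0.8, 0.0, 0.0]
      - [0.0, 0.0, 0.8, 1.0, 0.0, 0.0]
      - [0.0, 0.0, 0.0, 0.0, 1.0, 0.0]
      - [0.0, 0.0, 0.0, 0.0, 0.0, 1.0]
    heart:
      - [1.0, 0.8, 0.0, 0.0, 0.0, 0.0]
      - [0.8, 1.0, 0.0, 0.0, 0.0, 0.0]
      - [0.0, 0.0, 1.0, 0.8, 0.0, 0.0]
      - [0.0, 0.0, 0.8, 1.0, 0.0, 0.0]
      - [0.0, 0.0, 0.0, 0.0, 1.0, 0.0]
      - [0.0, 0.0, 0.0, 0.0, 0.0, 1.0]
  eqtl_effects:
    - {snp: rs6, reaction: R7, effect: 0.2}
  true_effects:
    - {snp: rs1, reaction: R1, beta_snp: 0.25, beta_interaction: 0.3}
    - {snp: rs2, reaction: R12, beta_snp: 0.25}
    - {snp: rs3, reaction: R12, beta_snp: 0.25}
    - {snp: rs4, reaction: R12, beta_snp: 0.25}
    - {snp: rs5, reaction: R12, beta_snp: 0.25}
    - {snp: rs6, reaction: R12, beta_snp: 0.25}

pipeline:
  snp_p_threshold: 1.0e-2
  r_threshold: 0.5
  ld_cut: 0.4
  alpha: 0.05
  borderline: 0.25
  min_events: 10
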