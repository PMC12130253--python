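"""Reusable simulation studies for validating the dual interaction test.

Each function here defines one self-contained study on synthetic cohorts —
method agreement, null calibration, parameter recovery, end-to-end demo
detection, two-cohort replication — returning plain result objects. The
same designs back both the test suite and ``scripts/acceptance.py``; only
the problem sizes differ between callers.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawns, so every study is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .interaction import test_pair
from .reporting import compare_cohorts, demo_config, run_pipeline, test_all_pairs
from .simulate import (
    PairEffects,
    ReactionSpec,
    SimConfig,
    SNPSpec,
    simulate_cohort,
)

__all__ = [
    "single_pair_config",
    "simulate_and_test_pair",
    "method_agreement_study",
    "type_one_error_study",
    "recovery_study",
    "demo_detection_study",
    "replication_study",
]


def single_pair_config(
    *,
    n: int,
    maf: float = 0.3,
    beta_snp: float = 0.15,
    beta_flux: float = 0.10,
    beta_interaction: float = 0.0,
    n_pcs: int = 0,
    seed: int = 0,
) -> SimConfig:
    """One SNP, one reaction, one tested pair; defaults give ~20% events."""
    return SimConfig(
        n_individuals=n,
        snp_specs=[SNPSpec("rs1", maf)],
        reaction_specs=[ReactionSpec("R1", "liver")],
        true_effects={
            ("rs1", "R1"): PairEffects(
                beta_snp=beta_snp,
                beta_flux=beta_flux,
                beta_interaction=beta_interaction,
            )
        },
        n_pcs=n_pcs,
        seed=seed,
    )


def simulate_and_test_pair(config: SimConfig):
    """Simulate one cohort and run both methods on its single pair."""
    sim = simulate_cohort(config)
    return test_pair(
        sim.cohort, sim.genotypes.column("rs1"), sim.fluxes.column("R1"),
        snp="rs1", reaction="R1", organ="liver",
    )


@dataclass
class AgreementStudy:
    beta_true: np.ndarray
    beta_interaction: np.ndarray  # interaction-model estimates
    slope_dosage: np.ndarray  # dosage-specific weighted slopes
    r: float  # Pearson correlation between the two


def method_agreement_study(
    n_pairs: int = 500, n: int = 20000, seed: int = 0
) -> AgreementStudy:
    """Independent SNP–flux pairs with interaction effects uniform in
    [-0.3, 0.3] and MAF uniform in [0.1, 0.45]; measures how tightly the
    interaction-model estimate tracks the dosage-specific weighted slope."""
    master = np.random.SeedSequence(seed)
    rng = np.random.default_rng(master.spawn(1)[0])
    seeds = rng.integers(0, 2**31 - 1, size=n_pairs)
    beta_true = rng.uniform(-0.3, 0.3, size=n_pairs)
    mafs = rng.uniform(0.1, 0.45, size=n_pairs)
    est_i, est_s, kept_true = [], [], []
    for bt, maf, s in zip(beta_true, mafs, seeds):
        res = simulate_and_test_pair(
            single_pair_config(
                n=n, maf=float(maf), beta_interaction=float(bt), seed=int(s)
            )
        )
        if res.error is not None:
            continue
        est_i.append(res.interaction.beta_interaction)
        est_s.append(res.dosage_test.slope)
        kept_true.append(bt)
    est_i = np.asarray(est_i)
    est_s = np.asarray(est_s)
    r = float(stats.pearsonr(est_i, est_s)[0])
    return AgreementStudy(
        beta_true=np.asarray(kept_true),
        beta_interaction=est_i,
        slope_dosage=est_s,
        r=r,
    )


@dataclass
class NullCalibrationStudy:
    p_interaction: np.ndarray
    p_dosage: np.ndarray
    rejection_rate: float  # Wald test at alpha = 0.05
    ks_p_interaction: float
    ks_p_dosage: float


def type_one_error_study(
    n_reps: int = 1000, n: int = 10000, seed: int = 0
) -> NullCalibrationStudy:
    """Null interaction with main effects present; checks size and p-value
    uniformity of both methods."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    p_i, p_d = [], []
    for s in seeds:
        res = simulate_and_test_pair(
            single_pair_config(n=n, beta_interaction=0.0, seed=int(s))
        )
        if res.error is not None:
            continue
        p_i.append(res.interaction.p)
        p_d.append(res.dosage_test.p)
    p_i = np.asarray(p_i)
    p_d = np.asarray(p_d)
    return NullCalibrationStudy(
        p_interaction=p_i,
        p_dosage=p_d,
        rejection_rate=float(np.mean(p_i < 0.05)),
        ks_p_interaction=float(stats.kstest(p_i, "uniform").pvalue),
        ks_p_dosage=float(stats.kstest(p_d, "uniform").pvalue),
    )


@dataclass
class RecoveryStudy:
    beta_true: float
    estimates: np.ndarray
    ses: np.ndarray
    mean_estimate: float
    se_of_mean: float
    coverage95: float  # fraction of 95% Wald intervals covering the truth


def recovery_study(
    beta_interaction: float = 0.3,
    n_reps: int = 200,
    n: int = 20000,
    seed: int = 0,
) -> RecoveryStudy:
    """Repeated-simulation recovery of a fixed interaction effect."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    est, ses = [], []
    for s in seeds:
        res = simulate_and_test_pair(
            single_pair_config(n=n, beta_interaction=beta_interaction, seed=int(s))
        )
        if res.error is None:
            est.append(res.interaction.beta_interaction)
            ses.append(res.interaction.se)
    est = np.asarray(est)
    ses = np.asarray(ses)
    cover = np.mean(np.abs(est - beta_interaction) <= 1.959964 * ses)
    return RecoveryStudy(
        beta_true=beta_interaction,
        estimates=est,
        ses=ses,
        mean_estimate=float(est.mean()),
        se_of_mean=float(est.std(ddof=1) / np.sqrt(len(est))),
        coverage95=float(cover),
    )


@dataclass
class DemoDetectionStudy:
    n_seeds: int
    planted_detected: int  # seeds where the planted pair (or an LD tag) is called
    seeds_with_null_call: int  # seeds where any non-planted pair is called
    null_pairs_called: int  # total spurious significant pairs across seeds


def demo_detection_study(n_seeds: int = 20, seed: int = 0) -> DemoDetectionStudy:
    """Run the bundled demo pipeline across seeds and score detection.

    The planted interaction is (rs1, R1); a call on the flux correlated with
    R1 tags the same signal and counts as detection, not as a false call.
    """
    tag_snps = {"rs1"}
    tag_reactions = {"R1", "R2"}  # R2 is the 0.8-correlated liver partner
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    detected = 0
    seeds_with_null = 0
    null_calls = 0
    for s in seeds:
        res = run_pipeline(demo_config(seed=int(s)))
        sig = res.calls[res.calls["call"] == "significant"]
        is_tag = sig["snp"].isin(tag_snps) & sig["reaction"].isin(tag_reactions)
        if is_tag.any():
            detected += 1
        n_null = int((~is_tag).sum())
        null_calls += n_null
        if n_null:
            seeds_with_null += 1
    return DemoDetectionStudy(
        n_seeds=n_seeds,
        planted_detected=detected,
        seeds_with_null_call=seeds_with_null,
        null_pairs_called=null_calls,
    )


def _replication_truth(n_pairs: int = 12):
    """Diagonal SNP–reaction pairs with strong interactions of both signs."""
    mags = np.linspace(0.1, 0.3, n_pairs // 2)
    betas = np.concatenate([mags, -mags])
    snps = [SNPSpec(f"rs{i + 1}", 0.3) for i in range(n_pairs)]
    reactions = [ReactionSpec(f"R{i + 1}", "liver") for i in range(n_pairs)]
    effects = {
        (f"rs{i + 1}", f"R{i + 1}"): PairEffects(
            beta_snp=0.1, beta_flux=0.1, beta_interaction=float(betas[i])
        )
        for i in range(n_pairs)
    }
    return snps, reactions, effects


def replication_study(n: int = 20000, n_pairs: int = 12, seed: int = 0):
    """Two independent cohorts drawn from one truth; the discovery pairs are
    re-tested in the replication cohort and compared (estimate correlation,
    sign consistency), mirroring a discovery -> external-validation design."""
    snps, reactions, effects = _replication_truth(n_pairs)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    s1, s2 = (int(x) for x in rng.integers(0, 2**31 - 1, size=2))
    tables = []
    for s in (s1, s2):
        cfg = SimConfig(
            n_individuals=n,
            snp_specs=snps,
            reaction_specs=reactions,
            true_effects=effects,
            n_pcs=0,
            seed=s,
        )
        sim = simulate_cohort(cfg)
        pairs = [(f"rs{i + 1}", f"R{i + 1}") for i in range(n_pairs)]
        rows = []
        for snp, reaction in pairs:
            tbl = test_all_pairs(
                sim.cohort, sim.genotypes, sim.fluxes, [snp], [reaction]
            )
            rows.append(tbl)
        import pandas as pd

        tables.append(pd.concat(rows, ignore_index=True))
    comparison = compare_cohorts(tables[0], tables[1])
    return comparison, tables
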