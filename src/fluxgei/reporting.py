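"""Quartile effect profiles, cross-cohort replication, and the pipeline.

``run_pipeline`` orchestrates the full analysis on a simulated (or loaded)
cohort: univariate SNP screen -> pair testing with both interaction methods
-> correlated-flux pruning -> BH-FDR and intersection calling -> LD-block
aggregation -> univariate flux screen, persisting every stage's table when
an output directory is given.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import io as fio
from .calling import call_pairs
from .cox import fit_cox
from .errors import FitError, ValidationError
from .interaction import _pc_columns, _strata_labels, test_pair
from .ldblocks import aggregate_locus_flux_pairs, pairwise_r2, single_linkage_blocks
from .pruning import (
    flux_correlation,
    prune_pairs,
    univariate_flux_screen,
    univariate_snp_screen,
)
from .simulate import (
    PairEffects,
    ReactionSpec,
    SimConfig,
    SNPSpec,
    simulate_cohort,
)

__all__ = [
    "quartile_variant_effects",
    "QuartileProfile",
    "compare_cohorts",
    "CohortComparison",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "demo_config",
    "load_config",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# quartile-binned variant effects
# ---------------------------------------------------------------------------


@dataclass
class QuartileProfile:
    beta: np.ndarray  # variant log-HR per quartile (length 4)
    se: np.ndarray
    n: np.ndarray
    events: np.ndarray
    slope: float  # weighted trend of beta on quartile index (1..4)
    intercept: float


def quartile_variant_effects(
    cohort: pd.DataFrame,
    dosage: np.ndarray,
    flux: np.ndarray,
    *,
    min_events: int = 10,
) -> QuartileProfile:
    """Variant effect size within each flux quartile plus a weighted trend.

    Individuals are binned into flux quartiles by ordinal rank (ties go to
    the lower quartile by rank, and quartile sizes differ by at most one);
    the SNP effect is estimated within each quartile by a stratified Cox fit
    with PCs as covariates; the trend line is 1/SE^2-weighted least squares
    of the quartile effects on quartile index 1..4.
    """
    flux = np.asarray(flux, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if len(np.unique(flux)) < 4:
        raise ValidationError("flux needs at least 4 distinct values for quartiles")
    n = len(flux)
    ranks = stats.rankdata(flux, method="ordinal")  # ties resolved by position
    q = np.floor(4 * (ranks - 1) / n).astype(int)  # 0..3
    beta = np.full(4, np.nan)
    se = np.full(4, np.nan)
    counts = np.zeros(4, dtype=int)
    events = np.zeros(4, dtype=int)
    for i in range(4):
        mask = q == i
        counts[i] = int(mask.sum())
        sub = cohort.loc[mask]
        events[i] = int(sub["event"].sum())
        if events[i] < min_events:
            raise ValidationError(f"flux quartile {i + 1} has too few events")
        design = pd.DataFrame({"snp": dosage[mask]}, index=sub.index)
        for c in _pc_columns(cohort):
            design[c] = sub[c]
        fit = fit_cox(sub["age"], sub["event"], design, _strata_labels(sub))
        if not fit.converged:
            raise FitError(f"quartile {i + 1} fit did not converge")
        beta[i] = fit.params["snp"]
        se[i] = fit.se["snp"]
    x = np.arange(1.0, 5.0)
    w = 1.0 / se**2
    X = np.column_stack([np.ones(4), x])
    cov = np.linalg.inv((X.T * w) @ X)
    coef = cov @ ((X.T * w) @ beta)
    return QuartileProfile(
        beta=beta,
        se=se,
        n=counts,
        events=events,
        slope=float(coef[1]),
        intercept=float(coef[0]),
    )


# ---------------------------------------------------------------------------
# cross-cohort replication
# ---------------------------------------------------------------------------


@dataclass
class CohortComparison:
    n_shared: int
    r_interaction: float
    r_slope: float
    sign_consistency: float
    n_significant_replication: int
    n_borderline_replication: int


def compare_cohorts(
    results_discovery: pd.DataFrame,
    results_replication: pd.DataFrame,
    alpha: float = 0.05,
    borderline: float = 0.25,
) -> CohortComparison:
    """Replication comparison restricted to the shared SNP–flux pairs.

    Reports the Pearson correlation of the interaction-model estimates and
    of the dosage-slope estimates between cohorts, the fraction of pairs
    with consistent interaction sign, and replication-set significance
    counts (BH within the replication pair set; a pair replicates when
    either test clears the threshold).
    """
    keys = ["snp", "reaction"]
    merged = results_discovery.merge(
        results_replication, on=keys, suffixes=("_disc", "_repl")
    )
    merged = merged.dropna(
        subset=["beta_interaction_disc", "beta_interaction_repl"]
    )
    if merged.empty:
        raise ValidationError("no shared pairs between the two result tables")
    r_int = float(
        stats.pearsonr(
            merged["beta_interaction_disc"], merged["beta_interaction_repl"]
        )[0]
    )
    if "slope_dosage_disc" in merged and merged["slope_dosage_disc"].notna().all():
        r_slope = float(
            stats.pearsonr(merged["slope_dosage_disc"], merged["slope_dosage_repl"])[0]
        )
    else:
        r_slope = np.nan
    sign_consistency = float(
        np.mean(
            np.sign(merged["beta_interaction_disc"])
            == np.sign(merged["beta_interaction_repl"])
        )
    )
    repl = results_replication.dropna(subset=["p_interaction", "p_dosage"]).copy()
    called = call_pairs(repl, alpha=alpha, borderline=borderline)
    either_sig = (called["fdr_interaction"] < alpha) | (called["fdr_dosage"] < alpha)
    either_bord = ~either_sig & (
        (called["fdr_interaction"] < borderline) | (called["fdr_dosage"] < borderline)
    )
    return CohortComparison(
        n_shared=len(merged),
        r_interaction=r_int,
        r_slope=r_slope,
        sign_consistency=sign_consistency,
        n_significant_replication=int(either_sig.sum()),
        n_borderline_replication=int(either_bord.sum()),
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    sim: SimConfig
    snp_p_threshold: float = 5e-8
    r_threshold: float = 0.5
    ld_cut: float = 0.4
    alpha: float = 0.05
    borderline: float = 0.25
    min_events: int = 10
    with_cardio: bool = False
    outdir: str | None = None


@dataclass
class PipelineResult:
    cohort_data: object
    snp_screen: pd.DataFrame
    pair_results: pd.DataFrame  # all tested pairs, pre-pruning
    pruned: object
    calls: pd.DataFrame  # post-pruning pairs with fdr/call/direction
    flux_screen: pd.DataFrame
    blocks: object
    locus_pairs: pd.DataFrame
    manifest: dict


def _pair_row(res) -> dict:
    row = {
        "snp": res.snp,
        "reaction": res.reaction,
        "organ": res.organ,
        "beta_interaction": np.nan,
        "se_interaction": np.nan,
        "p_interaction": np.nan,
        "welch_F": np.nan,
        "welch_df1": np.nan,
        "welch_df2": np.nan,
        "p_dosage": np.nan,
        "slope_dosage": np.nan,
        "slope_se": np.nan,
        "error": res.error or "",
    }
    if res.interaction is not None:
        row.update(
            beta_interaction=res.interaction.beta_interaction,
            se_interaction=res.interaction.se,
            p_interaction=res.interaction.p,
        )
    if res.dosage_test is not None:
        dt = res.dosage_test
        row.update(
            welch_F=dt.F,
            welch_df1=dt.df1,
            welch_df2=dt.df2,
            p_dosage=dt.p,
            slope_dosage=dt.slope,
            slope_se=dt.slope_se,
        )
        for i in range(3):
            row[f"beta_flux_d{i}"] = dt.strata.beta[i]
            row[f"se_flux_d{i}"] = dt.strata.se[i]
            row[f"n_d{i}"] = dt.strata.n[i]
            row[f"events_d{i}"] = dt.strata.events[i]
    return row


def test_all_pairs(
    cohort: pd.DataFrame,
    genotypes,
    fluxes,
    snps,
    reactions,
    *,
    extra_covariates: tuple = (),
    min_events: int = 10,
) -> pd.DataFrame:
    """Run both interaction methods for every (snp, reaction) combination.

    Per-pair failures are isolated: failing pairs appear with NaN statistics
    and a diagnostic in the ``error`` column.
    """
    rows = []
    for snp in snps:
        dosage = genotypes.column(snp)
        for reaction in reactions:
            res = test_pair(
                cohort,
                dosage,
                fluxes.column(reaction),
                snp=snp,
                reaction=reaction,
                organ=fluxes.organ_of(reaction),
                extra_covariates=extra_covariates,
                min_events=min_events,
            )
            rows.append(_pair_row(res))
    columns = [
        "snp", "reaction", "organ", "beta_interaction", "se_interaction",
        "p_interaction", "welch_F", "welch_df1", "welch_df2", "p_dosage",
        "slope_dosage", "slope_se", "error",
    ]
    return pd.DataFrame(rows) if rows else pd.DataFrame(columns=columns)


def _config_hash(config: PipelineConfig) -> str:
    def convert(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, dict):
            return {str(k): convert(v) for k, v in sorted(o.items(), key=lambda kv: str(kv[0]))}
        if isinstance(o, (list, tuple)):
            return [convert(v) for v in o]
        if hasattr(o, "__dict__"):
            return convert(vars(o))
        return o if isinstance(o, (str, int, float, bool, type(None))) else str(o)

    blob = json.dumps(convert(vars(config)), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage of the analysis on one simulated cohort."""
    sim = simulate_cohort(config.sim)
    cohort, genotypes, fluxes = sim.cohort, sim.genotypes, sim.fluxes

    snp_screen = univariate_snp_screen(
        cohort, genotypes, threshold=config.snp_p_threshold
    )
    selected_snps = list(snp_screen["snp"])

    annotated = [
        name
        for name, ok in zip(fluxes.reaction_names, fluxes.gene_annotated)
        if ok
    ]
    extra = (
        tuple(c for c in ("bmi", "sbp", "ldl", "hdl", "tg") if c in cohort)
        if config.with_cardio
        else ()
    )
    pair_results = test_all_pairs(
        cohort,
        genotypes,
        fluxes,
        selected_snps,
        annotated,
        extra_covariates=extra,
        min_events=config.min_events,
    )

    organs = sorted(
        {fluxes.organ_of(r) for r in annotated}
    )
    correlations = {}
    for organ in organs:
        names_in_organ = [r for r in annotated if fluxes.organ_of(r) == organ]
        if len(names_in_organ) >= 2:
            correlations[organ] = flux_correlation(fluxes, organ).loc[
                names_in_organ, names_in_organ
            ]
        else:
            correlations[organ] = pd.DataFrame(
                np.eye(len(names_in_organ)),
                index=names_in_organ,
                columns=names_in_organ,
            )

    testable = pair_results.dropna(subset=["p_interaction", "p_dosage"])
    pruned = prune_pairs(testable, correlations, r_threshold=config.r_threshold)
    calls = call_pairs(
        pruned.retained_pairs, alpha=config.alpha, borderline=config.borderline
    )

    retained_names = [
        r for r in fluxes.reaction_names if r in set(calls["reaction"])
    ]
    if retained_names:
        idx = [fluxes.reaction_names.index(r) for r in retained_names]
        from .simulate import FluxMatrix

        retained_fluxes = FluxMatrix(
            values=fluxes.values[:, idx],
            reaction_names=retained_names,
            organs=[fluxes.organs[i] for i in idx],
            gene_annotated=fluxes.gene_annotated[idx],
        )
        flux_screen = univariate_flux_screen(cohort, retained_fluxes)
    else:
        flux_screen = pd.DataFrame(
            columns=["reaction", "organ", "beta", "se", "p", "fdr"]
        )

    if len(selected_snps) >= 2:
        r2 = pairwise_r2(genotypes, selected_snps)
        blocks = single_linkage_blocks(r2, cut=config.ld_cut)
    else:
        from .ldblocks import LDBlockAssignment

        blocks = LDBlockAssignment(
            block_of={s: 0 for s in selected_snps},
            members={0: selected_snps} if selected_snps else {},
        )
    locus_pairs = aggregate_locus_flux_pairs(calls, blocks)

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.sim.seed,
        "package": "fluxgei 0.1.0",
        "n_individuals": config.sim.n_individuals,
        "n_snps_screened": len(genotypes.snp_names),
        "n_snps_selected": len(selected_snps),
        "n_pairs_tested": len(pair_results),
        "n_pairs_retained": len(calls),
        "n_significant": int((calls["call"] == "significant").sum()),
        "n_blocks": blocks.n_blocks,
        "n_locus_flux_pairs": len(locus_pairs),
    }
    result = PipelineResult(
        cohort_data=sim,
        snp_screen=snp_screen,
        pair_results=pair_results,
        pruned=pruned,
        calls=calls,
        flux_screen=flux_screen,
        blocks=blocks,
        locus_pairs=locus_pairs,
        manifest=manifest,
    )
    if config.outdir:
        _persist(result, config)
    return result


def _persist(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": result.manifest["config_hash"], "seed": config.sim.seed}
    sim = result.cohort_data
    fio.write_cohort(sim.cohort, out / "cohort.tsv")
    fio.write_genotypes(sim.genotypes, out / "genotypes.tsv")
    fio.write_fluxes(sim.fluxes, out / "fluxes.tsv")
    fio.write_sim_truth(sim.truth, out / "sim_truth.json")
    fio.write_table(result.snp_screen, out / "snp_screen.tsv", meta)
    fio.write_table(result.pair_results, out / "pair_results.tsv", meta)
    fio.write_table(result.pruned.removal_log, out / "pruning_log.tsv", meta)
    fio.write_table(result.calls, out / "calls.tsv", meta)
    fio.write_table(result.flux_screen, out / "flux_screen.tsv", meta)
    blocks_df = pd.DataFrame(
        sorted(result.blocks.block_of.items()), columns=["snp", "block"]
    )
    fio.write_table(blocks_df, out / "ld_blocks.tsv", meta)
    fio.write_table(result.locus_pairs, out / "locus_flux_pairs.tsv", meta)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


# ---------------------------------------------------------------------------
# bundled demo configuration
# ---------------------------------------------------------------------------


def demo_config(seed: int = 0, outdir: str | None = None) -> PipelineConfig:
    """Small end-to-end demonstration cohort.

    ~5,000 individuals, 6 unlinked SNPs, 12 reactions across two organs with
    block-correlated fluxes, and one planted amplification
    (beta_interaction = 0.3 between rs1 and liver reaction R1, so exactly
    one true pair exists). All SNPs carry a realistic main effect so the
    univariate screen (threshold 1e-2 at this sample size) retains them.
    """
    snps = [SNPSpec(f"rs{i + 1}", maf) for i, maf in enumerate(
        (0.30, 0.28, 0.25, 0.35, 0.20, 0.40)
    )]
    reactions = [
        ReactionSpec(f"R{i + 1}", "liver" if i < 6 else "heart") for i in range(12)
    ]
    # within-organ correlated pairs exercise the pruning stage
    block = np.eye(6)
    for i, j in ((0, 1), (3, 4)):
        block[i, j] = block[j, i] = 0.8
    flux_corr = {"liver": block, "heart": block.copy()}
    true_effects = {("rs1", "R1"): PairEffects(beta_snp=0.25, beta_interaction=0.3)}
    for s in ("rs2", "rs3", "rs4", "rs5", "rs6"):
        true_effects[(s, "R12")] = PairEffects(beta_snp=0.25)
    sim = SimConfig(
        n_individuals=5000,
        snp_specs=snps,
        reaction_specs=reactions,
        flux_corr=flux_corr,
        eqtl_effects={("rs6", "R7"): 0.2},
        true_effects=true_effects,
        n_pcs=4,
        seed=seed,
    )
    return PipelineConfig(sim=sim, snp_p_threshold=1e-2, outdir=outdir)


# ---------------------------------------------------------------------------
# YAML config loading
# ---------------------------------------------------------------------------


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (see examples/demo_config.yaml)."""
    raw = yaml.safe_load(Path(path).read_text())
    simraw = raw["sim"]
    snps = [SNPSpec(d["name"], float(d["maf"])) for d in simraw["snps"]]
    reactions = [
        ReactionSpec(d["name"], d["organ"], bool(d.get("gene_annotated", True)))
        for d in simraw["reactions"]
    ]
    eqtl = {
        (d["snp"], d["reaction"]): float(d["effect"])
        for d in simraw.get("eqtl_effects", [])
    }
    effects = {}
    for d in simraw.get("true_effects", []):
        effects[(d["snp"], d["reaction"])] = PairEffects(
            beta_snp=float(d.get("beta_snp", 0.0)),
            beta_flux=float(d.get("beta_flux", 0.0)),
            beta_snp2=float(d.get("beta_snp2", 0.0)),
            beta_flux2=float(d.get("beta_flux2", 0.0)),
            beta_interaction=float(d.get("beta_interaction", 0.0)),
        )
    sim = SimConfig(
        n_individuals=int(simraw["n_individuals"]),
        snp_specs=snps,
        reaction_specs=reactions,
        ld_corr=np.asarray(simraw["ld_corr"], dtype=float)
        if "ld_corr" in simraw
        else None,
        flux_corr={
            k: np.asarray(v, dtype=float)
            for k, v in simraw.get("flux_corr", {}).items()
        },
        eqtl_effects=eqtl,
        true_effects=effects,
        censor_age=float(simraw.get("censor_age", 70.0)),
        n_pcs=int(simraw.get("n_pcs", 10)),
        seed=int(simraw.get("seed", 0)),
    )
    pipe = raw.get("pipeline", {})
    return PipelineConfig(
        sim=sim,
        snp_p_threshold=float(pipe.get("snp_p_threshold", 5e-8)),
        r_threshold=float(pipe.get("r_threshold", 0.5)),
        ld_cut=float(pipe.get("ld_cut", 0.4)),
        alpha=float(pipe.get("alpha", 0.05)),
        borderline=float(pipe.get("borderline", 0.25)),
        min_events=int(pipe.get("min_events", 10)),
        outdir=pipe.get("outdir"),
    )
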