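"""Synthetic cohort generator.

Emulates the statistical structure that the interaction analysis assumes:

* genotype dosages under Hardy–Weinberg with tunable minor-allele frequency
  and pairwise LD (a latent-Gaussian haplotype threshold model);
* organ-specific reaction fluxes driven by SNP (eQTL-like) components plus a
  block-correlated Gaussian background, log-flux columns standardized to
  zero mean and unit variance;
* a time-to-event outcome on the age timescale from a stratified Weibull
  proportional-hazards model whose linear predictor carries first-order,
  second-order and interaction terms per SNP–flux pair, plus genetic-PC
  effects, with administrative censoring.

Ground truth (the effect sizes actually used) is returned alongside the
cohort so recovery and calibration are testable without any real data.
A single master seed deterministically spawns per-stage substreams, so the
same config always yields bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

__all__ = [
    "SNPSpec",
    "ReactionSpec",
    "PairEffects",
    "WeibullBaseline",
    "SimConfig",
    "GenotypeDosages",
    "FluxMatrix",
    "SimTruth",
    "SimulatedCohort",
    "simulate_genotypes",
    "simulate_fluxes",
    "simulate_survival",
    "simulate_cohort",
]

SEXES = ("F", "M")
ARRAYS = ("A", "B")
CARDIO_COLUMNS = ("bmi", "sbp", "ldl", "hdl", "tg")
# population-plausible (mean, sd) used only to put the optional
# cardiometabolic covariates on a recognizable scale
_CARDIO_SCALE = {
    "bmi": (27.0, 4.7),
    "sbp": (138.0, 19.0),
    "ldl": (3.6, 0.87),
    "hdl": (1.45, 0.38),
    "tg": (1.75, 1.0),
}


@dataclass(frozen=True)
class SNPSpec:
    name: str
    maf: float


@dataclass(frozen=True)
class ReactionSpec:
    name: str
    organ: str
    gene_annotated: bool = True


@dataclass(frozen=True)
class PairEffects:
    """Log-hazard effect sizes of one SNP–flux pair in the generating model."""

    beta_snp: float = 0.0
    beta_flux: float = 0.0
    beta_snp2: float = 0.0
    beta_flux2: float = 0.0
    beta_interaction: float = 0.0


@dataclass(frozen=True)
class WeibullBaseline:
    """Baseline hazard h0(t) = (shape/scale) * (t/scale)**(shape-1), t in years."""

    shape: float = 5.0
    scale: float = 95.0


def _check_corr(m: np.ndarray, what: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConfigurationError(f"{what} must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ConfigurationError(f"{what} must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-10):
        raise ConfigurationError(f"{what} must have unit diagonal")
    if np.linalg.eigvalsh(m).min() < -1e-8:
        raise ConfigurationError(f"{what} is not positive semidefinite")
    return m


def _chol(m: np.ndarray) -> np.ndarray:
    # tiny jitter tolerates exactly-singular PSD matrices
    return np.linalg.cholesky(m + 1e-10 * np.eye(len(m)))


@dataclass
class SimConfig:
    """Full specification of a synthetic cohort; see module docstring.

    ``flux_corr`` maps organ -> correlation matrix of the Gaussian flux
    background for that organ's reactions (identity when omitted).
    ``eqtl_effects`` maps (snp, reaction) -> raw-flux shift per dosage unit.
    ``true_effects`` maps (snp, reaction) -> :class:`PairEffects`.
    ``baseline`` is one :class:`WeibullBaseline` for every stratum or a
    mapping (sex, array) -> baseline.
    """

    n_individuals: int
    snp_specs: Sequence[SNPSpec]
    reaction_specs: Sequence[ReactionSpec]
    ld_corr: np.ndarray | None = None
    flux_corr: Mapping[str, np.ndarray] = field(default_factory=dict)
    eqtl_effects: Mapping[tuple, float] = field(default_factory=dict)
    true_effects: Mapping[tuple, PairEffects] = field(default_factory=dict)
    baseline: WeibullBaseline | Mapping[tuple, WeibullBaseline] = field(
        default_factory=WeibullBaseline
    )
    censor_age: float = 70.0
    n_pcs: int = 10
    pc_effects: np.ndarray | None = None
    p_female: float = 0.54
    p_array_b: float = 0.10
    cardio_covariates: bool = False
    cardio_flux_corr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ConfigurationError("n_individuals must be positive")
        if self.censor_age <= 0:
            raise ConfigurationError("censor_age must be positive")
        for s in self.snp_specs:
            if not (0.0 < s.maf <= 0.5):
                raise ConfigurationError(f"MAF of {s.name} must lie in (0, 0.5]")
        names = [s.name for s in self.snp_specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate SNP names")
        rnames = [r.name for r in self.reaction_specs]
        if len(set(rnames)) != len(rnames):
            raise ConfigurationError("duplicate reaction names")
        if self.ld_corr is None:
            self.ld_corr = np.eye(len(self.snp_specs))
        self.ld_corr = _check_corr(np.asarray(self.ld_corr), "ld_corr")
        if self.ld_corr.shape[0] != len(self.snp_specs):
            raise ConfigurationError("ld_corr size does not match snp_specs")
        organs = {r.organ for r in self.reaction_specs}
        for organ, m in self.flux_corr.items():
            if organ not in organs:
                raise ConfigurationError(f"flux_corr names unknown organ {organ!r}")
            n_org = sum(r.organ == organ for r in self.reaction_specs)
            m = _check_corr(np.asarray(m), f"flux_corr[{organ!r}]")
            if m.shape[0] != n_org:
                raise ConfigurationError(f"flux_corr[{organ!r}] size mismatch")
        for snp, reaction in list(self.eqtl_effects) + list(self.true_effects):
            if snp not in names:
                raise ConfigurationError(f"unknown SNP {snp!r} in effects mapping")
            if reaction not in rnames:
                raise ConfigurationError(
                    f"unknown reaction {reaction!r} in effects mapping"
                )
        if self.pc_effects is None:
            self.pc_effects = np.zeros(self.n_pcs)
        self.pc_effects = np.asarray(self.pc_effects, dtype=float)
        if len(self.pc_effects) != self.n_pcs:
            raise ConfigurationError("pc_effects length must equal n_pcs")
        for b in self._baselines().values():
            if b.shape <= 0 or b.scale <= 0:
                raise ConfigurationError("Weibull shape and scale must be positive")

    def _baselines(self) -> dict:
        if isinstance(self.baseline, WeibullBaseline):
            return {(s, a): self.baseline for s in SEXES for a in ARRAYS}
        return dict(self.baseline)

    def rngs(self) -> dict:
        """Deterministic per-stage substreams spawned from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        keys = ("genotypes", "fluxes", "survival", "covariates")
        return {k: np.random.default_rng(c) for k, c in zip(keys, children)}


@dataclass
class GenotypeDosages:
    """n_individuals x n_snps risk-allele dosages in [0, 2]."""

    dosages: np.ndarray
    snp_names: list
    maf_realized: np.ndarray

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def column(self, snp: str) -> np.ndarray:
        return self.dosages[:, self.snp_names.index(snp)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, columns=self.snp_names)


@dataclass
class FluxMatrix:
    """n_individuals x n_reactions standardized log2 flux values."""

    values: np.ndarray
    reaction_names: list
    organs: list
    gene_annotated: np.ndarray

    @property
    def n_reactions(self) -> int:
        return self.values.shape[1]

    def column(self, reaction: str) -> np.ndarray:
        return self.values[:, self.reaction_names.index(reaction)]

    def organ_of(self, reaction: str) -> str:
        return self.organs[self.reaction_names.index(reaction)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.reaction_names)


@dataclass
class SimTruth:
    """Generating parameters actually used; keys match the SimConfig."""

    true_effects: dict
    baselines: dict
    eqtl_effects: dict
    censor_age: float
    pc_effects: np.ndarray


@dataclass
class SimulatedCohort:
    genotypes: GenotypeDosages
    fluxes: FluxMatrix
    cohort: pd.DataFrame
    truth: SimTruth


def simulate_genotypes(config: SimConfig, rng=None) -> GenotypeDosages:
    """Draw dosages from a latent-Gaussian haplotype threshold model.

    Two haplotype indicator vectors are sampled per individual from a
    multivariate normal with correlation ``ld_corr``; a haplotype carries the
    risk allele when its latent value falls below the MAF-quantile threshold.
    The dosage is the sum of the two haplotypes, giving Hardy–Weinberg
    genotype frequencies marginally and tunable pairwise dosage R².
    """
    if rng is None:
        rng = config.rngs()["genotypes"]
    n, s = config.n_individuals, len(config.snp_specs)
    L = _chol(config.ld_corr)
    thresholds = stats.norm.ppf([spec.maf for spec in config.snp_specs])
    Z = rng.standard_normal((2, n, s)) @ L.T
    haplotypes = (Z < thresholds).astype(float)
    dosages = haplotypes.sum(axis=0)
    return GenotypeDosages(
        dosages=dosages,
        snp_names=[spec.name for spec in config.snp_specs],
        maf_realized=dosages.mean(axis=0) / 2.0,
    )


def simulate_fluxes(
    genotypes: GenotypeDosages, config: SimConfig, rng=None
) -> FluxMatrix:
    """Raw flux = sum of eQTL dosage effects + correlated Gaussian background,
    then each column standardized to mean 0, variance 1 (ddof=0)."""
    if rng is None:
        rng = config.rngs()["fluxes"]
    n = config.n_individuals
    rnames = [r.name for r in config.reaction_specs]
    organs = [r.organ for r in config.reaction_specs]
    raw = np.zeros((n, len(rnames)))
    # per-organ correlated noise
    for organ in dict.fromkeys(organs):  # stable order
        idx = [j for j, o in enumerate(organs) if o == organ]
        corr = config.flux_corr.get(organ)
        noise = rng.standard_normal((n, len(idx)))
        if corr is not None:
            noise = noise @ _chol(np.asarray(corr, dtype=float)).T
        raw[:, idx] += noise
    for (snp, reaction), effect in config.eqtl_effects.items():
        raw[:, rnames.index(reaction)] += effect * genotypes.column(snp)
    std = raw.std(axis=0)
    if np.any(std == 0):
        raise ConfigurationError("degenerate (constant) simulated flux column")
    values = (raw - raw.mean(axis=0)) / std
    return FluxMatrix(
        values=values,
        reaction_names=rnames,
        organs=organs,
        gene_annotated=np.array([r.gene_annotated for r in config.reaction_specs]),
    )


def _linear_predictor(genotypes, fluxes, config, pcs) -> np.ndarray:
    eta = pcs @ config.pc_effects if config.n_pcs else np.zeros(config.n_individuals)
    for (snp, reaction), eff in config.true_effects.items():
        s = genotypes.column(snp)
        f = fluxes.column(reaction)
        eta = eta + (
            eff.beta_snp * s
            + eff.beta_flux * f
            + eff.beta_snp2 * s**2
            + eff.beta_flux2 * f**2
            + eff.beta_interaction * s * f
        )
    return eta


def simulate_survival(
    genotypes: GenotypeDosages,
    fluxes: FluxMatrix,
    config: SimConfig,
    rng=None,
    rng_cov=None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw event ages by inverse transform from the stratified Weibull
    proportional-hazards model, censoring administratively at ``censor_age``.

    With baseline survival S0(t) = exp(-(t/scale)**shape) and linear
    predictor eta, the event age solves (T/scale)**shape * exp(eta) = E with
    E ~ Exp(1), i.e. T = scale * (E * exp(-eta))**(1/shape).
    """
    rngs = None
    if rng is None or rng_cov is None:
        rngs = config.rngs()
        rng = rng or rngs["survival"]
        rng_cov = rng_cov or rngs["covariates"]
    n = config.n_individuals
    sex = np.where(rng.random(n) < config.p_female, "F", "M")
    array = np.where(rng.random(n) < config.p_array_b, "B", "A")
    pcs = rng.standard_normal((n, config.n_pcs)) if config.n_pcs else np.zeros((n, 0))
    eta = _linear_predictor(genotypes, fluxes, config, pcs)

    baselines = config._baselines()
    shape = np.empty(n)
    scale = np.empty(n)
    for (sx, ar), b in baselines.items():
        mask = (sex == sx) & (array == ar)
        shape[mask] = b.shape
        scale[mask] = b.scale
    E = rng.exponential(size=n)
    t_event = scale * (E * np.exp(-eta)) ** (1.0 / shape)
    event = (t_event <= config.censor_age).astype(int)
    age = np.minimum(t_event, config.censor_age)
    age = np.maximum(age, 1e-8)  # ages strictly positive

    data = {"event": event, "age": age, "sex": sex, "array": array}
    for j in range(config.n_pcs):
        data[f"PC{j + 1}"] = pcs[:, j]
    if config.cardio_covariates:
        rho = float(config.cardio_flux_corr)
        if not -1.0 < rho < 1.0:
            raise ConfigurationError("cardio_flux_corr must lie in (-1, 1)")
        # latent signal shared with the fluxes, on a standardized scale
        signal = (
            fluxes.values.mean(axis=1) / max(fluxes.values.mean(axis=1).std(), 1e-12)
            if fluxes.n_reactions
            else np.zeros(n)
        )
        for name in CARDIO_COLUMNS:
            mean, sd = _CARDIO_SCALE[name]
            z = rho * signal + np.sqrt(1 - rho**2) * rng_cov.standard_normal(n)
            data[name] = mean + sd * z
    cohort = pd.DataFrame(data)
    truth = SimTruth(
        true_effects=dict(config.true_effects),
        baselines=baselines,
        eqtl_effects=dict(config.eqtl_effects),
        censor_age=config.censor_age,
        pc_effects=config.pc_effects.copy(),
    )
    return cohort, truth


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Run all three stages with the config's deterministic substreams."""
    rngs = config.rngs()
    genotypes = simulate_genotypes(config, rngs["genotypes"])
    fluxes = simulate_fluxes(genotypes, config, rngs["fluxes"])
    cohort, truth = simulate_survival(
        genotypes, fluxes, config, rngs["survival"], rngs["covariates"]
    )
    return SimulatedCohort(genotypes, fluxes, cohort, truth)
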