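"""The two complementary interaction-detection methods for one SNP–flux pair.

Method 1 (interaction effect size test): a stratified Cox model with age as
the timescale and linear predictor

    beta_SNP*SNP + beta_Flux*Flux + beta_SNP2*SNP^2 + beta_Flux2*Flux^2
        + beta_SNPxFlux*SNP*Flux  (+ PCs, + optional cardiometabolic covariates)

where Flux is first adjusted by regressing out the SNP dosage (to guard
against spurious interactions when the genetically predicted flux is itself
correlated with the risk allele). Significance is a two-tailed Wald test on
the interaction term.

Method 2 (dosage-specific test): individuals are split by hard-called risk
allele dosage (0, 1, 2); the flux effect on disease risk is estimated within
each dosage group by its own Cox fit; heterogeneity of the three estimates
is tested with Welch's ANOVA (no homogeneity-of-variance assumption), and an
interaction-comparable slope is obtained by inverse-variance weighted linear
regression of the per-dosage flux effects on dosage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cox import CoxFitResult, fit_cox, wald_p
from .errors import DegenerateDesignError, FitError, ValidationError

__all__ = [
    "InteractionResult",
    "DosageStratumResult",
    "DosageTestResult",
    "PairTestResult",
    "adjust_flux_for_snp",
    "interaction_effect_test",
    "hard_call_dosage",
    "dosage_specific_fits",
    "welch_anova",
    "weighted_dosage_slope",
    "test_pair",
]

INTERACTION_TERM = "snp_x_flux"


@dataclass
class InteractionResult:
    beta_interaction: float
    se: float
    p: float
    fit: CoxFitResult
    with_cardio: bool = False


@dataclass
class DosageStratumResult:
    """Per-dosage flux effect estimates; absent strata have NaN beta/se."""

    beta: np.ndarray  # length 3, index = dosage 0/1/2
    se: np.ndarray
    n: np.ndarray
    events: np.ndarray
    present: np.ndarray  # bool

    def n_present(self) -> int:
        return int(self.present.sum())


@dataclass
class DosageTestResult:
    F: float
    df1: float
    df2: float
    p: float
    slope: float
    slope_se: float
    strata: DosageStratumResult


@dataclass
class PairTestResult:
    """Both methods' outputs for one SNP–flux pair (NaN-filled on failure)."""

    snp: str
    reaction: str
    organ: str
    interaction: InteractionResult | None = None
    dosage_test: DosageTestResult | None = None
    error: str | None = None


def _strata_labels(cohort: pd.DataFrame) -> pd.Series:
    parts = [cohort[c].astype(str) for c in ("sex", "array") if c in cohort]
    if not parts:
        return pd.Series(["all"] * len(cohort), index=cohort.index)
    out = parts[0]
    for p in parts[1:]:
        out = out + "|" + p
    return out


def _pc_columns(cohort: pd.DataFrame) -> list:
    return [c for c in cohort.columns if c.startswith("PC")]


def adjust_flux_for_snp(flux: np.ndarray, dosage: np.ndarray) -> np.ndarray:
    """OLS residuals of flux on (intercept, dosage); not re-standardized."""
    flux = np.asarray(flux, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if flux.shape != dosage.shape:
        raise ValidationError("flux and dosage lengths differ")
    if np.ptp(dosage) == 0:
        raise DegenerateDesignError("dosage is constant; adjustment undefined")
    d = dosage - dosage.mean()
    f = flux - flux.mean()
    slope = (d @ f) / (d @ d)
    return f - slope * d


def interaction_effect_test(
    cohort: pd.DataFrame,
    dosage: np.ndarray,
    flux_adjusted: np.ndarray,
    *,
    extra_covariates: tuple = (),
) -> InteractionResult:
    """Fit the five-term stratified Cox model and Wald-test the interaction.

    ``flux_adjusted`` must already have the dosage regressed out (see
    :func:`adjust_flux_for_snp`). ``extra_covariates`` names cohort columns
    (e.g. the cardiometabolic set) added for the sensitivity variant.
    """
    dosage = np.asarray(dosage, dtype=float)
    flux = np.asarray(flux_adjusted, dtype=float)
    inter = dosage * flux
    if np.ptp(inter) == 0:
        raise DegenerateDesignError("interaction column has no variation")
    design = pd.DataFrame(
        {
            "snp": dosage,
            "flux": flux,
            "snp_sq": dosage**2,
            "flux_sq": flux**2,
            INTERACTION_TERM: inter,
        },
        index=cohort.index,
    )
    for c in _pc_columns(cohort) + list(extra_covariates):
        design[c] = cohort[c]
    fit = fit_cox(cohort["age"], cohort["event"], design, _strata_labels(cohort))
    if not fit.converged:
        raise FitError("interaction model did not converge")
    return InteractionResult(
        beta_interaction=float(fit.params[INTERACTION_TERM]),
        se=float(fit.se[INTERACTION_TERM]),
        p=wald_p(fit, INTERACTION_TERM),
        fit=fit,
        with_cardio=bool(extra_covariates),
    )


def hard_call_dosage(dosage: np.ndarray) -> np.ndarray:
    """Nearest-integer dosage calls in {0,1,2}; ties at .5 round up."""
    dosage = np.asarray(dosage, dtype=float)
    if np.any(dosage < 0) or np.any(dosage > 2):
        raise ValidationError("dosage values must lie in [0, 2]")
    return np.floor(dosage + 0.5).astype(int)


def dosage_specific_fits(
    cohort: pd.DataFrame,
    dosage_calls: np.ndarray,
    flux: np.ndarray,
    *,
    extra_covariates: tuple = (),
    min_events: int = 10,
) -> DosageStratumResult:
    """One stratified Cox fit of flux per dosage group (unadjusted flux).

    Groups with fewer than ``min_events`` events are flagged absent rather
    than fitted; downstream tests require at least two present groups.
    """
    calls = np.asarray(dosage_calls)
    flux = np.asarray(flux, dtype=float)
    beta = np.full(3, np.nan)
    se = np.full(3, np.nan)
    n = np.zeros(3, dtype=int)
    events = np.zeros(3, dtype=int)
    present = np.zeros(3, dtype=bool)
    for i in range(3):
        mask = calls == i
        n[i] = int(mask.sum())
        sub = cohort.loc[mask]
        events[i] = int(sub["event"].sum()) if n[i] else 0
        if events[i] < min_events:
            continue
        design = pd.DataFrame({"flux": flux[mask]}, index=sub.index)
        for c in _pc_columns(cohort) + list(extra_covariates):
            design[c] = sub[c]
        try:
            fit = fit_cox(sub["age"], sub["event"], design, _strata_labels(sub))
        except (FitError, DegenerateDesignError):
            continue
        if not fit.converged:
            continue
        beta[i] = fit.params["flux"]
        se[i] = fit.se["flux"]
        present[i] = True
    return DosageStratumResult(beta=beta, se=se, n=n, events=events, present=present)


def welch_anova(estimates: DosageStratumResult):
    """Welch's heteroscedastic ANOVA on the per-dosage effect estimates.

    Each dosage group enters as a "sample mean" beta_i whose squared
    standard error SE_i^2 plays the role of s_i^2/n_i; the group size n_i
    enters only the Welch–Satterthwaite degrees-of-freedom correction.
    Returns (F, df1, df2, p).
    """
    mask = estimates.present
    k = int(mask.sum())
    if k < 2:
        raise ValidationError("Welch ANOVA needs >= 2 dosage groups with estimates")
    b = estimates.beta[mask]
    se2 = estimates.se[mask] ** 2
    nn = estimates.n[mask].astype(float)
    if np.any(se2 <= 0) or not np.all(np.isfinite(se2)):
        raise ValidationError("non-positive or non-finite SE in Welch ANOVA")
    w = 1.0 / se2
    W = w.sum()
    xbar = (w * b).sum() / W
    num = (w * (b - xbar) ** 2).sum() / (k - 1)
    lam = (((1.0 - w / W) ** 2) / (nn - 1.0)).sum()
    denom = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * lam
    F = float(num / denom)
    df1 = float(k - 1)
    df2 = float((k**2 - 1.0) / (3.0 * lam)) if lam > 0 else np.inf
    p = float(stats.f.sf(F, df1, df2))
    return F, df1, df2, p


def weighted_dosage_slope(estimates: DosageStratumResult):
    """Inverse-variance weighted LS slope of beta_i on dosage i; (slope, SE)."""
    mask = estimates.present
    if int(mask.sum()) < 2:
        raise ValidationError("weighted slope needs >= 2 dosage groups")
    b = estimates.beta[mask]
    se2 = estimates.se[mask] ** 2
    if np.any(se2 <= 0) or not np.all(np.isfinite(se2)):
        raise ValidationError("non-positive or non-finite SE in weighted slope")
    x = np.flatnonzero(mask).astype(float)
    w = 1.0 / se2
    X = np.column_stack([np.ones_like(x), x])
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    coef = cov @ (XtW @ b)
    return float(coef[1]), float(np.sqrt(cov[1, 1]))


def test_pair(
    cohort: pd.DataFrame,
    dosage: np.ndarray,
    flux: np.ndarray,
    *,
    snp: str = "snp",
    reaction: str = "reaction",
    organ: str = "organ",
    extra_covariates: tuple = (),
    min_events: int = 10,
) -> PairTestResult:
    """Run both methods on one pair, isolating failures instead of raising."""
    result = PairTestResult(snp=snp, reaction=reaction, organ=organ)
    try:
        adjusted = adjust_flux_for_snp(flux, dosage)
        result.interaction = interaction_effect_test(
            cohort, dosage, adjusted, extra_covariates=extra_covariates
        )
        calls = hard_call_dosage(dosage)
        strata = dosage_specific_fits(
            cohort,
            calls,
            flux,
            extra_covariates=extra_covariates,
            min_events=min_events,
        )
        F, df1, df2, p = welch_anova(strata)
        slope, slope_se = weighted_dosage_slope(strata)
        result.dosage_test = DosageTestResult(
            F=F, df1=df1, df2=df2, p=p, slope=slope, slope_se=slope_se, strata=strata
        )
    except (FitError, DegenerateDesignError, ValidationError) as exc:
        result.error = f"{type(exc).__name__}: {exc}"
    return result
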