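"""Correlated-flux pruning and the univariate screens.

Reaction fluxes in a metabolic network are often strongly correlated
(stoichiometric coupling, shared carriers). To keep the tested pair set
interpretable, pairs are ranked by the *worse* of their two interaction
p-values and a greedy pass retains the best-ranked reaction while removing
every same-organ reaction correlated with it beyond the threshold (default
|r| > 0.5), together with all pairs involving the removed reactions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import bh_adjust
from .cox import fit_cox
from .errors import DegenerateDesignError, FitError, ValidationError
from .interaction import _pc_columns, _strata_labels
from .simulate import FluxMatrix, GenotypeDosages

__all__ = [
    "flux_correlation",
    "prune_pairs",
    "PruneResult",
    "univariate_flux_screen",
    "univariate_snp_screen",
]

logger = logging.getLogger(__name__)


def flux_correlation(fluxes: FluxMatrix, organ: str) -> pd.DataFrame:
    """Pairwise Pearson correlation of all reaction fluxes within one organ.

    Constant columns cannot be correlated; they are excluded with a warning.
    """
    names = [n for n, o in zip(fluxes.reaction_names, fluxes.organs) if o == organ]
    if len(names) < 2:
        raise ValidationError(f"organ {organ!r} has fewer than 2 reactions")
    cols = np.column_stack([fluxes.column(n) for n in names])
    keep = cols.std(axis=0) > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"constant flux column(s) excluded from correlation: {dropped}")
        names = [n for n, k in zip(names, keep) if k]
        cols = cols[:, keep]
    r = np.corrcoef(cols, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=names, columns=names)


@dataclass
class PruneResult:
    retained_pairs: pd.DataFrame
    retained_reactions: list
    removal_log: pd.DataFrame  # removed, kept, r, step


def prune_pairs(
    pairs: pd.DataFrame,
    correlations: dict,
    r_threshold: float = 0.5,
) -> PruneResult:
    """Greedy correlation pruning of SNP–reaction pairs.

    ``pairs`` needs columns snp, reaction, organ, p_interaction, p_dosage;
    ``correlations`` maps organ -> correlation DataFrame covering that
    organ's reactions. Pairs are visited in ascending max(p_interaction,
    p_dosage) order (ties broken by reaction then SNP name); the first visit
    to a surviving reaction keeps it and removes every same-organ reaction
    with |r| above the threshold. The threshold is applied to |r|: flux
    coupling can be stoichiometrically negative.
    """
    df = pairs.copy()
    for _, row in df.iterrows():
        corr = correlations.get(row["organ"])
        if corr is None or row["reaction"] not in corr.index:
            raise ValidationError(
                f"no correlation entry for reaction {row['reaction']!r} "
                f"in organ {row['organ']!r}"
            )
    organ_of = dict(zip(df["reaction"], df["organ"]))
    for reaction, organ in zip(pairs["reaction"], pairs["organ"]):
        if organ_of[reaction] != organ:
            raise ValidationError(f"reaction {reaction!r} has inconsistent organs")

    df["_maxp"] = df[["p_interaction", "p_dosage"]].max(axis=1)
    df = df.sort_values(["_maxp", "reaction", "snp"], kind="mergesort")

    removed: set = set()
    kept: list = []
    log_rows = []
    step = 0
    for _, row in df.iterrows():
        reaction = row["reaction"]
        if reaction in removed:
            continue
        if reaction not in kept:
            kept.append(reaction)
            step += 1
            corr = correlations[row["organ"]]
            r_vec = corr[reaction]
            for other in corr.index:
                if other == reaction or other in removed or other in kept:
                    continue
                if abs(r_vec[other]) > r_threshold:
                    removed.add(other)
                    log_rows.append(
                        {
                            "removed": other,
                            "kept": reaction,
                            "r": float(r_vec[other]),
                            "step": step,
                        }
                    )
    retained = pairs[~pairs["reaction"].isin(removed)].copy()
    removal_log = pd.DataFrame(log_rows, columns=["removed", "kept", "r", "step"])
    return PruneResult(
        retained_pairs=retained,
        retained_reactions=kept,
        removal_log=removal_log,
    )


def _univariate_cox(cohort: pd.DataFrame, exposure: np.ndarray, name: str):
    design = pd.DataFrame({name: exposure}, index=cohort.index)
    for c in _pc_columns(cohort):
        design[c] = cohort[c]
    fit = fit_cox(cohort["age"], cohort["event"], design, _strata_labels(cohort))
    if not fit.converged:
        raise FitError(f"univariate fit for {name!r} did not converge")
    return float(fit.params[name]), float(fit.se[name]), float(fit.p[name])


def univariate_flux_screen(cohort: pd.DataFrame, fluxes: FluxMatrix) -> pd.DataFrame:
    """Per-reaction Cox fit (flux + PCs, sex/array strata) with BH-FDR.

    The fluxome-wide association screen: one row per reaction with beta, se,
    p and fdr; reactions whose fit fails are emitted with NaN and logged.
    """
    rows = []
    for name in fluxes.reaction_names:
        try:
            beta, se, p = _univariate_cox(cohort, fluxes.column(name), "flux")
        except (FitError, DegenerateDesignError) as exc:
            logger.warning("flux screen failed for %s: %s", name, exc)
            beta = se = p = np.nan
        rows.append(
            {"reaction": name, "organ": fluxes.organ_of(name), "beta": beta,
             "se": se, "p": p}
        )
    out = pd.DataFrame(rows, columns=["reaction", "organ", "beta", "se", "p"])
    fdr = np.full(len(out), np.nan)
    ok = out["p"].notna().to_numpy()
    if ok.any():
        fdr[ok] = bh_adjust(out.loc[ok, "p"])
    out["fdr"] = fdr
    return out


def univariate_snp_screen(
    cohort: pd.DataFrame,
    genotypes: GenotypeDosages,
    threshold: float = 5e-8,
) -> pd.DataFrame:
    """Per-SNP Cox screen; returns SNPs with p below the threshold.

    Monomorphic SNPs are excluded with a warning. Columns: snp, beta, se, p.
    """
    rows = []
    for name in genotypes.snp_names:
        dosage = genotypes.column(name)
        if np.ptp(dosage) == 0:
            warnings.warn(f"monomorphic SNP {name!r} excluded from screen")
            continue
        try:
            beta, se, p = _univariate_cox(cohort, dosage, "snp")
        except (FitError, DegenerateDesignError) as exc:
            warnings.warn(f"SNP screen failed for {name!r}: {exc}")
            continue
        rows.append({"snp": name, "beta": beta, "se": se, "p": p})
    out = pd.DataFrame(rows, columns=["snp", "beta", "se", "p"])
    return out[out["p"] < threshold].reset_index(drop=True)
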