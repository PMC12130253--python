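"""Multiplicity control and the intersection calling rule.

A buffering/amplification event must be significant under *both* the
interaction effect size test and the dosage-specific test after
Benjamini–Hochberg adjustment (FDR < 0.05); pairs under 0.25 for both are
labelled borderline. Direction follows the sign of the interaction
coefficient: positive = amplification, negative = buffering.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = ["bh_adjust", "call_pairs", "CALL_LEVELS"]

logger = logging.getLogger(__name__)

CALL_LEVELS = ("significant", "borderline", "null")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_pairs(
    results: pd.DataFrame, alpha: float = 0.05, borderline: float = 0.25
) -> pd.DataFrame:
    """Adjust both p-value columns with BH and apply the intersection rule.

    ``results`` needs columns ``p_interaction``, ``p_dosage`` and
    ``beta_interaction`` (one row per post-pruning pair; both adjustments run
    over that same pair set). Rows with missing p-values get no call and are
    logged. Returns a copy with ``fdr_interaction``, ``fdr_dosage``,
    ``call`` and ``direction`` columns appended.
    """
    out = results.copy()
    n = len(out)
    fdr_i = np.full(n, np.nan)
    fdr_d = np.full(n, np.nan)
    valid = (
        out["p_interaction"].notna().to_numpy() & out["p_dosage"].notna().to_numpy()
    )
    if np.any(~valid):
        logger.warning(
            "%d pair(s) missing a p-value; emitted without a call", int((~valid).sum())
        )
    if valid.any():
        fdr_i[valid] = bh_adjust(out.loc[valid, "p_interaction"])
        fdr_d[valid] = bh_adjust(out.loc[valid, "p_dosage"])
    out["fdr_interaction"] = fdr_i
    out["fdr_dosage"] = fdr_d

    call = np.full(n, None, dtype=object)
    sig = valid & (fdr_i < alpha) & (fdr_d < alpha)
    bord = valid & ~sig & (fdr_i < borderline) & (fdr_d < borderline)
    call[sig] = "significant"
    call[bord] = "borderline"
    call[valid & ~sig & ~bord] = "null"
    out["call"] = call
    direction = np.where(
        out["beta_interaction"].to_numpy() > 0, "amplification", "buffering"
    )
    out["direction"] = np.where(
        out["beta_interaction"].notna(), direction, None
    )
    return out
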