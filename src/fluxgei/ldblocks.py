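"""LD-block definition and locus-level aggregation of significant pairs.

Independent risk loci are defined by single-linkage ("friends of friends")
clustering of 1 - R^2 between risk variants, cutting the tree at height 0.4.
For single linkage this partition equals the connected components of the
graph joining SNP pairs with R^2 strictly greater than 0.6, which is how it
is computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ValidationError
from .simulate import GenotypeDosages

__all__ = [
    "LDBlockAssignment",
    "pairwise_r2",
    "single_linkage_blocks",
    "aggregate_locus_flux_pairs",
]


@dataclass
class LDBlockAssignment:
    block_of: dict  # SNP -> block id
    members: dict  # block id -> list of SNPs

    @property
    def n_blocks(self) -> int:
        return len(self.members)


def pairwise_r2(genotypes: GenotypeDosages, snp_subset=None) -> pd.DataFrame:
    """Squared Pearson correlation of dosage vectors (symmetric, unit diag)."""
    names = list(snp_subset) if snp_subset is not None else list(genotypes.snp_names)
    if len(names) < 2:
        raise ValidationError("need at least 2 SNPs for pairwise R^2")
    cols = np.column_stack([genotypes.column(n) for n in names])
    sd = cols.std(axis=0)
    if np.any(sd == 0):
        bad = [n for n, s in zip(names, sd) if s == 0]
        raise ValidationError(f"constant dosage for SNP(s): {bad}")
    r2 = np.corrcoef(cols, rowvar=False) ** 2
    np.fill_diagonal(r2, 1.0)
    return pd.DataFrame(r2, index=names, columns=names)


def single_linkage_blocks(r2: pd.DataFrame, cut: float = 0.4) -> LDBlockAssignment:
    """Cut the single-linkage tree on 1-R^2 at ``cut``.

    Equivalent formulation used here: connected components of the graph with
    an edge wherever 1-R^2 < cut, i.e. R^2 strictly above 1-cut (an exact
    boundary value does not join). Singleton blocks are permitted. Block ids
    are consecutive integers ordered by each block's first SNP.
    """
    m = r2.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-10):
        raise ValidationError("R^2 matrix must be square and symmetric")
    adj = m > (1.0 - cut)
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    names = list(r2.index)
    # relabel in order of first appearance for determinism
    relabel = {}
    block_of = {}
    members: dict = {}
    for name, lab in zip(names, labels):
        b = relabel.setdefault(lab, len(relabel))
        block_of[name] = b
        members.setdefault(b, []).append(name)
    # structural invariant: every member of a multi-SNP block has a strict
    # R^2 partner inside the block
    for b, snps in members.items():
        if len(snps) < 2:
            continue
        idx = [names.index(s) for s in snps]
        sub = m[np.ix_(idx, idx)]
        np.fill_diagonal(sub, 0.0)
        assert np.all(sub.max(axis=1) > 1.0 - cut)
    return LDBlockAssignment(block_of=block_of, members=members)


def aggregate_locus_flux_pairs(
    calls: pd.DataFrame, blocks: LDBlockAssignment
) -> pd.DataFrame:
    """Collapse significant SNP-level calls to distinct (locus, reaction) pairs.

    Returns one row per (block, reaction) among rows with call ==
    "significant": member SNP count and a direction summary (the common
    direction, or "mixed").
    """
    sig = calls[calls["call"] == "significant"]
    unmapped = set(sig["snp"]) - set(blocks.block_of)
    if unmapped:
        raise ValidationError(f"SNP(s) without an LD block: {sorted(unmapped)}")
    rows = []
    if len(sig):
        grouped = sig.assign(block=[blocks.block_of[s] for s in sig["snp"]]).groupby(
            ["block", "reaction"], sort=True
        )
        for (block, reaction), g in grouped:
            directions = set(g["direction"])
            rows.append(
                {
                    "block": block,
                    "reaction": reaction,
                    "organ": g["organ"].iloc[0],
                    "n_snps": g["snp"].nunique(),
                    "direction": directions.pop() if len(directions) == 1 else "mixed",
                }
            )
    return pd.DataFrame(
        rows, columns=["block", "reaction", "organ", "n_snps", "direction"]
    )
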