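"""Tab-separated text I/O for cohorts, dosages, fluxes and results.

All tables are written as plain TSV with a header row; result tables carry
commented metadata lines (``# key: value``) ahead of the header. The flux
matrix is stored as two files: ``<path>`` with the value matrix and
``<path>`` with suffix ``.reactions.tsv`` holding per-reaction organ and
gene-annotation labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .simulate import FluxMatrix, GenotypeDosages, SimTruth

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_genotypes",
    "read_genotypes",
    "write_fluxes",
    "read_fluxes",
    "write_sim_truth",
    "write_table",
    "read_table",
]

SCHEMA_VERSION = "1"


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# schema_version: {SCHEMA_VERSION}\n")
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    write_table(cohort, path)


def read_cohort(path) -> pd.DataFrame:
    df = read_table(path)
    for col in ("event", "age", "sex"):
        if col not in df.columns:
            raise ValidationError(f"cohort file {path} lacks column {col!r}")
    if (df["age"] <= 0).any():
        raise ValidationError(f"cohort file {path}: ages must be strictly positive")
    if not set(df["event"]) <= {0, 1}:
        raise ValidationError(f"cohort file {path}: event must be 0/1")
    return df


def write_genotypes(genotypes: GenotypeDosages, path) -> None:
    write_table(genotypes.to_frame(), path)


def read_genotypes(path) -> GenotypeDosages:
    df = read_table(path)
    values = df.to_numpy(dtype=float)
    if values.size and (values.min() < 0 or values.max() > 2):
        raise ValidationError(f"dosage file {path}: values must lie in [0, 2]")
    return GenotypeDosages(
        dosages=values,
        snp_names=list(df.columns),
        maf_realized=values.mean(axis=0) / 2.0 if values.size else np.array([]),
    )


def _reactions_path(path) -> Path:
    return Path(str(path) + ".reactions.tsv")


def write_fluxes(fluxes: FluxMatrix, path) -> None:
    write_table(fluxes.to_frame(), path)
    meta = pd.DataFrame(
        {
            "reaction": fluxes.reaction_names,
            "organ": fluxes.organs,
            "gene_annotated": fluxes.gene_annotated.astype(int),
        }
    )
    write_table(meta, _reactions_path(path))


def read_fluxes(path) -> FluxMatrix:
    df = read_table(path)
    meta = read_table(_reactions_path(path))
    if list(df.columns) != list(meta["reaction"]):
        raise ValidationError(f"flux file {path}: reaction metadata mismatch")
    return FluxMatrix(
        values=df.to_numpy(dtype=float),
        reaction_names=list(df.columns),
        organs=list(meta["organ"]),
        gene_annotated=meta["gene_annotated"].to_numpy(dtype=bool),
    )


def write_sim_truth(truth: SimTruth, path) -> None:
    payload = {
        "true_effects": {
            f"{snp}::{reaction}": vars(eff)
            for (snp, reaction), eff in truth.true_effects.items()
        },
        "baselines": {
            f"{sex}|{array}": {"shape": b.shape, "scale": b.scale}
            for (sex, array), b in truth.baselines.items()
        },
        "eqtl_effects": {
            f"{snp}::{reaction}": float(v)
            for (snp, reaction), v in truth.eqtl_effects.items()
        },
        "censor_age": truth.censor_age,
        "pc_effects": [float(x) for x in truth.pc_effects],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
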