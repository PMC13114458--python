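"""Readers and writers for the plain-text interchange formats.

Expression is a TSV (gene rows, sample columns); sample metadata,
radiomic features and covariates are CSV; gene sets use the standard GMT
dialect (name TAB description TAB gene...).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .scoring import ExpressionMatrix, GeneSetCollection


def read_expression(expression_path, metadata_path) -> ExpressionMatrix:
    values = pd.read_csv(expression_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, index_col=0)
    return ExpressionMatrix(values, meta)


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    cats: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, desc, genes = parts[0], parts[1], parts[2:]
            sets[name] = [g for g in genes if g]
            cats[name] = desc if desc in ("hallmark", "neftel", "ivygap_module") else "hallmark"
    return GeneSetCollection(sets, cats)


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.sets.items():
            desc = sets.categories.get(name, "hallmark")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_radiomics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("patient_id", "subcompartment"):
        if col not in df.columns:
            raise ValueError(f"radiomics table lacks column {col!r}")
    return df


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise ValueError("covariates table lacks 'patient_id'")
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
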