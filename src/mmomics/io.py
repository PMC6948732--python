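"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats covered:

* feature-matrix TSV — features as rows, header row of sample ids, empty
  cell = missing;
* protein-group TSV — either the native dialect
  (``protein_id, unique_peptides, score, <samples>``) or a MaxQuant-style
  ``proteinGroups.txt`` subset matched case-insensitively;
* Skyline-style long CSV (``lipid,sample,area``) pivoted to a matrix;
* GCT v1.2 expression matrices;
* GMT gene-set collections;
* metabolic-network JSON
  (``{"metabolites": [{"id", "ubiquitous"}], "reactions": [...]}``);
* two-column id-mapping TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import FeatureMatrix, ProteinTable

__all__ = [
    "read_feature_matrix", "write_feature_matrix",
    "read_protein_table", "read_maxquant", "write_protein_table",
    "read_skyline_long",
    "read_gct", "write_gct",
    "read_gmt", "write_gmt",
    "read_id_mapping",
    "write_provenance",
]


# ---------------------------------------------------------------- TSV matrix
def read_feature_matrix(path, groups: Mapping[str, str], *, scale: str = "raw") -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return FeatureMatrix(values=df, groups=dict(groups), scale=scale)


def write_feature_matrix(m: FeatureMatrix, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = m.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------- proteins
def read_protein_table(path, groups: Mapping[str, str], *, scale: str = "raw") -> ProteinTable:
    """Read the native protein-table dialect.

    Columns: ``protein_id``, ``unique_peptides``, ``score`` then one column
    per sample.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["protein_id", "unique_peptides", "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"protein table missing required columns: {missing}")
    df = df.set_index("protein_id")
    df.index = df.index.astype(str)
    sample_cols = [c for c in df.columns if c not in ("unique_peptides", "score")]
    return ProteinTable(proteins=df[["unique_peptides", "score"]].copy(),
                        intensities=df[sample_cols].astype(float),
                        groups=dict(groups), scale=scale)


def read_maxquant(path, groups: Mapping[str, str], *, intensity_prefix: str = "Intensity ",
                  id_column: str = "Protein IDs") -> ProteinTable:
    """Read a MaxQuant-style ``proteinGroups.txt`` subset.

    Column names are matched case-insensitively: ``Unique peptides``,
    ``Score``, the protein-id column, and per-sample intensity columns
    identified by ``intensity_prefix``. Zero intensities are treated as
    missing, following the convention of that export.
    """
    df = pd.read_csv(path, sep="\t")
    lower = {c.lower(): c for c in df.columns}

    def find(name: str) -> str:
        if name.lower() not in lower:
            raise ValueError(f"protein table missing required column: {name!r}")
        return lower[name.lower()]

    id_col = find(id_column)
    pep_col = find("Unique peptides")
    score_col = find("Score")
    sample_cols = [c for c in df.columns
                   if c.lower().startswith(intensity_prefix.lower())
                   and c.lower() != intensity_prefix.strip().lower()]
    if not sample_cols:
        raise ValueError(f"no intensity columns with prefix {intensity_prefix!r}")
    intens = df[sample_cols].astype(float).replace(0.0, np.nan)
    intens.columns = [c[len(intensity_prefix):] for c in sample_cols]
    intens.index = df[id_col].astype(str)
    proteins = pd.DataFrame({"unique_peptides": df[pep_col].to_numpy(),
                             "score": df[score_col].to_numpy()},
                            index=intens.index)
    proteins.index.name = "protein_id"
    intens.index.name = "protein_id"
    return ProteinTable(proteins=proteins, intensities=intens, groups=dict(groups))


def write_protein_table(t: ProteinTable, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = pd.concat([t.proteins, t.intensities], axis=1)
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------- Skyline
def read_skyline_long(path, groups: Mapping[str, str]) -> FeatureMatrix:
    """Pivot a Skyline-style long export (``lipid,sample,area``) to a matrix."""
    df = pd.read_csv(path)
    lower = {c.lower(): c for c in df.columns}
    missing = [c for c in ("lipid", "sample", "area") if c not in lower]
    if missing:
        raise ValueError(f"Skyline export missing columns: {missing}")
    wide = df.pivot_table(index=lower["lipid"], columns=lower["sample"],
                          values=lower["area"], aggfunc="mean")
    wide.index = wide.index.astype(str)
    wide.columns = [str(c) for c in wide.columns]
    return FeatureMatrix(values=wide, groups=dict(groups), scale="raw")


# ---------------------------------------------------------------- GCT v1.2
def read_gct(path) -> pd.DataFrame:
    """Read a GCT v1.2 expression matrix; returns genes x samples DataFrame.

    The ``Description`` column is dropped; the ``Name`` column becomes the
    index.
    """
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.2",):
            raise ValueError(f"unsupported GCT version line: {version!r}")
        dims = fh.readline().split()
        nrow, ncol = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t")
    if df.shape[0] != nrow or df.shape[1] - 2 != ncol:
        raise ValueError(f"GCT dims line says {nrow}x{ncol}, data is "
                         f"{df.shape[0]}x{df.shape[1] - 2}")
    df = df.set_index(df.columns[0]).drop(columns=[df.columns[1]])
    df.index = df.index.astype(str)
    df.index.name = "Name"
    return df.astype(float)


def write_gct(df: pd.DataFrame, path, descriptions: Mapping[str, str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    desc = [descriptions.get(i, "na") if descriptions else "na" for i in df.index]
    body = df.copy()
    body.insert(0, "Description", desc)
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        body.index.name = "Name"
        body.to_csv(fh, sep="\t")


# ---------------------------------------------------------------- GMT
def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: ``set name \\t description \\t members...``"""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
            sets[parts[0]] = [p for p in parts[2:] if p]
    return sets


def write_gmt(sets: Mapping[str, list[str]], path,
              descriptions: Mapping[str, str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na") if descriptions else "na"
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------- mappings
def read_id_mapping(path) -> dict[str, str]:
    """Two-column TSV mapping source id -> target id (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("id mapping must have two tab-separated columns")
    first = df.iloc[0]
    if first.iloc[0].lower() in ("source", "source_id", "probe", "probe_id"):
        df = df.iloc[1:]
    mapping = {}
    for src, tgt in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if pd.isna(tgt) or not str(tgt):
            raise ValueError(f"empty mapping target for source {src!r}")
        mapping[str(src)] = str(tgt)
    return mapping


# ---------------------------------------------------------------- provenance
def write_provenance(path, *, steps: list, parameters: dict, seed: int | None = None) -> None:
    """JSON sidecar recording processing steps and parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"steps": steps, "parameters": parameters}
    if seed is not None:
        payload["seed"] = seed
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
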