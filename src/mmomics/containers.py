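"""In-memory containers shared across the pipeline.

Two containers carry almost all data between stages:

:class:`FeatureMatrix`
    A numeric features x samples matrix (lipid features, proteins or genes)
    with a two-group sample annotation and an explicit raw/log2 scale flag.
    Missing values are ``NaN``.

:class:`ProteinTable`
    A protein-group table in the style of a search-engine export: one row
    per protein with unique-peptide count and identification score, plus
    per-sample intensity columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix", "ProteinTable"]

RAW = "raw"
LOG2 = "log2"


@dataclass
class FeatureMatrix:
    """Features x samples intensity matrix with group labels.

    Parameters
    ----------
    values
        DataFrame, rows = feature ids, columns = sample ids, ``NaN`` = missing.
    groups
        Mapping from sample id to group label. Must cover every sample.
    scale
        ``"raw"`` (linear intensities, non-negative) or ``"log2"``.
    provenance
        Ordered record of processing steps applied so far.
    """

    values: pd.DataFrame
    groups: Mapping[str, str]
    scale: str = RAW
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.scale not in (RAW, LOG2):
            raise ValueError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        if self.scale == RAW:
            vals = self.values.to_numpy()
            if np.nanmin(vals, initial=np.inf) < 0:
                raise ValueError("raw-scale intensities must be non-negative")

    # -- convenience ---------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.groups[s], None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def with_values(self, values: pd.DataFrame, *, scale: str | None = None,
                    step: str | None = None) -> "FeatureMatrix":
        """Return a copy carrying ``values`` and an extended provenance."""
        prov = list(self.provenance)
        if step is not None:
            prov.append(step)
        return FeatureMatrix(values=values, groups=dict(self.groups),
                             scale=self.scale if scale is None else scale,
                             provenance=prov)

    def copy(self) -> "FeatureMatrix":
        return self.with_values(self.values.copy())


@dataclass
class ProteinTable:
    """Protein-group table: metadata columns plus per-sample intensities."""

    proteins: pd.DataFrame            # index protein_id; unique_peptides, score
    intensities: pd.DataFrame         # index protein_id; columns sample ids
    groups: Mapping[str, str]
    scale: str = RAW
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.proteins.index.has_duplicates:
            dupes = self.proteins.index[self.proteins.index.duplicated()].unique()
            raise ValueError(f"duplicate protein ids: {list(dupes)[:5]}")
        if not self.proteins.index.equals(self.intensities.index):
            raise ValueError("proteins and intensities must share one protein_id index")
        for col in ("unique_peptides", "score"):
            if col not in self.proteins.columns:
                raise ValueError(f"missing required column: {col}")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.proteins.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def as_feature_matrix(self) -> FeatureMatrix:
        return FeatureMatrix(values=self.intensities.copy(), groups=dict(self.groups),
                             scale=self.scale)

    def with_intensities(self, intensities: pd.DataFrame, *, scale: str | None = None,
                         keep: list | None = None, **meta) -> "ProteinTable":
        proteins = self.proteins.loc[intensities.index if keep is None else keep]
        if keep is not None:
            intensities = intensities.loc[keep]
        merged = dict(self.meta)
        merged.update(meta)
        return ProteinTable(proteins=proteins.copy(), intensities=intensities.copy(),
                            groups=dict(self.groups),
                            scale=self.scale if scale is None else scale, meta=merged)
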