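"""In-memory containers shared across the pipeline.

All matrices are pandas DataFrames oriented features x samples (genes,
pathways or drugs as rows; cell lines as columns).  Missing measurements
are NaN and are handled pairwise by downstream statistics, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

CULTURE_TYPES = ("adherent", "suspension")
MEDIA = ("RPMI", "DMEM", "other")

# Alias maps for annotation normalization (case-insensitive).
_MEDIUM_ALIASES = {
    "rpmi": "RPMI",
    "rpmi-1640": "RPMI",
    "rpmi 1640": "RPMI",
    "dmem": "DMEM",
    "dulbecco's modified eagle medium": "DMEM",
}
_CULTURE_ALIASES = {
    "adherent": "adherent",
    "suspension": "suspension",
    "mixed adherent and suspension": "adherent",
}


def normalize_medium(value) -> str | float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    key = str(value).strip().lower()
    if not key:
        return np.nan
    return _MEDIUM_ALIASES.get(key, "other")


def normalize_culture_type(value) -> str | float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    key = str(value).strip().lower()
    if not key:
        return np.nan
    return _CULTURE_ALIASES.get(key, np.nan)


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifiers: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """Log-scale expression, genes x samples, with per-sample annotations.

    ``annotations`` is indexed by sample id with columns ``culture_type``
    (adherent / suspension / NaN) and ``medium`` (RPMI / DMEM / other / NaN).
    """

    values: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        if self.annotations is None:
            self.annotations = pd.DataFrame(
                {"culture_type": np.nan, "medium": np.nan},
                index=self.values.columns,
            )
        missing = self.values.columns.difference(self.annotations.index)
        if len(missing):
            raise ValueError(f"samples without annotation rows: {list(missing)[:10]}")
        self.annotations = self.annotations.loc[self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(sample_ids)], self.annotations.loc[list(sample_ids)]
        )


@dataclass
class GeneSetCollection(Mapping):
    """Named gene (or drug) sets; members deduplicated, order preserved."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {set_id!r} is empty")
            self.sets[set_id] = list(dict.fromkeys(members))

    def __getitem__(self, set_id: str) -> list[str]:
        return self.sets[set_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def set_ids(self) -> list[str]:
        return list(self.sets)


@dataclass
class ScreenMatrix:
    """Per-sample screen readouts (CERES gene effects or drug AUCs).

    ``orientation`` maps every feature to +1/-1 such that
    ``oriented()`` returns values where larger means stronger
    dependency / stronger drug response.
    """

    values: pd.DataFrame  # features x samples
    orientation: pd.Series | None = None
    kind: str = "gene"  # "gene" or "drug"

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "feature")
        _check_unique(self.values.columns, "sample")
        if self.orientation is None:
            self.orientation = pd.Series(1.0, index=self.values.index)
        self.orientation = self.orientation.reindex(self.values.index)
        if self.orientation.isna().any():
            bad = self.orientation.index[self.orientation.isna()].tolist()
            raise ValueError(f"orientation undefined for features: {bad[:10]}")
        if not self.orientation.isin([1, -1]).all():
            raise ValueError("orientation values must be +1 or -1")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def oriented(self) -> pd.DataFrame:
        """Values multiplied by per-feature orientation."""
        return self.values.mul(self.orientation, axis=0)

    def subset_samples(self, sample_ids) -> "ScreenMatrix":
        keep = [s for s in sample_ids if s in self.values.columns]
        return ScreenMatrix(self.values[keep], self.orientation.copy(), self.kind)


@dataclass
class DrugMetadata:
    """Per-drug annotations: target gene symbols, MOA class, regulator direction.

    ``table`` is indexed by drug id with columns ``targets`` (list of gene
    symbols), ``moa`` and ``direction`` ("positive" for agonists/activators,
    "negative" otherwise).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "drug")
        required = {"targets", "moa", "direction"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"drug metadata missing columns: {sorted(missing)}")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.table.index)

    def targets(self, drug_id: str) -> list[str]:
        return list(self.table.at[drug_id, "targets"])

    def direction(self, drug_id: str) -> str:
        return self.table.at[drug_id, "direction"]


@dataclass
class PathwayActivityMatrix:
    """Pathway x sample activity scores (ssGSEA ssNES or NWAS).

    ``stratum`` records the (culture_type, medium) pair the scores were
    computed within; activity is only comparable within a stratum.
    """

    values: pd.DataFrame  # pathways x samples
    method: str = "ssgsea"
    stratum: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "pathway")
        _check_unique(self.values.columns, "sample")

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)
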