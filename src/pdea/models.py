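"""Model/Results interface over the PDEA stages.

``GeneticPDEA`` and ``PharmacologicalPDEA`` are built from data
(activity scores, a screen matrix, a pathway collection); ``fit()``
runs the correlation + enrichment estimation and returns a Results
object carrying the estimates (NES), their uncertainties (permutation
p, FDR q), diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DrugMetadata, GeneSetCollection, PathwayActivityMatrix, ScreenMatrix
from .genetic import (
    DEFAULT_MIN_PAIRS,
    PDEAMatrix,
    combine_datasets,
    genetic_pdea,
    self_dependency,
)
from .gsea import DEFAULT_N_PERM
from .pharm import DEFAULT_MIN_DRUGS, build_drug_sets, pharm_pdea_grid


def _leading_edge_csv(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    if "leading_edge" in out.columns:
        out["leading_edge"] = out["leading_edge"].map(
            lambda xs: ";".join(xs) if isinstance(xs, (list, tuple)) else xs
        )
    return out


@dataclass
class GeneticPDEAResults:
    """Estimated pathway-dependency grid from one genetic screen."""

    pdea: PDEAMatrix
    model: "GeneticPDEA"

    @property
    def grid(self) -> pd.DataFrame:
        return self.pdea.grid

    def nes_matrix(self, include_self: bool = True) -> pd.DataFrame:
        return self.pdea.matrix("nes", include_self)

    def self_dependency(self) -> pd.DataFrame:
        return self_dependency(self.pdea)

    def significant(self, q_max: float = 0.05, include_self: bool = False) -> pd.DataFrame:
        grid = self.grid if include_self else self.grid[~self.grid["self"]]
        return grid[grid["q"] < q_max].reset_index(drop=True)

    def combine_with(self, other: "GeneticPDEAResults",
                     hmp_threshold: float = 0.05,
                     q_threshold: float = 0.05) -> pd.DataFrame:
        return combine_datasets(self.pdea, other.pdea, hmp_threshold, q_threshold)

    def summary(self, q_max: float = 0.05) -> str:
        off = self.grid[~self.grid["self"]]
        diag = self.grid[self.grid["self"]]
        n_sig = int((off["q"] < q_max).sum())
        lines = [
            "Genetic PDEA results",
            "=" * 40,
            f"Activity pathways:        {off['activity_pathway'].nunique()}",
            f"Dependency pathways:      {off['dependency_pathway'].nunique()}",
            f"Off-diagonal tests:       {len(off)}",
            f"Significant (q < {q_max:g}):   {n_sig}",
            f"Self-dependencies:        {len(diag)} "
            f"({int((diag['nes'] > 0).sum())} positive / "
            f"{int((diag['nes'] < 0).sum())} negative NES)",
            f"Permutations per test:    {self.pdea.n_perm}",
        ]
        top = off.nlargest(5, "nes")[
            ["activity_pathway", "dependency_pathway", "nes", "p", "q"]
        ]
        lines += ["", "Strongest positive dependencies:",
                  top.to_string(index=False, float_format=lambda v: f"{v:.3f}")]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        _leading_edge_csv(self.grid).to_csv(path, index=False)


@dataclass
class GeneticPDEA:
    """Genetic pathway dependency model: activity vs gene-knockout fitness."""

    activity: PathwayActivityMatrix
    dependency: ScreenMatrix
    collection: GeneSetCollection
    min_pairs: int = DEFAULT_MIN_PAIRS

    @classmethod
    def from_dataframes(cls, activity: pd.DataFrame, dependency: pd.DataFrame,
                        sets: dict[str, list[str]], orientation: float = -1.0,
                        **kwargs) -> "GeneticPDEA":
        """Build from plain pathway x sample / gene x sample frames.

        ``orientation`` defaults to -1 (CERES input; oriented = -CERES).
        """
        return cls(
            PathwayActivityMatrix(values=activity),
            ScreenMatrix(values=dependency,
                         orientation=pd.Series(orientation, index=dependency.index),
                         kind="gene"),
            GeneSetCollection(sets=sets),
            **kwargs,
        )

    def fit(self, n_perm: int = DEFAULT_N_PERM, seed: int | None = None,
            weight_exponent: float = 1.0) -> GeneticPDEAResults:
        pdea = genetic_pdea(self.activity, self.dependency, self.collection,
                            n_perm=n_perm, seed=seed, min_pairs=self.min_pairs,
                            weight_exponent=weight_exponent)
        return GeneticPDEAResults(pdea=pdea, model=self)


@dataclass
class PharmacologicalPDEAResults:
    """Estimated drug-set enrichment grid from a pharmacological screen."""

    grid: pd.DataFrame
    drug_sets: GeneSetCollection
    model: "PharmacologicalPDEA"
    n_perm: int = DEFAULT_N_PERM

    def significant(self, q_max: float = 0.05) -> pd.DataFrame:
        return self.grid[self.grid["q"] < q_max].reset_index(drop=True)

    def summary(self, q_max: float = 0.05) -> str:
        lines = [
            "Pharmacological PDEA results",
            "=" * 40,
            f"Activity pathways:        {self.grid['activity_pathway'].nunique()}",
            f"Drug sets (>= {self.model.min_drugs} drugs): {len(self.drug_sets)}",
            f"Tests:                    {len(self.grid)}",
            f"Significant (q < {q_max:g}):   {int((self.grid['q'] < q_max).sum())}",
            f"Permutations per test:    {self.n_perm}",
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        _leading_edge_csv(self.grid).to_csv(path, index=False)


@dataclass
class PharmacologicalPDEA:
    """Pharmacological pathway dependency model: activity vs drug response."""

    activity: PathwayActivityMatrix
    drugs: ScreenMatrix
    metadata: DrugMetadata
    collection: GeneSetCollection
    min_pairs: int = DEFAULT_MIN_PAIRS
    min_drugs: int = DEFAULT_MIN_DRUGS
    _drug_sets: GeneSetCollection | None = field(default=None, repr=False)

    @property
    def drug_sets(self) -> GeneSetCollection:
        if self._drug_sets is None:
            self._drug_sets = build_drug_sets(self.metadata, self.collection,
                                              self.min_drugs)
        return self._drug_sets

    def fit(self, n_perm: int = DEFAULT_N_PERM,
            seed: int | None = None) -> PharmacologicalPDEAResults:
        grid = pharm_pdea_grid(self.activity, self.drugs, self.metadata,
                               self.drug_sets, n_perm=n_perm, seed=seed,
                               min_pairs=self.min_pairs, min_drugs=self.min_drugs)
        return PharmacologicalPDEAResults(grid=grid, drug_sets=self.drug_sets,
                                          model=self, n_perm=n_perm)
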