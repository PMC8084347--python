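"""Parallel integration of genetic and pharmacological evidence.

Two integration routes: (1) per drug+target pair, the gene-dependency
and drug-response correlation coefficients are summed and tested against
an empirical permutation null built from the pathway's own coefficient
pools; (2) at the pathway level, Genetic and Pharmacological PDEA grids
are intersected under sign-concordance plus p/q filters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import DrugMetadata

DEFAULT_N_PERM = 1000


def pair_gene_drug(
    profile_gene: pd.Series,
    profile_drug: pd.Series,
    meta: DrugMetadata,
    pathway_id: str,
) -> pd.DataFrame:
    """One row per (drug, annotated target) with both coefficients.

    ``profile_gene``: gene-dependency rhos for one activity pathway;
    ``profile_drug``: oriented drug rhos for the same pathway.  Targets
    absent from the gene profile are dropped (count in attrs); multi-
    target drugs contribute one row per target.
    """
    rows = []
    n_dropped = 0
    for drug in profile_drug.index:
        rho_drug = profile_drug[drug]
        if pd.isna(rho_drug) or drug not in meta.table.index:
            continue
        for target in meta.targets(drug):
            rho_gene = profile_gene.get(target, np.nan)
            if pd.isna(rho_gene):
                n_dropped += 1
                continue
            rows.append({
                "pathway_id": pathway_id, "drug_id": drug, "target_gene": target,
                "rho_gene": float(rho_gene), "rho_drug": float(rho_drug),
                "summed": float(rho_gene) + float(rho_drug),
            })
    out = pd.DataFrame(rows, columns=["pathway_id", "drug_id", "target_gene",
                                      "rho_gene", "rho_drug", "summed"])
    out.attrs["n_dropped_targets"] = n_dropped
    return out


def permutation_test(
    associations: pd.DataFrame,
    gene_pool: np.ndarray,
    drug_pool: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> pd.DataFrame:
    """Empirical one-sided p for each summed coefficient.

    For every row, ``n_perm`` random (gene rho, drug rho) pairs are drawn
    with replacement from the pathway's pools and summed.  The p-value is
    the share of same-signed permuted sums at least as large in magnitude
    as the observed sum, among all same-signed permuted sums.  A row with
    observed sum 0 gets p = 1; a row with zero same-signed permutations
    gets the 1/n_perm floor and is flagged.  Both the raw ratio and the
    floored p are returned.
    """
    rng = np.random.default_rng(seed)
    gene_pool = np.asarray(gene_pool, dtype=float)
    drug_pool = np.asarray(drug_pool, dtype=float)
    gene_pool = gene_pool[np.isfinite(gene_pool)]
    drug_pool = drug_pool[np.isfinite(drug_pool)]
    if len(gene_pool) == 0 or len(drug_pool) == 0:
        raise ValueError("empty permutation pool")
    out = associations.copy()
    floor = 1.0 / n_perm
    p_raw = np.full(len(out), np.nan)
    flagged = np.zeros(len(out), dtype=bool)
    observed = out["summed"].to_numpy(dtype=float)
    for i, obs in enumerate(observed):
        sums = rng.choice(gene_pool, n_perm) + rng.choice(drug_pool, n_perm)
        if obs == 0:
            p_raw[i] = 1.0
            continue
        same_sign = sums * np.sign(obs) > 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            p_raw[i] = 0.0
            flagged[i] = True
            continue
        p_raw[i] = (np.abs(sums[same_sign]) >= abs(obs)).sum() / n_same
    out["p_raw"] = p_raw
    out["p_perm"] = np.clip(p_raw, floor, 1.0)
    out["floored"] = flagged | (p_raw < floor)
    return out


def bh_correct(associations: pd.DataFrame, p_column: str = "p_perm") -> pd.DataFrame:
    """Benjamini-Hochberg step-up across all rows as one family."""
    out = associations.copy()
    out["q"] = multipletests(out[p_column], method="fdr_bh")[1]
    return out


def integrate_gene_drug(
    activity,
    dependency,
    drugs,
    meta: DrugMetadata,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    min_pairs: int | None = None,
    pool: str = "pathway",
) -> pd.DataFrame:
    """End-to-end drug+gene integration over every activity pathway.

    Permutation pools are pathway-specific by default (the activity
    pathway's own gene and drug coefficient vectors); ``pool="global"``
    pools coefficients across pathways instead.  BH is applied once over
    the full (drug, target, pathway) family.
    """
    from .genetic import DEFAULT_MIN_PAIRS, correlate_features
    from .pharm import orient_drug_correlations

    if min_pairs is None:
        min_pairs = DEFAULT_MIN_PAIRS
    if pool not in ("pathway", "global"):
        raise ValueError("pool must be 'pathway' or 'global'")
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.generate_state(len(activity.pathway_ids))
    per_pathway = {}
    for pathway in activity.pathway_ids:
        gene_profile = correlate_features(activity.values.loc[pathway],
                                          dependency, min_pairs)["rho"]
        drug_profile = correlate_features(activity.values.loc[pathway],
                                          drugs, min_pairs)
        drug_profile = orient_drug_correlations(drug_profile, meta)["rho"]
        per_pathway[pathway] = (gene_profile, drug_profile)
    if pool == "global":
        gene_pool = np.concatenate([g.to_numpy() for g, _ in per_pathway.values()])
        drug_pool = np.concatenate([d.to_numpy() for _, d in per_pathway.values()])
    frames = []
    for (pathway, (gene_profile, drug_profile)), sub_seed in zip(
        per_pathway.items(), child_seeds
    ):
        table = pair_gene_drug(gene_profile, drug_profile, meta, pathway)
        if table.empty:
            continue
        if pool == "pathway":
            gene_pool = gene_profile.dropna().to_numpy()
            drug_pool = drug_profile.dropna().to_numpy()
        table = permutation_test(table, gene_pool, drug_pool, n_perm,
                                 int(sub_seed) % (2**31))
        frames.append(table)
    combined = pd.concat(frames, ignore_index=True)
    return bh_correct(combined)


def merge_pdea(
    genetic_results: pd.DataFrame,
    pharm_results: pd.DataFrame,
    p_max: float = 0.05,
    q_max: float = 0.25,
) -> pd.DataFrame:
    """Pathway pairs significant and sign-concordant in both PDEA grids.

    Both inputs are long frames keyed by (activity_pathway,
    target_pathway) with nes, p, q columns; the genetic grid's
    ``dependency_pathway`` column is accepted as the target key.  A pair
    is returned when p < p_max and q < q_max in both analyses and the
    NES signs agree; loosening either threshold never removes a hit.
    """
    gen = genetic_results.rename(columns={"dependency_pathway": "target_pathway"})
    key = ["activity_pathway", "target_pathway"]
    merged = gen.merge(pharm_results, on=key, suffixes=("_genetic", "_pharm"))
    passing = (
        (merged["p_genetic"] < p_max) & (merged["q_genetic"] < q_max)
        & (merged["p_pharm"] < p_max) & (merged["q_pharm"] < q_max)
        & (np.sign(merged["nes_genetic"]) == np.sign(merged["nes_pharm"]))
        & (merged["nes_genetic"] != 0)
    )
    columns = key + ["nes_genetic", "p_genetic", "q_genetic",
                     "nes_pharm", "p_pharm", "q_pharm"]
    out = merged.loc[passing, columns].reset_index(drop=True)
    out.attrs["n_tested"] = len(merged)
    return out
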