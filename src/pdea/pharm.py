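"""Pharmacological PDEA: pathway activity vs drug response.

Drug response enters as -AUC (screen orientation), so larger oriented
values mean stronger growth inhibition.  Drugs annotated as positive
regulators (agonists / activators) additionally have their correlation
coefficients negated, making an activator of a pathway count like an
inhibitor.  Drugs are grouped into pathway-targeting sets through their
annotated target genes and queried against the ranked coefficients with
the same preranked GSEA engine as the genetic stage.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import DrugMetadata, GeneSetCollection, PathwayActivityMatrix, ScreenMatrix
from .genetic import DEFAULT_MIN_PAIRS, correlate_features
from .gsea import DEFAULT_N_PERM, DEFAULT_WEIGHT_EXPONENT, gsea_preranked, rank_features

DEFAULT_MIN_DRUGS = 4


def orient_drug_correlations(profile: pd.DataFrame, meta: DrugMetadata) -> pd.DataFrame:
    """Negate the correlation coefficients of positive regulators.

    The input profile is indexed by drug id with a ``rho`` column
    (already computed against -AUC).  Applying the function twice
    restores the input (involution).
    """
    missing = [d for d in profile.index if d not in meta.table.index
               or pd.isna(meta.table.at[d, "direction"])]
    if missing:
        raise ValueError(f"drugs without regulator direction: {missing[:20]}")
    directions = meta.table.loc[profile.index, "direction"]
    flip = np.where(directions == "positive", -1.0, 1.0)
    out = profile.copy()
    out["rho"] = out["rho"] * flip
    return out


def drug_pathway_correlations(
    activity: PathwayActivityMatrix,
    drugs: ScreenMatrix,
    meta: DrugMetadata,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    medium: str | None = None,
    bh_family: str = "per_pathway",
) -> pd.DataFrame:
    """Individual drug : pathway Spearman correlations with BH q-values.

    One row per (pathway, drug): oriented rho (activity vs -AUC, with
    the activator flip), two-sided p, and BH q.  The correction family
    is per pathway across its drugs (default) or a single global family.
    """
    if bh_family not in ("per_pathway", "global"):
        raise ValueError("bh_family must be 'per_pathway' or 'global'")
    frames = []
    for pathway in activity.pathway_ids:
        profile = correlate_features(
            activity.values.loc[pathway], drugs, min_pairs, with_p=True
        )
        profile = orient_drug_correlations(profile, meta)
        profile = profile.dropna(subset=["rho", "p"])
        frame = profile.reset_index(names="drug_id")
        frame.insert(0, "pathway_id", pathway)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    table["q"] = np.nan
    if bh_family == "per_pathway":
        for pathway, idx in table.groupby("pathway_id").groups.items():
            table.loc[idx, "q"] = multipletests(table.loc[idx, "p"], method="fdr_bh")[1]
    else:
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    if medium is not None:
        table["medium"] = medium
    return table


def build_drug_sets(
    meta: DrugMetadata,
    collection: GeneSetCollection,
    min_drugs: int = DEFAULT_MIN_DRUGS,
) -> GeneSetCollection:
    """Pathway -> drug sets via annotated targets (union over targets).

    A drug joins every pathway containing at least one of its targets;
    sets smaller than ``min_drugs`` are dropped.  Drugs without any
    resolvable target are excluded with a warning.
    """
    if min_drugs < 1:
        raise ValueError("min_drugs must be >= 1")
    no_target = [d for d in meta.drug_ids if not meta.targets(d)]
    if no_target:
        warnings.warn(
            f"build_drug_sets: {len(no_target)} drugs with no resolvable target "
            f"excluded: {no_target[:10]}", stacklevel=2,
        )
    sets: dict[str, list[str]] = {}
    for pathway, members in collection.sets.items():
        member_set = set(members)
        drugs = [
            d for d in meta.drug_ids
            if any(t in member_set for t in meta.targets(d))
        ]
        if len(drugs) >= min_drugs:
            sets[pathway] = drugs
    return GeneSetCollection(
        sets=sets, names={p: collection.names.get(p, "") for p in sets}
    )


def pharm_pdea(
    oriented_profile: pd.Series,
    drug_sets: GeneSetCollection,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    min_drugs: int = DEFAULT_MIN_DRUGS,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
) -> pd.DataFrame:
    """Preranked GSEA of drug sets in one pathway's oriented coefficients.

    ``oriented_profile`` is a Series of oriented rhos indexed by drug
    id.  Sets reduced below ``min_drugs`` members by the profile's drug
    universe are skipped with a warning.
    """
    scores = oriented_profile.dropna()
    ranked = rank_features(scores)
    usable: dict[str, list[str]] = {}
    for set_id, members in drug_sets.sets.items():
        present = [m for m in members if m in scores.index]
        if len(present) < min_drugs:
            warnings.warn(
                f"pharm_pdea: drug set {set_id!r} reduced to {len(present)} "
                f"drugs in the profiled universe; skipped", stacklevel=2,
            )
            continue
        usable[set_id] = present
    if not usable:
        raise ValueError("no drug sets left after universe filtering")
    reduced = GeneSetCollection(sets=usable,
                                names={k: drug_sets.names.get(k, "") for k in usable})
    return gsea_preranked(ranked, reduced, n_perm, seed, weight_exponent)


def pharm_pdea_grid(
    activity: PathwayActivityMatrix,
    drugs: ScreenMatrix,
    meta: DrugMetadata,
    drug_sets: GeneSetCollection,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    min_drugs: int = DEFAULT_MIN_DRUGS,
) -> pd.DataFrame:
    """Pharmacological PDEA over every activity pathway (long format)."""
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.generate_state(len(activity.pathway_ids))
    frames = []
    for pathway, sub_seed in zip(activity.pathway_ids, child_seeds):
        profile = correlate_features(activity.values.loc[pathway], drugs, min_pairs)
        profile = orient_drug_correlations(profile, meta)
        result = pharm_pdea(profile["rho"], drug_sets, n_perm,
                            int(sub_seed) % (2**31), min_drugs)
        result = result.rename(columns={"set_id": "target_pathway"})
        result.insert(0, "activity_pathway", pathway)
        frames.append(result)
    return pd.concat(frames, ignore_index=True)


def cross_medium_concordance(
    hits_a: pd.DataFrame,
    hits_b: pd.DataFrame,
    q_threshold: float = 0.05,
    labels: tuple[str, str] = ("RPMI", "DMEM"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drug:pathway pairs significant in both media with matching sign.

    Returns (concordant, discordant) frames; discordant pairs are
    significant in both media but with opposite correlation signs.
    """
    key = ["pathway_id", "drug_id"]
    a, b = labels
    merged = hits_a.merge(hits_b, on=key, suffixes=(f"_{a}", f"_{b}"))
    sig = (merged[f"q_{a}"] < q_threshold) & (merged[f"q_{b}"] < q_threshold)
    same_sign = np.sign(merged[f"rho_{a}"]) == np.sign(merged[f"rho_{b}"])
    concordant = merged[sig & same_sign].reset_index(drop=True)
    discordant = merged[sig & ~same_sign].reset_index(drop=True)
    return concordant, discordant
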