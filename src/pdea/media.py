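"""Media-composition comparison of pathway essentiality.

Pathway essentiality per medium is summarized as the mean over activity
pathways of NES weighted by -log10(FDR); pathways linked to metabolites
whose concentration differs between the two media are then tested for a
shift in essentiality with a paired rank test (Wilcoxon signed-rank,
the standard paired analogue of the Mann-Whitney U test).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genetic import PDEAMatrix


def weighted_mean_nes(pdea: PDEAMatrix, include_self: bool = True) -> pd.Series:
    """Per dependency pathway: mean over activity pathways of NES * -log10(q).

    q must be floored upstream (1/n_perm); a zero q here is a contract
    violation and raises.
    """
    grid = pdea.grid if include_self else pdea.grid[~pdea.grid["self"]]
    if (grid["q"] <= 0).any():
        raise ValueError("q = 0 reached weighted_mean_nes; floor violated upstream")
    weighted = grid["nes"] * (-np.log10(grid["q"]))
    return weighted.groupby(grid["dependency_pathway"]).mean().rename("weighted_mean_nes")


def classify_pathways(
    formulation: pd.DataFrame,
    links: pd.DataFrame,
    collection_ids,
    media: tuple[str, str] = ("RPMI", "DMEM"),
) -> pd.DataFrame:
    """Group pathways by whether a linked metabolite differs between media.

    ``formulation``: long frame (metabolite, medium, concentration[, units]);
    ``links``: (pathway_id, metabolite).  A pathway is media-differential
    when any linked metabolite has different concentrations in the two
    media.  For display, the mean relative abundance (medium B / mean)
    over linked metabolites is recorded.  Pathways without links default
    to non-differential and are flagged.
    """
    a, b = media
    conc = formulation.pivot_table(index="metabolite", columns="medium",
                                   values="concentration", aggfunc="mean")
    for m in media:
        if m not in conc.columns:
            raise ValueError(f"no formulation rows for medium {m!r}")
    rows = []
    linked = links.groupby("pathway_id")["metabolite"].apply(list)
    for pathway in collection_ids:
        metabolites = linked.get(pathway, [])
        unknown = [m for m in metabolites if m not in conc.index]
        if unknown:
            raise ValueError(f"pathway {pathway!r} links unknown metabolites: {unknown}")
        if not metabolites:
            rows.append({"pathway_id": pathway, "group": "non-differential",
                         "metabolites": [], "relative_abundance": np.nan,
                         "unlinked": True})
            continue
        sub = conc.loc[metabolites]
        differential = bool((sub[a] != sub[b]).any())
        # relative abundance of medium b vs the per-metabolite mean, averaged
        means = sub[[a, b]].mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = float((sub[b] / means).replace([np.inf, -np.inf], np.nan).mean())
        rows.append({
            "pathway_id": pathway,
            "group": "media-differential" if differential else "non-differential",
            "metabolites": metabolites, "relative_abundance": rel,
            "unlinked": False,
        })
    return pd.DataFrame(rows).set_index("pathway_id")


def paired_media_test(
    summary_a: pd.Series,
    summary_b: pd.Series,
    grouping: pd.DataFrame,
) -> pd.Series:
    """Two-sided paired signed-rank p per pathway group.

    Pathways are paired across media; zero differences are dropped
    (Wilcoxon convention).  Exact null distribution for n <= 25,
    normal approximation with continuity correction beyond.  Groups
    with fewer than 3 usable pairs get a missing p with a warning.
    """
    if set(summary_a.index) != set(summary_b.index):
        raise ValueError("summaries cover different pathway lists")
    diffs = (summary_b - summary_a.loc[summary_b.index]).dropna()
    ps = {}
    for group in sorted(grouping["group"].unique()):
        members = grouping.index[grouping["group"] == group]
        d = diffs.loc[diffs.index.intersection(members)]
        d_nonzero = d[d != 0]
        if len(d) < 3:
            warnings.warn(f"group {group!r} has fewer than 3 pathways", stacklevel=2)
            ps[group] = np.nan
            continue
        if len(d_nonzero) == 0:
            ps[group] = 1.0
            continue
        method = "exact" if len(d_nonzero) <= 25 else "approx"
        res = sps.wilcoxon(d_nonzero, alternative="two-sided", method=method,
                           correction=(method == "approx"))
        ps[group] = float(res.pvalue)
    return pd.Series(ps, name="p")


def media_dependency_summary(
    pdea_a: PDEAMatrix,
    pdea_b: PDEAMatrix,
    grouping: pd.DataFrame | None = None,
    media: tuple[str, str] = ("RPMI", "DMEM"),
) -> pd.DataFrame:
    """Side-by-side weighted-NES summaries with difference and grouping."""
    a, b = media
    s_a = weighted_mean_nes(pdea_a)
    s_b = weighted_mean_nes(pdea_b)
    out = pd.DataFrame({a: s_a, b: s_b})
    out["difference"] = out[b] - out[a]
    if grouping is not None:
        out = out.join(grouping[["group"]])
    return out.sort_values("difference")
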