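"""Genetic pathway dependency enrichment analysis (Genetic PDEA).

For every activity pathway, the per-sample activity score is Spearman-
correlated with the oriented gene-dependency readout of every screened
gene (pairwise-complete over samples); the resulting coefficients are
ranked and queried with preranked GSEA against the pathway collection.
A positive NES means stronger dependency on the target pathway when the
activity pathway is up.  Results from two screens sharing the same
expression input are combined with the harmonic mean p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import GeneSetCollection, PathwayActivityMatrix, ScreenMatrix
from .gsea import DEFAULT_N_PERM, DEFAULT_WEIGHT_EXPONENT, fdr_q, preranked_stats, rank_features

DEFAULT_MIN_PAIRS = 20


def spearman_rho_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Spearman rho and two-sided p (t approximation)."""
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return np.nan, np.nan
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n < 3 or abs(rho) >= 1:
        return rho, (0.0 if abs(rho) >= 1 and n >= 3 else np.nan)
    t = rho * np.sqrt((n - 2) / (1 - rho * rho))
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def correlate_features(
    activity_row: pd.Series,
    screen: ScreenMatrix,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    with_p: bool = False,
) -> pd.DataFrame:
    """Spearman correlation of one pathway's activity with every feature.

    Pairwise-complete over samples; features left with fewer than
    ``min_pairs`` overlapping observations, or with a constant vector,
    are excluded (rho = NaN, recorded in ``n_pairs``).  Returns a frame
    indexed by feature with columns rho, n_pairs (and p if requested).
    """
    shared = [s for s in activity_row.index if s in screen.values.columns]
    if len(shared) < min_pairs:
        raise ValueError(
            f"only {len(shared)} overlapping samples; need >= {min_pairs}"
        )
    x = activity_row[shared].to_numpy(dtype=float)
    oriented = screen.oriented()[shared]
    mat = oriented.to_numpy(dtype=float)

    n_features = mat.shape[0]
    rho = np.full(n_features, np.nan)
    pval = np.full(n_features, np.nan)
    n_pairs = np.zeros(n_features, dtype=int)

    finite = np.isfinite(mat)
    complete = finite.all(axis=1) & np.isfinite(x).all()
    n = len(shared)
    if complete.any():
        rx = sps.rankdata(x)
        ranks = sps.rankdata(mat[complete], axis=1)
        rx_c = rx - rx.mean()
        r_c = ranks - ranks.mean(axis=1, keepdims=True)
        denom = np.sqrt((r_c**2).sum(axis=1) * (rx_c**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (r_c @ rx_c) / denom
        rho[complete] = r
        n_pairs[complete] = n
        if with_p:
            with np.errstate(invalid="ignore", divide="ignore"):
                t = r * np.sqrt((n - 2) / np.clip(1 - r * r, 1e-300, None))
            pval[complete] = 2 * sps.t.sf(np.abs(t), df=n - 2)
            pval[complete & (np.abs(rho) >= 1)] = 0.0
    for i in np.flatnonzero(~complete):
        mask = finite[i] & np.isfinite(x)
        n_pairs[i] = int(mask.sum())
        if n_pairs[i] < min_pairs:
            continue
        rho[i], pval[i] = spearman_rho_p(x[mask], mat[i][mask])
    out = pd.DataFrame({"rho": rho, "n_pairs": n_pairs}, index=oriented.index)
    if with_p:
        out["p"] = pval
    return out


@dataclass
class PDEAMatrix:
    """Long-format PDEA grid plus the diagonal self-dependency view.

    ``grid`` columns: activity_pathway, dependency_pathway, es, nes, p,
    q, leading_edge, n_hits, self.  Off-diagonal q is computed within
    each activity pathway's off-diagonal family; diagonal q across the
    diagonal family.
    """

    grid: pd.DataFrame
    n_perm: int = DEFAULT_N_PERM
    meta: dict = field(default_factory=dict)

    def matrix(self, value: str = "nes", include_self: bool = True) -> pd.DataFrame:
        grid = self.grid if include_self else self.grid[~self.grid["self"]]
        return grid.pivot(index="dependency_pathway", columns="activity_pathway",
                          values=value)

    @property
    def n_off_diagonal_tests(self) -> int:
        return int((~self.grid["self"]).sum())


def genetic_pdea(
    activity: PathwayActivityMatrix,
    dependency: ScreenMatrix,
    collection: GeneSetCollection,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
) -> PDEAMatrix:
    """Full Genetic PDEA grid: every activity pathway vs every gene set.

    Self-dependencies (activity pathway == dependency pathway) are
    computed but kept out of the off-diagonal FDR family; their q values
    form a separate diagonal family, mirroring how the self-dependency
    question is a different hypothesis from cross-pathway crosstalk.
    """
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.generate_state(len(activity.pathway_ids))
    rows = []
    diag_stats = []
    for pathway, sub_seed in zip(activity.pathway_ids, child_seeds):
        profile = correlate_features(activity.values.loc[pathway], dependency, min_pairs)
        scores = profile["rho"].dropna()
        ranked = rank_features(scores)
        stats = preranked_stats(ranked, collection, n_perm, int(sub_seed) % (2**31),
                                weight_exponent)
        off = [s for s in stats if s.set_id != pathway]
        q_off = fdr_q(off, n_perm)
        for s in off:
            rows.append({
                "activity_pathway": pathway, "dependency_pathway": s.set_id,
                "es": s.es, "nes": s.nes, "p": s.p, "q": q_off[s.set_id],
                "leading_edge": s.leading_edge, "n_hits": s.n_hits, "self": False,
            })
        for s in stats:
            if s.set_id == pathway:
                diag_stats.append((pathway, s))
    if diag_stats:
        q_diag = fdr_q([s for _, s in diag_stats], n_perm)
        for pathway, s in diag_stats:
            rows.append({
                "activity_pathway": pathway, "dependency_pathway": pathway,
                "es": s.es, "nes": s.nes, "p": s.p, "q": q_diag[s.set_id],
                "leading_edge": s.leading_edge, "n_hits": s.n_hits, "self": True,
            })
    grid = pd.DataFrame(rows)
    return PDEAMatrix(grid=grid, n_perm=n_perm,
                      meta={"seed": seed, "min_pairs": min_pairs})


def self_dependency(pdea: PDEAMatrix) -> pd.DataFrame:
    """Diagonal of the PDEA grid: each pathway's link to its own genes.

    Attaches sign counts (how many pathways show positive vs negative
    self-NES) as frame attrs.
    """
    diag = pdea.grid[pdea.grid["self"]].copy()
    diag = diag.drop(columns=["self"]).reset_index(drop=True)
    diag.attrs["n_positive"] = int((diag["nes"] > 0).sum())
    diag.attrs["n_negative"] = int((diag["nes"] < 0).sum())
    diag.attrs["n_zero"] = int((diag["nes"] == 0).sum())
    return diag


def harmonic_mean_p(p_values) -> float:
    """Unweighted harmonic mean p-value: k / sum(1/p_i).

    Valid for combining dependent tests; inputs must lie in (0, 1]
    (floor zero p-values upstream).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return float(len(p) / np.sum(1.0 / p))


def combine_datasets(
    pdea_a: PDEAMatrix,
    pdea_b: PDEAMatrix,
    hmp_threshold: float = 0.05,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Cross-screen combination by harmonic mean p-value.

    For every pathway pair the nominal p-values of the two screens are
    combined by HMP.  A pair significant in screen A (q < q_threshold)
    counts as recapitulated when its HMP clears hmp_threshold and the
    two NES agree in sign.  The recapitulation rate (with and without
    the sign requirement) is attached as frame attrs.
    """
    key = ["activity_pathway", "dependency_pathway"]
    a = pdea_a.grid.set_index(key)
    b = pdea_b.grid.set_index(key)
    if set(a.index) != set(b.index):
        raise ValueError("PDEA grids cover different pathway pairs")
    b = b.loc[a.index]
    hmp = [harmonic_mean_p([pa, pb]) for pa, pb in zip(a["p"], b["p"])]
    out = pd.DataFrame({
        "p_a": a["p"].to_numpy(), "p_b": b["p"].to_numpy(),
        "nes_a": a["nes"].to_numpy(), "nes_b": b["nes"].to_numpy(),
        "q_a": a["q"].to_numpy(), "hmp": hmp,
    }, index=a.index).reset_index()
    concordant = np.sign(out["nes_a"]) == np.sign(out["nes_b"])
    out["recapitulated"] = (
        (out["q_a"] < q_threshold) & (out["hmp"] < hmp_threshold) & concordant
    )
    significant_a = out["q_a"] < q_threshold
    n_sig = int(significant_a.sum())
    out.attrs["n_significant_a"] = n_sig
    if n_sig:
        out.attrs["recapitulation_rate"] = float(
            out.loc[significant_a, "recapitulated"].mean()
        )
        out.attrs["recapitulation_rate_signless"] = float(
            ((out["hmp"] < hmp_threshold) & significant_a).sum() / n_sig
        )
    else:
        out.attrs["recapitulation_rate"] = np.nan
        out.attrs["recapitulation_rate_signless"] = np.nan
    return out
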