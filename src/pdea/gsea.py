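"""Preranked GSEA: weighted running-sum enrichment with a feature-set
permutation null, normalized enrichment scores, nominal p, GSEA-style FDR
and leading-edge extraction.

The ranked input is a list of features ordered by a real-valued score
(here: Spearman correlation coefficients between pathway activity and a
screen readout).  The null model draws random feature sets of matching
size from the ranked universe; no sample-label permutation is possible
once the list has been reduced to one coefficient per feature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 1000
DEFAULT_WEIGHT_EXPONENT = 1.0


def rank_features(scores: pd.Series) -> pd.Series:
    """Sort scores descending, breaking ties by feature id (stable).

    Tie frequency is logged: the tie-break keeps the procedure
    deterministic, and the tie-sensitivity of downstream enrichment is
    covered by the test-suite invariants.
    """
    if scores.isna().any():
        raise ValueError("ranked scores must not contain missing values")
    frame = scores.rename("score").rename_axis("feature").reset_index()
    frame = frame.sort_values(["score", "feature"], ascending=[False, True], kind="mergesort")
    n_ties = int(scores.duplicated().sum())
    if n_ties:
        logger.info("rank_features: %d tied scores broken by feature id", n_ties)
    return pd.Series(frame["score"].to_numpy(), index=frame["feature"].to_numpy())


def _es_from_hits(
    positions: np.ndarray, abs_weights: np.ndarray, n_total: int
) -> tuple[np.ndarray, np.ndarray]:
    """Enrichment score(s) from hit positions alone.

    ``positions``: (n_runs, k) 0-based positions of set members in the
    ranked list, sorted ascending along the last axis.  ``abs_weights``:
    |score|^exponent of the full ranked list.  Returns (es, extremum_hit)
    where ``extremum_hit`` is the 1-based index (within the sorted hits)
    of the running-sum extremum; it is positive for a positive ES
    (leading edge = hits 1..extremum) and negative for a negative ES
    (leading edge = hits |extremum|..k).
    """
    positions = np.atleast_2d(positions)
    n_runs, k = positions.shape
    miss_step = 1.0 / (n_total - k)
    w = abs_weights[positions]
    totals = w.sum(axis=1, keepdims=True)
    # all-zero in-set weights: fall back to uniform steps
    degenerate = totals[:, 0] == 0
    if degenerate.any():
        w = w.copy()
        w[degenerate] = 1.0
        totals = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) / totals
    i = np.arange(1, k + 1)
    gaps = (positions + 1 - i) * miss_step  # misses seen before/through hit i
    after = cum - gaps          # running sum just after hit i
    before = (cum - w / totals) - gaps  # running sum just before hit i
    pos_idx = after.argmax(axis=1)
    neg_idx = before.argmin(axis=1)
    pos_es = np.maximum(after[np.arange(n_runs), pos_idx], 0.0)
    neg_es = np.minimum(before[np.arange(n_runs), neg_idx], 0.0)
    # exact ties (possible with discrete weights) resolve to the positive
    # extremum; the tolerance keeps the rule stable under float roundoff
    take_pos = pos_es >= -neg_es - 1e-9
    es = np.where(take_pos, pos_es, neg_es)
    extremum = np.where(take_pos, pos_idx + 1, -(neg_idx + 1))
    return es, extremum


def enrichment_score(
    ranked: pd.Series,
    members,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
) -> tuple[float, list[str]]:
    """Weighted Kolmogorov-Smirnov running-sum enrichment of one set.

    Hits increment the running sum by |score|^exponent normalized over
    the in-set total; misses decrement by 1/(number of misses).  ES is
    the extremum of largest absolute value; the leading edge contains the
    in-set features at or before (positive ES) / at or after (negative
    ES) the extremum.
    """
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be >= 0")
    features = ranked.index.to_numpy()
    in_set = np.isin(features, list(members))
    k = int(in_set.sum())
    if k == 0:
        warnings.warn("enrichment_score: empty intersection with ranked list", stacklevel=2)
        return np.nan, []
    if k == len(ranked):
        raise ValueError("set covers the whole ranked list (no misses)")
    abs_w = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    positions = np.flatnonzero(in_set)
    es, extremum = _es_from_hits(positions[None, :], abs_w, len(ranked))
    es, ext = float(es[0]), int(extremum[0])
    hits = features[positions]
    if es > 0:
        leading = list(hits[:ext])
    elif es < 0:
        leading = list(hits[-ext - 1:])
    else:
        leading = []
    return es, leading


@dataclass
class _SetStats:
    set_id: str
    es: float
    nes: float
    p: float
    leading_edge: list[str]
    n_hits: int
    perm_nes: np.ndarray  # permuted NES pool for this set


def _permuted_es(
    sizes: list[int],
    abs_w: np.ndarray,
    n_total: int,
    n_perm: int,
    rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    """Permutation ES nulls per set size, sharing one random matrix.

    The same (n_perm, n_total) random keys select the members for every
    size: draws for one size are valid uniform without-replacement draws,
    and sharing across sizes mirrors classic GSEA's reuse of one
    permutation stream for all sets.
    """
    keys = rng.random((n_perm, n_total))
    out: dict[int, np.ndarray] = {}
    for k in sorted(set(sizes)):
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        idx.sort(axis=1)
        es, _ = _es_from_hits(idx, abs_w, n_total)
        out[k] = es
    return out


def _normalize(es: float, perm: np.ndarray) -> tuple[float, float, np.ndarray]:
    """NES, nominal p and permuted-NES pool from one set's permutation ES."""
    pos = perm[perm > 0]
    neg = perm[perm < 0]
    mean_pos = pos.mean() if len(pos) else np.abs(perm).mean() or 1.0
    mean_neg = np.abs(neg).mean() if len(neg) else np.abs(perm).mean() or 1.0
    perm_nes = np.where(perm > 0, perm / mean_pos, perm / mean_neg)
    n_perm = len(perm)
    floor = 1.0 / n_perm
    if es > 0:
        nes = es / mean_pos
        p = (pos >= es).sum() / max(len(pos), 1)
    elif es < 0:
        nes = es / mean_neg
        p = (neg <= es).sum() / max(len(neg), 1)
    else:  # ES == 0 corner: NES 0, p 1 by convention
        return 0.0, 1.0, perm_nes
    return float(nes), float(min(max(p, floor), 1.0)), perm_nes


def preranked_stats(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
) -> list[_SetStats]:
    """Per-set ES/NES/p with permutation pools, before any FDR family choice."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    features = ranked.index.to_numpy()
    n_total = len(ranked)
    abs_w = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    sizes = []
    hit_positions: dict[str, np.ndarray] = {}
    for set_id, members in collection.sets.items():
        pos = np.flatnonzero(np.isin(features, members))
        if len(pos) == 0 or len(pos) >= n_total:
            warnings.warn(
                f"gsea_preranked: set {set_id!r} skipped "
                f"({len(pos)} of {n_total} features in list)",
                stacklevel=2,
            )
            continue
        hit_positions[set_id] = pos
        sizes.append(len(pos))
    perm_by_size = _permuted_es(sizes, abs_w, n_total, n_perm, rng)
    stats: list[_SetStats] = []
    for set_id, pos in hit_positions.items():
        es, extremum = _es_from_hits(pos[None, :], abs_w, n_total)
        es, ext = float(es[0]), int(extremum[0])
        hits = features[pos]
        if es > 0:
            leading = list(hits[:ext])
        elif es < 0:
            leading = list(hits[-ext - 1:])
        else:
            leading = []
        nes, p, perm_nes = _normalize(es, perm_by_size[len(pos)])
        stats.append(_SetStats(set_id, es, nes, p, leading, len(pos), perm_nes))
    return stats


def fdr_q(stats: list[_SetStats], n_perm: int | None = None) -> pd.Series:
    """GSEA-style FDR within sign pools over the given family of sets.

    q(NES*) = [fraction of pooled permuted NES at least as extreme, same
    sign] / [fraction of observed NES at least as extreme, same sign],
    clipped to [1/n_perm, 1].
    """
    if not stats:
        return pd.Series(dtype=float)
    if n_perm is None:
        n_perm = len(stats[0].perm_nes)
    floor = 1.0 / n_perm
    perm_pool = np.concatenate([s.perm_nes for s in stats])
    obs = np.array([s.nes for s in stats])
    pos_perm = perm_pool[perm_pool >= 0]
    neg_perm = perm_pool[perm_pool <= 0]
    qs = {}
    for s in stats:
        if s.nes > 0:
            num = (pos_perm >= s.nes).mean() if len(pos_perm) else 0.0
            den = (obs[obs > 0] >= s.nes).mean()
        elif s.nes < 0:
            num = (neg_perm <= s.nes).mean() if len(neg_perm) else 0.0
            den = (obs[obs < 0] <= s.nes).mean()
        else:
            qs[s.set_id] = 1.0
            continue
        qs[s.set_id] = float(min(max(num / den if den > 0 else 1.0, floor), 1.0))
    return pd.Series(qs, name="q")


def gsea_preranked(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
) -> pd.DataFrame:
    """Preranked GSEA over a collection; one row per analyzable set.

    Columns: set_id, es, nes, p, q, leading_edge (list), n_hits.
    Reproducible bit-for-bit under a fixed seed.
    """
    stats = preranked_stats(ranked, collection, n_perm, seed, weight_exponent)
    q = fdr_q(stats, n_perm)
    rows = [
        {
            "set_id": s.set_id,
            "es": s.es,
            "nes": s.nes,
            "p": s.p,
            "q": q[s.set_id],
            "leading_edge": s.leading_edge,
            "n_hits": s.n_hits,
        }
        for s in stats
    ]
    return pd.DataFrame(rows)


def running_sum_coordinates(
    ranked: pd.Series, members, weight_exponent: float = DEFAULT_WEIGHT_EXPONENT
) -> pd.DataFrame:
    """Full running-sum curve for mountain plots (position, value, is_hit)."""
    features = ranked.index.to_numpy()
    in_set = np.isin(features, list(members))
    k = int(in_set.sum())
    n = len(ranked)
    if k == 0 or k == n:
        raise ValueError("set must intersect the list and leave misses")
    abs_w = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    hit_w = np.where(in_set, abs_w, 0.0)
    total = hit_w.sum()
    if total == 0:
        hit_w = in_set.astype(float)
        total = hit_w.sum()
    running = np.cumsum(hit_w / total - (~in_set) / (n - k))
    return pd.DataFrame(
        {"position": np.arange(1, n + 1), "running_sum": running, "is_hit": in_set},
        index=features,
    )
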