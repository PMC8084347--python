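"""Per-sample metabolic pathway activity from expression.

Two scorers are provided: single-sample GSEA (the default: rank-ECDF
gap integration with range normalization across the stratum) and
normalized weighted average expression (NWAS), which down-weights genes
shared between pathways.  Both operate on unit-normalized expression and
are only comparable within one (culture type, medium) stratum.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection, PathwayActivityMatrix

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.25  # ssGSEA rank-weight exponent


def unit_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every gene to mean 0, sample SD 1 across the stratum's samples.

    Zero-variance genes carry no relative information and are dropped
    (count logged).  Requires at least two samples.
    """
    if expr.values.shape[1] < 2:
        raise ValueError("unit normalization needs >= 2 samples")
    values = expr.values
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("unit_normalize: dropped %d zero-variance genes", n_dropped)
    normalized = values.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)
    return ExpressionMatrix(values=normalized, annotations=expr.annotations.copy())


def _rank_orders(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Per-sample descending rank order; ties broken by gene id (stable)."""
    id_order = np.argsort(gene_ids, kind="mergesort")
    # lexsort: primary key descending value, secondary key gene id
    orders = np.empty_like(values, dtype=np.int64)
    for j in range(values.shape[1]):
        col = values[id_order, j]
        orders[:, j] = id_order[np.argsort(-col, kind="mergesort")]
    return orders


def ssgsea_score(sample_values: pd.Series, gene_set, alpha: float = DEFAULT_ALPHA) -> float:
    """Raw ssGSEA enrichment of one gene set in one sample.

    Genes are ranked by descending value; the score integrates the gap
    between the weighted in-set ECDF (weights |value|^alpha normalized
    over set members) and the uniform out-of-set ECDF over all ranks.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    genes = sample_values.index.to_numpy()
    in_set = np.isin(genes, list(gene_set))
    k = int(in_set.sum())
    n = len(genes)
    if k == 0:
        warnings.warn("ssgsea_score: empty intersection with sample genes", stacklevel=2)
        return np.nan
    if k == n:
        raise ValueError("gene set covers all genes (empty complement)")
    order = _rank_orders(sample_values.to_numpy(dtype=float)[:, None], genes)[:, 0]
    ordered_vals = sample_values.to_numpy(dtype=float)[order]
    ordered_in = in_set[order]
    w = np.abs(ordered_vals) ** alpha
    hit_w = np.where(ordered_in, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        hit_w = ordered_in.astype(float)
        total = float(k)
    ecdf_in = np.cumsum(hit_w) / total
    ecdf_out = np.cumsum(~ordered_in) / (n - k)
    return float(np.sum(ecdf_in - ecdf_out))


def ssgsea_matrix(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    normalization: str = "global",
    stratum: tuple[str, str] | None = None,
) -> PathwayActivityMatrix:
    """ssGSEA scores for every pathway x sample, range-normalized.

    Raw scores are divided by (max - min) over the whole matrix
    ("global", the classic ssGSEA projection) or per pathway row
    ("per_pathway").  Input is expected to be unit-normalized.
    """
    values = expr.values.to_numpy(dtype=float)
    genes = expr.values.index.to_numpy()
    n, n_samples = values.shape
    orders = _rank_orders(values, genes)
    ordered_vals = np.take_along_axis(values, orders, axis=0)
    w_all = np.abs(ordered_vals) ** alpha

    raw = np.full((len(collection), n_samples), np.nan)
    for row, (set_id, members) in enumerate(collection.sets.items()):
        in_set = np.isin(genes, members)
        k = int(in_set.sum())
        if k == 0:
            warnings.warn(f"ssgsea_matrix: pathway {set_id!r} has no expressed genes",
                          stacklevel=2)
            continue
        if k == n:
            raise ValueError(f"pathway {set_id!r} covers all genes")
        ordered_in = in_set[orders]
        hit_w = np.where(ordered_in, w_all, 0.0)
        totals = hit_w.sum(axis=0)
        degenerate = totals == 0
        if degenerate.any():
            hit_w[:, degenerate] = ordered_in[:, degenerate].astype(float)
            totals = hit_w.sum(axis=0)
        ecdf_in = np.cumsum(hit_w, axis=0) / totals
        ecdf_out = np.cumsum(~ordered_in, axis=0) / (n - k)
        raw[row] = (ecdf_in - ecdf_out).sum(axis=0)

    frame = pd.DataFrame(raw, index=list(collection.sets), columns=expr.values.columns)
    if normalization == "global":
        span = np.nanmax(frame.to_numpy()) - np.nanmin(frame.to_numpy())
        if span > 0:
            frame = frame / span
    elif normalization == "per_pathway":
        span = frame.max(axis=1) - frame.min(axis=1)
        frame = frame.div(span.replace(0, np.nan), axis=0)
    else:
        raise ValueError("normalization must be 'global' or 'per_pathway'")
    return PathwayActivityMatrix(values=frame, method="ssgsea", stratum=stratum)


def nwas_matrix(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    stratum: tuple[str, str] | None = None,
) -> PathwayActivityMatrix:
    """Normalized weighted average expression per pathway and sample.

    score(P, j) = (1/|P|) * sum over expressed members g of z_gj / c_g,
    where c_g counts how many pathways of the collection contain g.  The
    shared-gene down-weighting is the point of the metric; the 1/|P|
    averaging makes scores comparable across set sizes.
    """
    counts: dict[str, int] = {}
    for members in collection.sets.values():
        for g in members:
            counts[g] = counts.get(g, 0) + 1
    z = expr.values
    rows = {}
    for set_id, members in collection.sets.items():
        present = [g for g in members if g in z.index]
        if not present:
            rows[set_id] = pd.Series(np.nan, index=z.columns)
            continue
        weights = pd.Series({g: 1.0 / counts[g] for g in present})
        rows[set_id] = z.loc[present].mul(weights, axis=0).sum(axis=0) / len(members)
    frame = pd.DataFrame(rows).T
    frame.columns = z.columns
    return PathwayActivityMatrix(values=frame, method="nwas", stratum=stratum)
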