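"""Small shared helpers: seed fan-out and a plain clustering utility."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def spawn_seeds(master_seed: int | None, n: int) -> list[int]:
    """Deterministic per-stage seeds (< 2**31) from one master seed."""
    return [int(s) % (2**31)
            for s in np.random.SeedSequence(master_seed).generate_state(n)]


def cluster_order(matrix: pd.DataFrame, axis: int = 0,
                  method: str = "average", metric: str = "euclidean") -> list:
    """Leaf order from average-linkage clustering of rows (or columns).

    Output-ordering utility only; NaNs are filled with the matrix mean
    for distance computation.
    """
    data = matrix if axis == 0 else matrix.T
    values = data.to_numpy(dtype=float)
    if np.isnan(values).any():
        values = np.where(np.isnan(values), np.nanmean(values), values)
    if len(data.index) < 3:
        return list(data.index)
    linkage = hierarchy.linkage(pdist(values, metric=metric), method=method)
    return [data.index[i] for i in hierarchy.leaves_list(linkage)]
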