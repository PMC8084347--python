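"""Readers, writers and filtering rules for the standard input formats.

Supported dialects: GMT gene sets, GCT 1.2 / plain CSV expression,
DepMap-style gene-effect CSV (cell lines x "SYMBOL (ENTREZ)" columns),
PRISM-style drug-response tables (long or wide), and a simple media
formulation CSV.
"""

from __future__ import annotations

import logging
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    DrugMetadata,
    ExpressionMatrix,
    GeneSetCollection,
    ScreenMatrix,
    normalize_culture_type,
    normalize_medium,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_GENES = 5  # smallest analyzable pathway after intersection
DEFAULT_MIN_SAMPLES = 150  # smallest per-drug sample count retained
VALID_MEDIA = ("RPMI", "DMEM", "other")
VALID_CULTURE_TYPES = ("adherent", "suspension")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Parse a tab-separated GMT file (set id, description, members...).

    Duplicate member symbols within a line are collapsed; a duplicated
    set id across lines is an error.
    """
    sets: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: malformed GMT line {lineno}: expected >=3 "
                    f"tab-separated fields, got {len(fields)}"
                )
            set_id, description, *members = fields
            if set_id in sets:
                raise ValueError(f"{path}: duplicate gene set id {set_id!r} (line {lineno})")
            members = [m.strip() for m in members if m.strip()]
            sets[set_id] = list(dict.fromkeys(members))
            names[set_id] = description
    if not sets:
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
    return GeneSetCollection(sets=sets, names=names)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as handle:
        for set_id, members in collection.sets.items():
            desc = collection.names.get(set_id, "")
            handle.write("\t".join([set_id, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def read_expression(path, annotations_path=None) -> ExpressionMatrix:
    """Read a genes x samples expression matrix from GCT 1.2 or CSV.

    GCT is detected by the ``#1.2`` signature on the first line.  The
    optional annotation CSV must have a sample id column plus
    ``culture_type`` and ``medium`` columns; values are normalized
    case-insensitively through the alias maps.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
    if first.startswith("#1.2"):
        frame = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        frame = frame.drop(columns=["Description"], errors="ignore")
    else:
        frame = pd.read_csv(path, index_col=0)
    frame = frame.astype(float)
    annotations = read_annotations(annotations_path) if annotations_path else None
    if annotations is not None:
        annotations = annotations.reindex(frame.columns)
    return ExpressionMatrix(values=frame, annotations=annotations)


def read_annotations(path) -> pd.DataFrame:
    """Read sample annotations (sample id, culture_type, medium) from CSV."""
    raw = pd.read_csv(path, index_col=0)
    out = pd.DataFrame(index=raw.index)
    out["culture_type"] = raw["culture_type"].map(normalize_culture_type)
    out["medium"] = raw["medium"].map(normalize_medium)
    return out


def stratify_samples(annotations: pd.DataFrame, culture_type: str, medium: str) -> list[str]:
    """Sample ids in the requested (culture type, medium) stratum.

    Samples with a missing annotation for either key are always excluded,
    so the four strata plus the excluded pool partition the cohort.
    """
    if culture_type not in VALID_CULTURE_TYPES:
        raise ValueError(
            f"unknown culture type {culture_type!r}; valid: {VALID_CULTURE_TYPES}"
        )
    if medium not in VALID_MEDIA:
        raise ValueError(f"unknown medium {medium!r}; valid: {VALID_MEDIA}")
    mask = (annotations["culture_type"] == culture_type) & (
        annotations["medium"] == medium
    )
    return list(annotations.index[mask.fillna(False)])


def filter_gene_sets(
    collection: GeneSetCollection,
    expr: ExpressionMatrix,
    min_genes: int = DEFAULT_MIN_GENES,
) -> GeneSetCollection:
    """Intersect sets with the expressed genes and drop small sets.

    Members absent from the expression matrix are removed from each set;
    sets whose expressed membership falls below ``min_genes`` are dropped.
    Idempotent by construction.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    expressed = set(expr.gene_ids)
    kept: dict[str, list[str]] = {}
    for set_id, members in collection.sets.items():
        present = [m for m in members if m in expressed]
        if len(present) >= min_genes:
            kept[set_id] = present
    dropped = len(collection) - len(kept)
    if dropped:
        logger.info("filter_gene_sets: dropped %d of %d sets", dropped, len(collection))
    if not kept:
        raise ValueError("no analyzable pathways after filtering")
    return GeneSetCollection(
        sets=kept, names={k: collection.names.get(k, "") for k in kept}
    )


# ---------------------------------------------------------------------------
# Dependency screens (DepMap gene-effect dialect)
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"^\s*(?P<symbol>\S+)\s*\(\s*\d+\s*\)\s*$")


def _reduce_header(header: str) -> str:
    match = _HEADER_RE.match(header)
    return match.group("symbol") if match else header.strip()


def read_dependency_matrix(path) -> ScreenMatrix:
    """Read a DepMap-style gene-effect CSV (cell lines as rows).

    Column headers "SYMBOL (ENTREZ)" are reduced to the symbol.  The
    orientation is set to -1 for every gene so that oriented values equal
    -CERES: larger means more essential.  Missing cells stay NaN and are
    handled pairwise downstream.
    """
    raw = pd.read_csv(path, index_col=0)
    symbols = [_reduce_header(c) for c in raw.columns]
    counts = pd.Series(symbols).value_counts()
    collisions = counts[counts > 1].index.tolist()
    if collisions:
        raise ValueError(f"duplicate gene symbols after header reduction: {collisions}")
    raw.columns = symbols
    values = raw.T.astype(float)  # genes x samples
    orientation = pd.Series(-1.0, index=values.index)
    return ScreenMatrix(values=values, orientation=orientation, kind="gene")


# ---------------------------------------------------------------------------
# Drug response (PRISM dialect)
# ---------------------------------------------------------------------------

_POSITIVE_WORDS = ("agonist", "activator")


def classify_direction(moa: str | float) -> str | float:
    """Positive regulators (agonists / activators) vs everything else."""
    if moa is None or (isinstance(moa, float) and np.isnan(moa)):
        return np.nan
    text = str(moa).lower()
    return "positive" if any(w in text for w in _POSITIVE_WORDS) else "negative"


def read_drug_response(
    path,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    direction_overrides: dict[str, str] | None = None,
) -> tuple[ScreenMatrix, DrugMetadata]:
    """Read a PRISM-style drug response table (long or wide).

    Long format needs columns ``drug_id, sample_id, auc, target, moa``;
    multiple target symbols are comma-separated.  Drugs measured in fewer
    than ``min_samples`` cell lines are dropped.  The screen orientation is
    set to -1 (oriented value = -AUC, larger = stronger response); the
    activator sign flip is *not* applied here — it is recorded as
    ``direction`` metadata and applied once in the pharmacological stage.
    """
    raw = pd.read_csv(path)
    required = {"drug_id", "sample_id", "auc"}
    if not required <= set(raw.columns):
        raise ValueError(f"drug response table needs columns {sorted(required)}")
    wide = raw.pivot_table(index="drug_id", columns="sample_id", values="auc", aggfunc="mean")
    n_obs = wide.notna().sum(axis=1)
    kept = n_obs[n_obs >= min_samples].index
    dropped = len(wide) - len(kept)
    if dropped:
        logger.info(
            "read_drug_response: dropped %d drugs measured in < %d samples",
            dropped, min_samples,
        )
    wide = wide.loc[kept]

    meta_rows = raw.drop_duplicates("drug_id").set_index("drug_id")
    meta_rows = meta_rows.reindex(wide.index)
    targets = meta_rows.get("target", pd.Series("", index=wide.index)).fillna("")
    target_lists = [
        [t.strip() for t in str(ts).split(",") if t.strip()] for ts in targets
    ]
    moa = meta_rows.get("moa", pd.Series(np.nan, index=wide.index))
    direction = moa.map(classify_direction).astype(object)
    if direction_overrides:
        for drug, d in direction_overrides.items():
            if drug in direction.index:
                direction.loc[drug] = d
    unresolved = direction.index[direction.isna()].tolist()
    if unresolved:
        raise ValueError(
            "drugs with no MOA annotation and no direction override: "
            f"{unresolved[:20]}"
        )
    meta = DrugMetadata(
        table=pd.DataFrame(
            {"targets": target_lists, "moa": moa, "direction": direction},
            index=wide.index,
        )
    )
    screen = ScreenMatrix(
        values=wide,
        orientation=pd.Series(-1.0, index=wide.index),
        kind="drug",
    )
    return screen, meta


# ---------------------------------------------------------------------------
# Media formulation
# ---------------------------------------------------------------------------

def read_media_formulation(path) -> pd.DataFrame:
    """Media formulation CSV: metabolite, medium, concentration, units."""
    frame = pd.read_csv(path)
    required = {"metabolite", "medium", "concentration"}
    if not required <= set(frame.columns):
        raise ValueError(f"media formulation needs columns {sorted(required)}")
    if (frame["concentration"] < 0).any():
        raise ValueError("negative metabolite concentration")
    return frame


def read_pathway_metabolite_links(path) -> pd.DataFrame:
    """Pathway -> metabolite link table (columns: pathway_id, metabolite)."""
    frame = pd.read_csv(path)
    required = {"pathway_id", "metabolite"}
    if not required <= set(frame.columns):
        raise ValueError(f"link table needs columns {sorted(required)}")
    return frame
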