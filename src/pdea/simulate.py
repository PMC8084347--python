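"""Synthetic cohorts with the statistical structure the pipeline assumes.

Two generators: (1) the PDEA sensitivity simulation — i.i.d.
Normal(0, 0.5) expression and screen matrices with a planted feature
set whose per-sample mean follows a linear gradient from -X to +X across
the sample order, analyzed end to end for many replicates over a grid of
gradient magnitudes; (2) a small end-to-end fixture cohort with two
media strata, planted activity->dependency and activity->drug
associations of known sign, drug metadata including activators, and an
undersized drug set, for planted-truth and calibration testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .activity import ssgsea_matrix, unit_normalize
from .containers import (
    DrugMetadata,
    ExpressionMatrix,
    GeneSetCollection,
    PathwayActivityMatrix,
    ScreenMatrix,
)
from .genetic import correlate_features
from .gsea import gsea_preranked, rank_features

GENETIC_N_SAMPLES = 300
PHARM_N_SAMPLES = 200
GENETIC_N_FEATURES = 16_643  # genome-wide knockout count
PHARM_N_FEATURES = 1_390  # retained drug count


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the sensitivity simulation.

    Defaults follow the genetic variant: 300 cell lines, Normal(0, 0.5)
    background, a 25-feature planted set, gradient magnitudes in
    [0, 0.5], 50 replicates.  ``n_features`` defaults to the reduced
    2,000-feature scale used throughout the test-suite; the genome-wide
    16,643 (or 1,390 drugs) scale is supported by passing it explicitly.
    """

    n_samples: int = GENETIC_N_SAMPLES
    n_features: int = 2000
    mu: float = 0.0
    sigma: float = 0.5
    set_size: int = 25
    x_expr: float = 0.0
    x_dep: float = 0.0
    n_replicates: int = 50
    n_perm: int = 1000
    alpha: float = 0.25
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_features < 2 or self.set_size < 1:
            raise ValueError("non-positive dimensions")
        if self.x_expr < 0 or self.x_dep < 0:
            raise ValueError("gradient magnitudes must be >= 0")


def _feature_ids(n: int, prefix: str) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def simulate_matrix(
    config: SimulationConfig,
    kind: str = "expression",
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix | ScreenMatrix:
    """An i.i.d. Normal(mu, sigma) features x samples matrix.

    ``kind`` selects the container: "expression" -> ExpressionMatrix,
    "dependency"/"drug" -> ScreenMatrix with +1 orientation (simulated
    readouts are generated already oriented).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    prefix = {"expression": "G", "dependency": "G", "drug": "D"}.get(kind)
    if prefix is None:
        raise ValueError(f"unknown matrix kind {kind!r}")
    values = rng.normal(config.mu, config.sigma,
                        size=(config.n_features, config.n_samples))
    width = len(str(config.n_samples))
    samples = [f"C{i:0{width}d}" for i in range(1, config.n_samples + 1)]
    frame = pd.DataFrame(values, index=_feature_ids(config.n_features, prefix),
                         columns=samples)
    if kind == "expression":
        return ExpressionMatrix(values=frame)
    return ScreenMatrix(values=frame, orientation=pd.Series(1.0, index=frame.index),
                        kind="gene" if kind == "dependency" else "drug")


def plant_gradient(
    matrix: pd.DataFrame,
    member_features,
    x: float,
    sigma: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Replace member rows with Normal(mu_i, sigma) draws, mu_i linear in i.

    Sample i of n (in column order) draws from mean mu_i, with the means
    an arithmetic sequence from -x (first sample) to +x (last sample).
    Non-member rows are returned bit-identical.
    """
    if x < 0:
        raise ValueError("gradient magnitude x must be >= 0")
    members = [m for m in member_features if m in matrix.index]
    if len(members) != len(list(member_features)):
        raise ValueError("member_features must be a subset of matrix features")
    n = matrix.shape[1]
    mus = np.linspace(-x, x, n)
    out = matrix.copy()
    out.loc[members] = rng.normal(mus[None, :], sigma, size=(len(members), n))
    return out


def simulate_pdea_replicate(
    config: SimulationConfig,
    rng: np.random.Generator,
    pipeline: str = "genetic",
) -> dict:
    """One full planted-set analysis: simulate, score, correlate, enrich.

    Returns the enrichment record for the planted set plus the mean
    planted-gene correlation, for both PDEA- and per-feature-level
    sensitivity summaries.
    """
    screen_kind = "dependency" if pipeline == "genetic" else "drug"
    expr = simulate_matrix(config, "expression", rng)
    members = expr.gene_ids[: config.set_size]
    expr = ExpressionMatrix(
        plant_gradient(expr.values, members, config.x_expr, config.sigma, rng),
        expr.annotations,
    )
    screen = simulate_matrix(config, screen_kind, rng)
    screen_members = screen.feature_ids[: config.set_size]
    screen = ScreenMatrix(
        plant_gradient(screen.values, screen_members, config.x_dep, config.sigma, rng),
        screen.orientation, screen.kind,
    )
    collection = GeneSetCollection(sets={"PLANTED": members})
    normalized = unit_normalize(expr)
    activity = ssgsea_matrix(normalized, collection, alpha=config.alpha)
    profile = correlate_features(activity.values.loc["PLANTED"], screen,
                                 min_pairs=2)
    query = GeneSetCollection(sets={"PLANTED": screen_members})
    result = gsea_preranked(rank_features(profile["rho"].dropna()), query,
                            n_perm=config.n_perm,
                            seed=int(rng.integers(2**31)))
    record = result.iloc[0].to_dict()
    record["mean_planted_rho"] = float(profile.loc[screen_members, "rho"].mean())
    return record


def run_sensitivity_grid(
    config: SimulationConfig,
    pipeline: str = "genetic",
    grid: list[tuple[float, float]] | None = None,
    alpha_sig: float = 0.05,
) -> pd.DataFrame:
    """Replicated planted-set analyses over (x_expr, x_dep) gradient pairs.

    Returns one row per (x_expr, x_dep, replicate) with the planted
    set's es/nes/p/q; significance fractions (by FDR q and by nominal
    p, both at ``alpha_sig``) are attached via ``summarize_grid``.
    Replicate seeds are spawned deterministically from ``config.seed``.
    """
    if pipeline not in ("genetic", "pharmacological"):
        raise ValueError("pipeline must be 'genetic' or 'pharmacological'")
    if grid is None:
        grid = [(x_e, x_d) for x_e in np.linspace(0, 0.5, 6)
                for x_d in np.linspace(0, 0.5, 6)]
    seed_seq = np.random.SeedSequence(config.seed)
    rows = []
    for x_expr, x_dep in grid:
        cell_config = replace(config, x_expr=float(x_expr), x_dep=float(x_dep))
        children = seed_seq.spawn(config.n_replicates)
        for rep, child in enumerate(children):
            rng = np.random.default_rng(child)
            record = simulate_pdea_replicate(cell_config, rng, pipeline)
            rows.append({
                "x_expr": float(x_expr), "x_dep": float(x_dep), "replicate": rep,
                "es": record["es"], "nes": record["nes"],
                "p": record["p"], "q": record["q"],
                "mean_planted_rho": record["mean_planted_rho"],
                "significant_q": record["q"] < alpha_sig,
                "significant_p": record["p"] < alpha_sig,
            })
    return pd.DataFrame(rows)


def summarize_grid(grid_results: pd.DataFrame) -> pd.DataFrame:
    """Fraction of replicates significant per (x_expr, x_dep) cell."""
    grouped = grid_results.groupby(["x_expr", "x_dep"])
    return grouped.agg(
        fraction_significant_q=("significant_q", "mean"),
        fraction_significant_p=("significant_p", "mean"),
        n_replicates=("replicate", "count"),
    ).reset_index()


# ---------------------------------------------------------------------------
# End-to-end fixture cohort
# ---------------------------------------------------------------------------

@dataclass
class FixtureCohort:
    expression: ExpressionMatrix
    dependency: ScreenMatrix
    drugs: ScreenMatrix
    drug_metadata: DrugMetadata
    collection: GeneSetCollection
    annotations: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def make_fixture_cohort(
    seed: int | None = 0,
    n_background_genes: int = 100,
    gradient: float = 0.5,
    sigma: float = 0.5,
) -> FixtureCohort:
    """Small cohort with planted pathway-level associations of known sign.

    60 samples (40 adherent RPMI, 16 adherent DMEM, 2 suspension RPMI,
    2 with missing annotations), 400 genes in 12 overlapping 25-gene
    pathways plus background, 40 drugs.  Planted within each adherent
    stratum's sample order:

    * P01 activity gradient -> P02 gene dependency gradient (positive
      genetic link) and P02-targeting drug response (positive
      pharmacological link, so the merged analysis recovers P01->P02);
    * P03 activity gradient -> P04 dependency anti-gradient (negative
      genetic link).

    Drug metadata includes two activators inside the planted drug set
    (with inverted response gradients, so the activator sign flip is
    exercised) and one pathway with only three annotated drugs (dropped
    by the min-drug filter).  The manifest records the planted truth.
    """
    rng = np.random.default_rng(seed)
    n_pathways, set_size = 12, 25
    gene_ids = _feature_ids(n_pathways * set_size + n_background_genes, "G")
    pathways = {
        f"P{i + 1:02d}": gene_ids[i * set_size:(i + 1) * set_size]
        for i in range(n_pathways)
    }
    # overlap between two unplanted pathways so shared-gene weighting
    # (NWAS) is exercised without leaking planted gradients
    pathways["P06"] = pathways["P06"] + pathways["P07"][:3]
    collection = GeneSetCollection(sets=pathways)

    strata = {
        "RPMI": [f"R{i:02d}" for i in range(1, 41)],
        "DMEM": [f"D{i:02d}" for i in range(1, 17)],
    }
    extra = ["S01", "S02", "X01", "X02"]
    samples = strata["RPMI"] + strata["DMEM"] + extra
    annotations = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    annotations["culture_type"] = ["adherent"] * 56 + ["suspension"] * 2 + [np.nan] * 2
    annotations["medium"] = (["RPMI"] * 40 + ["DMEM"] * 16 + ["RPMI"] * 2 + [np.nan] * 2)

    expr = pd.DataFrame(rng.normal(0, sigma, (len(gene_ids), len(samples))),
                        index=gene_ids, columns=samples)
    dep = pd.DataFrame(rng.normal(0, sigma, (len(gene_ids), len(samples))),
                       index=gene_ids, columns=samples)

    drug_ids = _feature_ids(40, "DR")
    auc = pd.DataFrame(rng.normal(0.8, 0.15, (len(drug_ids), len(samples))),
                       index=drug_ids, columns=samples)

    # drug annotation: 6 drugs target P02 genes (2 of them activators),
    # 3 drugs target P05 genes (below the min-drug threshold), the rest
    # spread over P06-P08 and background genes
    targets: dict[str, list[str]] = {}
    moa: dict[str, str] = {}
    planted_drugs = drug_ids[:6]
    activators = drug_ids[:2]
    for i, d in enumerate(planted_drugs):
        targets[d] = [pathways["P02"][i]]
        moa[d] = "HMGCR activator" if d in activators else "HMGCR inhibitor"
    for i, d in enumerate(drug_ids[6:9]):
        targets[d] = [pathways["P05"][i]]
        moa[d] = "kinase inhibitor"
    other_pathways = ["P06", "P07", "P08"]
    for i, d in enumerate(drug_ids[9:33]):
        p = other_pathways[i % 3]
        targets[d] = [pathways[p][i % set_size]]
        moa[d] = "receptor antagonist"
    for i, d in enumerate(drug_ids[33:]):
        targets[d] = [gene_ids[-(i + 1)], pathways["P06"][(i + 7) % set_size]]
        moa[d] = "channel blocker"

    for medium, stratum in strata.items():
        n = len(stratum)
        # two independent latent gradients so the P01->P02 and P03->P04
        # links do not induce cross-pathway associations
        mus1 = np.linspace(-gradient, gradient, n)
        mus3 = mus1[rng.permutation(n)]
        expr.loc[pathways["P01"], stratum] = rng.normal(
            mus1[None, :], sigma, (set_size, n))
        expr.loc[pathways["P03"], stratum] = rng.normal(
            mus3[None, :], sigma, (set_size, n))
        # dependency responses (planted as -CERES gradients, stored as
        # CERES so the -1 orientation recovers them)
        dep.loc[pathways["P02"], stratum] = -rng.normal(
            mus1[None, :], sigma, (set_size, n))
        dep.loc[pathways["P04"], stratum] = -rng.normal(
            -mus3[None, :], sigma, (set_size, n))
        # drug responses: inhibitors' AUC falls with P01 activity (stronger
        # kill), the two activators rise (restored by the sign flip)
        for d in planted_drugs:
            sign = +1 if d in activators else -1
            auc.loc[d, stratum] = 0.8 + 0.3 * sign * mus1 + rng.normal(
                0, 0.15, n)

    expression = ExpressionMatrix(values=expr, annotations=annotations)
    dependency = ScreenMatrix(values=dep,
                              orientation=pd.Series(-1.0, index=dep.index),
                              kind="gene")
    drugs = ScreenMatrix(values=auc,
                         orientation=pd.Series(-1.0, index=auc.index),
                         kind="drug")
    meta = DrugMetadata(table=pd.DataFrame({
        "targets": [targets[d] for d in drug_ids],
        "moa": [moa[d] for d in drug_ids],
        "direction": ["positive" if d in activators else "negative"
                      for d in drug_ids],
    }, index=pd.Index(drug_ids, name="drug_id")))
    manifest = {
        "planted_genetic": [
            {"activity_pathway": "P01", "dependency_pathway": "P02", "sign": +1},
            {"activity_pathway": "P03", "dependency_pathway": "P04", "sign": -1},
        ],
        "planted_pharm": [
            {"activity_pathway": "P01", "target_pathway": "P02", "sign": +1},
        ],
        "activators": list(activators),
        "undersized_drug_pathway": "P05",
        "strata": {k: len(v) for k, v in strata.items()},
        "gradient": gradient,
        "seed": seed,
    }
    return FixtureCohort(expression, dependency, drugs, meta, collection,
                         annotations, manifest)


def fixture_activity(
    cohort: FixtureCohort, medium: str = "RPMI", method: str = "ssgsea"
) -> PathwayActivityMatrix:
    """Stratified, normalized activity scores for one fixture stratum."""
    from .activity import nwas_matrix
    from .io import stratify_samples

    stratum_samples = stratify_samples(cohort.annotations, "adherent", medium)
    expr = unit_normalize(cohort.expression.subset_samples(stratum_samples))
    scorer = ssgsea_matrix if method == "ssgsea" else nwas_matrix
    activity = scorer(expr, cohort.collection)
    activity.stratum = ("adherent", medium)
    return activity
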