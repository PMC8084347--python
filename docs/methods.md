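# Methods

This note documents the statistical machinery in `pdea`, the choices
made where the design was genuinely open, and what the synthetic data
used by the test-suite does and does not establish.

## Pathway activity

Expression is analyzed strictly within one (culture type, medium)
stratum, because culture conditions shape metabolism strongly enough
that cross-stratum activity scores are not comparable; the interface
refuses to mix strata. Samples missing either annotation are excluded
from every stratum. Annotation strings are normalized
case-insensitively through a small alias map (e.g. "RPMI-1640" →
RPMI).

Within a stratum, each gene is scaled to mean 0 and sample SD 1
(ddof = 1). Zero-variance genes carry no relative signal and are
dropped with a logged count.

**ssGSEA.** For sample *j* and pathway *P* with |P| = k of N genes,
genes are sorted by descending normalized expression (ties broken by
gene identifier, stable). The score integrates the ECDF gap over all
ranks:

    ES(P, j) = Σ_{i=1..N} [ P_in(i) − P_out(i) ]
    P_in(i)  = Σ_{g ∈ P, rank(g) ≤ i} |z_g|^α / Σ_{g ∈ P} |z_g|^α
    P_out(i) = #{g ∉ P, rank(g) ≤ i} / (N − k)

α defaults to 0.25, the exponent used by the common ssGSEA
implementations; it is configurable because the choice is conventional
rather than derived. Raw scores are normalized by dividing by
(max − min) over all pathways and samples of the stratum — a single
scale, so scores remain comparable across pathways; per-pathway range
normalization is available behind a flag. If every in-set weight is
zero (possible only for degenerate all-zero inputs) uniform in-set
steps are used instead of failing.

**NWAS.** score(P, j) = (1/|P|) Σ_{g∈P} z_gj / c_g, with c_g the
number of collection pathways containing g. The division by |P| makes
scores comparable across set sizes; this averaging convention is a
package decision — the weighting by 1/c_g (shared genes count less) is
the point of the metric.

## Correlation profiles

Activity is correlated with screen readouts by Spearman rank
correlation: activity scores are strongly bimodal across cell lines,
so a rank statistic is the appropriate choice. Screens carry an
orientation sign per feature so that larger oriented values always
mean stronger dependency or drug response: gene effects enter as
−CERES, drug response as −AUC. Drugs annotated as positive regulators
(mechanism of action containing "agonist" or "activator") have their
correlation coefficients multiplied by −1; both sign rules are folded
into a single per-drug multiplier so nothing is flipped twice.

Correlations are pairwise-complete over samples. A feature is excluded
(and counted) when fewer than `min_pairs` overlapping observations
remain or its vector is constant; `min_pairs` defaults to 20, a
package choice that keeps rank correlations away from the very small
samples where they are noise. Average ranks (tie-corrected) are used
throughout; p-values use the t approximation, matching
`scipy.stats.spearmanr`.

## Preranked GSEA

The enrichment engine is the weighted Kolmogorov–Smirnov running sum:
hits add |score|^exponent normalized over the in-set total (exponent
1 by default; 0 gives the classic unweighted statistic), misses
subtract 1/(N − k), and ES is the extremum of largest absolute value.
Exact positive/negative ties at the extremum (possible with discrete
weights) resolve to the positive extremum, with a 1e-9 tolerance so
the rule is stable under float roundoff. The leading edge contains the
in-set features at or before (positive ES) / at or after (negative ES)
the extremum.

**Null model.** Because the ranked list holds one correlation
coefficient per feature, no sample-label permutation is possible at
this stage; the null is random feature sets of matching size drawn
without replacement from the ranked universe (`n_perm` default 1,000,
minimum 100). One matrix of random keys is shared across set sizes —
each size's draws remain exact uniform without-replacement samples,
and sharing mirrors the classic engine's reuse of one permutation
stream for all query sets.

NES = ES / mean(|permuted ES| of matching sign); nominal p = fraction
of same-sign permuted ES at least as extreme. FDR q compares the
pooled permuted NES with the observed NES distribution within each
sign pool. p and q are floored at 1/n_perm — a permutation test cannot
certify anything smaller — and an ES of exactly 0 reports NES 0,
p = 1 by convention. Ties in ranked scores are broken by feature id
(stable) and their frequency logged.

## Genetic PDEA

Each activity pathway's gene-level profile is ranked and queried with
the full pathway collection. The diagonal (a pathway's association
with its own genes' essentiality) answers a different question from
cross-pathway crosstalk, so self-tests are computed but excluded from
the off-diagonal FDR family; their q-values are corrected across the
diagonal family instead. With 69 pathways this yields 69 × 68 = 4,692
off-diagonal tests per stratum.

**Cross-screen combination.** Two screens profiled against the same
expression input are dependent, so nominal p-values are combined with
the harmonic mean p-value, HMP = k / Σ(1/pᵢ), which is valid under
dependence. A pair significant in the reference screen (q < 0.05)
counts as *recapitulated* when its HMP < 0.05 and the NES signs agree;
the rate is also reported without the sign requirement. Note an
arithmetic property of the HMP of two tests: it is bounded above by
2·min(p), so for pairs already at the permutation floor in the
reference screen the HMP gate is nearly always passed and the
recapitulation decision is carried by sign concordance — under a null
second screen the expected rate is therefore ≈ 0.5, not ≈ 0.

## Pharmacological PDEA

Drugs map to a pathway when **any** annotated target gene belongs to
it (union semantics; per-drug promiscuity is logged — promiscuous
compounds join several sets, which is why conclusions should rest on
the aggregated enrichment rather than single drugs). Sets with fewer
than 4 drugs are dropped, and sets reduced below that by the profiled
drug universe are skipped with a warning. Individual drug:pathway
correlations are BH-corrected per pathway across its drugs (a global
family is available behind a flag). Media strata are analyzed fully
independently; cross-medium screening keeps pairs significant in both
media with equal correlation sign and reports discordant-sign pairs
separately.

## Gene+drug integration

For every (drug, annotated target, pathway) triple, the gene and drug
coefficients are summed (|sum| ≤ 2). The empirical null draws
`n_perm` (gene rho, drug rho) pairs with replacement from the
pathway's own coefficient pools;

    p = #(same-signed permuted sums with |sum| ≥ |observed|)
        / #(same-signed permuted sums)

An observed sum of exactly 0 reports p = 1; zero same-signed
permutations report the 1/n_perm floor with a flag, and both raw and
floored p are written. Pools are pathway-specific by default (a
global-pool option exists). BH runs once over the whole association
family. Because p is floored at 1/n_perm, the attainable BH q is
bounded below by roughly (family size)/(n_perm × rank); at small
cohort scales planted associations therefore surface as top-ranked
nominal p rather than q < 0.05, and the test-suite asserts exactly
that.

The pathway-level merge keeps pairs with same-sign NES, p < 0.05 and
q < 0.25 in both the genetic and pharmacological grids — thresholds in
the permissive range conventional for GSEA-style screens — and is
monotone in both thresholds.

## Media comparison

Per-medium pathway essentiality is the mean over activity pathways of
NES · (−log₁₀ q); the q floor upstream guarantees finite weights, and
a q of 0 reaching this stage raises. Pathways are grouped by whether
any linked metabolite differs in concentration between the two media
(the pathway ↔ metabolite linkage is user-supplied; an example
formulation table with folate 1 vs 4 mg/L and aspartate 150 vs 0 μM
ships with the package). The paired test between media is the Wilcoxon
signed-rank test — the standard paired rank analogue of the
Mann–Whitney U test — with zero differences dropped, the exact null
for n ≤ 25 and the continuity-corrected normal approximation beyond.

## Synthetic data

`simulate_matrix` draws i.i.d. Normal(μ = 0, σ = 0.5) values per cell
line, matching the shape of stratum-normalized expression data.
`plant_gradient` replaces a 25-feature set with draws from
Normal(μᵢ, σ) where μᵢ is an arithmetic sequence from −X (first
sample) to +X (last sample) — the only reading consistent with stated
endpoints; non-member rows are returned bit-identical.
`run_sensitivity_grid` runs the full pipeline (ssGSEA → Spearman →
preranked GSEA) for 50 replicates per (X_expr, X_dep) cell, with
per-replicate seeds spawned deterministically from a master seed, and
reports the fraction significant both by FDR q < 0.05 and by nominal
p < 0.05, since either can reasonably define "significant" for a
single planted set. The genetic variant uses 300 cell lines, the
pharmacological one 200; the suite and the acceptance script run at a
reduced 2,000-feature scale (full 16,643-gene / 1,390-drug scale is
supported by configuration), with grid cells chosen to cover the null,
the saturated regime and mirrored expression/dependency-heavy pairs.

**What the generator shows — and does not.** Under these conditions
the planted-set correlation is approximately the product
c_A(X_expr) · c_D(X_dep), where the activity side averages 25 genes
(effective noise ≈ σ/√25) and the dependency side is single-gene
(noise σ). The activity side therefore saturates first: at matched
small gradients, dependency-heavy cells reach significance slightly
*more* often than their mirrored expression-heavy counterparts, while
at moderate gradients (≥ 0.1 on both axes) both saturate at fraction
1.0. Any directional claim about which gradient matters more is thus
regime-dependent, and the suite asserts only the saturated-regime
comparison. The generator makes no attempt to emulate real expression
covariance, lineage structure, measurement batch effects or
dose-response curve shapes; passing tests establish the statistical
machinery (calibration, power, sign handling), not biological
fidelity.

`make_fixture_cohort` builds a 60-sample cohort (40 adherent RPMI, 16
adherent DMEM, 2 suspension, 2 with missing annotations), 12
overlapping 25-gene pathways over 400 genes, and 40 drugs, with two
planted activity→dependency links of opposite sign riding on two
independent latent gradients (so no cross-pathway associations are
induced), one activity→drug link sharing a pathway pair with a genetic
link (so the merged analysis can recover it), two activator drugs with
inverted response gradients (exercising the sign flip), and one
pathway with only three annotated drugs (exercising the min-drug
filter). The planted truth is recorded in the returned manifest.

## Numerical and engineering choices

- All randomness flows through `numpy.random.Generator`; one master
  seed fans out to per-stage seeds via `SeedSequence`, so full runs
  are byte-reproducible and parallelizable.
- Thresholds (min 5 genes per set, min 150 samples per drug, min 4
  drugs per set, min 20 pairs per correlation, n_perm, α, p/q cutoffs)
  are configuration constants, not hard-coded.
- Missing values are preserved at I/O and handled pairwise in
  statistics; nothing is imputed.
- Exact antisymmetry of PDEA under screen negation holds for tie-free
  profiles; with tied coefficients the stable identifier tie-break
  does not mirror under negation, so only NES signs (not the last
  digits of ES) are guaranteed to flip.

## Known limitations

Activity is inferred from expression, which proxies — imperfectly —
protein abundance, post-translational regulation and flux. Drug-based
conclusions inherit target-annotation errors and off-target effects.
The multi-target mapping means one compound can drive several drug
sets. The permutation floor bounds attainable significance (see
above), which matters whenever the correction family is much larger
than n_perm × the number of true signals.
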