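# pdea — pathway dependency enrichment analysis

`pdea` identifies cancer-cell vulnerabilities at the level of metabolic
**pathways** rather than individual genes, by linking inferred pathway
activity to genome-wide loss-of-function fitness screens and
drug-response screens across panels of cell lines.

It is written for computational biologists working with
CCLE/DepMap/PRISM-style resources: an expression matrix (genes × cell
lines), a CRISPR gene-effect matrix (CERES scores), a drug-response
table (AUC per drug × cell line with target/mechanism annotations),
per-sample culture annotations, and KEGG-style gene sets in GMT format.

## The method

For each (culture type, medium) stratum of cell lines:

1. **Pathway activity.** Expression is unit-normalized per gene within
   the stratum, then scored per sample with single-sample GSEA: for
   pathway *P* and sample *j*, genes are ranked by descending
   expression and

   ES(P, j) = Σᵢ [ P_in(i) − P_out(i) ],

   where P_in is the in-set ECDF weighted by |z|^α (α = 0.25) and
   P_out the uniform out-of-set ECDF. Raw scores are divided by the
   range across the whole matrix, giving normalized enrichment scores
   (ssNES) comparable within the stratum. Normalized weighted average
   expression (NWAS), which down-weights genes shared between
   pathways, is available as an alternative metric.

2. **Dependency profiling.** The ssNES of each pathway is
   Spearman-correlated (pairwise-complete) with every oriented screen
   readout: −CERES for gene knockouts, −AUC for drugs (so larger
   always means stronger dependency / response). Correlation
   coefficients of drugs annotated as positive regulators (agonists /
   activators) are multiplied by −1.

3. **Enrichment (PDEA).** The ranked coefficient list is queried with
   preranked GSEA (weighted Kolmogorov–Smirnov running sum, feature-set
   permutation null): positive NES = stronger dependency on the target
   pathway when the activity pathway is up. **Genetic PDEA** queries
   gene sets in the knockout profile; **Pharmacological PDEA** queries
   drug sets built from annotated targets (pathways with < 4 drugs are
   dropped).

4. **Combination and integration.** Screens sharing the same
   expression input are combined by the harmonic mean p-value
   HMP = k / Σ(1/pᵢ). Genetic and pharmacological evidence is merged
   at the pathway level (same-sign NES, p < 0.05, q < 0.25 in both)
   and at the drug+target level (summed correlation coefficients with
   an empirical permutation test and BH correction). Media effects are
   summarized per medium by the mean of NES · (−log₁₀ q) and compared
   with a paired signed-rank test between pathways that do / do not
   contain media-differential metabolites.

A synthetic-data module generates the cohorts used throughout the test
suite: i.i.d. Normal(0, 0.5) matrices with a planted 25-feature set
whose per-sample mean follows a linear gradient from −X to +X, plus a
small end-to-end fixture cohort with planted associations of known sign.

## Worked example

```python
from pdea import GeneticPDEA
from pdea.simulate import make_fixture_cohort, fixture_activity

cohort = make_fixture_cohort(seed=1)          # synthetic 60-line cohort
activity = fixture_activity(cohort, medium="RPMI")
model = GeneticPDEA(activity, cohort.dependency, cohort.collection,
                    min_pairs=10)
results = model.fit(n_perm=1000, seed=0)
print(results.summary())
```

```
Genetic PDEA results
========================================
Activity pathways:        12
Dependency pathways:      12
Off-diagonal tests:       132
Significant (q < 0.05):   10
Self-dependencies:        12 (6 positive / 6 negative NES)
Permutations per test:    1000

Strongest positive dependencies:
activity_pathway dependency_pathway   nes     p     q
             P01                P02 2.892 0.001 0.001
             P08                P04 2.310 0.001 0.001
             P10                P04 2.121 0.002 0.009
             P02                P04 1.850 0.004 0.013
             P05                P11 1.595 0.024 0.095
```

The cohort plants a positive link from P01 activity to P02 gene
dependency (cells with high P01 activity depend more on P02 genes) and
it surfaces as the top hit: NES 2.89 at the permutation floor
p = q = 0.001. The 132 off-diagonal tests are the 12 × 11 cross-pathway
hypotheses; the 12 diagonal self-dependencies are tested as their own
family (`results.self_dependency()`). `PharmacologicalPDEA` works the
same way on the drug screen, and `pdea.integrate.merge_pdea` intersects
the two result grids.

The same pipeline is scriptable from the shell:

```sh
pdea simulate --seed 3 --outdir fixture        # write a synthetic cohort
pdea run --config config.yaml --outdir out     # activity -> PDEA -> integrate
pdea media-compare --config config.yaml --outdir out
```

Every run writes its resolved configuration and a JSON manifest with
the seeds consumed; reruns with the same config are byte-identical.

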