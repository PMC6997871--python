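# gcomics

Multi-omic analysis of neuronal **growth cones** (GCs) across development,
and of lipid remodelling in **induced optic-nerve regeneration** — as a
tested, reusable Python pipeline.

## The scientific problem

Growth cones drive axon elongation; their plasma membrane expands by
coordinated protein–lipid remodelling. A typical study design profiles the
GC proteome and lipidome in two subcellular fractions — growth cone
membrane (GCM) and growth cone particulate (GCP) — across five
developmental stages (E18, P0, P3, P6, P9) with ~6 biological replicates
per cell, and compares the developmental lipid signature with the lipidome
of adult optic nerves induced to regenerate (Wnt3a or Zymosan after nerve
crush) versus uninjured controls.

`gcomics` implements the statistical core of such an analysis:

* **Preprocessing** — total-intensity/median normalization, autoscaling,
  replicate QC via coefficients of variation (CV = SD/mean on raw
  intensities, within stage×fraction groups), lipid shorthand parsing
  (`Cer(d18:1/24:0)` → class, chains, carbons, double bonds) and
  species→class aggregation.
* **Multivariate stage modelling** — PCA; ANOVA-simultaneous component
  analysis (ASCA), which splits the centered data matrix **X** into
  per-factor effect matrices plus residual, `X = X_fraction + X_stage +
  X_interaction + E`, and runs PCA within each effect; PLS regression of
  the stage ordinal (E18=0 … P9=4) with variable importance in projection,
  `VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)`; Ward/Euclidean
  clustering with purity; a 2-means early/late partition; sample Pearson
  correlation matrices.
* **Differential statistics** — Welch-t volcano gates (BH q < 0.05, fold
  change > 2), linear stage trends (Pearson p < 0.01, |r| > 0.7), and
  per-lipid-class treatment/timepoint tests with `*`/`***` tiers.
* **Enrichment** — one-sided hypergeometric (Fisher) term enrichment with
  Benjamini–Hochberg correction over GMT term sets, plus per-term
  annotation counts.
* **Networks** — lipid×protein Pearson matrices; a dual-requirement filter
  for literature protein–protein edges (both endpoints detected, profiles
  mutually correlated at p < 0.01); Fisher *r*-to-*Z*-to-*r* combination,
  `r̄ = tanh(mean(atanh(r_i)))`, of per-species correlations into class
  level coefficients; protein-complex annotation.
* **Regeneration arm** — parametric empirical-Bayes (ComBat-style) batch
  correction across experiments, ROC ranking of lipid species by midrank
  Mann–Whitney AUC with best-threshold accuracy, and intersection of
  significant ontology terms between early development and regeneration.
* **Synthetic data** — `gcomics.simulate` generates both study arms with
  lognormal measurement noise and planted, fully recorded effects
  (`SyntheticTruth`), so every stage is exercised end-to-end with no
  external data and parameter recovery is testable.

## Worked example

```python
from gcomics import generate_gc_multiomic, preprocess
from gcomics.multivariate import asca, pls_stage_model, hierarchical_cluster

bundle = generate_gc_multiomic(seed=1)          # 29 GCM + 29 GCP samples
log2 = preprocess.normalize(bundle.protein_matrix, "total_intensity").to_log2()
scaled = preprocess.normalize(log2, "autoscale")

print(asca(scaled, bundle.meta).summary())
print(pls_stage_model(log2, bundle.meta.stage_ordinal, n_components=2).summary())
print(hierarchical_cluster(scaled, k=2, labels=bundle.meta.fraction).summary())
```

prints

```
ANOVA-simultaneous component analysis
--------------------------------------
fraction             SS share  34.30%   effect-PC1 100.00%
stage                SS share  17.78%   effect-PC1  83.33%
fraction:stage       SS share   3.81%   effect-PC1  26.85%
residual             SS share  44.44%

PLS stage regression
--------------------
components: 2
R2  = 0.9959
Q2  = 0.9906
accuracy = 1.0000
features with VIP > 2: 109

ward/euclidean clustering, k=2
purity vs labels: 100.0%
```

Reading: the subcellular fraction accounts for a third of total variance
and its effect matrix is one-dimensional (PC1 = 100% — a two-level factor),
developmental stage is almost perfectly predictable from the proteome
(R² = 0.996, cross-validated Q² = 0.991, every sample's rounded prediction
correct), and Ward clustering at k = 2 separates GCM from GCP samples
without error. The 109 proteins with VIP > 2 are dominated by the planted
stage-trending proteins.

Command-line equivalents:

```bash
gcomics simulate --outdir sim --seed 1     # write TSV/GMT datasets
gcomics gc --outdir gc_run --seed 1        # development pipeline
gcomics regen --outdir regen_run --seed 42 # regeneration pipeline
```

## Layout

```
src/gcomics/      library (simulate, preprocess, multivariate, differential,
                  enrichment, network, regeneration, pipeline, cli)
tests/            pytest suite incl. property-based and recovery tests
docs/methods.md   models, assumptions, defaults and limitations
scripts/          acceptance script
```
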