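# Methods

This note documents the statistical models implemented in `gcomics`, the
defaults they ship with, what the synthetic-data generator does and does
not emulate, and the numerical choices a maintainer should know about.

## Noise model and synthetic study design

Measurement noise is multiplicative lognormal: intensities are assembled
in log2 space as `baseline + planted effects + Normal(0, σ)` with
`σ = sqrt(ln(1 + CV²)) / ln 2`, so the raw-scale within-group coefficient
of variation is targetable directly. The default `noise_cv = 0.08` puts
the median within-group sample CV near 7–8% (the CV estimator at n≈6 is
slightly downward-biased), comfortably inside the replicate-QC bounds the
pipeline checks (11% proteome, 10% lipidome). Baseline log2 intensities
are drawn Normal(20, 2) per feature — a typical MS dynamic range; real
intensity distributions are instrument-dependent, and this assumption is
recorded in the config.

The growth-cone arm generates 600 proteins and 200 lipid species over 20
classes in 2 fractions × 5 stages × 6 replicates, with the GCM/E18 and
GCP/P9 cells at n = 5 (29 + 29 = 58 samples). The regeneration arm
generates 208 species over 53 samples: control n = 21, crush + saline
n = 16, Wnt3a n = 6, Zymosan n = 10, treated samples spread over 3/7/15
days post injection.

Planted effects, all multiplicative (additive in log2), with defaults:

| effect | default | rationale |
| --- | --- | --- |
| protein stage trends | 60 up + 60 down, slope 1.0 σ per stage, linear in ordinal | at n = 29 per fraction this puts the expected Pearson r at ≈0.82, above the 0.7 gate with ~0.9 power |
| P:L-coupled proteins | 8 per class (TG, CerG1), slope 1.5 σ | pairwise profile correlations ≈0.82, so planted protein–protein edges clear the p < 0.01 filter with a wide margin |
| fraction shift | 200 proteins, ±2.0 log2 (half GCM-, half GCP-enriched) | passes the FC > 2 volcano gate; enough coordinated features that the k = 2 Ward cut follows fraction, not stage |
| lipid class switching | early classes (TG, DG, MG, ChE, ZyE, So) high at E18–P0, late classes (CerG1, LPC, LPS, LPG) high at P3–P9; step of 3 σ | class switching between E18–P0 and P3–P9 is the planted structure; a *step* rather than a linear profile is used because a linear profile makes the two-cluster solutions {E18,P0} vs {E18,P0,P3} exact cost ties |
| marker species | `Cer(d18:1/24:0)` + 8 σ in Wnt3a/Zymosan samples | produces complete separation (AUC 1) at the 16-vs-21 design |
| regeneration class effects | TG ±1.5 σ at day 7 / +4 σ at day 15; CerG1 mirrored negative; MG, PG +4 σ at day 15 only | weak day-7, strong day-15 responses |
| crush depletion | 9 species (8 PC + 1 PE), −1.5 log2 in every crushed eye | passes the volcano gate exactly and only for these species |
| batch offsets | +0.6 / −0.4 log2 for the Wnt3a/Zymosan experiment batches | realistic between-experiment shifts, several noise SD |

Protein stage effects are linear in the stage ordinal (E18 = 0 … P9 = 4,
equally spaced) because the trend analysis is a linear (Pearson) screen.
Class membership of species is drawn uniformly (sizes differ by at most
one) from per-class enumerations of plausible chain compositions spanning
0–6 double bonds; sphingoid classes carry d/t long-chain-base prefixes.

What the generator does **not** emulate: spectra, retention times,
identification error, isotopes/adducts, missing values, heteroscedastic
(intensity-dependent) noise, and correlated technical drift. Passing the
recovery tests therefore shows the statistics recover planted structure
under idealized lognormal noise — not that the pipeline is robust to the
full messiness of real LC-MS/MS data.

## Normalization and QC

Default normalization is total-intensity column scaling (each sample
scaled to the mean column sum) followed by `log2(x + 1)`; median scaling
and per-feature autoscaling (zero mean, unit n−1 variance) are available.
CVs are computed on raw intensities within stage×fraction groups with n−1
SDs; the report also carries the between-group dispersion (CV of group
means) so intra- vs inter-group variation can be compared. Whether CVs
should be computed pre- or post-normalization is a judgement call; the
pipeline computes them on the (raw-space) normalized matrix and the raw
generator output gives indistinguishable medians.

The lipid-name grammar accepts `CLASS(chain[/chain…])` with 1–4 chains and
optional d/t hydroxylation prefixes. Unknown class codes parse and pass
through flagged rather than failing, so novel classes survive the
pipeline.

## Multivariate models

**PCA** is SVD-based with a deterministic sign convention (the
largest-magnitude loading of each component is made positive). Constant
features are rejected with advice to remove them.

**ASCA** partitions the column-centered samples×features matrix into
per-factor effect matrices (level-mean deviations broadcast to samples),
an interaction term (cell means minus main effects) and a residual, then
runs PCA within each effect matrix. The decomposition identity holds by
construction; pairwise orthogonality of the effect matrices holds on
balanced designs (and for the fraction factor of the default design,
which is balanced at 29/29 even though two stage cells are reduced — this
is why the two-level fraction effect matrix is exactly rank 1 and its PC1
carries 100% of its variance). Because the "share of variance explained"
can mean either the effect-matrix-internal PCA ratio or the share of
total SS, the results object reports both (`effect_pca_ratio`,
`ss_share`); the PC1 = 100% statement refers to the former.

**PLS stage regression** autoscales features internally, centers the
stage ordinal response and delegates the NIPALS fit to scikit-learn's
`PLSRegression`. VIP scores use the standard formula and satisfy
`Σ VIP² = p` identically. Q² = 1 − PRESS/TSS comes from 7-fold
cross-validation stratified by stage with re-autoscaling inside every
training fold (preventing leakage of test-fold means/variances); the fold
assignment is seeded. "Accuracy" is the fraction of samples whose single
continuous prediction, rounded and clipped to the ordinal range, matches
the true stage — one reasonable reading of a classification accuracy for
a regression model; alternatives (per-stage one-vs-rest models) would
differ.

**Clustering**: Ward linkage on Euclidean distances of autoscaled
samples, cut with `maxclust`; purity is the percentage of samples whose
cluster's majority label matches their own. The early/late split is
k-means (k = 2, k-means++ with 50 restarts, seeded); the cluster with the
lower mean stage ordinal is labelled "early". All-identical inputs
degrade to a single cluster with a warning instead of an error.

## Differential statistics

Welch (unequal-variance) t-tests everywhere; log2 fold change is the
difference of group means in log2 space; BH correction is applied within
each analysis family (per fraction, per contrast), not globally. The
trend screen gates on the raw p (p < 0.01) jointly with |r| > 0.7 and
reports the BH q alongside, since whether trend p-values should be
FDR-corrected is itself a thresholding choice; both columns are emitted.

## Enrichment

One-sided upper-tail hypergeometric probabilities (`hypergeom.sf(k−1, N,
K, n)`), BH-corrected across terms; depletion uses the complementary
tail. The background is the set of detected features in the relevant
fraction, not a global universe — detection-conditioned enrichment. Odds
ratios use a Haldane 0.5 correction so empty cells stay finite. Term sets
travel as GMT. The lipid ontology stand-in is a packaged static
class→term map (storage/membrane/headgroup-charge/bilayer-biophysics
vocabulary) expanded to species membership per dataset; it emulates the
*shape* of a lipid-ontology analysis, not any specific database's
statistic.

## Networks

Protein–lipid correlations are Pearson over the intersection of sample
ids (proteome and lipidome sample sets need not be identical); a
stage-mean mode is deliberately not the default. The protein–protein edge
filter implements the dual requirement — endpoints detected, and endpoint
profiles mutually Pearson-correlated at p < 0.01 (either sign) across the
relevant fraction's samples. Correlations are clipped to ±(1 − 1e−6)
before `atanh` so the Fisher combination stays finite. Class-level
combined coefficients average over species within each class (averaging
over classes instead would be the other reading; the per-class table
makes both derivable). Complexes with fewer than two detected members are
flagged, not dropped.

## Batch correction

The empirical-Bayes location/scale model: per-feature standardization
against the batch-size-weighted grand mean and pooled within-batch
variance; per-batch per-feature means and variances shrunk toward
normal/inverse-gamma priors with method-of-moments hyperparameters;
posterior updates iterated to relative tolerance 1e−4 (max 100
iterations). A single-batch input is returned unchanged. Degenerate
priors (zero across-feature variance of the batch estimates) disable
shrinkage for that batch rather than dividing by zero. As a package
design choice the adjusted matrix is re-centred per feature to its
original grand mean: raw EB shrinkage leaves a residual offset of the
order of the shrinkage bias, and exact mean preservation makes downstream
fold changes invariant to the correction. The test suite checks numerical
agreement with R's `sva::ComBat` (after applying the same re-centring to
its output) to 1e−3 — the residual is the 1e−4 convergence stop acting on
values of magnitude ~20.

In the regeneration pipeline, correction is applied across the two
regeneration-experiment batches only (the arms that were acquired
separately), never jointly with the control group: batch is confounded
with treatment there, and a joint correction would subtract the biology.
Class-level timepoint tests run on the corrected intensities for the same
reason. Wnt3a and Zymosan samples are pooled as "regeneration" for ROC
ranking across all days (a per-day restriction is available via the
metadata).

## ROC ranking

AUC is the midrank Mann–Whitney statistic, `U/(n₁·n₂)` with half-credit
ties, orientation-corrected to ≥ 0.5 with the direction recorded.
Best-threshold accuracy scans midpoints between consecutive distinct
pooled values in both orientations — the Youden-optimal cut under equal
misclassification cost. Ties in the ranking are broken by accuracy and
then feature id, so output order is deterministic.

## Problem sizes and tolerances

Default problem sizes (600 proteins / 200 + 208 species, 58 + 53 samples)
were chosen so the full suite — including the 50-seed recovery loops for
cluster purity, the early/late split and marker ranking, and the 40-seed
null-calibration checks — completes in about a minute. Analytic
identities are asserted at 1e−9 (ASCA decomposition/orthogonality, VIP
normalization), exact-arithmetic oracles at 1e−12 (hypergeometric
enumeration, AUC pair counting, Fisher combination), and the single-batch
identity at 1e−8.

## Known limitations

* The generator's effects are additive in log2 with homoscedastic noise;
  no missing values, censoring, or intensity-dependent variance.
* ASCA significance is not assessed by permutation; the package reports
  variance shares, not p-values, for the factor effects.
* The trend screen is linear; non-monotone developmental profiles (e.g.
  a P3 peak) are invisible to it and only partially captured by PLS.
* ComBat here has no covariate-preserving mode; corrections are applied
  only within arms where batch is not confounded with the contrast of
  interest.
* The enrichment module does no ontology-graph propagation or semantic
  grouping of terms; terms are treated as flat, possibly overlapping
  sets.
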