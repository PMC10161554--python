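# Methods

This note documents the statistical machinery implemented in `tetragwas`,
the choices made where the design was genuinely open, and what the
synthetic test bed does and does not establish about real data.

## Genotypes and filtering

Genotypes are allele dosages: the number of alternate-allele copies at a
marker in a tetraploid, 0–4 for called ("most probable") genotypes or real
values in [0, 4] for posterior-mean dosages. Missing calls are NaN.

Variant filtering retains heterozygous biallelic SNPs (single-nucleotide,
single-ALT, with at least one sample at dosage 1–3; multi-allelic records
and indels are dropped, never decomposed) and then applies three rules in
order — missingness, QualByDepth, minor allele frequency — attributing each
removed marker to the first rule it fails so the filter report's counts sum
to the number removed:

* **Missingness.** A marker passes with missing fraction ≤ 0.10. The
  boundary is deliberately inclusive for markers (exactly 10% passes) and
  exclusive for samples (a sample with *more than* 10% missing is removed);
  `strict_missing` flips the marker rule.
* **QD.** Variant quality divided by the summed read depth of
  non-homozygous samples (dosage 1–3); markers with QD < 2, or with QD
  undefined (no het sample with positive depth), fail. The rule only
  applies when quality and depths are available, i.e. VCF input; dosage-CSV
  input carries neither. Depths are used as read from the VCF.
* **MAF.** min(f, 1 − f) with f = mean dosage / 4 over non-missing
  samples; the threshold is strict (MAF exactly 0.01 fails).

## LD pruning

Per chromosome, markers are sorted by position and a start marker is drawn
uniformly (seeded; the seed is recorded in the output since the procedure
is order-dependent). Scanning rightwards from the start, a candidate is
dropped when **any** already-retained marker within 100 kb (inclusive
window) has r² > 0.5 with it; at the chromosome end the scan resumes left
of the start towards the beginning under the same rule. r² is the squared
Pearson correlation over complete observations; with fewer than two
complete pairs or a constant column r² is undefined and treated as "no
linkage" (the candidate survives; `drop_undefined` inverts this). The
candidate is tested against the whole retained set restricted to the
window, not only the nearest retained marker. Chromosomes are pruned
independently; per-chromosome seeds are spawned from the global seed.

## Population structure

* **PCA** on mean-imputed, column-centered dosages (full SVD).
* **Cluster count** by k-means over 1–10 clusters with
  BIC(k) = n·log(WSS/n) + k·log(n); smallest k at the minimum wins. This
  BIC needs the retained principal components to include dimensions the
  sub-division of a true cluster cannot compress — with very few retained
  components it keeps decreasing in k; use a few dozen components.
* **DAPC**: linear discriminant axes from the generalized eigenproblem
  B·a = λW·a on the retained PCs; membership probabilities are Gaussian
  posteriors with a pooled within-cluster covariance in discriminant space
  and equal priors. Cross-validation (stratified 90/10, repeated) reports
  accuracy and membership RMSE per candidate number of retained PCs; the
  toolkit selects the accuracy maximizer (ties toward fewer PCs) but emits
  both curves, since "performance still high, RMSE still low" is a
  judgement call.
* **STRUCTURE post-processing** (the MCMC itself is external): the
  Evanno-style second-difference statistic
  Δ(nS) = |mean L(nS+1) − 2·mean L(nS) + mean L(nS−1)| / sd(L(nS)) over
  replicate runs (undefined at endpoints and at zero replicate sd), and
  label-switching alignment that matches each run's columns to the first
  run's by optimal linear assignment on column correlations before
  averaging and renormalizing. Import/export of the STRUCTURE text formats
  writes each tetraploid sample as four 0/1 allele rows (missing −9).
* **Kinship**: K = MMᵀ from mean-imputed, column-centered (not
  variance-scaled) dosages, rescaled so the mean diagonal is one; the LOCO
  variant recomputes K for each chromosome from all other chromosomes so a
  tested marker never contributes to its own correction.

## Phenotypes

Bruising is scored 0 (none) to 5 (extensive) on several tubers per
biological replicate per genotype. BLUEs come from the mixed model with
genotype fixed and replicate nested in genotype random; the single
replicate-to-residual variance ratio is profiled out of the REML criterion
and maximized by bounded scalar search on the log scale (tolerance 1e-8,
explicit boundary check at ratio 0). With balanced data and no replicate
variance this collapses to genotype means. BLUEs are then Yeo–Johnson
transformed (λ maximizing the Gaussian profile likelihood on [−2, 2], ties
toward the identity λ = 1) and standardized to mean 0, sd 1 (ddof = 1).

Low/high bruising groups for expression contrasts use per-genotype mean
tuber scores with inclusive boundaries: mean ≤ 1 is low, mean ≥ 2 is high,
in between is excluded.

## GWAS

Eight genetic models map dosage d to design columns: additive (d, used raw
for fractional posterior-mean dosages), simplex/duplex dominant for either
allele (indicators for ≥1 or ≥2 copies of the reference or alternate
allele), diploidized additive ({0→0; 1,2,3→1; 4→2}), diploidized general
(het and hom-alt indicators) and general (an indicator per observed dosage
level against the lowest, so its numerator degrees of freedom are the
number of observed levels minus one). All class-based encodings round
fractional dosages to the nearest integer first — the diploidized-additive
map is only defined on integer classes, so it rounds too. Missing dosages
are mean-imputed per marker before encoding, keeping the tested sample set
fixed per chromosome.

Six population settings: naive (K = I, no covariates), K only, Q only with
either membership source, and K+Q. Q covariates drop their last column
(rows sum to one, collinear with the intercept). Variance components are
estimated once per (setting, chromosome) under the null by REML on the
eigenbasis of K — profiling σ²e out and maximizing over the variance ratio
by bounded scalar search — and reused for all markers (P3D). Each marker
is then an F-test of its encoded columns added to the null fixed effects
in the whitened (eigenrotated, weighted) space; constant or collinear
encodings are skipped with a recorded reason, and a numerically perfect
fit is reported at the p-value floor (1e-300) rather than skipped.

Diagnostics: the inflation factor is the no-intercept regression slope of
sorted observed scores on the null expectation −log₁₀(i/(m+1)); setting
selection takes the smallest per-setting mean inflation above one, falling
back (flagged) to the closest to one when none exceed it.
Benjamini–Hochberg runs at α = 0.05 and the threshold is reported on the
score scale as −log₁₀ of the largest significant p (+∞ sentinel when
nothing passes); "high-scoring" markers have score strictly above 4
(p < 10⁻⁴). Cross-model score correlations are Pearson over markers scored
in both sets, displayed in average-linkage (1 − r) dendrogram order.

## Expression integration

Genes with at least five samples below 5 reads are removed before DE
analysis. DE tables (from any upstream tool) are classified at adjusted
p < 0.05, split by log2 fold-change sign; exact zeros are reported as
ambiguous. The built-in `simple_de_test` is plumbing for the synthetic
pipeline — Welch t on log2(median-of-ratios-normalized counts + 1) with BH
adjustment — not a negative-binomial DE model, and it underestimates
significance for low-count genes relative to one.

Functional-class scoring contrasts a gene set's mean score (−log₁₀
adjusted p, floored at 1e-300) against the background of all other scored
genes with a Welch t statistic and one-sided (greater) p by default. The
default variance term uses the actual background size, which makes the
null rejection rate match the nominal level; the deliberately conservative
"virtual random set of the same size" variant (background variance divided
by the set size) is available as `virtual_set=True`. A permutation mode
cross-checks the analytic p-values.

## HIDECAN and colocalization

The HIDECAN table stacks three layers per chromosome: markers with score
above the threshold (deduplicated across result sets keeping the best
score), DE genes with adjusted p below α (plotted at their interval
midpoint — no convention exists for gene points), and candidate genes
passed through unfiltered. The plot draws one horizontal track per
chromosome scaled to true length, writes a CSV sidecar that is a lossless
projection of the table, and can split the chromosomes into two panels.
Colocalization is a formalization of narratively described overlap
regions: DE genes are linked to every high-scoring marker within 1 Mb and
connected components containing both layers become regions, with bounds
rounded outward to 0.1 Mb. The windowing rule is this package's own
definition and is labelled as such in outputs.

## The simulator

The generator emulates the study design it is meant to stress:
a 23-cross half-sib panel with two recurrent parents and 158 progeny
(`table1_design()`), 12 chromosomes, a 0–5 bruising score on 2 biological
replicates × 3 tubers, and an expression block of 25,000 genes with 57
planted DE genes at |log2FC| = 2 contrasted at 41 low vs 33 high samples.
Founder dosages are binomial draws from per-marker allele frequencies
(uniform 0.1–0.9), optionally from diverged founder pools (assigned in
contiguous parent blocks so crosses stay within pools) to plant
structure; markers planted as QTLs are forced to duplex founders so they
segregate. Meiosis transmits gamete dosages from
Hypergeometric(4, dosage, 2) — random bivalent pairing, **no double
reduction and no recombination map**, so markers are independent given
the parents. LD for pruning tests is instead planted by copying block-head
columns with a small resampling rate. Phenotype latent values combine
unit-scaled QTL encodings (weight √pve), a polygenic term through random
marker effects, and residual noise, then are discretized by fixed
population quantiles with replicate/tuber noise; realized QTL variance
shares land in roughly [0.1, 0.3] for a planted 0.2. Expression counts are
gamma–Poisson with configurable dispersion (Poisson at 0) and uniform
library-size factors.

Because genetic linkage, read-depth-driven genotype uncertainty, selection
and real admixture are not modelled, passing tests demonstrate the
*statistical machinery* (calibration, ranking, correction ordering,
algorithmic agreement with oracles) rather than field performance on any
particular crop dataset.

## Numerical choices and degenerate inputs

* REML searches run on log-ratio ∈ [−12, 12] with an explicit boundary
  check at ratio 0; kinship eigenvalues are clipped at 0.
* Rank decisions (skipping collinear encodings) use an absolute 1e-8
  tolerance in the whitened design; encoding columns that project to ~0
  after removing null covariates are reported `collinear_encoding`.
* The inflation factor requires ≥ 10 scores and errors on constant input.
* k-means WSS is floored at 1e-12 before the log for duplicated points.
* Ties: smallest cluster count at equal BIC, fewer PCs at equal CV
  accuracy, λ = 1 on a flat Yeo–Johnson likelihood, smallest mean at equal
  inflation.
* Pipeline problem sizes: the acceptance run uses 12 × 100 markers for the
  158-progeny panel and the replicate counts above; statistical checks use
  100 replicates (inflation ordering, 80-sample two-pool panels) and 50
  replicates (QTL recovery, 200-sample panels). These sizes were chosen as
  desk-scale renderings of the study design.

## Known limitations

* No genotype-posterior estimation, imputation (beyond mean imputation
  internal to PCA/kinship), multi-trait or multi-locus models, or Bayesian
  admixture inference.
* The P3D approximation fixes variance components across markers; exact
  per-marker REML would differ slightly for very large effects.
* When no STRUCTURE output is supplied, the pipeline fills the second
  membership slot with soft k-means posteriors on PCA scores — an
  admixture-style stand-in, not a Bayesian admixture estimate; the
  STRUCTURE import path replaces it when a file is given.
* SVG output embeds no fonts beyond matplotlib defaults; the determinism
  guarantee covers the CSV sidecar, not image bytes across matplotlib
  versions.
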