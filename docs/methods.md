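# Methods

This note documents the statistical procedures, the generative model
behind the synthetic cohort, the numerical choices, and the limits of
what the test suite demonstrates.

## Scales and conversions

Methylation enters as beta values β ∈ [0, 1] (fraction methylated).
Linear modelling and batch adjustment operate on M-values,
M = log₂(β/(1−β)), which stabilizes variance near the boundaries. Betas
are clipped to [ε, 1−ε] with ε = 10⁻⁶ before the transform; deposited
matrices contain values at or near 0 and 1, and the clip makes the
transform total while perturbing interior values not at all. The inverse
is β = 2^M/(1+2^M). Matrices are CpG × sample; autosomes only.

## Outlier handling

"Outliers" are defined by Tukey's boxplot fences, Q1 − 1.5·IQR and
Q3 + 1.5·IQR, with linear-interpolation quartiles. Truncation replaces
each outlier by the most extreme observed value inside the fences on its
side, so output never leaves the observed data range and the rank order
of non-outlier values is preserved. Truncation is applied once (to
methylation responses before regression, and to continuous factor
variables; categorical factors are never truncated). A second pass is a
no-op whenever outliers are sparse enough not to move the quartiles; for
pathological inputs with ≥ 25% outliers the fences themselves shift, so
idempotence is a practical property, not an algebraic one.

## Variability filter

Per CpG and tissue: range_excl_outliers = max − min over in-fence values;
p99 − p1 and IQR computed on **all** values (outliers are excluded only
for the range clause; the percentile clause on outlier-excluded values is
available as a switch). A CpG is variable iff range > 0.10 AND
(p99 − p1) > 0.05, both strict. Thresholds are configurable; defaults are
the published 10%/5%. Percentiles use linear interpolation between order
statistics — the convention must be fixed somewhere for reproducibility,
and this is numpy's default.

## Batch adjustment (parametric empirical Bayes)

ComBat-style location/scale harmonization on M-values. Per CpG, a model
with batch indicators plus covariates is fitted by least squares; data
are standardized by the pooled residual SD; per-batch means and variances
of the standardized data are shrunk toward their across-CpG moments
(normal prior on locations, inverse-gamma on scales, moment-matched
hyperparameters, fixed-point solver) and removed; covariate signal is
restored. Conventions follow the reference R implementation (sample
variance, ddof = 1, for per-batch scales and prior moments), which a test
verifies to ~10⁻⁵ agreement on a shared fixture.

One deliberate deviation, on by default (`df_corrected_variance=True`):
the pooled variance divides by the residual degrees of freedom n − p
rather than n. With this package's rich designs (p ≈ 37 columns at
n = 200) the classical 1/n estimator understates σ and the rescale step
then shrinks *all* signal by ≈ √(n/(n−p)) (≈ −9% on implanted effects);
the correction reduces the systematic attenuation to the small-batch
Jensen term (≈ −3% with 12-sample chips). Set the flag to False for the
classical behaviour. Covariate columns nested within batch (chip-set
dummies when batch is chip) carry no information once batch is modelled
and are dropped with a log entry. Batches need ≥ 2 samples; a single
batch is a no-op.

## Cell-type deconvolution

Reference-based: per sample, minimize ‖Pw − b‖² over the probability
simplex (w ≥ 0, Σw = 1), where P holds reference beta profiles at
signature CpGs. The quadratic program is solved per sample with SLSQP
(tolerance 10⁻¹⁴), which is exact to ~10⁻⁷ on noiseless mixtures at the
panel sizes used (≤ 7 cell types). The per-sample residual norm is
reported. Downstream designs use the leading principal components of the
proportions — the smallest k explaining ≥ 90% of variance, capped at
(number of cell types − 1) because simplex rows are rank-deficient.

## Design matrices

Intercept; sex; gestational age (weeks, untransformed); ethnicity,
hospital, bisulfite batch, chip position as reference-coded dummies with
the most frequent level as reference; DNA extraction batch for cord
tissue vs chip-set for cord blood; cell-proportion PCs; and
cellPC × ethnicity-dummy interactions (main effects plus interactions).
Rank deficiency is resolved by a greedy left-to-right sweep that keeps a
maximal independent column set and logs what it drops, making the design
deterministic given its inputs.

## Surrogate variables

Simplified residual-PCA form: project the M-matrix on the orthogonal
complement of the design, take the top n_sv left singular vectors
(default n_sv = 5). This captures hidden batch/composition structure that
is orthogonal to the design — the property the sensitivity analysis
needs — without the iteratively re-weighted published algorithm.
Components with numerically zero singular values are zeroed.

## Association scans

Every scan fits, per response and predictor, OLS of the (truncated)
methylation value on [design + predictor]. With a shared complete design
this is computed by the Frisch–Waugh–Lovell route: residualize response
and predictor against an orthonormal design basis, then the slope, SE,
t and two-sided P follow in closed form with df = n − rank(design) − 1.
This is algebraically identical to the full fit (verified against
normal-equations and statsmodels oracles to 10⁻⁸ relative) and lets a
chromosome's worth of CpG × SNP fits run as two matrix products. SNPs
with missing calls fall back to per-SNP complete-case fits; there is no
dosage imputation. P values are floored at 10⁻³⁰⁰ to keep rankings finite;
min-p ties break by larger |t|, then lexicographic predictor id.

* **cis-mQTL**: cis = same chromosome, no distance window. Response is the
  adjusted beta value by default (M-scale optional). Genome-wide call at
  min-P < 5 × 10⁻⁸.
* **Prenatal factors**: continuous factors are truncated then tested on
  their coefficient; categorical factors are dummy-coded and tested with
  the overall F-test for the block (one P per factor; the reported
  "effect" is the largest-magnitude level coefficient). Per-factor
  complete-case fits; factors missing in > 50% of samples are skipped.
  Call at min-P < 10⁻³ across the factor set — a per-CpG Bonferroni over
  factors with no CpG-dimension correction, as the method prescribes.

Genotype QC precedes scanning: SNPs need call rate ≥ 95%, MAF ≥ 10% and a
1-df chi-square Hardy–Weinberg goodness-of-fit P ≥ 10⁻⁶ (monomorphic SNPs
return P = 1 by convention); samples then need call rate ≥ 99% on the
surviving SNPs.

## Overlap accounting

The four-category variability partition uses the shared CpG universe; the
eight-category association accounting uses CpGs variable in ≥ 1 tissue,
with each tissue's status in {associated, variable-not-associated, not
variable} and the impossible (not-variable, not-variable) cell excluded.
The both-associated overlap is reported as a percentage of each tissue's
associated count (both denominators), since the two denominators differ.

## Reference clustering

Cohort tissues are represented by per-CpG median profiles. Harmonization
masks reference observations with coverage < 30×, then requires sites to
be present in all cohort profiles, observed in ≥ 10 of 25 references
(rescaled as ceil(0.4 · n) for other panel sizes), and to have IQR > 10%
across references; each dropped site records one reason. Distance is
1 − Spearman (pairwise-complete), agglomeration is average linkage, and
columns are sorted lexicographically first so ties break deterministically.
The distance/linkage pair is a declared package default, configurable;
per-sample Spearman correlations against each reference accompany the
dendrogram (also exported as Newick).

## Synthetic cohort

Per tissue, bulk M-values are assembled as baseline + person-level
deviation + implanted effects, then cell-mixed, batch-shifted and noised:

* **Baselines**: non-variable CpGs near the boundaries (|M| ~ U(2.5, 4),
  sign shared between tissues for 70% of CpGs, redrawn for 30% to give
  tissue-specific methylomes); variable CpGs intermediate (M ~ U(−1, 1)).
* **Variable sets**: defaults place 37.5% of CpGs variable in cord
  tissue, 23.3% in cord blood with a 20% shared core — the observed
  two-tissue landscape, landing the four-category split near 20/18/3/59.
* **Person-level variance**: SD 0.6 (M units) at variable CpGs, giving
  beta-scale ranges comfortably above the 10% filter at intermediate
  baselines while 0.1-SD measurement noise keeps boundary CpGs below it.
* **mQTL implants**: 200 CpGs drawn from the shared variable core, each
  tied to a same-chromosome SNP, ±0.7 M per allele (≈ 1.1 residual SD) —
  the paired-tissue concordance analyses need shared implants, so the
  same CpG/SNP/effect is implanted in both tissues.
* **Factor implants**: 100 CpGs, ±0.25 M per SD of a continuous factor
  (≈ 0.4 residual SD). Factors: 40 standard-normal variables in
  correlated blocks of 5 (ρ = 0.5, a placeholder for the observed
  correlated factor groups, not a calibration) plus 5 three-level
  categoricals.
* **Genotypes**: independent SNPs, allele frequencies U(0.15, 0.5) —
  common variants that pass the 10% MAF filter — dosages Binomial(2, p).
  No linkage disequilibrium is simulated.
* **Cell structure**: per tissue, 300 signature CpGs drawn from the
  variable set get cell-type-specific profiles (random half of the types
  high ~U(0.8, 0.95), rest low ~U(0.05, 0.2)); mixing weights are
  symmetric-Dirichlet (concentration 5). Signature CpGs carry no person
  effects or implants, so their variability is purely compositional and
  deconvolution is well-posed. All other CpGs are identical across cell
  types, so mixing is exact there.
* **Batch**: 12-sample chips; per-chip location shift ~N(0, 0.3²) and
  scale factor ~1 + N(0, 0.05²) applied on the M scale.

Reference methylomes: per lineage an M-profile offset ~N(0, 1.5²) from a
mixed baseline, per tissue a further ~N(0, 0.3²) (5:1 divergence ratio);
coverage ~Poisson(40), 5% of sites missing per tissue.

What the generator does **not** emulate: probe chemistry and type-2 bias,
detection-P missingness, linkage disequilibrium, correlated CpG blocks,
cell-type-specific mQTL/factor effects, and real factor distributions.
Passing tests therefore demonstrate the statistical machinery under the
stated generative assumptions, not performance on raw array data.

## Problem sizes and seeds

The default desk-scale cohort is 200 samples × 20,000 CpGs × 5,000 SNPs
on 4 chromosomes — large enough that the genome-wide thresholds and the
multi-factor null rate are meaningfully exercised, small enough for a
full pipeline run in well under a minute. Unit tests use a 120 × 2,000 ×
400 miniature; at that n the 5 × 10⁻⁸ threshold is deliberately
underpowered, so mini-scale tests assert detection at milder levels and
leave threshold-level recall to the desk-scale checks. One global seed
expands to fixed per-stage seeds (SHA-256 of "seed:stage", reduced below
2³¹) so stages re-run reproducibly in isolation.

## Known limitations

* The published per-CpG counts for the real cohort can only be checked
  against the deposited matrices, which are too large to ship; the
  corresponding check runs only when those files are supplied.
* Single-SNP scans only: no conditional, joint or trans models, no LD
  clumping.
* The empirical-Bayes adjustment retains a small O(1/batch-size)
  attenuation of covariate-orthogonal signal even with the df correction.
* The exact-recovery guarantee of the deconvolution holds for
  well-conditioned panels; nearly collinear reference profiles degrade it
  like any least-squares problem.
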