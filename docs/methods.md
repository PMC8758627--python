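# Methods

This document describes the statistical methods implemented in `mtcnkit`,
module by module. Throughout, "metric" means the standardized mtDNA
copy-number estimate and "truth ledger" means the table of planted effects
emitted by the simulator.

## Synthetic cohorts (`synthdata`)

Diploid nuclear genotypes are drawn through a Gaussian copula with
blockwise AR(1) correlation (ρ = 0.8 in 20-SNP blocks by default), so
Hardy–Weinberg holds marginally while realistic linkage disequilibrium
exists within blocks. Haploid mitochondrial genotypes descend from a small
set of backbone haplotypes with Dirichlet-skewed frequencies and a per-site
mutation rate, mimicking haplogroup structure.

The latent copy number is `G·β + 0.3·shared + noise`, where `shared` also
loads on the first two cell-count columns — a deliberate confounder that
covariate selection must find. True copy number is
`100·exp(0.25·latent)`. Traits carry a direct copy-number loading, a mild
age effect, and cluster-template SNP effects: each functional cluster of
SNPs affects its trait block proportionally to its copy-number effect,
which is exactly the structure the scaled-beta clustering stage assumes.
Survival times are exponential under proportional hazards with an optional
planted log hazard ratio for carriers of one backbone; causes of death are
drawn from fixed probabilities (external / cancer / non-cancer).

Assay simulators add the artifacts each estimator must remove: array batch
shifts and probe noise on `log(true copy number)`; Poisson sequencing reads
with mitochondrial expectation proportional to copy number; and triplicate
qPCR ΔCt values carrying `−log₂(copy number)`, a plate random intercept,
and a linear pipetting-order trend, with calibrator wells on every plate.

## Copy-number estimation (`copynum`)

- **Array.** The raw metric is the median mitochondrial probe intensity
  over probes homozygous in the sample. Technical structure is captured as
  principal components of nuclear probe intensities and regressed out
  stepwise: components enter in variance order and inclusion stops at the
  first term not significant at α = 0.05.
- **Sequencing.** The metric is the mitochondrial read fraction.
- **qPCR.** Replicate-level ΔCt values are corrected in two stages. The
  pipetting-order slope is estimated by plate-demeaned replicate-level
  least squares (plate fixed effects; the order trend is identified from
  within-plate contrasts, where biology is independent of well order).
  Sample-level means are then cleaned of plate effects by a random-intercept
  mixed model fitted by REML. Fitting the mixed model at replicate level
  instead would misattribute replicate correlation to the plate variance
  component and shrink real biological signal into the plate BLUPs.
- **Calibration.** The array metric is regressed on a sequencing metric
  over the overlap subset (≥30 samples) and the fitted line maps the whole
  cohort onto the sequencing scale.
- **Cell-count covariates.** Forward selection by cross-validated
  out-of-fold R²: a candidate stays if it improves mean out-of-fold R² by
  more than ε. The out-of-fold R² gain of a pure-noise covariate does not
  shrink to zero — a chance correlation of order χ²₁/n is a property of the
  whole dataset and survives fold splitting — so ε must exceed this noise
  floor for the cohort size used (e.g. ε = 10⁻³ at n = 5,000; the default
  10⁻⁴ is appropriate around n = 10⁵).
- The final metric is the z-standardized residual of the calibrated value
  on the chosen covariates.

## Association (`assoc`)

Per-variant ordinary least squares with covariates; monomorphic variants
yield missing estimates with a warning. Stratum results are combined by
fixed-effect inverse-variance weighting after allele alignment (effect
alleles are harmonized, irreconcilable records rejected). Genomic inflation
λ is the median association χ²(1) over its null median. Loci are 1 Mb
windows around genome-wide-significant (p < 5×10⁻⁸) lead SNPs, merged
greedily from the smallest p; a locus is retained if it has two
genome-wide-significant members or a directly genotyped lead. Conditional
scans re-run the regression with lead dosages as covariates and report
newly significant variants. Two loci are "shared" across analyses when
their leads are within 500 kb.

## Fine-mapping and gene assignment (`finemap`)

The Wakefield log approximate Bayes factor is
`0.5·log(1−r) + 0.5·z²·r` with `r = W²/(se² + W²)` and prior effect
standard deviation W = 0.15. Normalized per-locus ABFs give posterior
inclusion probabilities; the 95% credible set is the smallest
descending-PIP prefix reaching the coverage. The final lead replaces the
GWAS lead by the top-PIP SNP only when its PIP exceeds 0.2 and is ≥1.75×
the runner-up.

Colocalization follows the ABF framework: per-hypothesis sums over SNP
configurations (H3 via an outer sum excluding the shared-SNP diagonal),
priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵, computed with log-sum-exp. A
sensitivity variant drops the SNP with the smallest combined GWAS/eQTL
p-value and recomputes. Extreme z-scores are rescaled so the largest maps
to a two-sided p of 5×10⁻³⁰⁰ (z = 37.02 cap), preserving rank order.

Gene assignment is tiered: a missense variant inside the credible set; else
colocalization with PP4 > 0.5 (ties within 0.05 assign all tied genes);
else an enrichment-prioritized gene at p < 0.05; else the nearest gene
within 1 Mb of the final lead; else unassigned.

## Phenotype clustering (`pheclust`)

A phenome scan regresses each trait on the metric with covariates and
flags traits at a Bonferroni threshold. SNP × trait effects (age modeled
with a natural cubic spline basis when requested) are divided by each SNP's
copy-number effect — the "scaled beta", invariant to allele orientation —
and SNPs with |copy-number effect| below a floor are excluded. The matrix
is embedded with UMAP and clustered with DBSCAN; a robustness grid reports
label stability across UMAP settings.

Cluster–phenotype enrichment uses the statistic |in-cluster median −
out-of-cluster median| with membership permutations and the add-one
estimator `p = (1 + #{null ≥ observed}) / (1 + n_perm)`. The study-wide
threshold repeats the whole scan on label permutations and takes the
rank-⌈0.05·n_outer⌉ smallest of the outer minimum p-values (rank 15 for 300
outer rounds), which calibrates the family-wise error rate to ~5% by
exchangeability.

## Gene-set enrichment (`genesets`)

Hypergeometric (upper-tail) term enrichment over a fixed universe. To avoid
multi-gene loci driving terms, one gene is sampled uniformly per locus
(genes at designated primary loci prioritized), a significance cutoff is
the 5th percentile of minimum term p-values over random same-size gene
draws, and the procedure repeats; terms passing in ≥80% of iterations are
retained. A one-sided Fisher exact test measures overlap of assigned genes
with a 16-gene mtDNA-depletion panel.

## Mitochondrial genome (`mito`)

Haploid SNPs are tested per genotyping stratum (per-stratum filters
MAF > 0.005 and imputation INFO > 0.80) and combined by IVW meta-analysis;
collinear covariates are dropped with a warning. The study-wide threshold
runs the scan on 300 N(0,1) dummy traits and divides the 15th smallest
per-trait minimum p by the number of real tests (42). With independent
SNPs the per-trait minima follow the min-of-m-uniforms law Beta(1, m),
which the calibration suite verifies by Kolmogorov–Smirnov.

Haplotypes concatenate, across credible sets, the highest-PIP member SNP
directly genotyped on both arrays (substituting down the PIP order, error
if none qualifies); haplotypes with frequency < 0.005 are set missing and
the most common is the reference. Trait association is a nested-regression
F-test over haplotype indicator columns (levels with fewer than two
carriers are set missing). Mortality uses Cox proportional hazards with
cause-specific censoring — external causes always censored; `cancer` and
`non_cancer` modes censor the competing cause — with a likelihood-ratio
global p for the haplotype block against the reduced model (a hand-rolled
Breslow partial likelihood when the reduced model has no covariates). An
iterative multivariate pruner retains credible-set SNPs while their best
p across traits stays below 5×10⁻⁴.

## Pipeline and I/O (`io`, `pipeline`, `cli`)

TSV with explicit headers is the interchange format; the VCF reader is
deliberately minimal (uncompressed, GT/DS only) and reports the offending
line number on malformed input. `PipelineConfig` rejects unknown YAML keys
and writes a resolved copy next to every run's outputs. `run_pipeline`
executes the enabled stages in dependency order (synthdata → mtcn → assoc →
finemap → pheclust/genesets → mito), raising a `StageDependencyError`
naming the missing upstream stage, and emits per-stage TSVs plus a JSON
report. All randomness flows from the configuration seed, so identical
seeds reproduce identical outputs.
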