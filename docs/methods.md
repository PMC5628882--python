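# Methods

This note documents the models, parameter choices and numerical conventions
behind `aicvd`, and what the synthetic-data experiments do and do not
establish about real data.

## Study design being emulated

The package reimplements a multi-cohort cross-phenotype analysis of
cardiovascular disease (CVD) risk in six autoimmune diseases.  The design
constants carried throughout are: cohort sizes RA 1,281 / PS 1,123 / PA 989 /
SLE 907 / CD 1,358 / UC 827 (6,485 patients), an external healthy-control
cohort of 1,558 used only for Hardy–Weinberg QC, a composite CVD endpoint
(any of coronary heart disease, cerebrovascular accident, peripheral arterial
disease) with aggregate post-QC prevalence 140/5,317 ≈ 2.6%, and exclusion of
patients whose cardiovascular event predates the autoimmune diagnosis.

The genotype panel is the one deliberately scaled quantity: the emulated
study analyzed ~507k genome-wide SNPs, which is neither necessary nor
informative for verifying the statistics.  Default panels are 1,200–5,000
SNPs in blockwise-LD blocks; every threshold acts on per-SNP quantities, so
panel size affects only multiplicity, which the tests account for at their
own scale.

## Synthetic data generator

**Genotypes.** Per haplotype, a latent Gaussian vector with exchangeable
within-block correlation `ld_rho` (default 0.8, block size 20) is thresholded
at the `Φ⁻¹(MAF)` quantile; the genotype is the sum of two independent
haplotypes.  Hardy–Weinberg therefore holds marginally, and within-block
dosage correlation is an attenuated, MAF-dependent image of the latent
correlation (r² ≈ 0.25–0.5 at `ld_rho` 0.8–0.95) — enough to make `r² > 0.2`
pruning meaningful.  Blocks sit ≥ 2.5 Mb apart so between-block dosages are
independent and fall outside the 1 Mb pruning window.  MAFs are uniform on
(0.05, 0.5); ~30% of variants are marked imputed with info scores uniform on
(0.75, 1), so the info > 0.8 filter has work to do; entries go missing at
rate 0.001.

**Phenotypes.** CVD status follows a logistic model: per-disease intercept +
covariate effects + planted SNP effects on centred dosages.  The intercept is
calibrated *within each disease* (by root-finding on the mean predicted
probability) to the aggregate prevalence; per-disease calibration was chosen
because the cohorts' covariate profiles differ (RA older, SLE 90% female),
and a single global intercept would starve the young, female-dominated
cohorts of events, making their planted effects untestable.  The study
reports no per-disease event counts, so equal prevalence is the neutral
assumption.  Covariate distributions (age means 40–58 by disease, female
fractions 0.45–0.9, binary risk-factor rates 0.07–0.4, plausible log-odds
0.03–0.6) are loosely realistic defaults and are not asserted against any
table.  A configurable 2% of all samples is converted to cases with an event
date before diagnosis (≈130 of 6,485, exercising the exclusion rule at the
study's reported magnitude of 127).

**Resources.** Nearest-gene annotation is positional: one gene per 500 kb
window, so all variants of an LD block share a gene — as real nearest-gene
mapping does when a pruned proxy replaces the variant it tags.  Candidate
lists (defaults 103 CVD, 315 autoimmune) draw planted SNPs first, with the
risk allele set to the allele whose planted log-odds is positive.  For each
planted pattern one GMT set contains the pattern's genes plus 3 random
padding genes; 40 decoy sets of 15 random non-planted genes provide the
multiple-testing background.

**Seeding.** One master seed; `numpy` `SeedSequence` children per component
(MAF/metadata, patient genotypes, control genotypes, phenotypes, resources).
All iteration is in a fixed disease order, so output is bit-identical across
processes.

**Planted scenario.** The recovery experiments plant three patterns of 12
SNPs each (one per LD block) with per-dosage log-OR 1.4 in the clinically
paired diseases (A: RA+SLE, B: CD+UC, C: PS+PA), MAF ≥ 0.1.  OR ≈ 4 on
common variants reflects the effect sizes replicated loci show for this kind
of rare composite endpoint (roughly 2–7); cohorts with ~25–35 cases resolve
only effects of that order, and the point of the scenario is that a real
signal of plausible size survives the whole chain.

**What passing does not show.** The generator has no realistic human LD
map, no confounding between ancestry and phenotype (PCA outlier removal is
exercised on planted frequency-shifted subgroups in tests, not in the default
scenario), no survival-time structure in event dates, no genotyping batch
effects, and exchangeable — not distance-decaying — within-block LD.
Recovery results certify the statistical machinery, not performance on any
particular real cohort.

## Statistical components

**Logistic dosage regression.** Newton/IRLS with log-likelihood convergence
tolerance 1e-8 (max 100 iterations), warm-started per scan from the
covariate-only fit (identical MLE, shorter path).  Wald inference on the
dosage term; 95% CI as `exp(β̂ ± 1.96·se)`.  Separation is detected (runaway
coefficients, singular information, or fitted probabilities reproducing the
outcome to 1e-6) and surfaced as `converged=False` with infinite SE and
missing P — never as a significant result.  Firth correction is deliberately
not applied; with ~2.6% prevalence rare or near-monomorphic variants may
legitimately fail, and the QC MAF floor keeps this rare.  statsmodels serves
as an independent oracle in the tests, not as the implementation.

**Complete-case analysis.** Samples with any missing covariate are dropped
from a disease scan with a logged count; per-SNP missing dosages drop only
that SNP's rows.

**Hardy–Weinberg.** Exact conditional test: probabilities of all
heterozygote counts compatible with the observed allele counts, P = total
probability of configurations no more probable than the observed one
(computed in log space with a `1+1e-12` tie guard).  Evaluated on
hard-called control-cohort genotypes, at P < 1e-4.

**PCA outlier removal.** Variants standardized by `(g − 2p̂)/√(2p̂(1−p̂))`
with missing values zero-filled after centring; top 10 PCs via truncated SVD
(fixed start vector, deterministic); samples beyond 6 SD on any PC removed;
up to 10 iterations with early stop.  The 6 SD threshold follows the
convention of the standard tool; the emulated study states PCs and
iterations but not the threshold.

**Breslow–Day.** Allele-count (not carrier) 2×2 tables, dosages rounded
ties-to-even.  The expected case/risk-allele cell under the Mantel–Haenszel
common OR is the admissible root of the quadratic
`ψ(r₁−ã)(c₁−ã) = ã(n−r₁−c₁+ã)`; variance is the inverse sum of reciprocal
expected cells; the statistic sums squared standardized deviations over
strata (χ²_{K−1}).  Tarone's correction is off by default and available by
flag.  Zero-margin strata are dropped with a warning.

**CPMA.** Closed-form likelihood ratio for the exponential decay rate of
`−ln p` (two-sided in λ; a one-sided excess-association variant is
available).  P-values of exactly 1 are clamped to 1−1e-16 with a warning.
The nominal gate is ≥1 disease at P < 0.05 (configurable `min_nominal`);
retention at P_CPMA < 0.01.  At k = 6 the χ²₁ reference is mildly
anticonservative (true null rejection ≈ 0.0108 at the 0.01 gate, measured by
simulation); this finite-k behaviour is a property of the statistic itself
and is documented rather than corrected.

**LD pruning.** Greedy by ascending P_CPMA (ties: chromosome, then
position), dropping SNPs with dosage-correlation r² > 0.2 against any kept
SNP within a 1 Mb window.  Dosage r² stands in for haplotype r² (no phased
data post-simulation); the window default is a package choice, as the
emulated analysis names none.

**Clustering.** P-values are discretized to categories 1–4 at boundaries
0.05/0.02/0.005, each boundary belonging to the less-significant category.
Gower distance treats categories as unordered symbols (mismatch fraction;
an ordered/Manhattan variant exists for sensitivity analysis).  Ward
linkage follows the classic R `ward.D` convention — the Lance–Williams
recurrence applied to the dissimilarities as given — implemented via the
identity ward.D(d) = ward.D2(√d) with squared merge heights; `ward.D2` is
available by flag.  `k="auto"` cuts at the largest merge-height gap over
k ∈ [2, 15] (the classic dendrogram elbow).  Mean-silhouette selection was
tried first and is still available as `k="silhouette"` (skipping
singleton-producing cuts), but on the coarse Gower grid duplicate category
profiles form zero-distance shards with silhouette near 1, so the mean
systematically rewards shattering genuine patterns into fragments; the
height-gap rule proved stable where silhouette over-split.  Fisher's
method assumes
independent P-values across a cluster's SNPs; the upstream r² pruning is the
mitigation, and residual dependence would make combined P-values
anticonservative — a caveat inherited from the design.  Bonferroni defaults
to (clusters × diseases) tests.

**Enrichment.** One-sided hypergeometric tail `P(X ≥ x)` with the universe
defaulting to all genes in the annotation table (configurable); sets are
intersected with the universe; BH FDR across all set × cluster tests.

## Problem sizes in tests and the acceptance script

Simulation-backed checks run at sizes chosen to keep the full suite within a
desk-scale budget while leaving Monte-Carlo error well inside each assertion
band: calibration checks use 10⁴–10⁵ draws, recovery checks 150–500
replicates, the null genome scan ~1,600 regressions, the end-to-end recovery
experiment 20 pipeline runs at full cohort size on a 1,200-SNP panel.  The
CPMA null-rate check uses 10⁵ draws because at 10⁴ the Monte-Carlo standard
error (≈0.001) is comparable to the width of the ±0.002 acceptance band
around the nominal 1% rate.

## Known limitations

* GEN/SAMPLE support covers the 5-metadata-column dialect with chromosome
  encoded in the SNP identifier; VCF/BGEN/PLINK and chromosome X are out of
  scope.
* Heterogeneity testing is unadjusted (no covariate-adjusted interaction
  model), matching the emulated analysis.
* The cluster count the height-gap rule returns on real, messier profiles
  may differ from the emulated study's 10; an explicit `k` flag reproduces
  any fixed choice.
* Fisher-combined cluster P-values inherit whatever LD the r² < 0.2 pruning
  leaves behind.
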