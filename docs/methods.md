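# Methods

## Overview

`circgse` tests whether a named gene set is enriched with GWAS signal for a
quantitative trait. The chain is: SNP quality control → mixed-linear-model
association scan → assignment of SNPs to gene sets by genomic position →
sum-of-squared-effects statistic with a circular-rotation permutation null.
Gene sets typically come from a differential-expression analysis (fold-change
bins) or a co-expression network (module membership files); both are consumed
as plain gene-id lists, and the DE model fit and network construction
themselves are outside the package's scope.

## The enrichment statistic and its null

For gene set *g*, a SNP is a member when its position lies in
[gene_start − f, gene_end + f] for any member gene, with flank f = 5,000 bp,
inclusive at both ends, clipped at position 1, and strand-agnostic. The
statistic is T_sum = Σ β², summed over the m_g member SNPs, with β the raw
per-SNP effect estimate (a (β/se)² variant can be formed by the caller from
the summary table; the raw-β form is the default and the one reported).

The null treats the genome-ordered SNP vector (chromosomes concatenated in
lexicographic order) as a circle. Each permutation draws one offset k uniform
on {1, …, n−1} and rotates the whole membership mask by k while the β vector
stays fixed. Rotation preserves m_g exactly and preserves the mask's local
clustering, so the null respects the two features that make member SNPs
non-exchangeable individually: genes cover several nearby SNPs, and nearby
SNPs have correlated effect estimates under LD. The empirical p-value is

    p = (1 + #{T_perm ≥ T_obs}) / (n_perm + 1),

one-tailed, with ties counted against significance; the +1 terms re-include
the identity rotation conservatively, so p ≥ 1/(n_perm + 1) > 0 always.
Default n_perm = 10,000.

Design choices made where more than one convention exists:

- **Genome-wide rotation** is the default; per-chromosome rotation (an
  independent offset within each chromosome) is available via
  `per_chromosome=True`. Genome-wide rotation gives n−1 distinct null states
  even for small panels and keeps the null exchangeable across chromosomes.
- **The identity offset is excluded** from the draws; the estimator's +1
  re-includes it conservatively.
- All rotation T_sum values are computed exactly by direct indexed summation
  when n·m_g is small, and by FFT circular cross-correlation (error ~1e-12
  relative) for large panels.
- Raw empirical p-values are reported per (trait, set); adjusting across
  pairs is left to the caller (a BH column is one `bh_adjust` call away).

A closed-form identity used as a self-check throughout the tests: over all n
rotations (identity included) each SNP is covered by exactly m_g rotations,
so the mean of the exhaustive rotation distribution is (m_g/n)·Σβ² exactly.

## Mixed-linear-model GWAS

Model: y = 1μ + x_j b_j + g + e with g ~ N(0, σ²_a G), e ~ N(0, σ²_e I);
phenotypes are assumed pre-adjusted for environmental fixed effects, so the
only fixed effect is the intercept.

- **GRM**: VanRaden method 1, G = ZZᵀ / (2Σp_k(1−p_k)), dosages mean-imputed
  (to 2p_k) and centred by 2p_k; all SNPs, no leave-one-chromosome-out.
  Monomorphic SNPs contribute zero to numerator and denominator.
- **REML**: the restricted likelihood of the single-random-effect model is
  profiled over δ = σ²_e/σ²_a in the eigenbasis of G (one eigendecomposition,
  every δ evaluation O(n)): a 56-point log₁₀ grid on [10⁻⁵, 10⁶] brackets the
  optimum, refined by bounded scalar minimisation. σ̂²_a follows in closed
  form from the profiled quadratic form. The δ-grid bounds act as soft
  boundaries: a pure-noise phenotype lands at large δ (ĥ² ≈ 0) rather than
  at a hard σ²_a = 0 constraint.
- **Scan**: EMMAX-style — variance components held fixed across SNPs.
  With V = σ̂²_a G + σ̂²_e I, data are whitened in the eigenbasis, the
  intercept is projected out, and b̂_j = (x̃ᵀỹ)/(x̃ᵀx̃) with
  se = (x̃ᵀx̃)^{-1/2} and a Wald normal-approximation p (appropriate at the
  intended n ≫ 1 scale). Monomorphic SNPs are flagged NaN and skipped.
  Missing dosages are mean-imputed in both GRM and scan (deterministic).

## SNP quality control

Thresholds (module `circgse.defaults`): missing-call rate > 0.05, minor
allele frequency < 0.01 (computed over non-missing calls), exact
Hardy–Weinberg p < 10⁻⁶. The HWE test enumerates all heterozygote counts
compatible with the observed allele counts (the Levene–Haldane conditional
distribution) and sums the probabilities of configurations no more likely
than the observed one; monomorphic sites return p = 1. Filters run
sequentially — missingness, then MAF, then HWE — because per-filter removal
counts are attribution-dependent; the order is fixed and reported.

## DEG stratification and expression filters

- DEG call: BH-adjusted p < 0.05, strict. BH is the standard step-up
  procedure (delegated to `statsmodels`; the test suite checks it against a
  from-definition oracle).
- Fold bins are on |log2FC| with half-open intervals (0,1], (1,2], (2,3],
  (3,∞) per direction. The binning is defined on the log2 scale because an
  "upregulated, fold change 0–1" stratum is only coherent there; boundary
  values fall in the lower bin. Both the scale and the edges are arguments.
  A DEG with log2FC exactly 0 has no direction; it is excluded and logged.
- Expressed-gene filter: TPM > 0 in at least 7 samples. Co-expression
  prefilter: a gene is dropped when more than one sample within any one
  group has TPM < 0.05 (strict inequality at the threshold).

## Synthetic data

The generator emulates a small livestock-style association cohort:

| parameter | default | meaning |
|---|---|---|
| n_individuals | 500 | cohort size |
| n_snps | 2,000 | markers, uniform positions |
| n_genes | 150 | non-overlapping genes |
| chrom_lengths | 2 × 1.5 Mb | genome; ~1 SNP / 1.5 kb, gene windows well separated |
| gene_length / min_gene_gap | 2 kb / 12 kb | slot packing guarantees ≥ 6 kb between genes, so 5-kb flank windows of distinct genes never merge |
| maf_range | (0.05, 0.5) | per-SNP allele frequency, uniform |
| ld_rho | 0.3 | adjacent-SNP allelic correlation |
| h2_set / h2_polygenic | 0 / 0.3 | variance fractions; causal SNPs confined to the designated set (±5 kb) |
| genes_per_set / n_decoy_sets | 15 / 4 | tested sets, sampled disjoint |

Haplotypes are first-order Markov chains whose conditional carrier
probabilities are chosen to keep each SNP's marginal frequency exactly at its
drawn value while adjacent alleles correlate at ≈ ld_rho (clipped where
neighbouring frequencies differ too much for the target correlation to be
attainable); the chain restarts at chromosome boundaries. Genotype = sum of
two independent haplotypes. Phenotype components (set-genetic, polygenic,
residual) are each rescaled post hoc so realized variance fractions equal
their targets exactly — convenient for parameter-recovery tests at any n.
Effects are drawn on the allele-dosage scale, matching the additive coding
of the scan.

What the generator does **not** emulate: population structure or family
relatedness beyond the polygenic term, long-range LD, MAF-dependent effect
sizes, genotyping error, covariates/fixed effects (phenotypes are generated
pre-adjusted). Calibration and power results on these simulations therefore
speak to the mechanics of the statistic and its null — set-size preservation,
clustering robustness, empirical-p validity — not to robustness against
stratification or cryptic relatedness in real cohorts.

## Operating characteristics (recomputed by `scripts/acceptance.py`)

Problem sizes were chosen to make each study run in minutes on one CPU while
keeping the Monte-Carlo error well below the effect being checked:

- **Calibration**: 1,000 independent null datasets (h2_set = 0, one 15-gene
  set, 200 rotations each); the rejection rate at p ≤ 0.05 is compared with
  the binomial 99% band [0.035, 0.065].
- **Power**: 200 datasets with h2_set = 0.3; detection at p ≤ 0.05 and the
  rank of the causal set among 5 tested sets (ties for smallest p count as
  first, relevant at the 1/201 p-value floor).
- **REML recovery**: 20 simulations at n = 1,000, 2,000 SNPs, true h² = 0.5.
- **Exact fixtures**: the enumerable 4-SNP rotation example, the
  two-individual GRM, the ten-SNP QC fixture, the three-value BH example.

These studies simulate clean panels (no missingness, MAF ≥ 0.05), so the QC
stage would remove nothing and is skipped inside the replicate loops.

## Known limitations

- The EMMAX approximation understates significance for SNPs with very large
  effects (where per-SNP variance-component re-estimation would matter).
- The rotation null assumes the β² landscape is stationary along the genome
  order; a strongly non-stationary landscape (e.g. one chromosome with
  systematically inflated effects) would need per-chromosome rotation.
- Binary PLINK files are not read; use the text .map/.ped pair or the TSV
  dosage dialect.
- Gene-set p-values are marginal; overlapping sets are tested independently
  with no conditional analysis.
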