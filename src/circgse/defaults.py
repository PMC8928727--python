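"""Pipeline-wide default parameters.

Every stage exposes these as its keyword defaults and through the CLI, so a
single place documents the analysis conventions: symmetric 5-kb gene flanks
for SNP-to-set assignment, 10,000 rotation permutations, BH-adjusted p < 0.05
for DEG calling, the SNP QC triple (MAF / missingness / HWE), and the two
expression filters applied before DE and co-expression analysis.
"""

# SNP-to-gene-set assignment: a SNP belongs to a set when it lies inside a
# member gene or within this many bp up/downstream (strand-agnostic).
FLANK_BP: int = 5_000

# Rotation permutations per (trait, set) enrichment test.
N_PERM: int = 10_000

# DEG call: BH-adjusted p-value strictly below this.
PADJ_MAX: float = 0.05

# SNP quality control, applied sequentially missingness -> MAF -> HWE.
MAF_MIN: float = 0.01      # drop SNPs with minor allele frequency < MAF_MIN
MISS_MAX: float = 0.05     # drop SNPs with missing-call rate > MISS_MAX
HWE_MIN: float = 1e-6      # drop SNPs with exact HWE p < HWE_MIN

# Expression filters.
MIN_EXPRESSED_SAMPLES: int = 7   # gene expressed iff TPM > 0 in >= 7 samples
WGCNA_TPM_MIN: float = 0.05      # co-expression prefilter: low-expression cut
WGCNA_MAX_LOW_PER_GROUP: int = 1  # drop gene if > 1 low sample in any group
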