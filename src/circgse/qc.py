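"""SNP quality control: exact Hardy–Weinberg test and sequential filtering.

Filters are applied in a fixed order — missingness, then minor allele
frequency, then HWE — with per-filter removal counts, so the reported counts
are reproducible (the criteria themselves are order-independent only for the
surviving set, not for the per-filter attribution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import defaults
from .io import MarkerPanel

logger = logging.getLogger("circgse")

__all__ = ["hwe_test", "qc_filter", "QcReport"]


def hwe_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact two-sided Hardy–Weinberg equilibrium p-value.

    Enumerates every heterozygote count compatible with the observed allele
    counts (rare-allele copies fix the parity), computes the conditional
    probability of each genotype configuration, and sums the probabilities of
    all configurations no more likely than the observed one.

    Parameters are the three genotype counts (either homozygote first; the
    test is symmetric).  Monomorphic sites have a single attainable
    configuration and return p = 1.
    """
    counts = (n_hom1, n_het, n_hom2)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be >= 0")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het  # copies of the rarer allele
    # het counts share the parity of n_rare and cannot exceed min(n_rare, 2n - n_rare)
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log P(het | allele counts) via the Levene/Haldane conditional distribution
    from scipy.special import gammaln

    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
    )
    logp -= np.max(logp)
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == n_het][0]
    # ties included: configurations as extreme as observed count against HWE
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


@dataclass(frozen=True)
class QcReport:
    n_input: int
    n_removed_missing: int
    n_removed_maf: int
    n_removed_hwe: int
    n_kept: int


def qc_filter(
    panel: MarkerPanel,
    maf_min: float = defaults.MAF_MIN,
    miss_max: float = defaults.MISS_MAX,
    hwe_min: float = defaults.HWE_MIN,
) -> tuple[MarkerPanel, QcReport]:
    """Drop SNPs failing missingness, MAF or exact-HWE thresholds.

    A SNP is removed when its missing-call rate exceeds ``miss_max``, its
    minor allele frequency (over non-missing calls) is below ``maf_min``, or
    its exact HWE p-value is below ``hwe_min``.  Filters run sequentially in
    that order; each SNP is attributed to the first filter it fails.
    """
    if panel.genotypes is None:
        raise ValueError("qc_filter requires genotypes")
    g = panel.genotypes
    n_input = panel.n_snps

    miss_rate = np.isnan(g).mean(axis=0)
    keep = miss_rate <= miss_max
    n_miss = int((~keep).sum())

    with np.errstate(invalid="ignore"):
        freq = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    fail_maf = keep & ~(maf >= maf_min)  # NaN freq (all-missing) also fails
    n_maf = int(fail_maf.sum())
    keep &= ~fail_maf

    n_hwe = 0
    for j in np.flatnonzero(keep):
        col = g[:, j]
        col = col[~np.isnan(col)]
        n0 = int((col == 0).sum())
        n1 = int((col == 1).sum())
        n2 = int((col == 2).sum())
        if hwe_test(n0, n1, n2) < hwe_min:
            keep[j] = False
            n_hwe += 1

    report = QcReport(n_input, n_miss, n_maf, n_hwe, int(keep.sum()))
    if report.n_kept == 0:
        logger.warning("qc_filter: no SNPs survive filtering")
    logger.info(
        "qc_filter: %d SNPs in, removed %d (missingness) + %d (MAF) + %d (HWE), "
        "%d remain",
        n_input, n_miss, n_maf, n_hwe, report.n_kept,
    )
    return panel.subset(keep), report
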