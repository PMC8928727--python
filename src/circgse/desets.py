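"""Expression filtering, BH adjustment and DEG fold-change stratification.

Differentially expressed genes (BH-adjusted p < 0.05) are split by direction
and by |log2 fold change| into eight bins — up/down x (0,1], (1,2], (2,3],
(3, inf) — the stratification used to ask whether stronger expression
responses carry more GWAS signal.  Bins are on the log2 scale with boundary
values falling in the lower bin; both choices are overridable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import defaults
from .io import DETable, GeneSetCollection

logger = logging.getLogger("circgse")

__all__ = [
    "filter_expressed",
    "wgcna_prefilter",
    "bh_adjust",
    "classify_deg_bins",
    "FOLD_BIN_EDGES",
    "FOLD_BIN_LABELS",
]

# |log2FC| bin edges; bin b holds values in (edges[b], edges[b+1]]
FOLD_BIN_EDGES = (0.0, 1.0, 2.0, 3.0, np.inf)
FOLD_BIN_LABELS = ("fold_01", "fold_12", "fold_23", "fold_3x")


def filter_expressed(
    tpm: pd.DataFrame, min_samples: int = defaults.MIN_EXPRESSED_SAMPLES
) -> list[str]:
    """Genes with TPM > 0 in at least ``min_samples`` samples.

    ``tpm`` is genes x samples (gene_id index).
    """
    if tpm.shape[1] < min_samples:
        raise ValueError(
            f"TPM matrix has {tpm.shape[1]} samples, fewer than "
            f"min_samples={min_samples}"
        )
    kept = (tpm > 0).sum(axis=1) >= min_samples
    return list(tpm.index[kept])


def wgcna_prefilter(
    tpm: pd.DataFrame,
    group_labels: dict[str, str] | pd.Series,
    tpm_min: float = defaults.WGCNA_TPM_MIN,
    max_low_per_group: int = defaults.WGCNA_MAX_LOW_PER_GROUP,
) -> list[str]:
    """Drop genes lowly expressed in more than one sample of any one group.

    A sample is "low" when TPM < ``tpm_min`` (strict); a gene is removed when
    any group contains more than ``max_low_per_group`` low samples.
    """
    labels = pd.Series(group_labels)
    missing = [s for s in tpm.columns if s not in labels.index]
    if missing:
        raise ValueError(f"samples without group label: {missing}")
    low = tpm < tpm_min
    drop = pd.Series(False, index=tpm.index)
    for _, samples in labels.groupby(labels):
        cols = [s for s in samples.index if s in tpm.columns]
        drop |= low[cols].sum(axis=1) > max_low_per_group
    return list(tpm.index[~drop])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~((p > 0) & (p <= 1))):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_deg_bins(
    de_table: DETable,
    padj_max: float = defaults.PADJ_MAX,
    edges: tuple = FOLD_BIN_EDGES,
) -> GeneSetCollection:
    """Assign DEGs (padj < ``padj_max``) to direction x |log2FC| bins.

    Returns ten sets: the eight (direction, bin) strata plus the combined
    ``up`` and ``down`` sets.  Genes with log2fc exactly 0 but padj below
    threshold belong to no direction; they are excluded and logged.
    """
    df = de_table.frame
    if "padj" not in df.columns:
        raise ValueError("DE table has no padj column; run bh_adjust first")
    deg = df[df["padj"] < padj_max]
    zero = deg[deg["log2fc"] == 0]
    if len(zero):
        logger.warning(
            "%d DEGs with log2fc == 0 excluded from fold bins: %s",
            len(zero), ", ".join(zero["gene_id"].head(5)),
        )
        deg = deg[deg["log2fc"] != 0]

    sets: dict[str, set[str]] = {
        f"{direction}_{label}": set()
        for direction in ("up", "down")
        for label in FOLD_BIN_LABELS
    }
    sets["up"] = set()
    sets["down"] = set()
    lfc = deg["log2fc"].to_numpy(float)
    direction = np.where(lfc > 0, "up", "down")
    bins = np.searchsorted(edges[1:-1], np.abs(lfc), side="left")
    for gid, d, b in zip(deg["gene_id"], direction, bins):
        sets[f"{d}_{FOLD_BIN_LABELS[b]}"].add(gid)
        sets[d].add(gid)
    return GeneSetCollection(sets)
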