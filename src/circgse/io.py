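"""Readers, writers and the shared in-memory data model.

All pipeline stages exchange five containers defined here:

``GeneAnnotation``
    per-gene genomic intervals, stored 1-based inclusive (GFF3 convention;
    BED's half-open 0-based records are converted at the boundary).
``MarkerPanel``
    genome-ordered SNPs with optional dosage genotypes (0/1/2, NaN missing).
``GwasSummary``
    per-SNP effect estimates (beta, se, p) aligned to the genome order.
``GeneSetCollection``
    named gene sets (DEG bins, co-expression modules, ...).
``DETable``
    per-gene differential-expression results (log2FC, p, BH-adjusted p).

Canonical genome order everywhere is lexicographic by chromosome string then
ascending position; chromosome names are opaque (no "chr" normalisation).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("circgse")

__all__ = [
    "GeneAnnotation",
    "MarkerPanel",
    "GwasSummary",
    "GeneSetCollection",
    "DETable",
    "read_gene_annotation",
    "read_marker_panel",
    "read_gwas_summary",
    "read_gene_sets",
    "read_de_table",
    "read_tpm_matrix",
    "write_gene_annotation",
    "write_marker_panel",
    "write_gwas_summary",
    "write_gene_sets",
    "write_de_table",
    "write_tpm_matrix",
    "write_enrichment_report",
    "read_enrichment_report",
]

MISSING_CODES = {"NA", "-9", "nan", ""}  # accepted missing genotype spellings


class FormatError(ValueError):
    """Malformed input file; message names the offending line/column."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _canonical_site_order(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class GeneAnnotation:
    """Collection of gene intervals, 1-based inclusive, sorted (chrom, start).

    ``frame`` columns: gene_id, chrom, start, end, strand.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame.reset_index(drop=True)
        required = ["gene_id", "chrom", "start", "end"]
        for col in required:
            if col not in df.columns:
                raise FormatError(f"gene annotation missing column {col!r}")
        if "strand" not in df.columns:
            df = df.assign(strand="unknown")
        df = df[["gene_id", "chrom", "start", "end", "strand"]].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["gene_id"] = df["gene_id"].astype(str)
        if len(df):
            if (df["start"] < 1).any():
                raise FormatError("gene start < 1 (coordinates are 1-based)")
            bad = df.index[df["end"] < df["start"]]
            if len(bad):
                raise FormatError(
                    f"gene record {df.loc[bad[0], 'gene_id']!r}: end < start"
                )
            if df["gene_id"].duplicated().any():
                dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
                raise FormatError(f"duplicate gene_id {dup!r}")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        object.__setattr__(self, "frame", df)

    def __len__(self) -> int:
        return len(self.frame)

    def gene_ids(self) -> set[str]:
        return set(self.frame["gene_id"])

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneAnnotation) and self.frame.equals(other.frame)


@dataclass
class MarkerPanel:
    """Genome-ordered SNPs, optionally with a dosage matrix.

    ``sites`` columns: snp_id, chrom, pos, a1, a2 (allele codes; a1 is the
    counted allele).  ``genotypes`` is individuals x SNPs, values in
    {0, 1, 2, NaN}; columns follow ``sites`` order.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self):
        df = self.sites.reset_index(drop=True)
        for col in ("snp_id", "chrom", "pos"):
            if col not in df.columns:
                raise FormatError(f"marker table missing column {col!r}")
        for col in ("a1", "a2"):
            if col not in df.columns:
                df[col] = "?"
        df = df[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["snp_id"] = df["snp_id"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        if df["snp_id"].duplicated().any():
            dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise FormatError(f"duplicate snp_id {dup!r}")
        order = np.lexsort((df["pos"].to_numpy(), df["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(df))):
            logger.warning("marker panel not in genome order; re-sorting")
            df = df.iloc[order].reset_index(drop=True)
            if self.genotypes is not None:
                self.genotypes = np.asarray(self.genotypes)[:, order]
        self.sites = df.reset_index(drop=True)
        if self.genotypes is not None:
            g = np.asarray(self.genotypes, dtype=float)
            if g.ndim != 2 or g.shape[1] != len(df):
                raise FormatError(
                    f"genotype matrix shape {g.shape} does not match "
                    f"{len(df)} markers"
                )
            valid = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
            if not valid.all():
                bad = g[~valid].flat[0]
                raise FormatError(f"genotype code {bad!r} not in {{0,1,2,missing}}")
            self.genotypes = g
            if self.sample_ids is None:
                self.sample_ids = [f"ind{i+1}" for i in range(g.shape[0])]
            elif len(self.sample_ids) != g.shape[0]:
                raise FormatError("sample_ids length does not match genotype rows")

    @property
    def n_snps(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return 0 if self.genotypes is None else self.genotypes.shape[0]

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted (a1) allele per SNP, over non-missing calls."""
        if self.genotypes is None:
            raise ValueError("panel has no genotypes")
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.genotypes, axis=0) / 2.0

    def subset(self, keep: np.ndarray) -> "MarkerPanel":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        g = None if self.genotypes is None else self.genotypes[:, keep]
        return MarkerPanel(
            self.sites.iloc[keep].reset_index(drop=True), g,
            None if self.sample_ids is None else list(self.sample_ids),
        )


@dataclass(frozen=True)
class GwasSummary:
    """Per-SNP association results in canonical genome order.

    ``frame`` columns: snp_id, chrom, pos, beta, and optionally se, p.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame.reset_index(drop=True)
        for col in ("snp_id", "chrom", "pos", "beta"):
            if col not in df.columns:
                raise FormatError(f"GWAS summary missing column {col!r}")
        cols = ["snp_id", "chrom", "pos", "beta"] + [
            c for c in ("se", "p") if c in df.columns
        ]
        df = df[cols].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["snp_id"] = df["snp_id"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        if df["snp_id"].duplicated().any():
            dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise FormatError(f"duplicate snp_id {dup!r} in GWAS summary")
        if "se" in df.columns:
            se = df["se"].to_numpy(float)
            if np.any(se[np.isfinite(se)] <= 0):
                raise FormatError("GWAS summary: se must be > 0 where present")
        if "p" in df.columns:
            p = df["p"].to_numpy(float)
            ok = np.isnan(p) | ((p > 0) & (p <= 1))
            if not ok.all():
                raise FormatError("GWAS summary: p must lie in (0, 1]")
        df = _canonical_site_order(df)
        object.__setattr__(self, "frame", df)

    @property
    def n_snps(self) -> int:
        return len(self.frame)

    @property
    def beta(self) -> np.ndarray:
        return self.frame["beta"].to_numpy(float)

    def __eq__(self, other) -> bool:
        return isinstance(other, GwasSummary) and self.frame.equals(other.frame)


@dataclass(frozen=True)
class GeneSetCollection:
    """Mapping set_name -> frozenset of gene ids; sets may overlap."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "sets", {str(k): frozenset(map(str, v)) for k, v in self.sets.items()}
        )

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def resolve(self, annotation: GeneAnnotation) -> dict[str, list[str]]:
        """Gene ids per set absent from ``annotation`` (the unmapped report)."""
        known = annotation.gene_ids()
        unmapped = {
            name: sorted(g for g in genes if g not in known)
            for name, genes in self.sets.items()
        }
        for name, missing in unmapped.items():
            if missing:
                logger.info(
                    "gene set %s: %d/%d ids not in annotation",
                    name, len(missing), len(self.sets[name]),
                )
        return unmapped


@dataclass(frozen=True)
class DETable:
    """Per-gene DE results: gene_id, log2fc, pvalue, optional padj."""

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame.reset_index(drop=True)
        for col in ("gene_id", "log2fc", "pvalue"):
            if col not in df.columns:
                raise FormatError(f"DE table missing column {col!r}")
        cols = ["gene_id", "log2fc", "pvalue"] + (
            ["padj"] if "padj" in df.columns else []
        )
        df = df[cols].copy()
        df["gene_id"] = df["gene_id"].astype(str)
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise FormatError(f"duplicate gene_id {dup!r} in DE table")
        for col in ("pvalue", "padj"):
            if col in df.columns:
                v = df[col].to_numpy(float)
                ok = np.isnan(v) | ((v > 0) & (v <= 1))
                if not ok.all():
                    raise FormatError(f"DE table: {col} must lie in (0, 1]")
        object.__setattr__(self, "frame", df)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, DETable) and self.frame.equals(other.frame)


# ---------------------------------------------------------------------------
# gene annotation I/O
# ---------------------------------------------------------------------------

_GFF_ID_RE = re.compile(r"(?:^|;)\s*ID=(?:gene:)?([^;]+)")
_GFF_GENEID_RE = re.compile(r"(?:^|;)\s*gene_id[=\s]\"?([^;\"]+)\"?")


def read_gene_annotation(path: str | Path, format: str | None = None) -> GeneAnnotation:
    """Read gene intervals from BED, GFF3 or the internal TSV dialect.

    BED records (0-based, half-open) are converted to 1-based inclusive:
    an interval ``[s, e)`` becomes ``[s + 1, e]``.  From GFF3 only ``gene``
    features are kept.  Format is inferred from the extension unless forced.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".bed": "BED", ".gff": "GFF3", ".gff3": "GFF3"}.get(suffix, "TSV")
    format = format.upper()
    if format == "BED":
        return _read_bed(path)
    if format == "GFF3":
        return _read_gff3(path)
    if format == "TSV":
        df = pd.read_csv(path, sep="\t")
        return GeneAnnotation(df)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_bed(path: Path) -> GeneAnnotation:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start0, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start0:
                raise FormatError(f"{path}:{lineno}: end <= start")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else f"feature{lineno}"
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "unknown"
            rows.append((name, parts[0], start0 + 1, end, strand))
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    )


def _read_gff3(path: Path) -> GeneAnnotation:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 needs 9 columns")
            if parts[2] != "gene":
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end < start:
                raise FormatError(f"{path}:{lineno}: end < start")
            attrs = parts[8]
            m = _GFF_ID_RE.search(attrs) or _GFF_GENEID_RE.search(attrs)
            if m is None:
                raise FormatError(f"{path}:{lineno}: gene feature lacks ID attribute")
            strand = parts[6] if parts[6] in "+-" else "unknown"
            rows.append((m.group(1), parts[0], start, end, strand))
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    )


def write_gene_annotation(
    annotation: GeneAnnotation, path: str | Path, format: str = "TSV"
) -> None:
    path = Path(path)
    format = format.upper()
    if format == "TSV":
        annotation.frame.to_csv(path, sep="\t", index=False)
    elif format == "BED":
        df = annotation.frame
        bed = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"] - 1,  # back to 0-based half-open
                "end": df["end"],
                "name": df["gene_id"],
                "score": 0,
                "strand": df["strand"].replace("unknown", "."),
            }
        )
        bed.to_csv(path, sep="\t", index=False, header=False)
    else:
        raise ValueError(f"unsupported annotation output format {format!r}")


# ---------------------------------------------------------------------------
# marker panel I/O
# ---------------------------------------------------------------------------

def read_marker_panel(prefix_or_path: str | Path, format: str = "tsv") -> MarkerPanel:
    """Read a marker panel from the TSV dialect or PLINK text (.map/.ped).

    TSV dialect: mandatory columns snp_id, chrom, pos, optional a1/a2, then
    one dosage column per individual (0/1/2, NA or -9 missing).  For
    ``plink_text``, ``prefix_or_path`` is the shared prefix of ``.map`` and
    (optionally) ``.ped``; dosages count the minor allele.
    """
    if format == "tsv":
        return _read_panel_tsv(Path(prefix_or_path))
    if format == "plink_text":
        return _read_panel_plink_text(Path(prefix_or_path))
    raise ValueError(f"unknown marker panel format {format!r}")


def _read_panel_tsv(path: Path) -> MarkerPanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp_id": str})
    meta_cols = [c for c in ("snp_id", "chrom", "pos", "a1", "a2") if c in df.columns]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    sites = df[meta_cols]
    genotypes = None
    sample_ids = None
    if sample_cols:
        raw = df[sample_cols].astype(str).apply(lambda s: s.str.strip())
        raw = raw.mask(raw.isin(MISSING_CODES))
        try:
            genotypes = raw.to_numpy(dtype=float).T  # individuals x SNPs
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric genotype code") from exc
        sample_ids = sample_cols
    return MarkerPanel(sites, genotypes, sample_ids)


def _read_panel_plink_text(prefix: Path) -> MarkerPanel:
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    sites = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos"], dtype={"chrom": str, "snp_id": str},
    )[["snp_id", "chrom", "pos"]]
    if not ped_path.exists():
        return MarkerPanel(sites)
    n_snps = len(sites)
    sample_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields, "
                    f"got {len(parts)}"
                )
            sample_ids.append(parts[1])
            allele_rows.append(parts[6:])
    alleles = np.array(allele_rows)  # n_ind x 2*n_snps
    a = alleles[:, 0::2]
    b = alleles[:, 1::2]
    genotypes = np.full((len(sample_ids), n_snps), np.nan)
    a1_codes, a2_codes = [], []
    for j in range(n_snps):
        col = np.concatenate([a[:, j], b[:, j]])
        obs = col[col != "0"]
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) > 2:
            raise FormatError(f"{ped_path}: SNP {sites['snp_id'][j]} has >2 alleles")
        called = (a[:, j] != "0") & (b[:, j] != "0")
        if len(uniq) == 0:
            a1_codes.append("?"); a2_codes.append("?")
            continue
        if len(uniq) == 1:
            # monomorphic: the minor allele is absent, dosage 0 where called
            a1_codes.append("?"); a2_codes.append(uniq[0])
            genotypes[called, j] = 0.0
            continue
        # count the minor allele; lexicographic tie-break for determinism
        order = np.lexsort((uniq, counts))
        minor, major = uniq[order[0]], uniq[order[-1]]
        a1_codes.append(minor)
        a2_codes.append(major)
        genotypes[called, j] = (a[called, j] == minor).astype(int) + (
            b[called, j] == minor
        ).astype(int)
    sites = sites.assign(a1=a1_codes, a2=a2_codes)
    return MarkerPanel(sites, genotypes, sample_ids)


def write_marker_panel(panel: MarkerPanel, path: str | Path) -> None:
    """Write a panel in the TSV dialect (missing dosages as NA)."""
    df = panel.sites.copy()
    if panel.genotypes is not None:
        geno = pd.DataFrame(
            panel.genotypes.T, columns=panel.sample_ids, index=df.index
        )
        geno = geno.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
        df = pd.concat([df, geno], axis=1)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# flat-table I/O
# ---------------------------------------------------------------------------

def read_gwas_summary(path: str | Path) -> GwasSummary:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp_id": str})
    return GwasSummary(df)


def write_gwas_summary(summary: GwasSummary, path: str | Path) -> None:
    summary.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("set_name", "gene_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: gene set file missing column {col!r}")
    sets = {
        name: frozenset(group["gene_id"])
        for name, group in df.groupby("set_name", sort=True)
    }
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    rows = [
        (name, gid)
        for name in sorted(collection.names())
        for gid in sorted(collection[name])
    ]
    pd.DataFrame(rows, columns=["set_name", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_de_table(path: str | Path) -> DETable:
    return DETable(pd.read_csv(path, sep="\t", dtype={"gene_id": str}))


def write_de_table(table: DETable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_tpm_matrix(path: str | Path) -> pd.DataFrame:
    """TPM matrix: gene_id column then one numeric column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: TPM matrix missing column 'gene_id'")
    return df.set_index("gene_id")


def write_tpm_matrix(tpm: pd.DataFrame, path: str | Path) -> None:
    tpm.rename_axis("gene_id").reset_index().to_csv(path, sep="\t", index=False)


REPORT_COLUMNS = [
    "trait", "set_name", "n_genes", "n_genes_mapped",
    "m_g", "t_obs", "n_perm", "p_emp",
]


def write_enrichment_report(results, path: str | Path, header_lines=()) -> None:
    """One row per (trait, set): T_sum, SNP count m_g, permutations, empirical p.

    ``results`` is an iterable of objects exposing the REPORT_COLUMNS as
    attributes (see enrich.EnrichmentResult); ``header_lines`` are provenance
    comments written as leading '#' lines.
    """
    rows = [[getattr(r, c) for c in REPORT_COLUMNS] for r in results]
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_enrichment_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
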