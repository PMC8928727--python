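"""Synthetic genotype/phenotype/expression data with planted ground truth.

Every generator is a pure function of its inputs and a seed, and each returns
a truth record sufficient to check the downstream stage without
re-simulation: drawn allele frequencies, causal effect vectors and realized
variance components, DEG bin labels.

The genetic model is deliberately simple but exercises everything the
pipeline relies on: diploid dosages built from two haplotypes whose adjacent
alleles follow a first-order Markov copy process (adjacent-SNP allelic
correlation ~ ``ld_rho``, reset at chromosome boundaries), and phenotypes

    y = X_c beta_c + X beta_poly + e

in which causal SNPs are confined to one designated gene set (+/- 5 kb) and
the realized variance fractions are rescaled to hit ``h2_set`` and
``h2_polygenic`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import defaults
from .io import DETable, GeneAnnotation, GeneSetCollection, MarkerPanel

__all__ = [
    "SimulationConfig",
    "simulate_landscape",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_de_table",
    "simulate_tpm_matrix",
    "random_gene_sets",
    "simulate_dataset",
    "PhenotypeTruth",
    "SimulatedDataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Desk-scale stand-in for a cattle GWAS cohort with planted enrichment."""

    n_individuals: int = 500
    n_snps: int = 2000
    n_genes: int = 150
    chrom_lengths: tuple[int, ...] = (1_500_000, 1_500_000)
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.3
    causal_set_name: str = "causal"
    h2_set: float = 0.0
    h2_polygenic: float = 0.3
    missing_rate: float = 0.0
    gene_length: int = 2_000
    min_gene_gap: int = 12_000
    genes_per_set: int = 15
    n_decoy_sets: int = 4
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0, 1)")
        for name in ("h2_set", "h2_polygenic"):
            if not (0 <= getattr(self, name) < 1):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.h2_set + self.h2_polygenic >= 1:
            raise ValueError("h2_set + h2_polygenic must be < 1")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("chrom_lengths", "maf_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def simulate_landscape(config: SimulationConfig) -> tuple[GeneAnnotation, MarkerPanel]:
    """Place non-overlapping genes and uniform SNP positions on chromosomes.

    Genes occupy randomly chosen slots of width gene_length + min_gene_gap,
    guaranteeing at least min_gene_gap/2 bp between neighbouring genes, so
    5-kb flank windows of distinct genes never merge with the defaults.
    Raises when the chromosomes cannot hold ``n_genes`` such slots.
    """
    rng = np.random.default_rng(config.seed)
    slot = config.gene_length + config.min_gene_gap
    chrom_names = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    slots = [
        (c, s)
        for c, length in zip(chrom_names, config.chrom_lengths)
        for s in range(length // slot)
    ]
    if config.n_genes > len(slots):
        raise ValueError(
            f"cannot place {config.n_genes} genes with >= {config.min_gene_gap} bp "
            f"spacing on chromosomes of lengths {config.chrom_lengths}"
        )
    chosen = rng.choice(len(slots), size=config.n_genes, replace=False)
    jitter = rng.integers(0, max(config.min_gene_gap // 2, 1), size=config.n_genes)
    genes = []
    for g, (slot_idx, off) in enumerate(zip(chosen, jitter)):
        chrom, s = slots[slot_idx]
        start = s * slot + 1 + int(off)
        genes.append((f"g{g:04d}", chrom, start, start + config.gene_length - 1))
    annotation = GeneAnnotation(
        pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end"])
    )
    # rename in genomic order so ids are stable across identical configs
    frame = annotation.frame.copy()
    frame["gene_id"] = [f"g{i:04d}" for i in range(len(frame))]
    annotation = GeneAnnotation(frame)

    total = sum(config.chrom_lengths)
    per_chrom = rng.multinomial(
        config.n_snps, np.asarray(config.chrom_lengths) / total
    )
    rows = []
    for chrom, length, n in zip(chrom_names, config.chrom_lengths, per_chrom):
        pos = np.sort(rng.choice(length, size=n, replace=False)) + 1
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    sites = pd.concat(rows, ignore_index=True)
    sites.insert(0, "snp_id", [f"snp{i:06d}" for i in range(len(sites))])
    return annotation, MarkerPanel(sites)


def simulate_genotypes(
    panel: MarkerPanel, config: SimulationConfig
) -> tuple[MarkerPanel, np.ndarray]:
    """Draw diploid dosages for every site of ``panel``.

    Per-SNP allele frequency ~ Uniform(maf_range); each of the two haplotypes
    per individual is a Markov chain along the genome: allele j copies allele
    j-1 with probability ``ld_rho`` (zero across chromosome boundaries),
    otherwise is a fresh Bernoulli(freq_j) draw.  Returns the genotyped panel
    and the drawn frequencies (the truth record for MAF checks).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    m = panel.n_snps
    n = config.n_individuals
    freq = rng.uniform(*config.maf_range, size=m)
    chroms = panel.sites["chrom"].to_numpy()
    new_chrom = np.empty(m, dtype=bool)
    new_chrom[0] = True
    new_chrom[1:] = chroms[1:] != chroms[:-1]

    # first-order Markov chain with exact marginals: conditional carrier
    # probabilities chosen so P(h_j = 1) = freq_j while corr(h_{j-1}, h_j)
    # ~ ld_rho (clipped to [0, 1] where the frequencies differ too much)
    rho = config.ld_rho
    p_prev, p_cur = freq[:-1], freq[1:]
    shift = rho * np.sqrt(p_cur * (1 - p_cur))
    a = np.clip(p_cur + shift * np.sqrt((1 - p_prev) / p_prev), 0.0, 1.0)
    b = np.clip(p_cur - shift * np.sqrt(p_prev / (1 - p_prev)), 0.0, 1.0)

    hap = np.empty((2 * n, m), dtype=np.int8)
    draw = rng.random((2 * n, m))
    hap[:, 0] = draw[:, 0] < freq[0]
    for j in range(1, m):
        if rho > 0 and not new_chrom[j]:
            thresh = np.where(hap[:, j - 1] == 1, a[j - 1], b[j - 1])
            hap[:, j] = draw[:, j] < thresh
        else:
            hap[:, j] = draw[:, j] < freq[j]
    dosage = (hap[0::2] + hap[1::2]).astype(float)
    if config.missing_rate > 0:
        dosage[rng.random(dosage.shape) < config.missing_rate] = np.nan
    sites = panel.sites.assign(a1="A", a2="B")
    out = MarkerPanel(sites, dosage, [f"ind{i + 1}" for i in range(n)])
    return out, freq


@dataclass(frozen=True)
class PhenotypeTruth:
    """Planted genetic architecture behind one simulated phenotype."""

    causal_beta: np.ndarray      # per-SNP causal effects (0 outside the set)
    causal_mask: np.ndarray      # SNPs eligible for causal effects
    polygenic_beta: np.ndarray
    g_set: np.ndarray            # realized set-genetic values (var = h2_set)
    g_polygenic: np.ndarray
    residual: np.ndarray
    h2_set: float
    h2_polygenic: float

    @property
    def genetic_value(self) -> np.ndarray:
        return self.g_set + self.g_polygenic


def simulate_phenotype(
    panel: MarkerPanel,
    annotation: GeneAnnotation,
    gene_sets: GeneSetCollection,
    config: SimulationConfig,
) -> tuple[np.ndarray, PhenotypeTruth]:
    """Phenotype with set-confined causal effects plus polygenic background.

    Causal effects are drawn only for SNPs inside the ``causal_set_name``
    genes or their 5-kb flanks; each realized component is rescaled so the
    variance fractions equal ``h2_set`` and ``h2_polygenic`` exactly and the
    total variance is 1.
    """
    from .enrich import map_snps_to_set

    if panel.genotypes is None:
        raise ValueError("simulate_phenotype requires genotypes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n, m = panel.genotypes.shape
    g = panel.genotypes
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(g, axis=0)
    x = np.where(np.isnan(g), col_mean, g) - col_mean

    causal_beta = np.zeros(m)
    g_set = np.zeros(n)
    causal_mask = np.zeros(m, dtype=bool)
    if config.h2_set > 0:
        if config.causal_set_name not in gene_sets:
            raise ValueError(
                f"causal set {config.causal_set_name!r} not in gene_sets"
            )
        mask = map_snps_to_set(
            _sites_as_summary(panel), annotation,
            gene_sets[config.causal_set_name], flank=defaults.FLANK_BP,
            set_name=config.causal_set_name,
        )
        causal_mask = mask.mask
        if mask.m_g == 0:
            raise ValueError(
                f"causal set {config.causal_set_name!r} has no mapped SNPs"
            )
        causal_beta[causal_mask] = rng.normal(size=mask.m_g)
        g_set = x @ causal_beta
        g_set, f = _scale_to_var(g_set, config.h2_set)
        causal_beta *= f

    polygenic_beta = rng.normal(size=m)
    g_poly = x @ polygenic_beta
    if config.h2_polygenic > 0:
        g_poly, f = _scale_to_var(g_poly, config.h2_polygenic)
        polygenic_beta *= f
    else:
        g_poly = np.zeros(n)
        polygenic_beta[:] = 0.0

    e = rng.normal(size=n)
    e, _ = _scale_to_var(e, 1.0 - config.h2_set - config.h2_polygenic)
    y = g_set + g_poly + e
    truth = PhenotypeTruth(
        causal_beta=causal_beta, causal_mask=causal_mask,
        polygenic_beta=polygenic_beta, g_set=g_set, g_polygenic=g_poly,
        residual=e, h2_set=config.h2_set, h2_polygenic=config.h2_polygenic,
    )
    return y, truth


def _scale_to_var(v: np.ndarray, target: float) -> tuple[np.ndarray, float]:
    current = float(np.var(v))
    if current <= 0:
        raise ValueError("cannot rescale a zero-variance component")
    f = float(np.sqrt(target / current))
    return v * f, f


def _sites_as_summary(panel: MarkerPanel):
    from .io import GwasSummary

    df = panel.sites[["snp_id", "chrom", "pos"]].assign(beta=0.0)
    return GwasSummary(df)


DE_BIN_LABELS = tuple(
    f"{d}_{b}" for d in ("up", "down")
    for b in ("fold_01", "fold_12", "fold_23", "fold_3x")
)


def simulate_de_table(
    config: SimulationConfig, bin_fractions: dict[str, float]
) -> tuple[DETable, dict[str, str]]:
    """DE table with planted fold-change bin labels.

    ``bin_fractions`` maps the eight up/down fold bins (and optionally
    "null") to gene fractions; including "null" the fractions must sum to 1
    (+/- 1e-9), otherwise the remainder is the null fraction.  DE genes get
    padj < 0.05 and a |log2FC| uniform within their bin ((3, 5] for fold_3x);
    null genes get padj >= 0.05.  Returns the table and gene -> label truth.
    """
    unknown = set(bin_fractions) - set(DE_BIN_LABELS) - {"null"}
    if unknown:
        raise ValueError(f"unknown bin labels: {sorted(unknown)}")
    frac = {label: float(bin_fractions.get(label, 0.0)) for label in DE_BIN_LABELS}
    if any(v < 0 for v in frac.values()):
        raise ValueError("bin fractions must be >= 0")
    de_total = sum(frac.values())
    if "null" in bin_fractions:
        total = de_total + float(bin_fractions["null"])
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"bin fractions sum to {total}, expected 1")
    elif de_total > 1 + 1e-9:
        raise ValueError(f"bin fractions sum to {de_total} > 1")
    frac["null"] = 1.0 - de_total

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    labels_all = DE_BIN_LABELS + ("null",)
    probs = np.array([frac[label] for label in labels_all])
    assignment = rng.choice(len(labels_all), size=config.n_genes, p=probs)

    edges = {"fold_01": (0.0, 1.0), "fold_12": (1.0, 2.0),
             "fold_23": (2.0, 3.0), "fold_3x": (3.0, 5.0)}
    rows = []
    truth = {}
    for i, k in enumerate(assignment):
        gid = f"g{i:04d}"
        label = labels_all[k]
        truth[gid] = label
        if label == "null":
            lfc = rng.normal(scale=0.5)
            padj = rng.uniform(0.05, 1.0)
        else:
            direction, bin_label = label.split("_", 1)
            lo, hi = edges[bin_label]
            mag = rng.uniform(lo, hi)
            if mag <= lo:  # uniform draws the open lower edge w.p. 0; be safe
                mag = np.nextafter(lo, hi)
            lfc = mag if direction == "up" else -mag
            padj = rng.uniform(1e-4, 0.05 * (1 - 1e-9))
        pvalue = padj * rng.uniform(0.3, 1.0)
        rows.append((gid, lfc, max(pvalue, 1e-300), padj))
    table = DETable(pd.DataFrame(rows, columns=["gene_id", "log2fc", "pvalue", "padj"]))
    return table, truth


def simulate_tpm_matrix(
    n_genes: int,
    sample_groups: dict[str, str],
    seed: int = 0,
    dropout: float = 0.15,
) -> pd.DataFrame:
    """Log-normal TPM matrix (genes x samples) with random dropout zeros."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    samples = list(sample_groups)
    tpm = np.exp(rng.normal(loc=1.0, scale=1.5, size=(n_genes, len(samples))))
    tpm[rng.random(tpm.shape) < dropout] = 0.0
    return pd.DataFrame(
        tpm, index=[f"g{i:04d}" for i in range(n_genes)], columns=samples
    ).rename_axis("gene_id")


def random_gene_sets(
    annotation: GeneAnnotation,
    n_sets: int,
    genes_per_set: int,
    seed: int = 0,
    names: list[str] | None = None,
) -> GeneSetCollection:
    """Disjoint random gene sets drawn without replacement from the annotation."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    ids = annotation.frame["gene_id"].to_numpy()
    need = n_sets * genes_per_set
    if need > ids.size:
        raise ValueError(f"need {need} genes but annotation has {ids.size}")
    chosen = rng.choice(ids.size, size=need, replace=False)
    if names is None:
        names = [f"set{k}" for k in range(n_sets)]
    sets = {
        names[k]: frozenset(ids[chosen[k * genes_per_set:(k + 1) * genes_per_set]])
        for k in range(n_sets)
    }
    return GeneSetCollection(sets)


@dataclass(frozen=True)
class SimulatedDataset:
    """One complete synthetic study: landscape, genotypes, sets, phenotype."""

    config: SimulationConfig
    annotation: GeneAnnotation
    panel: MarkerPanel
    gene_sets: GeneSetCollection
    y: np.ndarray
    truth: PhenotypeTruth
    snp_freq: np.ndarray = field(repr=False, default=None)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Landscape + genotypes + gene sets (causal first) + phenotype."""
    annotation, sites = simulate_landscape(config)
    panel, freq = simulate_genotypes(sites, config)
    names = [config.causal_set_name] + [
        f"decoy{k}" for k in range(config.n_decoy_sets)
    ]
    gene_sets = random_gene_sets(
        annotation, len(names), config.genes_per_set, seed=config.seed, names=names
    )
    y, truth = simulate_phenotype(panel, annotation, gene_sets, config)
    return SimulatedDataset(config, annotation, panel, gene_sets, y, truth, freq)
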