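import numpy as np
import pandas as pd
import pytest

from circgse.io import GeneAnnotation, GeneSetCollection, GwasSummary, MarkerPanel


@pytest.fixture
def toy_annotation():
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["geneA", "geneB", "geneC"],
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [10_000, 50_000, 20_000],
                "end": [12_000, 52_000, 25_000],
                "strand": ["+", "-", "unknown"],
            }
        )
    )


@pytest.fixture
def toy_gwas():
    """Ten SNPs on two chromosomes with fixed betas."""
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(10)],
            "chrom": ["chr1"] * 6 + ["chr2"] * 4,
            "pos": [4_999, 5_000, 11_000, 17_000, 17_001, 60_000,
                    1_000, 19_000, 22_000, 31_000],
            "beta": rng.normal(size=10),
            "se": np.full(10, 0.1),
            "p": rng.uniform(0.01, 1.0, size=10),
        }
    )
    return GwasSummary(df)


@pytest.fixture
def toy_panel():
    """Four individuals, three clean SNPs (one with a missing call)."""
    sites = pd.DataFrame(
        {
            "snp_id": ["a", "b", "c"],
            "chrom": ["chr1", "chr1", "chr2"],
            "pos": [100, 200, 50],
        }
    )
    geno = np.array(
        [
            [0.0, 1.0, 2.0],
            [1.0, np.nan, 0.0],
            [2.0, 1.0, 1.0],
            [1.0, 0.0, 1.0],
        ]
    )
    return MarkerPanel(sites, geno, ["i1", "i2", "i3", "i4"])


@pytest.fixture
def toy_sets():
    return GeneSetCollection(
        {"one": {"geneA"}, "two": {"geneA", "geneC"}, "ghost": {"geneA", "nope"}}
    )
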