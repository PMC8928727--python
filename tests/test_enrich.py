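"""SNP-to-set mapping, T_sum, the rotation null and its invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from circgse.enrich import (
    SetEnrichment,
    circular_null,
    empirical_p,
    map_snps_to_set,
    rotation_tsum_all,
    run_enrichment,
    t_sum,
)
from circgse.io import GeneAnnotation, GeneSetCollection, GwasSummary


def _summary(beta, pos=None, chrom=None):
    beta = np.asarray(beta, float)
    n = beta.size
    return GwasSummary(
        pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(n)],
                "chrom": chrom if chrom is not None else ["1"] * n,
                "pos": pos if pos is not None else np.arange(1, n + 1) * 10,
                "beta": beta,
            }
        )
    )


class TestMapSnpsToSet:
    def test_flank_window_arithmetic(self, toy_annotation):
        """geneA spans [10000, 12000]; with 5-kb flanks, 5000 is the first
        covered position and 4999 is outside."""
        gwas = _summary(
            np.ones(4), pos=[4_999, 5_000, 17_000, 17_001],
            chrom=["chr1"] * 4,
        )
        mask = map_snps_to_set(gwas, toy_annotation, {"geneA"})
        assert list(mask.mask) == [False, True, True, False]
        assert mask.m_g == 2

    def test_zero_flank_includes_gene_ends(self, toy_annotation):
        gwas = _summary(
            np.ones(3), pos=[9_999, 10_000, 12_000], chrom=["chr1"] * 3
        )
        mask = map_snps_to_set(gwas, toy_annotation, {"geneA"}, flank=0)
        assert list(mask.mask) == [False, True, True]

    def test_overlapping_genes_flag_once(self):
        annotation = GeneAnnotation(
            pd.DataFrame(
                {
                    "gene_id": ["g1", "g2"],
                    "chrom": ["1", "1"],
                    "start": [100, 150],
                    "end": [200, 250],
                }
            )
        )
        gwas = _summary(np.ones(1), pos=[175], chrom=["1"])
        mask = map_snps_to_set(gwas, annotation, {"g1", "g2"}, flank=0)
        assert mask.m_g == 1

    def test_window_clipped_at_position_one(self, toy_annotation):
        gwas = _summary(np.ones(1), pos=[1], chrom=["chr2"])
        mask = map_snps_to_set(gwas, toy_annotation, {"geneC"}, flank=50_000)
        assert mask.m_g == 1

    def test_unresolvable_set_errors(self, toy_annotation, toy_gwas):
        with pytest.raises(ValueError, match="no resolvable"):
            map_snps_to_set(toy_gwas, toy_annotation, {"nothing"})

    def test_unmapped_ids_recorded(self, toy_annotation, toy_gwas):
        mask = map_snps_to_set(toy_gwas, toy_annotation, {"geneA", "ghostly"})
        assert mask.unmapped == ("ghostly",)
        assert mask.n_genes == 2 and mask.n_genes_mapped == 1

    def test_membership_respects_chromosome(self, toy_annotation):
        gwas = _summary(np.ones(2), pos=[11_000, 11_000], chrom=["chr1", "chr2"])
        mask = map_snps_to_set(gwas, toy_annotation, {"geneA"})
        assert list(mask.mask) == [True, False]


class TestTsum:
    def test_sum_of_squares(self):
        gwas = _summary([0.5, -0.5, 1.0])
        assert t_sum(gwas, np.array([True, True, True])) == pytest.approx(1.5)
        assert t_sum(gwas, np.array([True, True, False])) == pytest.approx(0.5)

    def test_empty_mask_is_zero(self):
        gwas = _summary([0.5, -0.5, 1.0])
        assert t_sum(gwas, np.zeros(3, dtype=bool)) == 0.0

    def test_non_finite_flagged_beta_errors(self):
        gwas = _summary([0.5, np.nan, 1.0])
        with pytest.raises(ValueError, match="non-finite"):
            t_sum(gwas, np.array([True, True, False]))


class TestRotationNull:
    def test_four_snp_worked_example_support(self):
        """beta = (1,2,3,4), mask (1,1,0,0): the three non-identity rotations
        give T_sum in {13, 25, 17} exactly."""
        gwas = _summary([1.0, 2.0, 3.0, 4.0])
        mask = np.array([True, True, False, False])
        t_all = rotation_tsum_all(gwas.beta, mask)
        np.testing.assert_allclose(t_all, [5.0, 13.0, 25.0, 17.0])
        perm = circular_null(gwas, mask, n_perm=500, seed=1)
        assert set(np.round(perm, 9)) <= {13.0, 25.0, 17.0}

    def test_matches_numpy_roll_brute_force(self):
        rng = np.random.default_rng(2)
        beta = rng.normal(size=37)
        mask = rng.random(37) < 0.3
        t_all = rotation_tsum_all(beta, mask)
        brute = [np.sum(beta[np.roll(mask, k)] ** 2) for k in range(37)]
        np.testing.assert_allclose(t_all, brute, rtol=1e-10)

    def test_fft_path_agrees_with_direct_path(self):
        rng = np.random.default_rng(3)
        n = 3000
        beta = rng.normal(size=n)
        mask = rng.random(n) < 0.5  # n * m_g above the direct-path cutoff
        t_all = rotation_tsum_all(beta, mask)
        s = beta**2
        for k in (0, 1, n // 2, n - 1):
            assert t_all[k] == pytest.approx(np.sum(s[np.roll(mask, k)]), rel=1e-9)

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_rotation_mean_identity(self, data):
        """Mean of T_sum over all n rotations equals (m_g/n) * sum(beta^2)."""
        n = data.draw(st.integers(min_value=2, max_value=40))
        beta = np.array(
            data.draw(
                st.lists(
                    st.floats(-5, 5, allow_nan=False), min_size=n, max_size=n
                )
            )
        )
        mask = np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
        t_all = rotation_tsum_all(beta, mask)
        expected = mask.sum() / n * np.sum(beta**2)
        assert t_all.mean() == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_sampled_null_converges_to_uniform_rotations(self):
        """n_snps <= 12: sampled offsets are uniform over the n-1 rotations
        (chi-square goodness of fit, alpha = 0.01)."""
        rng = np.random.default_rng(4)
        beta = rng.normal(size=11)
        gwas = _summary(beta)
        mask = np.zeros(11, dtype=bool)
        mask[[0, 3, 4]] = True
        t_all = rotation_tsum_all(beta, mask)
        perm = circular_null(gwas, mask, n_perm=20_000, seed=9)
        counts = [np.sum(np.isclose(perm, t_all[k])) for k in range(1, 11)]
        assert sum(counts) == 20_000
        assert stats.chisquare(counts).pvalue > 0.01

    def test_rotation_preserves_set_size(self):
        rng = np.random.default_rng(5)
        mask = rng.random(50) < 0.2
        for k in range(50):
            assert np.roll(mask, k).sum() == mask.sum()

    def test_too_few_snps_errors(self):
        gwas = _summary([1.0])
        with pytest.raises(ValueError, match=">= 2 SNPs"):
            circular_null(gwas, np.array([True]), n_perm=10, seed=0)

    def test_per_chromosome_rotation_preserves_total(self):
        rng = np.random.default_rng(6)
        beta = rng.normal(size=40)
        chrom = ["1"] * 25 + ["2"] * 15
        gwas = _summary(beta, pos=list(range(1, 26)) + list(range(1, 16)),
                        chrom=chrom)
        mask = rng.random(40) < 0.3
        perm = circular_null(gwas, mask, n_perm=200, seed=3, per_chromosome=True)
        assert perm.shape == (200,) and (perm >= 0).all()


class TestEmpiricalP:
    def test_observed_above_all_nine(self):
        assert empirical_p(10.0, np.arange(9.0)) == pytest.approx(0.1)

    def test_observed_below_all(self):
        assert empirical_p(-1.0, np.arange(9.0)) == pytest.approx(1.0)

    def test_tie_counts_against_significance(self):
        perm = np.concatenate([[5.0], np.zeros(18)])
        assert empirical_p(5.0, perm) == pytest.approx(2 / 20)

    def test_empty_perm_errors(self):
        with pytest.raises(ValueError):
            empirical_p(1.0, np.array([]))

    @given(
        st.floats(-10, 10, allow_nan=False),
        st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=200),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_away_from_zero(self, t_obs, perm):
        p = empirical_p(t_obs, np.array(perm))
        assert 1 / (len(perm) + 1) <= p <= 1.0


class TestNullBehaviour:
    def test_scaling_flagged_betas_never_raises_p(self):
        """Multiplying flagged betas by c > 1 (others fixed) cannot increase
        the empirical p under matched rotation draws."""
        rng = np.random.default_rng(7)
        n = 200
        beta = rng.normal(size=n)
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, 20, replace=False)] = True
        for c in (1.5, 3.0, 10.0):
            scaled = np.where(mask, c * beta, beta)
            g0, g1 = _summary(beta), _summary(scaled)
            p0 = empirical_p(
                t_sum(g0, mask), circular_null(g0, mask, 500, seed=11)
            )
            p1 = empirical_p(
                t_sum(g1, mask), circular_null(g1, mask, 500, seed=11)
            )
            assert p1 <= p0

    def test_p_uniform_when_membership_is_an_independent_rotation(self):
        """True-null construction: rotate the mask by a random offset, test
        against the exhaustive rotation distribution; over 1000 replicates
        the empirical p is uniform (KS, alpha = 0.01)."""
        rng = np.random.default_rng(8)
        n = 500
        beta = rng.normal(size=n)
        base = np.zeros(n, dtype=bool)
        base[rng.choice(n, 40, replace=False)] = True
        t_all = rotation_tsum_all(beta, base)
        pvals = []
        for _ in range(1000):
            k = rng.integers(0, n)
            others = t_all[(k + np.arange(1, n)) % n]
            pvals.append(empirical_p(t_all[k], others))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestRunEnrichment:
    def test_results_deterministic_and_order_free(
        self, toy_annotation, toy_gwas, toy_sets, tmp_path
    ):
        model = SetEnrichment(toy_gwas, toy_annotation, toy_sets)
        r1 = model.fit(n_perm=99, seed=5)
        r2 = model.fit(n_perm=99, seed=5)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        r1.save(p1)
        r2.save(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_one_result_per_trait_set_pair(
        self, toy_annotation, toy_gwas, toy_sets
    ):
        results = run_enrichment(
            {"cw": toy_gwas, "ms": toy_gwas}, toy_annotation, toy_sets,
            n_perm=50, seed=1,
        )
        assert len(results) == 2 * len(toy_sets)
        for r in results:
            assert r.n_perm == 50
            assert 1 / 51 <= r.p_emp <= 1.0
            assert r.perm_stats.size == 50

    def test_misaligned_traits_rejected(self, toy_annotation, toy_gwas, toy_sets):
        other = GwasSummary(toy_gwas.frame.iloc[:-1])
        with pytest.raises(ValueError, match="aligned"):
            run_enrichment(
                {"a": toy_gwas, "b": other}, toy_annotation, toy_sets,
                n_perm=10, seed=0,
            )

    def test_summary_text_mentions_key_fields(
        self, toy_annotation, toy_gwas, toy_sets
    ):
        fitted = SetEnrichment(toy_gwas, toy_annotation, toy_sets).fit(
            n_perm=50, seed=2
        )
        text = fitted.summary()
        assert "T_sum" in text and "p_emp" in text and "flank" in text
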