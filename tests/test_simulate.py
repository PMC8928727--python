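"""Synthetic-data generators: determinism, planted structure, stated errors."""

import numpy as np
import pandas as pd
import pytest

from circgse.io import GeneSetCollection
from circgse.simulate import (
    SimulationConfig,
    random_gene_sets,
    simulate_dataset,
    simulate_de_table,
    simulate_genotypes,
    simulate_landscape,
    simulate_phenotype,
    simulate_tpm_matrix,
)


class TestConfig:
    def test_heritabilities_must_sum_below_one(self):
        with pytest.raises(ValueError, match="h2"):
            SimulationConfig(h2_set=0.6, h2_polygenic=0.5)

    def test_maf_range_must_be_in_unit_half(self):
        with pytest.raises(ValueError, match="maf_range"):
            SimulationConfig(maf_range=(0.0, 0.6))

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text(
            "n_individuals: 50\nn_snps: 100\nmaf_range: [0.1, 0.4]\nseed: 3\n"
        )
        conf = SimulationConfig.from_yaml(path)
        assert conf.n_individuals == 50 and conf.maf_range == (0.1, 0.4)


class TestLandscape:
    def test_deterministic_given_seed(self):
        conf = SimulationConfig(seed=5)
        a1, p1 = simulate_landscape(conf)
        a2, p2 = simulate_landscape(conf)
        assert a1 == a2
        assert p1.sites.equals(p2.sites)

    def test_no_genes_still_places_snps(self):
        conf = SimulationConfig(n_genes=0, seed=1)
        annotation, panel = simulate_landscape(conf)
        assert len(annotation) == 0 and panel.n_snps == conf.n_snps

    def test_infeasible_packing_errors(self):
        conf = SimulationConfig(n_genes=50, chrom_lengths=(100_000,))
        with pytest.raises(ValueError, match="cannot place"):
            simulate_landscape(conf)

    def test_genes_do_not_overlap_and_keep_spacing(self):
        conf = SimulationConfig(seed=8)
        annotation, _ = simulate_landscape(conf)
        for _, group in annotation.frame.groupby("chrom"):
            starts = group["start"].to_numpy()
            ends = group["end"].to_numpy()
            assert (starts[1:] > ends[:-1] + conf.min_gene_gap // 2).all()


class TestGenotypes:
    def test_deterministic_given_seed(self):
        conf = SimulationConfig(n_individuals=50, n_snps=100, seed=4)
        _, sites = simulate_landscape(conf)
        p1, f1 = simulate_genotypes(sites, conf)
        p2, f2 = simulate_genotypes(sites, conf)
        np.testing.assert_array_equal(p1.genotypes, p2.genotypes)
        np.testing.assert_array_equal(f1, f2)

    def test_unlinked_snps_have_near_zero_adjacent_correlation(self):
        conf = SimulationConfig(
            n_individuals=2000, n_snps=200, ld_rho=0.0, seed=6
        )
        _, sites = simulate_landscape(conf)
        panel, _ = simulate_genotypes(sites, conf)
        g = panel.genotypes
        r = [
            np.corrcoef(g[:, j], g[:, j + 1])[0, 1]
            for j in range(g.shape[1] - 1)
        ]
        assert np.max(np.abs(r)) < 0.1

    def test_linked_snps_track_requested_correlation(self):
        conf = SimulationConfig(
            n_individuals=2000, n_snps=200, ld_rho=0.6, seed=6
        )
        _, sites = simulate_landscape(conf)
        panel, _ = simulate_genotypes(sites, conf)
        g = panel.genotypes
        chroms = panel.sites["chrom"].to_numpy()
        r = [
            np.corrcoef(g[:, j], g[:, j + 1])[0, 1]
            for j in range(g.shape[1] - 1)
            if chroms[j] == chroms[j + 1]
        ]
        assert np.mean(r) == pytest.approx(0.6, abs=0.1)

    def test_empirical_maf_tracks_drawn_frequency(self):
        conf = SimulationConfig(n_individuals=2000, n_snps=300, seed=7)
        _, sites = simulate_landscape(conf)
        panel, freq = simulate_genotypes(sites, conf)
        assert np.max(np.abs(panel.allele_freq() - freq)) < 0.05

    def test_missing_rate_applied(self):
        conf = SimulationConfig(
            n_individuals=200, n_snps=100, missing_rate=0.1, seed=9
        )
        _, sites = simulate_landscape(conf)
        panel, _ = simulate_genotypes(sites, conf)
        assert np.isnan(panel.genotypes).mean() == pytest.approx(0.1, abs=0.02)


class TestPhenotype:
    def _dataset(self, **kw):
        conf = SimulationConfig(
            n_individuals=1000, n_snps=1000, n_genes=100, seed=10, **kw
        )
        return conf, simulate_dataset(conf)

    def test_deterministic_given_seed(self):
        conf, data = self._dataset(h2_set=0.3)
        data2 = simulate_dataset(conf)
        np.testing.assert_array_equal(data.y, data2.y)

    def test_variance_fractions_exact(self):
        _, data = self._dataset(h2_set=0.3, h2_polygenic=0.2)
        assert np.var(data.truth.g_set) == pytest.approx(0.3, rel=1e-9)
        assert np.var(data.truth.g_polygenic) == pytest.approx(0.2, rel=1e-9)
        assert np.var(data.y) == pytest.approx(1.0, abs=0.1)

    def test_regression_on_true_genetic_value_has_unit_slope(self):
        _, data = self._dataset(h2_set=0.3, h2_polygenic=0.2)
        g = data.truth.genetic_value
        slope = np.cov(data.y, g)[0, 1] / np.var(g, ddof=1)
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_null_set_has_no_causal_effects(self):
        _, data = self._dataset(h2_set=0.0)
        assert not data.truth.causal_mask.any()
        assert np.all(data.truth.causal_beta == 0)

    def test_causal_set_without_mapped_snps_errors(self):
        conf = SimulationConfig(n_individuals=50, n_snps=50, h2_set=0.3, seed=2)
        annotation, sites = simulate_landscape(conf)
        panel, _ = simulate_genotypes(sites, conf)
        ghost = GeneSetCollection({"causal": {"not-a-gene"}})
        with pytest.raises(ValueError, match="no resolvable|no mapped"):
            simulate_phenotype(panel, annotation, ghost, conf)


class TestDeTable:
    def test_fractions_must_sum_to_one_with_null(self):
        conf = SimulationConfig(n_genes=10)
        with pytest.raises(ValueError, match="sum"):
            simulate_de_table(conf, {"up_fold_01": 0.5, "null": 0.6})

    def test_all_null_yields_no_degs(self):
        conf = SimulationConfig(n_genes=50, seed=1)
        table, truth = simulate_de_table(conf, {"null": 1.0})
        assert (table.frame["padj"] >= 0.05).all()
        assert set(truth.values()) == {"null"}

    def test_deterministic_given_seed(self):
        conf = SimulationConfig(n_genes=100, seed=12)
        t1, l1 = simulate_de_table(conf, {"up_fold_01": 0.3})
        t2, l2 = simulate_de_table(conf, {"up_fold_01": 0.3})
        assert t1 == t2 and l1 == l2

    def test_unknown_bin_label_rejected(self):
        conf = SimulationConfig(n_genes=10)
        with pytest.raises(ValueError, match="unknown bin"):
            simulate_de_table(conf, {"sideways_fold_01": 1.0})


class TestHelpers:
    def test_random_gene_sets_are_disjoint(self):
        conf = SimulationConfig(seed=3)
        annotation, _ = simulate_landscape(conf)
        sets = random_gene_sets(annotation, n_sets=4, genes_per_set=10, seed=1)
        all_genes = [g for name in sets.names() for g in sets[name]]
        assert len(all_genes) == len(set(all_genes)) == 40

    def test_tpm_matrix_shape_and_zeros(self):
        groups = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        tpm = simulate_tpm_matrix(100, groups, seed=5)
        assert tpm.shape == (100, 6)
        assert (tpm.to_numpy() == 0).any() and (tpm.to_numpy() >= 0).all()
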