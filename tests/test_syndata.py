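import json

import numpy as np
import pandas as pd
import pytest

from rootmap.genotypes import ld_r2, mean_impute, read_vcf
from rootmap.syndata import (
    SimulationConfig,
    TraitPlan,
    read_gene_table,
    simulate_cohort,
    simulate_genotypes,
    write_cohort,
)

from conftest import small_cohort_config


class TestSimulateGenotypes:
    def test_panel_design_label_counts(self):
        cfg = small_cohort_config(seed=1)
        gd, subpops = simulate_genotypes(cfg)
        counts = subpops["subpop4"].value_counts()
        assert sorted(counts.tolist()) == [7, 10, 19, 21]
        assert gd.n_samples == 57
        assert subpops["subpop6"].nunique() == 6

    def test_positions_strictly_increasing_per_chromosome(self):
        gd, _ = simulate_genotypes(small_cohort_config(seed=2))
        for ch, grp in gd.variants.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing
            assert grp["pos"].is_unique

    def test_dosages_are_valid(self):
        gd, _ = simulate_genotypes(small_cohort_config(seed=3))
        assert set(np.unique(gd.dosages)) <= {0.0, 1.0, 2.0}

    def test_zero_divergence_single_pool_equalizes_frequencies(self):
        cfg = small_cohort_config(
            seed=4, n_samples=400, subpop_sizes=[200, 200],
            fst_like_divergence=0.0, n_snps=200, n_genes=10,
        )
        gd, subpops = simulate_genotypes(cfg)
        lab = subpops["subpop4"].to_numpy()
        f1 = gd.dosages[lab == "pop1"].mean(axis=0) / 2
        f2 = gd.dosages[lab == "pop2"].mean(axis=0) / 2
        # binomial sampling error at n=200 haplotype pairs
        se = np.sqrt(2 * 0.25 / 200)
        assert np.mean(np.abs(f1 - f2)) < 3 * se

    def test_block_size_one_has_no_ld(self):
        cfg = small_cohort_config(seed=5, n_samples=150,
                                  subpop_sizes=[150], ld_block_size=1,
                                  fst_like_divergence=0.0,
                                  n_snps=200, n_genes=10, n_chromosomes=1)
        gd, _ = simulate_genotypes(cfg)
        d = mean_impute(gd).dosages
        rng = np.random.default_rng(0)
        obs, perm = [], []
        for _ in range(300):
            i, j = rng.choice(d.shape[1], size=2, replace=False)
            r2 = ld_r2(d[:, i], d[:, j])
            if np.isfinite(r2):
                obs.append(r2)
            r2p = ld_r2(d[:, i], rng.permutation(d[:, j]))
            if np.isfinite(r2p):
                perm.append(r2p)
        # adjacent-column r^2 indistinguishable from permuted columns
        assert np.mean(obs) == pytest.approx(np.mean(perm), abs=0.01)

    def test_block_structure_creates_ld(self, small_cohort):
        gd = mean_impute(small_cohort.genotypes)
        rng = np.random.default_rng(1)
        within, across = [], []
        for i in range(0, 100, 5):
            r2 = ld_r2(gd.dosages[:, i], gd.dosages[:, i + 1])
            if np.isfinite(r2):
                within.append(r2)
            j = (i + 50 + int(rng.integers(50))) % gd.n_snps
            r2 = ld_r2(gd.dosages[:, i], gd.dosages[:, j])
            if np.isfinite(r2):
                across.append(r2)
        assert np.mean(within) > 3 * np.mean(across)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(n_samples=10, subpop_sizes=[5, 6]).validate()
        with pytest.raises(ValueError, match="positive"):
            SimulationConfig(n_samples=5, subpop_sizes=[5, 0]).validate()
        with pytest.raises(ValueError, match="divergence"):
            SimulationConfig(n_samples=5, subpop_sizes=[5],
                             fst_like_divergence=1.0).validate()


class TestSimulateExpression:
    def test_library_sizes_bound_column_sums(self):
        cfg = small_cohort_config(seed=6, library_size_range=(5e6, 2e7))
        cohort = simulate_cohort(cfg)
        sums = cohort.counts.sum(axis=0).to_numpy(dtype=float)
        drawn = np.array([
            cohort.truth["expression"]["library_sizes"][s]
            for s in cohort.counts.columns
        ])
        # Poisson counting error around each sample's drawn library size
        assert np.abs(sums - drawn).max() < 5 * np.sqrt(drawn.max())
        assert (sums > 5e6 - 5 * np.sqrt(2e7)).all()
        assert (sums < 2e7 + 5 * np.sqrt(2e7)).all()

    def test_planted_cis_slope_recovered_by_regression_oracle(self):
        cfg = small_cohort_config(
            seed=7, n_samples=200, subpop_sizes=[50, 50, 50, 50],
            n_genes=100, n_snps=600, n_auto_cis_eqtls=10,
            auto_cis_effect=1.0, n_hidden_factors=0,
            expression_noise_sd=0.3,
        )
        cohort = simulate_cohort(cfg)
        gd = mean_impute(cohort.genotypes)
        lib = cohort.counts.sum(axis=0).to_numpy(dtype=float)
        exon_kb = cohort.gene_table.set_index("gene_id")["exon_length_bp"] / 1e3
        fpkm = cohort.counts.div(exon_kb, axis=0) / (lib / 1e6)
        prof = np.log2(fpkm + 1)
        ratios = []
        for eqtl in cohort.truth["expression"]["cis_eqtls"]:
            dos = gd.dosage_of(eqtl["snp"])
            if np.std(dos) < 0.3:
                continue
            slope = np.polyfit(dos, prof.loc[eqtl["gene"]].to_numpy(), 1)[0]
            ratios.append(slope / eqtl["effect"])
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)

    def test_null_model_has_no_genotype_signal(self):
        cfg = small_cohort_config(seed=8, n_auto_cis_eqtls=0,
                                  hidden_factor_sd=0.0)
        cohort = simulate_cohort(cfg)
        gd = mean_impute(cohort.genotypes)
        rng = np.random.default_rng(0)
        r2s = []
        logc = np.log2(cohort.counts.to_numpy(dtype=float) + 1)
        for _ in range(100):
            g = rng.integers(logc.shape[0])
            s = rng.integers(gd.n_snps)
            r2 = ld_r2(logc[g], gd.dosages[:, s])
            if np.isfinite(r2):
                r2s.append(r2)
        assert np.mean(r2s) < 0.05

    def test_unknown_gene_or_snp_in_plan_rejected(self):
        cfg = small_cohort_config(seed=9)
        gd, _ = simulate_genotypes(cfg)
        cfg.cis_eqtl_plan = [("NOGENE", gd.variants["snp_id"][0], 1.0)]
        from rootmap.syndata import simulate_expression_counts
        with pytest.raises(ValueError, match="unknown gene"):
            simulate_expression_counts(cfg, gd)


class TestSimulatePhenotypes:
    def test_pure_noise_trait_variance(self):
        cfg = small_cohort_config(
            seed=10, n_samples=400, subpop_sizes=[100] * 4, n_genes=20,
            phenotype_plan={"t": TraitPlan(noise_var=1.0)},
        )
        cohort = simulate_cohort(cfg)
        assert cohort.phenotypes["t"].var() == pytest.approx(1.0, rel=0.25)
        assert cohort.truth["phenotypes"]["t"]["realized_fractions"]["noise"] \
            == pytest.approx(1.0, abs=1e-9)

    def test_single_causal_gene_has_top_correlation(self):
        wins = 0
        for seed in range(20):
            # strong biological variation, mild confounding: the planted
            # gene-trait link must dominate all competitor correlations
            cfg = small_cohort_config(
                seed=seed, n_samples=100, subpop_sizes=[25] * 4,
                n_genes=100, n_snps=200, n_auto_cis_eqtls=3,
                biological_sd=1.0, hidden_factor_sd=0.2,
                expression_noise_sd=0.3,
            )
            probe = simulate_cohort(cfg)
            gene = probe.gene_table["gene_id"].iloc[5]
            cfg.phenotype_plan = {
                "t": TraitPlan(gene_effects=[(gene, 3.0)], noise_var=0.5)
            }
            cohort = simulate_cohort(cfg)
            y = cohort.phenotypes["t"].to_numpy()
            logc = np.log2(cohort.counts.to_numpy(dtype=float) + 1)
            cors = np.abs([
                np.corrcoef(logc[i], y)[0, 1] for i in range(logc.shape[0])
            ])
            wins += cohort.counts.index[np.argmax(cors)] == gene
        assert wins >= 19

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            TraitPlan(polygenic_frac=1.2).validate()

    def test_truth_references_existing_entities(self, small_cohort):
        genes = set(small_cohort.gene_table["gene_id"])
        snps = set(small_cohort.genotypes.variants["snp_id"])
        for e in small_cohort.truth["expression"]["cis_eqtls"]:
            assert e["gene"] in genes and e["snp"] in snps


class TestWriteCohort:
    def test_round_trip_is_lossless(self, small_cohort, tmp_path):
        paths = write_cohort(small_cohort, tmp_path)
        gd = read_vcf(paths["vcf"])
        np.testing.assert_array_equal(gd.dosages, small_cohort.genotypes.dosages)
        assert gd.samples == small_cohort.genotypes.samples
        genes = read_gene_table(paths["gff3"])
        merged = genes.merge(small_cohort.gene_table, on="gene_id",
                             suffixes=("_r", "_w"))
        assert len(merged) == len(small_cohort.gene_table)
        np.testing.assert_array_equal(merged["start_r"], merged["start_w"])
        np.testing.assert_array_equal(merged["end_r"], merged["end_w"])
        np.testing.assert_array_equal(
            merged["exon_length_bp_r"], merged["exon_length_bp_w"]
        )
        counts = pd.read_csv(paths["counts"], sep="\t", index_col=0)
        np.testing.assert_array_equal(counts.to_numpy(),
                                      small_cohort.counts.to_numpy())
        with open(paths["truth"]) as fh:
            truth = json.load(fh)
        assert truth["seed"] == small_cohort.truth["seed"]

    def test_vcf_validates_with_standard_parser(self, small_cohort, tmp_path):
        from cyvcf2 import VCF

        paths = write_cohort(small_cohort, tmp_path)
        records = sum(1 for _ in VCF(paths["vcf"]))
        assert records == small_cohort.genotypes.n_snps

    def test_different_seeds_differ(self):
        a = simulate_cohort(small_cohort_config(seed=0))
        b = simulate_cohort(small_cohort_config(seed=1))
        assert not np.array_equal(a.genotypes.dosages, b.genotypes.dosages)

    def test_same_seed_reproduces(self):
        a = simulate_cohort(small_cohort_config(seed=0))
        b = simulate_cohort(small_cohort_config(seed=0))
        np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_array_equal(a.phenotypes, b.phenotypes)
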