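import numpy as np
import pandas as pd
import pytest

from rootmap.genotypes import GenotypeData, compute_maf
from rootmap.syndata import SimulationConfig, TraitPlan, simulate_cohort


def make_genotypes(dosages, positions=None, chroms=None, snp_ids=None):
    """GenotypeData from a raw dosage array, for toy constructions."""
    d = np.asarray(dosages, dtype=float)
    m = d.shape[1]
    positions = positions if positions is not None else (np.arange(m) + 1) * 1000
    chroms = chroms if chroms is not None else ["chr1"] * m
    snp_ids = snp_ids if snp_ids is not None else [f"snp{i}" for i in range(m)]
    variants = pd.DataFrame({
        "snp_id": snp_ids,
        "chrom": chroms,
        "pos": positions,
        "ref": "A",
        "alt": "T",
        "maf": compute_maf(d),
    })
    return GenotypeData(
        dosages=d, variants=variants,
        samples=[f"S{i}" for i in range(d.shape[0])],
    )


def small_cohort_config(seed=0, **overrides):
    """Compact cohort with the emulated 57-sample panel design."""
    defaults = dict(
        n_samples=57,
        subpop_sizes=[7, 19, 21, 10],
        n_snps=400,
        n_chromosomes=2,
        chrom_length_bp=4_000_000,
        ld_block_size=5,
        n_genes=60,
        n_auto_cis_eqtls=5,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def planted_cohort_config(seed=0, trait_effect=1.0, **overrides):
    """n=200 cohort with one cis-driven gene causally affecting a trait."""
    defaults = dict(
        n_samples=200,
        subpop_sizes=[50, 50, 50, 50],
        n_snps=1000,
        n_chromosomes=2,
        chrom_length_bp=10_000_000,
        ld_block_size=5,
        n_genes=100,
        n_auto_cis_eqtls=10,
        auto_cis_effect=1.0,
        seed=seed,
    )
    defaults.update(overrides)
    cfg = SimulationConfig(**defaults)
    probe = simulate_cohort(cfg)
    causal = probe.truth["expression"]["cis_eqtls"][0]
    cfg.phenotype_plan = {
        "RL_C": TraitPlan(
            gene_effects=[(causal["gene"], trait_effect)],
            polygenic_frac=0.2,
            noise_var=1.0,
        )
    }
    return cfg, causal


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_cohort_config(seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
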