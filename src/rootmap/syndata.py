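"""Synthetic genotype-expression-phenotype cohorts.

The generator emulates the statistical structure the analysis assumes:
a small, highly structured diversity panel (57 samples in four
subpopulations by default), SNPs in haplotype-block LD, expression
counts with library-size and hidden-confounder structure plus planted
cis-eQTLs, and phenotypes driven by a few causal genes/SNPs on top of a
polygenic background.  A machine-readable truth record accompanies every
cohort so planted quantities can be recomputed independently of the
generator's internals.

All randomness flows from a single integer seed; per-stage substreams
are derived deterministically with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeData, compute_maf, grm_vanraden, mean_impute

_BASES = np.array(list("ACGT"))


@dataclass
class TraitPlan:
    """Causal architecture of one simulated trait.

    ``gene_effects`` act per unit of true (noise-free) expression;
    ``snp_effects`` per alternate allele.  ``polygenic_frac`` is the
    fraction of total trait variance from the GRM-structured polygenic
    term; ``noise_var`` is the absolute variance of the independent
    noise.
    """

    gene_effects: list = field(default_factory=list)  # [(gene_id, beta)]
    snp_effects: list = field(default_factory=list)  # [(snp_id, beta)]
    polygenic_frac: float = 0.0
    noise_var: float = 1.0

    def validate(self):
        if not (0.0 <= self.polygenic_frac < 1.0):
            raise ValueError("polygenic fraction must lie in [0, 1)")
        if self.noise_var < 0:
            raise ValueError("noise variance must be non-negative")


@dataclass
class SimulationConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the emulated diversity-panel design: 57 samples in
    four subpopulations of 7/19/21/10, block-LD SNPs on 4 chromosomes,
    1,000 expressed genes with 5 hidden confounding factors, and
    library sizes of 5-20 million reads.
    """

    n_samples: int = 57
    subpop_sizes: list = field(default_factory=lambda: [7, 19, 21, 10])
    n_snps: int = 10_000
    n_chromosomes: int = 4
    chrom_length_bp: int = 30_000_000
    ld_block_size: int = 10
    n_founder_haplotypes: int = 4
    fst_like_divergence: float = 0.10
    n_genes: int = 1_000
    n_hidden_factors: int = 5
    hidden_factor_sd: float = 0.5
    biological_sd: float = 0.5
    expression_noise_sd: float = 0.5
    count_overdispersion_sd: float = 0.15
    library_size_range: tuple = (5e6, 2e7)
    cis_eqtl_plan: list | None = None  # [(gene_id, snp_id, effect)] or None
    n_auto_cis_eqtls: int = 50
    cis_max_dist_bp: int = 100_000
    auto_cis_effect: float = 1.0
    phenotype_plan: dict = field(default_factory=dict)  # name -> TraitPlan
    seed: int = 0

    def validate(self):
        if any(s <= 0 for s in self.subpop_sizes):
            raise ValueError("subpopulation sizes must be positive")
        if sum(self.subpop_sizes) != self.n_samples:
            raise ValueError("subpopulation sizes must sum to n_samples")
        if not (0.0 <= self.fst_like_divergence < 1.0):
            raise ValueError("fst_like_divergence must lie in [0, 1)")
        for plan in self.phenotype_plan.values():
            plan.validate()


@dataclass
class SyntheticCohort:
    genotypes: GenotypeData
    gene_table: pd.DataFrame  # gene_id, chrom, start, end, strand, exon_length_bp
    counts: pd.DataFrame  # genes x samples, integer
    phenotypes: pd.DataFrame  # samples x traits
    subpops: pd.DataFrame  # sample, subpop4, subpop6
    truth: dict


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_genotypes(config: SimulationConfig):
    """Block-haplotype genotypes with subpopulation divergence.

    Per LD block, a small pool of founder haplotypes is drawn around
    shared ancestral allele frequencies; each subpopulation gets its own
    haplotype frequencies (Dirichlet around uniform, spread controlled
    by the divergence parameter), and each sample draws two block
    haplotypes.  Zero divergence means every subpopulation shares the
    same haplotype frequencies exactly.
    """
    config.validate()
    rng = _streams(config.seed, 6)[0]
    n = config.n_samples
    n_subpops = len(config.subpop_sizes)
    labels = np.repeat(
        [f"pop{i+1}" for i in range(n_subpops)], config.subpop_sizes
    )

    per_chrom = [config.n_snps // config.n_chromosomes] * config.n_chromosomes
    per_chrom[-1] += config.n_snps - sum(per_chrom)

    dosage_cols, rows = [], []
    for c, m in enumerate(per_chrom, start=1):
        if m == 0:
            continue
        pos = np.sort(rng.choice(
            np.arange(1, config.chrom_length_bp + 1), size=m, replace=False
        ))
        start = 0
        while start < m:
            size = min(config.ld_block_size, m - start)  # final block truncated
            p_anc = rng.uniform(0.05, 0.95, size=size)
            h = config.n_founder_haplotypes
            haps = (rng.random((h, size)) < p_anc).astype(float)
            fst = config.fst_like_divergence
            base = np.full(h, 1.0 / h)
            if fst == 0:
                freqs = np.tile(base, (n_subpops, 1))
            else:
                conc = (1.0 - fst) / fst
                freqs = rng.dirichlet(base * h * conc, size=n_subpops)
            block = np.zeros((n, size))
            offset = 0
            for sp, nsamp in enumerate(config.subpop_sizes):
                draws = rng.choice(h, size=(nsamp, 2), p=freqs[sp])
                block[offset:offset + nsamp] = haps[draws[:, 0]] + haps[draws[:, 1]]
                offset += nsamp
            dosage_cols.append(block)
            start += size
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append((f"chr{c}_{p}", f"chr{c}", int(p), _BASES[ref], _BASES[alt]))

    dosages = np.hstack(dosage_cols)
    variants = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    variants["maf"] = compute_maf(dosages)
    gd = GenotypeData(
        dosages=dosages,
        variants=variants,
        samples=[f"S{i+1:03d}" for i in range(n)],
    )
    subpops = pd.DataFrame({"sample": gd.samples, "subpop4": labels})
    # finer grouping: split the last subpopulation into sublevels, to
    # exercise six-group covariate models
    fine = labels.astype(object).copy()
    last = f"pop{n_subpops}"
    idx = np.flatnonzero(labels == last)
    for i, j in enumerate(idx):
        fine[j] = f"{last}{'abc'[i % 3]}"
    subpops["subpop6"] = fine
    return gd, subpops


def _default_cis_plan(config: SimulationConfig, gd: GenotypeData,
                      gene_table: pd.DataFrame, rng) -> list:
    plan = []
    vt = gd.variants
    genes = gene_table.sample(
        n=min(config.n_auto_cis_eqtls, len(gene_table)),
        random_state=int(rng.integers(2**31)),
    )
    for _, g in genes.iterrows():
        near = vt[
            (vt["chrom"] == g["chrom"])
            & ((vt["pos"] - g["start"]).abs() <= config.cis_max_dist_bp)
            & (vt["maf"] > 0.05)
        ]
        if near.empty:
            continue
        snp = near.sample(n=1, random_state=int(rng.integers(2**31))).iloc[0]
        plan.append((g["gene_id"], snp["snp_id"], config.auto_cis_effect))
    return plan


def simulate_expression_counts(config: SimulationConfig, gd: GenotypeData):
    """Counts with library-size, hidden-factor, and planted cis structure.

    Log2-scale expression = baseline + hidden-factor loadings x sample
    scores + planted cis effect x dosage + noise.  Counts are a Poisson
    mixture of log-normal rates (negative-binomial-like), with each
    sample's expected total pinned to its drawn library size.

    Returns (gene_table, counts, truth-fragment dict).
    """
    rngs = _streams(config.seed, 6)
    rng = rngs[1]
    n, ngenes = config.n_samples, config.n_genes

    per_chrom = ngenes // config.n_chromosomes
    rows = []
    gid = 0
    for c in range(1, config.n_chromosomes + 1):
        count = per_chrom if c < config.n_chromosomes else ngenes - per_chrom * (
            config.n_chromosomes - 1)
        starts = np.sort(rng.choice(
            np.arange(1, config.chrom_length_bp - 10_000), size=count, replace=False
        ))
        for s in starts:
            gid += 1
            length = int(rng.integers(1_000, 6_000))
            exon = int(length * rng.uniform(0.5, 0.9))
            rows.append((
                f"GENE{gid:05d}", f"chr{c}", int(s), int(s) + length,
                rng.choice(["+", "-"]), exon,
            ))
    gene_table = pd.DataFrame(rows, columns=[
        "gene_id", "chrom", "start", "end", "strand", "exon_length_bp",
    ])

    plan = config.cis_eqtl_plan
    if plan is None:
        plan = _default_cis_plan(config, gd, gene_table, rng)
    gene_ids = list(gene_table["gene_id"])
    gene_idx = {g: i for i, g in enumerate(gene_ids)}
    snp_ids = set(gd.variants["snp_id"])
    for g, s, _ in plan:
        if g not in gene_idx:
            raise ValueError(f"cis plan references unknown gene {g!r}")
        if s not in snp_ids:
            raise ValueError(f"cis plan references unknown SNP {s!r}")

    mu = rng.uniform(1.0, 6.0, size=ngenes)
    k = config.n_hidden_factors
    scores = rng.normal(size=(n, k))
    loadings = rng.normal(scale=config.hidden_factor_sd, size=(ngenes, k))

    # true expression: baseline + per-sample biological variation + cis
    # genetic effects; hidden factors and measurement noise sit on top
    # and are what residualization is meant to strip
    true_log = np.tile(mu[:, None], (1, n)) \
        + rng.normal(scale=config.biological_sd, size=(ngenes, n))
    for g, s, eff in plan:
        dos = np.nan_to_num(gd.dosage_of(s), nan=0.0)
        true_log[gene_idx[g]] += eff * dos
    obs_log = true_log + loadings @ scores.T \
        + rng.normal(scale=config.expression_noise_sd, size=(ngenes, n))
    obs_log = np.maximum(obs_log, 0.0)

    fpkm_target = 2.0 ** obs_log - 1.0
    exon_kb = gene_table["exon_length_bp"].to_numpy() / 1e3
    mass = fpkm_target * exon_kb[:, None]
    lib = rng.uniform(*config.library_size_range, size=n)
    # log-normal gene-wise rate jitter (negative-binomial-like), then
    # renormalize so each sample's expected depth equals its drawn
    # library size: sequencing redistributes a fixed read budget
    od = np.exp(rng.normal(
        scale=config.count_overdispersion_sd, size=mass.shape
    ) - 0.5 * config.count_overdispersion_sd**2)
    mass = mass * od
    lam = mass / mass.sum(axis=0) * lib
    counts = rng.poisson(lam).astype(np.int64)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=gd.samples)

    truth = {
        "cis_eqtls": [
            {"gene": g, "snp": s, "effect": float(e)} for g, s, e in plan
        ],
        "baseline_log2": dict(zip(gene_ids, mu.tolist())),
        "true_log2_expression": None,  # filled by simulate_cohort if requested
        "hidden_factor_sd": config.hidden_factor_sd,
        "biological_sd": config.biological_sd,
        "expression_noise_sd": config.expression_noise_sd,
        "library_sizes": dict(zip(gd.samples, lib.tolist())),
    }
    return gene_table, counts_df, truth, true_log


def simulate_phenotypes(
    config: SimulationConfig,
    gd: GenotypeData,
    gene_table: pd.DataFrame,
    true_log: np.ndarray,
):
    """Traits from causal genes/SNPs, a polygenic term, and noise.

    trait = sum(gene effects x true expression) + sum(SNP effects x
    dosage) + polygenic (MVN with covariance proportional to the GRM) +
    independent noise.  The polygenic variance is set so its share of
    the total trait variance equals the planned fraction; realized
    fractions land in the truth record.
    """
    rng = _streams(config.seed, 6)[2]
    n = config.n_samples
    plans = config.phenotype_plan or {"trait1": TraitPlan()}
    gene_idx = {g: i for i, g in enumerate(gene_table["gene_id"])}

    grm = grm_vanraden(mean_impute(gd))
    grm_n = grm / max(np.trace(grm) / n, 1e-12)
    chol = np.linalg.cholesky(grm_n + 1e-8 * np.eye(n))

    data, truth = {}, {}
    for name, plan in plans.items():
        plan.validate()
        fixed = np.zeros(n)
        for g, beta in plan.gene_effects:
            if g not in gene_idx:
                raise ValueError(f"phenotype plan references unknown gene {g!r}")
            fixed += beta * true_log[gene_idx[g]]
        for s, beta in plan.snp_effects:
            fixed += beta * np.nan_to_num(gd.dosage_of(s), nan=0.0)
        base_var = float(np.var(fixed)) + plan.noise_var
        f = plan.polygenic_frac
        sigma_u2 = f / (1.0 - f) * base_var if f > 0 else 0.0
        u = np.sqrt(sigma_u2) * (chol @ rng.normal(size=n))
        e = rng.normal(scale=np.sqrt(plan.noise_var), size=n)
        y = fixed + u + e
        data[name] = y
        total = float(np.var(y)) or 1.0
        truth[name] = {
            "gene_effects": [[g, float(b)] for g, b in plan.gene_effects],
            "snp_effects": [[s, float(b)] for s, b in plan.snp_effects],
            "polygenic_frac_planned": plan.polygenic_frac,
            "polygenic_var": sigma_u2,
            "noise_var": plan.noise_var,
            "realized_fractions": {
                "fixed": float(np.var(fixed)) / total,
                "polygenic": float(np.var(u)) / total,
                "noise": float(np.var(e)) / total,
            },
        }
    phenos = pd.DataFrame(data, index=gd.samples)
    return phenos, truth


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Run all three simulation stages and assemble the truth record."""
    gd, subpops = simulate_genotypes(config)
    gene_table, counts, expr_truth, true_log = simulate_expression_counts(config, gd)
    phenos, pheno_truth = simulate_phenotypes(config, gd, gene_table, true_log)
    truth = {
        "seed": config.seed,
        "expression": expr_truth,
        "phenotypes": pheno_truth,
    }
    truth["expression"].pop("true_log2_expression", None)
    return SyntheticCohort(
        genotypes=gd,
        gene_table=gene_table,
        counts=counts,
        phenotypes=phenos,
        subpops=subpops,
        truth=truth,
    )


# ---------------------------------------------------------------- I/O ----

def write_vcf(gd: GenotypeData, path):
    """Write dosages as a minimal VCF 4.2 with GT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for ch in pd.unique(gd.variants["chrom"]):
            fh.write(f"##contig=<ID={ch}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gd.samples) + "\n")
        gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, row in gd.variants.iterrows():
            calls = [
                gt_of.get(d, "./.") if np.isfinite(d) else "./."
                for d in gd.dosages[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t{row['ref']}"
                f"\t{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_gff3(gene_table: pd.DataFrame, path):
    """Gene + exon features; exon lengths split over two exons when the
    gene is long enough, so exon-length summation gets exercised."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in gene_table.iterrows():
            attrs = f"ID={g['gene_id']}"
            fh.write(
                f"{g['chrom']}\trootmap\tgene\t{g['start']}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\t{attrs}\n"
            )
            exon = int(g["exon_length_bp"])
            half = exon // 2
            if half >= 2 and g["end"] - g["start"] + 1 > exon + 10:
                e1 = (g["start"], g["start"] + half - 1)
                e2 = (g["end"] - (exon - half) + 1, g["end"])
                spans = [e1, e2]
            else:
                spans = [(g["start"], g["start"] + exon - 1)]
            for i, (a, b) in enumerate(spans, 1):
                fh.write(
                    f"{g['chrom']}\trootmap\texon\t{a}\t{b}\t.\t{g['strand']}"
                    f"\t.\tID={g['gene_id']}.exon{i};Parent={g['gene_id']}\n"
                )


def read_gene_table(path) -> pd.DataFrame:
    """Gene spans + summed exon lengths from a GFF3 file."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "source", "type", "start", "end", "score",
               "strand", "phase", "attrs"],
        dtype={"chrom": str},
    )

    def attr_id(a):
        for part in str(a).split(";"):
            if part.startswith("ID="):
                return part[3:]
        return None

    genes = df[df["type"] == "gene"].copy()
    genes["gene_id"] = genes["attrs"].map(attr_id)
    exons = df[df["type"] == "exon"].copy()

    def parent(a):
        for part in str(a).split(";"):
            if part.startswith("Parent="):
                return part[7:]
        return None

    exons["gene_id"] = exons["attrs"].map(parent)
    exons["len"] = exons["end"] - exons["start"] + 1
    exon_len = exons.groupby("gene_id")["len"].sum()
    out = genes[["gene_id", "chrom", "start", "end", "strand"]].copy()
    out["exon_length_bp"] = out["gene_id"].map(exon_len).fillna(
        out["end"] - out["start"] + 1).astype(int)
    return out.reset_index(drop=True)


def _toy_go_files(cohort: SyntheticCohort, directory: Path, rng):
    """Toy GO annotation + MSU<->RAP id map covering the cohort's genes.

    Includes a couple of deliberately multi-mapped ids so the strict
    one-to-one mapping rule gets exercised downstream.
    """
    genes = list(cohort.gene_table["gene_id"])
    n_terms = max(5, len(genes) // 20)
    terms = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    rows_map, rows_go = [], []
    for i, g in enumerate(genes):
        rap = f"Os{i+1:06d}"
        rows_map.append((g, rap))
        for t in terms:
            if rng.random() < 0.08:
                rows_go.append((f"{rap}-01", t, f"process {t[-4:]}"))
    if len(genes) >= 2:
        rows_map.append((genes[0], "OsX00001"))  # multi-mapped MSU id
    pd.DataFrame(rows_map, columns=["msu_id", "rap_id"]).to_csv(
        directory / "id_map.tsv", sep="\t", index=False)
    pd.DataFrame(rows_go, columns=["transcript_id", "term_id", "term_name"]) \
        .to_csv(directory / "go_annotation.tsv", sep="\t", index=False)


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write a cohort as VCF/GFF3/TSVs plus a JSON truth file.

    Returns a dict of the written paths.  Round-trips losslessly through
    the package's own readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": directory / "genotypes.vcf",
        "gff3": directory / "genes.gff3",
        "counts": directory / "counts.tsv",
        "phenotypes": directory / "phenotypes.tsv",
        "subpopulations": directory / "subpopulations.tsv",
        "go": directory / "go_annotation.tsv",
        "idmap": directory / "id_map.tsv",
        "truth": directory / "truth.json",
    }
    write_vcf(cohort.genotypes, paths["vcf"])
    write_gff3(cohort.gene_table, paths["gff3"])
    cohort.counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    cohort.phenotypes.to_csv(paths["phenotypes"], sep="\t", index_label="sample")
    cohort.subpops.to_csv(paths["subpopulations"], sep="\t", index=False)
    _toy_go_files(cohort, directory,
                  np.random.default_rng(cohort.truth.get("seed", 0)))
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
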