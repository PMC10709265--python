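"""End-to-end orchestration: genotypes -> expression -> GWAS -> peaks ->
TWAS -> gene sets -> enrichment -> eGWAS/colocalization.

Every stage writes TSV outputs into the result directory plus a JSON
manifest of parameters and counts; runs are deterministic given the
config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc as coloc_mod
from . import enrich as enrich_mod
from . import expression as expr_mod
from . import genotypes as geno_mod
from . import peaks as peaks_mod
from . import twas as twas_mod
from .mixedmodel import MixedModelSpec, build_design, marker_scan, select_covariate_model
from .syndata import read_gene_table

logger = logging.getLogger(__name__)

STAGES = ("preprocess", "gwas", "twas", "enrich", "egwas", "coloc")

#: phenotype-name stems whose directional top-1% lists are merged into
#: per-root-class root-size unions
ROOT_SIZE_STEMS = ("RL", "RSA", "RV", "NRT")


@dataclass
class PipelineConfig:
    """File paths, thresholds (defaulting to the published parameter
    set), and the seed."""

    vcf: str = ""
    gff3: str = ""
    counts: str = ""
    phenotypes: str = ""
    subpopulations: str = ""
    go: str = ""
    idmap: str = ""
    out_dir: str = "rootmap_results"

    maf_threshold: float = 0.10
    prune_r2: float = 0.99
    prune_window_bp: int = 100_000
    prune_step_variants: int = 100
    fdr_threshold: float = 0.10
    peak_merge_dist_bp: int = 100_000
    peak_merge_r2: float = 0.50
    candidate_half_width_bp: int = 250_000
    cis_half_width_bp: int = 250_000
    coloc_max_dist_bp: int = 250_000
    coloc_r2: float = 0.50
    n_hidden_factors: int = 5
    top_k: int = 10
    top_frac: float = 0.01
    min_expressed_profile: float = 1.0
    seed: int = 0

    def validate(self):
        for name, lo, hi in [
            ("maf_threshold", 0, 0.5), ("prune_r2", 0, 1),
            ("fdr_threshold", 0, 1), ("peak_merge_r2", 0, 1),
            ("coloc_r2", 0, 1), ("top_frac", 0, 1),
        ]:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")


def _read_subpops(path):
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    labels4 = df[cols[1]].to_numpy()
    labels6 = df[cols[2]].to_numpy() if len(cols) > 2 else None
    return df[cols[0]].to_numpy(), labels4, labels6


def run_pipeline(config: PipelineConfig, stages=STAGES, return_state=False):
    """Execute the requested pipeline stages in order.

    Returns a manifest dict (also written to out_dir/manifest.json), or
    (manifest, state) with the in-memory stage products when
    ``return_state`` is set.  Any stage failure aborts with the stage
    name attached.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"parameters": asdict(config), "counts": {}, "outputs": {}}
    state: dict = {}
    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            _run_stage(stage, config, state, manifest, out)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {state.get('_stage', '?')!r} failed: {err}") from err
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return (manifest, state) if return_state else manifest


def _run_stage(stage, config, state, manifest, out: Path):
    state["_stage"] = stage
    if stage == "preprocess":
        _stage_preprocess(config, state, manifest, out)
    elif stage == "gwas":
        _stage_gwas(config, state, manifest, out)
    elif stage == "twas":
        _stage_twas(config, state, manifest, out)
    elif stage == "enrich":
        _stage_enrich(config, state, manifest, out)
    elif stage in ("egwas", "coloc"):
        _stage_egwas_coloc(config, state, manifest, out)


def _stage_preprocess(config, state, manifest, out):
    gd = geno_mod.read_vcf(config.vcf)
    gd, maf_counts = geno_mod.maf_filter(gd, config.maf_threshold)
    gd = geno_mod.ld_prune(
        gd, config.prune_window_bp, config.prune_step_variants, config.prune_r2
    )
    gd = geno_mod.mean_impute(gd)
    state["genotypes"] = gd
    state["grm"] = geno_mod.grm_vanraden(gd)
    state["gene_table"] = read_gene_table(config.gff3)

    counts = pd.read_csv(config.counts, sep="\t", index_col=0)
    exon = state["gene_table"].set_index("gene_id")["exon_length_bp"]
    cm = expr_mod.ExpressionMatrix(
        values=counts, stage="counts",
        exon_lengths=exon.reindex(counts.index),
    )
    factors = expr_mod.tmm_factors(cm)
    profiles = expr_mod.log_profile(expr_mod.fpkm(cm, factors))
    profiles, expr_counts = expr_mod.expressed_filter(
        profiles, config.min_expressed_profile
    )
    factor_model, residuals = expr_mod.hidden_factor_residuals(
        profiles, config.n_hidden_factors
    )
    state["profiles"] = profiles
    state["residuals"] = residuals

    phenos = pd.read_csv(config.phenotypes, sep="\t", index_col=0)
    samples, labels4, labels6 = _read_subpops(config.subpopulations)
    order = {s: i for i, s in enumerate(gd.samples)}
    if set(phenos.index) != set(gd.samples):
        raise ValueError("phenotype samples do not match genotype samples")
    state["phenotypes"] = phenos.loc[gd.samples]
    idx = [order[s] for s in samples]
    lab4 = np.empty(len(samples), dtype=object)
    lab4[idx] = labels4
    state["labels4"] = lab4
    if labels6 is not None:
        lab6 = np.empty(len(samples), dtype=object)
        lab6[idx] = labels6
        state["labels6"] = lab6
    else:
        state["labels6"] = None

    gd.variants.to_csv(out / "snps_pruned.tsv", sep="\t", index=False)
    pd.DataFrame(state["grm"], index=gd.samples, columns=gd.samples) \
        .to_csv(out / "grm.tsv", sep="\t")
    factors.to_csv(out / "tmm_factors.tsv", sep="\t")
    factor_model.relevance_table().to_csv(
        out / "factor_relevance.tsv", sep="\t", index=False)
    manifest["counts"].update({
        "snps_after_maf": maf_counts["kept"],
        "snps_after_prune": gd.n_snps,
        "genes_expressed": len(profiles.genes),
        "genes_removed_not_expressed": expr_counts["removed"],
        "samples": gd.n_samples,
    })


def _stage_gwas(config, state, manifest, out):
    gd = state["genotypes"]
    results, loci_rows, cand_rows = {}, [], []
    for pheno in state["phenotypes"].columns:
        y = state["phenotypes"][pheno].to_numpy(dtype=float)
        sel = select_covariate_model(
            y, state["grm"], state["labels4"], state["labels6"]
        )
        lab = {"none": None, "subpop4": state["labels4"],
               "subpop6": state["labels6"]}[sel.selected]
        x = build_design(y.size, lab)
        spec = MixedModelSpec(y=y, x=x, kinship=state["grm"], p3d=True)
        res = marker_scan(
            spec, gd.dosages, predictor_ids=list(gd.variants["snp_id"]),
            null=sel.fits[sel.selected],
        )
        res = res.merge(gd.variants[["snp_id", "chrom", "pos"]],
                        left_on="predictor_id", right_on="snp_id").drop(columns="snp_id")
        res["model"] = sel.selected
        results[pheno] = res
        sig = peaks_mod.call_significant(res, config.fdr_threshold)
        loci = peaks_mod.merge_peaks(
            sig, gd, config.peak_merge_dist_bp, config.peak_merge_r2,
            config.candidate_half_width_bp, phenotype=pheno,
        )
        for locus in loci:
            loci_rows.append((
                pheno, locus.peak_snp, locus.chrom, locus.pos,
                locus.minus_log10_p, locus.fdr_p, len(locus.members),
                locus.interval[0], locus.interval[1],
            ))
            cands = peaks_mod.candidate_interval(
                locus, state["gene_table"], config.candidate_half_width_bp
            )
            ranked = peaks_mod.prioritize_by_anova(
                locus, cands, state["profiles"], gd, state["labels4"]
            )
            for _, r in ranked.iterrows():
                cand_rows.append((pheno, locus.peak_snp, r["gene_id"],
                                  r["anova_p"], r["minus_log10_p"]))
        state.setdefault("gwas_loci", {})[pheno] = loci
    state["gwas_results"] = results
    pd.concat(
        [r.assign(phenotype=p) for p, r in results.items()], ignore_index=True
    ).to_csv(out / "gwas_results.tsv", sep="\t", index=False)
    pd.DataFrame(loci_rows, columns=[
        "phenotype", "peak_snp", "chrom", "pos", "minus_log10_p", "fdr_p",
        "n_members", "interval_start", "interval_end",
    ]).to_csv(out / "gwas_peaks.tsv", sep="\t", index=False)
    pd.DataFrame(cand_rows, columns=[
        "phenotype", "peak_snp", "gene_id", "anova_p", "minus_log10_p",
    ]).to_csv(out / "gwas_candidates.tsv", sep="\t", index=False)
    manifest["counts"]["gwas_peak_loci"] = len(loci_rows)


def _stage_twas(config, state, manifest, out):
    results = {}
    for pheno in state["phenotypes"].columns:
        y = state["phenotypes"][pheno].to_numpy(dtype=float)
        sel = select_covariate_model(
            y, state["grm"], state["labels4"], state["labels6"]
        )
        lab = {"none": None, "subpop4": state["labels4"],
               "subpop6": state["labels6"]}[sel.selected]
        x = build_design(y.size, lab)
        res = twas_mod.twas_scan(
            y, state["residuals"], state["grm"], x, null=sel.fits[sel.selected]
        )
        results[pheno] = res
    state["twas_results"] = results
    pd.concat(
        [r.assign(phenotype=p) for p, r in results.items()], ignore_index=True
    ).to_csv(out / "twas_results.tsv", sep="\t", index=False)

    union = twas_mod.top_k_union(results, config.top_k)
    union.to_csv(out / "twas_top_genes.tsv", sep="\t", index=False)
    state["twas_top_union"] = union

    sets = {
        p: twas_mod.top_percent_sets(r, config.top_frac)
        for p, r in results.items()
    }
    # root-size unions where phenotype names follow the STEM_C/_L scheme
    unions = {}
    for root_class in ("C", "L"):
        for direction in ("positive", "negative"):
            members = {
                f"{stem}_{root_class}": sets[f"{stem}_{root_class}"][direction]
                for stem in ROOT_SIZE_STEMS
                if f"{stem}_{root_class}" in sets
            }
            if len(members) == len(ROOT_SIZE_STEMS):
                unions[f"RS_{root_class}:{direction}"] = \
                    twas_mod.union_root_size(members)
    state["top_percent_sets"] = sets
    state["root_size_unions"] = unions
    with open(out / "top_percent_sets.json", "w") as fh:
        json.dump({
            "per_phenotype": sets,
            "root_size_unions": {
                k: v["provenance"] for k, v in unions.items()
            },
        }, fh, indent=1)
    manifest["counts"]["twas_top_union_genes"] = len(union)


def _stage_enrich(config, state, manifest, out):
    if not config.go or not config.idmap:
        logger.info("enrichment skipped: no GO annotation configured")
        return
    for path, name in [(config.go, "GO annotation"), (config.idmap, "ID map")]:
        if not Path(path).exists():
            raise FileNotFoundError(f"{name} file missing: {path}")
    annot = enrich_mod.build_annotation(
        config.go, config.idmap, list(state["profiles"].genes)
    )
    tables = []
    targets = {}
    for name, u in state.get("root_size_unions", {}).items():
        targets[name] = u["genes"]
    for pheno, dirs in state.get("top_percent_sets", {}).items():
        stem = pheno.rsplit("_", 1)[0] if "_" in pheno else pheno
        if stem in ROOT_SIZE_STEMS:
            continue  # covered by the root-size unions
        for direction, genes in dirs.items():
            if genes:
                targets[f"{pheno}:{direction}"] = genes
    for name, genes in targets.items():
        res = enrich_mod.hypergeom_enrich(genes, annot)
        if len(res):
            tables.append(res.assign(gene_set=name))
    enr = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    state["enrichment"] = enr
    manifest["counts"]["enrichment_background"] = len(annot.background)


def _stage_egwas_coloc(config, state, manifest, out):
    if "egwas_done" in state:
        return
    state["egwas_done"] = True
    gd = state["genotypes"]
    gene_table = state["gene_table"].set_index("gene_id")
    union = state.get("twas_top_union")
    if union is None or union.empty:
        logger.info("eGWAS skipped: no TWAS top genes")
        return
    peaks_rows, coloc_rows = [], []
    for _, row in union.iterrows():
        gene = row["gene_id"]
        if gene not in gene_table.index or gene not in state["profiles"].values.index:
            continue
        expr = state["profiles"].values.loc[gene].to_numpy(dtype=float)
        _, cis_peak, trans_peaks = coloc_mod.egwas_scan(
            expr, gene, gene_table.loc[gene], gd, state["grm"],
            state["labels4"], state["labels6"],
            config.fdr_threshold, config.cis_half_width_bp,
        )
        for pk in ([cis_peak] if cis_peak else []) + trans_peaks:
            peaks_rows.append((gene, pk.snp_id, pk.chrom, pk.pos,
                               pk.minus_log10_p, pk.fdr_p, pk.kind))
        if cis_peak is None:
            continue
        for pheno in row["phenotypes"]:
            gres = state.get("gwas_results", {}).get(pheno)
            if gres is None:
                continue
            try:
                rep = coloc_mod.colocalize(
                    cis_peak, gres, pheno, gd,
                    config.coloc_max_dist_bp, config.coloc_r2,
                )
            except ValueError:
                continue
            coloc_rows.append((
                rep.gene_id, rep.phenotype, rep.egwas_snp, rep.gwas_snp,
                rep.gwas_minus_log10_p, rep.distance_bp, rep.r2, rep.overlap,
            ))
    peaks_df = pd.DataFrame(peaks_rows, columns=[
        "gene_id", "snp_id", "chrom", "pos", "minus_log10_p", "fdr_p", "kind",
    ])
    coloc_df = pd.DataFrame(coloc_rows, columns=[
        "gene_id", "phenotype", "egwas_snp", "gwas_snp",
        "gwas_minus_log10_p", "distance_bp", "r2", "overlap",
    ])
    peaks_df.to_csv(out / "egwas_peaks.tsv", sep="\t", index=False)
    coloc_df.to_csv(out / "colocalization.tsv", sep="\t", index=False)
    state["egwas_peaks"] = peaks_df
    state["coloc"] = coloc_df
    manifest["counts"]["egwas_cis_peaks"] = int((peaks_df["kind"] == "cis").sum())
    manifest["counts"]["colocalized_genes"] = sorted(
        coloc_df.loc[coloc_df["overlap"], "gene_id"].unique().tolist()
    )
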