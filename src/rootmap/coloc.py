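"""eGWAS of candidate genes and GWAS-eGWAS colocalization.

Each candidate gene's expression profile becomes the response of the
same mixed-model scan used for the phenotypes (including BIC-based
covariate-model selection).  Significant SNPs within 250 kb of the gene
define the cis peak; a cis peak colocalizes with a GWAS signal when the
lowest-p GWAS SNP on the same chromosome lies closer than 250 kb and in
LD (r^2 > 0.50) with it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeData, ld_r2
from .mixedmodel import MixedModelSpec, build_design, marker_scan, select_covariate_model
from .peaks import bh_fdr, call_significant, span_distance

logger = logging.getLogger(__name__)


@dataclass
class EgwasPeak:
    gene_id: str
    snp_id: str
    chrom: str
    pos: int
    minus_log10_p: float
    fdr_p: float
    kind: str  # "cis" | "trans"
    cis_half_width_bp: int = 250_000
    #: equally significant cis SNPs, nearest to the gene first
    equivalent_snps: list = field(default_factory=list)


def classify_peak(
    snp_chrom, snp_pos: int, gene_chrom, gene_start: int, gene_end: int,
    half_width_bp: int = 250_000,
) -> str:
    """"cis" iff the SNP sits on the gene's chromosome within
    ``half_width_bp`` (inclusive) of the gene span, else "trans"."""
    if str(snp_chrom) != str(gene_chrom):
        return "trans"
    d = span_distance(int(snp_pos), int(gene_start), int(gene_end))
    return "cis" if d <= half_width_bp else "trans"


def egwas_scan(
    expression,  # per-sample expression values for one gene
    gene_id: str,
    gene_row,  # mapping with chrom/start/end
    genotypes: GenotypeData,
    kinship: np.ndarray,
    labels4=None,
    labels6=None,
    fdr_threshold: float = 0.10,
    cis_half_width_bp: int = 250_000,
):
    """Genome-wide scan with a gene's expression as the response.

    Returns (AssociationResult frame, cis EgwasPeak or None, list of
    trans EgwasPeak).  Trans peaks are reported but take no part in
    colocalization.
    """
    sel = select_covariate_model(expression, kinship, labels4, labels6)
    lab = {"none": None, "subpop4": labels4, "subpop6": labels6}[sel.selected]
    x = build_design(np.asarray(expression).size, lab)
    spec = MixedModelSpec(y=expression, x=x, kinship=kinship, p3d=True)
    res = marker_scan(
        spec, genotypes.dosages,
        predictor_ids=list(genotypes.variants["snp_id"]),
        null=sel.fits[sel.selected],
    )
    res = res.merge(
        genotypes.variants[["snp_id", "chrom", "pos"]],
        left_on="predictor_id", right_on="snp_id", how="left",
    ).drop(columns="snp_id")
    sig = call_significant(res, fdr_threshold)
    cis_peak = None
    trans_peaks = []
    if not sig.empty:
        gchrom = str(gene_row["chrom"])
        gstart, gend = int(gene_row["start"]), int(gene_row["end"])
        kinds = np.array([
            classify_peak(c, p, gchrom, gstart, gend, cis_half_width_bp)
            for c, p in zip(sig["chrom"], sig["pos"])
        ])
        cis = sig[kinds == "cis"]
        if not cis.empty:
            best_p = cis["p"].min()
            ties = cis[cis["p"] == best_p].copy()
            ties["gene_dist"] = [
                span_distance(int(p), gstart, gend) for p in ties["pos"]
            ]
            ties = ties.sort_values(["gene_dist", "pos"])
            rep = ties.iloc[0]
            cis_peak = EgwasPeak(
                gene_id=gene_id,
                snp_id=str(rep["predictor_id"]),
                chrom=str(rep["chrom"]),
                pos=int(rep["pos"]),
                minus_log10_p=float(rep["minus_log10_p"]),
                fdr_p=float(rep["fdr_p"]),
                kind="cis",
                cis_half_width_bp=cis_half_width_bp,
                equivalent_snps=list(ties["predictor_id"]),
            )
        for _, row in sig[kinds == "trans"].iterrows():
            trans_peaks.append(EgwasPeak(
                gene_id=gene_id,
                snp_id=str(row["predictor_id"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                minus_log10_p=float(row["minus_log10_p"]),
                fdr_p=float(row["fdr_p"]),
                kind="trans",
                cis_half_width_bp=cis_half_width_bp,
            ))
    return res, cis_peak, trans_peaks


@dataclass
class ColocReport:
    gene_id: str
    phenotype: str
    egwas_snp: str
    gwas_snp: str
    gwas_minus_log10_p: float
    distance_bp: int
    r2: float
    overlap: bool


def colocalize(
    peak: EgwasPeak,
    gwas_result: pd.DataFrame,
    phenotype: str,
    genotypes: GenotypeData,
    max_dist_bp: int = 250_000,
    r2_min: float = 0.50,
) -> ColocReport:
    """Compare a cis-eGWAS peak with the strongest same-chromosome GWAS SNP.

    The comparator is the lowest-p GWAS SNP on the peak's chromosome (no
    significance requirement; its p is reported).  Overlap holds when the
    two SNPs are strictly closer than ``max_dist_bp`` and r^2 is strictly
    above ``r2_min``.
    """
    same = gwas_result[gwas_result["chrom"].astype(str) == peak.chrom]
    same = same.dropna(subset=["p"])
    if same.empty:
        raise ValueError(f"no GWAS SNPs on chromosome {peak.chrom}")
    best = same.sort_values(["p", "pos"]).iloc[0]
    dist = abs(int(best["pos"]) - peak.pos)
    r2 = ld_r2(
        genotypes.dosage_of(peak.snp_id),
        genotypes.dosage_of(str(best["predictor_id"])),
    )
    return ColocReport(
        gene_id=peak.gene_id,
        phenotype=phenotype,
        egwas_snp=peak.snp_id,
        gwas_snp=str(best["predictor_id"]),
        gwas_minus_log10_p=float(best["minus_log10_p"]),
        distance_bp=dist,
        r2=float(r2),
        overlap=bool(dist < max_dist_bp and np.isfinite(r2) and r2 > r2_min),
    )


def gene_region_variants(
    gene_row,  # mapping with chrom/start/end and optional strand
    variants: GenotypeData,
    peak_snps: dict | None = None,  # label -> snp_id
    upstream_bp: int = 2_000,
    high_ld_r2: float = 0.90,
) -> pd.DataFrame:
    """Variants from ``upstream_bp`` upstream of the gene to its 3' end.

    Upstream is strand-aware (5' of the gene's strand); a gene table
    without strand defaults to '+' with a logged warning.  Per variant,
    r^2 to each named peak SNP is reported, with a boolean high-LD flag
    at r^2 > ``high_ld_r2``.
    """
    strand = gene_row.get("strand") if hasattr(gene_row, "get") else None
    if strand not in ("+", "-"):
        logger.warning("gene %s: no strand; assuming '+'",
                       gene_row.get("gene_id", "?"))
        strand = "+"
    start, end = int(gene_row["start"]), int(gene_row["end"])
    if strand == "+":
        lo, hi = start - upstream_bp, end
    else:
        lo, hi = start, end + upstream_bp
    vt = variants.variants
    mask = (
        (vt["chrom"].astype(str) == str(gene_row["chrom"]))
        & (vt["pos"] >= lo) & (vt["pos"] <= hi)
    )
    out = vt[mask].copy().reset_index(drop=True)
    if peak_snps:
        for label, snp_id in peak_snps.items():
            peak_dos = variants.dosage_of(snp_id)
            r2s = [
                ld_r2(variants.dosage_of(s), peak_dos) for s in out["snp_id"]
            ]
            out[f"r2_{label}"] = r2s
            out[f"high_ld_{label}"] = [
                bool(np.isfinite(v) and v > high_ld_r2) for v in r2s
            ]
    return out
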