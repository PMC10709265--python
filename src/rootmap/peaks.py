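"""From association scans to peak loci, candidate intervals, and
ANOVA-prioritized genes.

Significant SNPs (BH-FDR adjusted p < 0.10) are merged into peak loci by
single linkage: any pair within 100 kb with r^2 > 0.50 joins the same
locus, and connected components under that relation partition the
significant set.  Each locus contributes a +-250 kb candidate interval
around its most significant SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genotypes import GenotypeData, ld_r2

logger = logging.getLogger(__name__)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant(result: pd.DataFrame, fdr_threshold: float = 0.10) -> pd.DataFrame:
    """Rows with FDR-adjusted p strictly below the threshold."""
    if "fdr_p" not in result.columns:
        raise ValueError("result lacks an fdr_p column")
    return result[result["fdr_p"] < fdr_threshold].copy()


@dataclass
class PeakLocus:
    peak_snp: str
    chrom: str
    pos: int
    minus_log10_p: float
    fdr_p: float
    members: list = field(default_factory=list)
    interval: tuple = (0, 0)  # [pos - half_width, pos + half_width], clipped at 1
    phenotype: str | None = None


def merge_peaks(
    significant: pd.DataFrame,
    genotypes: GenotypeData,
    dist_bp: int = 100_000,
    r2_min: float = 0.50,
    half_width_bp: int = 250_000,
    phenotype: str | None = None,
) -> list[PeakLocus]:
    """Merge significant SNPs into peak loci.

    Edges connect pairs at distance <= ``dist_bp`` (inclusive) with
    r^2 > ``r2_min`` (strict); connected components become loci.  The
    peak SNP is the member with the smallest p (ties to the smallest
    position).  ``significant`` needs columns predictor_id/chrom/pos/
    minus_log10_p/fdr_p, where predictor_id matches genotype snp_ids.
    """
    if significant.empty:
        return []
    sig = significant.reset_index(drop=True)
    k = len(sig)
    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    chrom = sig["chrom"].to_numpy()
    pos = sig["pos"].to_numpy()
    dosages = {
        sid: genotypes.dosage_of(sid) for sid in sig["predictor_id"]
    }
    for i in range(k - 1):
        for j in range(i + 1, k):
            if chrom[i] != chrom[j] or abs(int(pos[i]) - int(pos[j])) > dist_bp:
                continue
            r2 = ld_r2(dosages[sig["predictor_id"][i]], dosages[sig["predictor_id"][j]])
            if np.isfinite(r2) and r2 > r2_min:
                union(i, j)

    comps: dict[int, list[int]] = {}
    for i in range(k):
        comps.setdefault(find(i), []).append(i)
    loci = []
    for members in comps.values():
        sub = sig.iloc[members]
        best = sub.sort_values(
            ["minus_log10_p", "pos"], ascending=[False, True]
        ).iloc[0]
        loci.append(PeakLocus(
            peak_snp=str(best["predictor_id"]),
            chrom=str(best["chrom"]),
            pos=int(best["pos"]),
            minus_log10_p=float(best["minus_log10_p"]),
            fdr_p=float(best["fdr_p"]),
            members=list(sub["predictor_id"]),
            interval=(max(1, int(best["pos"]) - half_width_bp),
                      int(best["pos"]) + half_width_bp),
            phenotype=phenotype,
        ))
    loci.sort(key=lambda p: (p.chrom, p.pos))
    return loci


def span_distance(pos: int, start: int, end: int) -> int:
    """0 if pos falls inside [start, end], else bp gap to the nearest edge."""
    if start <= pos <= end:
        return 0
    return start - pos if pos < start else pos - end


def candidate_interval(
    locus: PeakLocus,
    gene_table: pd.DataFrame,
    half_width_bp: int = 250_000,
) -> pd.DataFrame:
    """Genes whose span intersects the closed +-``half_width_bp`` window.

    ``gene_table`` needs columns gene_id/chrom/start/end.  The returned
    frame adds the bp distance from the peak SNP to each gene span.
    """
    if locus.chrom not in set(gene_table["chrom"].astype(str)):
        raise ValueError(f"chromosome {locus.chrom!r} absent from gene table")
    lo, hi = locus.pos - half_width_bp, locus.pos + half_width_bp
    sub = gene_table[
        (gene_table["chrom"].astype(str) == locus.chrom)
        & (gene_table["end"] >= lo)
        & (gene_table["start"] <= hi)
    ].copy()
    sub["distance_bp"] = [
        span_distance(locus.pos, int(s), int(e))
        for s, e in zip(sub["start"], sub["end"])
    ]
    return sub.sort_values("distance_bp").reset_index(drop=True)


def prioritize_by_anova(
    locus: PeakLocus,
    candidates: pd.DataFrame,
    profiles,  # ExpressionMatrix at profile stage
    genotypes: GenotypeData,
    subpop_labels,
) -> pd.DataFrame:
    """Rank expressed candidate genes by the ANOVA dosage-term p-value.

    Only genes present in ``profiles`` (i.e. that survived the expressed
    filter) are tested; the model is expression ~ peak-SNP dosage +
    subpopulation.  Returns an ascending-p frame with a -log10 p column.
    """
    from .mixedmodel import anova_dosage_subpop

    profiles.require_stage("profile")
    dosage = genotypes.dosage_of(locus.peak_snp)
    rows = []
    for gene in candidates["gene_id"]:
        if gene not in profiles.values.index:
            continue
        expr = profiles.values.loc[gene].to_numpy()
        try:
            p = anova_dosage_subpop(expr, dosage, subpop_labels)
        except ValueError:
            continue
        rows.append((gene, p))
    if not rows:
        logger.info("locus %s: no expressed candidates to test", locus.peak_snp)
        return pd.DataFrame(columns=["gene_id", "anova_p", "minus_log10_p"])
    out = pd.DataFrame(rows, columns=["gene_id", "anova_p"])
    out["minus_log10_p"] = -np.log10(out["anova_p"])
    return out.sort_values("anova_p").reset_index(drop=True)
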