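"""Transcriptome-wide association on residualized expression.

The scan reuses the mixed-model engine, swapping the SNP dosage matrix
for gene expression residuals; signed effects support the directional
top-1% gene lists and their root-size unions.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .mixedmodel import MixedModelSpec, NullFit, marker_scan


def twas_scan(
    phenotype,
    residuals,  # ExpressionMatrix at residual stage
    kinship: np.ndarray,
    covariates: np.ndarray,
    null: NullFit | None = None,
) -> pd.DataFrame:
    """Mixed-model association of a phenotype with every gene's residual
    expression (P3D).  Returns a frame with gene_id, beta, p, fdr_p,
    minus_log10_p and a dense 1..n rank (ascending p, ties by gene id).
    """
    residuals.require_stage("residual")
    spec = MixedModelSpec(y=phenotype, x=covariates, kinship=kinship, p3d=True)
    res = marker_scan(
        spec,
        residuals.values.to_numpy().T,
        predictor_ids=list(residuals.genes),
        null=null,
    )
    res = res.rename(columns={"predictor_id": "gene_id"})
    order = res.sort_values(["p", "gene_id"], na_position="last")
    res["rank"] = pd.Series(
        np.arange(1, len(res) + 1), index=order.index
    ).reindex(res.index)
    return res


def top_k(result: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """The k strongest associations (smallest p; ties at the boundary
    are all included and flagged in a ``tied`` column)."""
    n = result["p"].notna().sum()
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} scored genes")
    ordered = result.dropna(subset=["p"]).sort_values(["p", "gene_id"])
    cutoff = ordered["p"].iloc[k - 1]
    out = ordered[ordered["p"] <= cutoff].copy()
    out["tied"] = len(out) > k
    return out.reset_index(drop=True)


def top_k_union(results_by_phenotype: dict, k: int = 10) -> pd.DataFrame:
    """Deduplicated union of per-phenotype top-k lists with the number
    of phenotype associations per gene."""
    rows = []
    for pheno, res in results_by_phenotype.items():
        for g in top_k(res, k)["gene_id"]:
            rows.append((g, pheno))
    df = pd.DataFrame(rows, columns=["gene_id", "phenotype"])
    agg = df.groupby("gene_id")["phenotype"].agg(["count", list])
    agg.columns = ["n_associations", "phenotypes"]
    return agg.reset_index()


def top_percent_sets(result: pd.DataFrame, frac: float = 0.01) -> dict:
    """Directional top-``frac`` gene lists.

    The list size is floor(frac * n_genes) computed on the full gene
    count; within each sign of the effect, genes are ranked by ascending
    p (ties by gene id).  Genes with effect exactly 0 join neither list.
    Returns {"positive": [...], "negative": [...]}.
    """
    n_genes = len(result)
    size = math.floor(frac * n_genes)
    scored = result.dropna(subset=["p", "beta"])
    out = {}
    for name, mask in (("positive", scored["beta"] > 0),
                       ("negative", scored["beta"] < 0)):
        sub = scored[mask].sort_values(["p", "gene_id"])
        out[name] = list(sub["gene_id"].iloc[:size])
    return out


def union_root_size(sets_by_phenotype: dict) -> dict:
    """Union of the four root-size phenotype gene lists for one root
    class and direction, with per-gene provenance.

    Returns {"genes": sorted list, "provenance": {gene: [phenotypes]}}.
    """
    prov: dict[str, list] = {}
    for pheno, genes in sets_by_phenotype.items():
        for g in genes:
            prov.setdefault(g, []).append(pheno)
    return {"genes": sorted(prov), "provenance": prov}


def overlap_rate(set_a, set_b) -> float:
    """100 * |A intersect B| / |A|, for equal-size gene lists."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("overlap rate undefined for empty sets")
    return 100.0 * len(a & b) / len(a)


def subpop_correlations(gene_profile, phenotype, labels) -> pd.Series:
    """Pearson r between expression profile and phenotype, overall and
    per subpopulation (groups with fewer than 3 samples give NaN)."""
    x = np.asarray(gene_profile, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    lab = np.asarray(labels, dtype=object)

    def _r(xx, yy):
        if xx.size < 3 or np.std(xx) == 0 or np.std(yy) == 0:
            return float("nan")
        return float(np.corrcoef(xx, yy)[0, 1])

    out = {"all": _r(x, y)}
    for g in sorted(map(str, pd.unique(lab))):
        idx = lab == g
        out[g] = _r(x[idx], y[idx])
    return pd.Series(out, name="pearson_r")
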