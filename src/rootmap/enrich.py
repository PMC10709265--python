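"""GO over-representation of top gene sets.

The test is the exact hypergeometric upper tail: drawing n annotated
set genes from a background of N annotated genes of which K carry the
term, the enrichment p-value is P(X >= k).  Gene identifiers pass
through a strict one-to-one MSU<->RAP mapping before annotation lookup;
any gene on either side of a multi-mapping is dropped and audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .peaks import bh_fdr

logger = logging.getLogger(__name__)


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError("inconsistent hypergeometric counts")
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass
class AnnotationMap:
    """Gene -> GO-term sets over a fixed annotated background."""

    terms_by_gene: dict  # gene id -> set of term ids
    background: set  # annotated genes among the expressed set
    term_names: dict = field(default_factory=dict)
    dropped_multi_mapped: list = field(default_factory=list)

    def genes_with_term(self, term: str) -> set:
        return {g for g, ts in self.terms_by_gene.items() if term in ts}


def build_annotation(
    go_tsv, id_map_tsv, expressed_genes
) -> AnnotationMap:
    """Assemble the annotation map from RAP-style inputs.

    ``go_tsv``: columns transcript_id, term_id[, term_name]; transcripts
    belong to a RAP gene (the part before any ``-`` suffix).  ``id_map_tsv``:
    columns msu_id, rap_id.  Genes whose MSU and RAP ids are not in
    one-to-one correspondence are removed (and recorded); per retained
    gene the GO terms are the union over all of its transcripts.  The
    background is the retained expressed genes with at least one term.
    """
    idmap = pd.read_csv(id_map_tsv, sep="\t", dtype=str)
    idmap.columns = [c.lower() for c in idmap.columns]
    idmap = idmap.dropna().drop_duplicates()
    msu_counts = idmap.groupby("msu_id")["rap_id"].nunique()
    rap_counts = idmap.groupby("rap_id")["msu_id"].nunique()
    bad_msu = set(msu_counts[msu_counts > 1].index)
    bad_rap = set(rap_counts[rap_counts > 1].index)
    dropped = sorted(
        set(idmap.loc[idmap["msu_id"].isin(bad_msu), "msu_id"])
        | set(idmap.loc[idmap["rap_id"].isin(bad_rap), "msu_id"])
    )
    clean = idmap[~idmap["msu_id"].isin(bad_msu) & ~idmap["rap_id"].isin(bad_rap)]
    rap_of = dict(zip(clean["msu_id"], clean["rap_id"]))

    go = pd.read_csv(go_tsv, sep="\t", dtype=str)
    go.columns = [c.lower() for c in go.columns]
    term_names = {}
    if "term_name" in go.columns:
        term_names = dict(zip(go["term_id"], go["term_name"]))
    go["rap_gene"] = go["transcript_id"].str.split("-").str[0]
    terms_by_rap: dict[str, set] = {}
    for rap, term in zip(go["rap_gene"], go["term_id"]):
        terms_by_rap.setdefault(rap, set()).add(term)

    terms_by_gene = {}
    for msu in expressed_genes:
        rap = rap_of.get(msu)
        if rap is None:
            continue
        terms = terms_by_rap.get(rap)
        if terms:
            terms_by_gene[msu] = set(terms)
    background = set(terms_by_gene)
    logger.info(
        "annotation: %d background genes of %d expressed; %d multi-mapped dropped",
        len(background), len(list(expressed_genes)), len(dropped),
    )
    return AnnotationMap(
        terms_by_gene=terms_by_gene,
        background=background,
        term_names=term_names,
        dropped_multi_mapped=dropped,
    )


def hypergeom_enrich(
    gene_set, annotation: AnnotationMap, min_set_genes: int = 1
) -> pd.DataFrame:
    """Per-term enrichment of ``gene_set`` against the annotated background.

    The set is first intersected with the background (defining the draw
    count n); every term carried by at least ``min_set_genes`` set genes
    is tested, and BH-FDR runs across exactly those tested terms.
    Columns: term_id, description, k, n, K, N, p, fdr_p.
    """
    in_bg = sorted(set(gene_set) & annotation.background)
    n = len(in_bg)
    big_n = len(annotation.background)
    counts: dict[str, int] = {}
    for g in in_bg:
        for t in annotation.terms_by_gene[g]:
            counts[t] = counts.get(t, 0) + 1
    rows = []
    for term, k in sorted(counts.items()):
        if k < min_set_genes:
            continue
        big_k = len(annotation.genes_with_term(term))
        if big_k == 0:
            continue
        p = hypergeom_upper_tail(k, n, big_k, big_n)
        rows.append((term, annotation.term_names.get(term, ""), k, n, big_k, big_n, p))
    out = pd.DataFrame(
        rows, columns=["term_id", "description", "k", "n", "K", "N", "p"]
    )
    if len(out):
        out["fdr_p"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values("p").reset_index(drop=True)
    else:
        out["fdr_p"] = []
    return out
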