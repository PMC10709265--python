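"""Genotype I/O and population-genetic preprocessing.

Dosage conventions: samples x SNPs matrix of alternate-allele counts
(0/1/2), ``NaN`` marking missing calls until imputation.  Coordinates are
1-based inclusive throughout (VCF/GFF3 convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt", "maf"]


@dataclass
class GenotypeData:
    """Dosage matrix plus per-SNP metadata.

    Attributes
    ----------
    dosages : ndarray, shape (n_samples, n_snps)
        Alternate-allele counts; float so missing calls can be NaN.
    variants : DataFrame
        Columns ``snp_id, chrom, pos, ref, alt, maf``; positions sorted
        ascending within each chromosome.
    samples : list of str
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_snps(self, mask_or_idx) -> "GenotypeData":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeData(
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
        )

    def subset_samples(self, idx) -> "GenotypeData":
        idx = np.asarray(idx)
        gd = GenotypeData(
            dosages=self.dosages[idx, :],
            variants=self.variants.copy(),
            samples=[self.samples[i] for i in idx],
        )
        gd.variants["maf"] = compute_maf(gd.dosages)
        return gd

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.variants["snp_id"].to_numpy() == snp_id)
        if hits.size == 0:
            raise KeyError(f"unknown SNP id: {snp_id}")
        return int(hits[0])

    def dosage_of(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_index(snp_id)]


def compute_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per SNP from non-missing dosages."""
    with np.errstate(invalid="ignore"):
        p_alt = np.nanmean(dosages, axis=0) / 2.0
    p_alt = np.where(np.isnan(p_alt), 0.0, p_alt)
    return np.minimum(p_alt, 1.0 - p_alt)


_BASES = {"A", "C", "G", "T"}


def read_vcf(path) -> GenotypeData:
    """Read biallelic SNP records from a VCF into a GenotypeData.

    Multiallelic records and indels are skipped (counts logged); missing
    genotypes become NaN dosages, to be mean-imputed downstream.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    rows = []
    cols = []
    skipped = 0
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1 or rec.REF not in _BASES or alts[0] not in _BASES:
            skipped += 1
            continue
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        dos = np.empty(len(samples))
        for i, g in enumerate(gts):
            a = g[:-1]
            if any(x < 0 for x in a):
                dos[i] = np.nan
            else:
                dos[i] = float(sum(1 for x in a if x > 0))
        snp_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        rows.append((snp_id, rec.CHROM, rec.POS, rec.REF, alts[0]))
        cols.append(dos)
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    variants = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    variants["maf"] = compute_maf(dosages)
    return GenotypeData(dosages=dosages, variants=variants, samples=samples)


def maf_filter(gd: GenotypeData, threshold: float = 0.10):
    """Keep SNPs with MAF strictly above ``threshold``.

    MAF is recomputed on the current sample set.  Returns the filtered
    GenotypeData and a dict with kept/removed counts.
    """
    maf = compute_maf(gd.dosages)
    keep = maf > threshold
    out = gd.subset_snps(keep)
    out.variants["maf"] = maf[keep]
    counts = {"kept": int(keep.sum()), "removed": int((~keep).sum())}
    logger.info("maf_filter(>%g): kept %d, removed %d", threshold, *counts.values())
    return out, counts


def mean_impute(gd: GenotypeData) -> GenotypeData:
    """Replace missing dosages with the per-SNP mean of observed dosages."""
    d = gd.dosages.copy()
    if np.isnan(d).any():
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(d, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        nan_r, nan_c = np.where(np.isnan(d))
        d[nan_r, nan_c] = col_mean[nan_c]
    return replace(gd, dosages=d, variants=gd.variants.copy())


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing entries are excluded pairwise; a zero-variance vector yields
    NaN (LD undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or np.var(x) == 0 or np.var(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _pairwise_r2(d: np.ndarray) -> np.ndarray:
    """r^2 matrix across columns of a complete (no-NaN) dosage block."""
    c = d - d.mean(axis=0)
    sd = c.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = c / sd
    z[:, sd == 0] = np.nan
    r = (z.T @ z) / d.shape[0]
    return r * r


def ld_prune(
    gd: GenotypeData,
    window_bp: int = 100_000,
    step_variants: int = 100,
    r2_threshold: float = 0.99,
) -> GenotypeData:
    """Remove highly collinear SNPs with a sliding position window.

    Within each window (SNPs within ``window_bp`` of the window's first
    SNP, boundary inclusive) pairs with r^2 > ``r2_threshold`` are broken
    by dropping one member: the lower-MAF SNP, ties going to the larger
    position.  The window start advances by ``step_variants`` surviving
    SNPs.  A final cleanup pass guarantees no surviving pair within
    ``window_bp`` violates the threshold, which also makes the operation
    idempotent.
    """
    d = mean_impute(gd).dosages
    maf = compute_maf(d)
    pos = gd.variants["pos"].to_numpy()
    chrom = gd.variants["chrom"].to_numpy()
    alive = np.ones(gd.n_snps, dtype=bool)

    def prune_window(idx: np.ndarray):
        """Greedy pair-breaking among currently alive SNPs in idx."""
        while True:
            cur = idx[alive[idx]]
            if cur.size < 2:
                return
            r2 = _pairwise_r2(d[:, cur])
            violated = False
            for a in range(cur.size - 1):
                for b in range(a + 1, cur.size):
                    if abs(pos[cur[b]] - pos[cur[a]]) > window_bp:
                        continue
                    if r2[a, b] > r2_threshold:
                        i, j = cur[a], cur[b]
                        if maf[i] < maf[j]:
                            drop = i
                        elif maf[j] < maf[i]:
                            drop = j
                        else:
                            drop = j if pos[j] >= pos[i] else i
                        alive[drop] = False
                        violated = True
                        break
                if violated:
                    break
            if not violated:
                return

    for ch in pd.unique(chrom):
        cidx = np.flatnonzero(chrom == ch)
        start = 0
        while start < cidx.size:
            anchor = cidx[start]
            in_win = cidx[
                (pos[cidx] >= pos[anchor]) & (pos[cidx] - pos[anchor] <= window_bp)
            ]
            prune_window(in_win)
            start += step_variants
        # cleanup pass: enforce the post-condition across the chromosome
        for k in range(cidx.size):
            anchor = cidx[k]
            if not alive[anchor]:
                continue
            in_win = cidx[
                (pos[cidx] >= pos[anchor]) & (pos[cidx] - pos[anchor] <= window_bp)
            ]
            prune_window(in_win)
    kept = gd.subset_snps(alive)
    logger.info(
        "ld_prune(r2>%g within %d bp): kept %d of %d SNPs",
        r2_threshold, window_bp, kept.n_snps, gd.n_snps,
    )
    return kept


def grm_vanraden(gd: GenotypeData) -> np.ndarray:
    """Genomic relationship matrix, VanRaden's first formula.

    G = W W' / (2 sum_j p_j (1 - p_j)) with W = M - 2P, where p_j is the
    alternate-allele frequency in the analysis samples.  Requires complete
    dosages (mean-impute first) and at least one polymorphic SNP.
    """
    d = gd.dosages
    if np.isnan(d).any():
        raise ValueError("grm_vanraden requires complete dosages; mean-impute first")
    p = d.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: GRM denominator is zero")
    w = d - 2.0 * p
    return (w @ w.T) / denom


def ld_decay(
    gd: GenotypeData,
    max_dist_bp: int = 500_000,
    bin_width_bp: int = 10_000,
    labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Mean r^2 per physical-distance bin over intra-chromosome SNP pairs.

    Returns a tidy frame (group, bin_start, bin_end, mean_r2, n_pairs)
    with group "all" and, if subpopulation ``labels`` are given, one group
    per label (r^2 recomputed within that subpopulation's samples).  Empty
    bins carry NaN.  No monotone smoothing is applied.
    """
    groups = {"all": np.arange(gd.n_samples)}
    if labels is not None:
        lab = np.asarray(labels)
        for g in pd.unique(lab):
            groups[str(g)] = np.flatnonzero(lab == g)

    n_bins = int(np.ceil(max_dist_bp / bin_width_bp))
    pos = gd.variants["pos"].to_numpy()
    chrom = gd.variants["chrom"].to_numpy()
    out = []
    for gname, sidx in groups.items():
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins, dtype=int)
        for ch in pd.unique(chrom):
            cidx = np.flatnonzero(chrom == ch)
            if cidx.size < 2:
                continue
            dsub = mean_impute(gd.subset_samples(sidx).subset_snps(cidx)).dosages
            cpos = pos[cidx]
            c = dsub - dsub.mean(axis=0)
            sd = c.std(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                z = np.where(sd > 0, c / sd, np.nan)
            for i in range(cidx.size - 1):
                j_hi = np.searchsorted(cpos, cpos[i] + max_dist_bp, side="right")
                if j_hi <= i + 1:
                    continue
                dist = cpos[i + 1:j_hi] - cpos[i]
                r = (z[:, i + 1:j_hi].T @ z[:, i]) / dsub.shape[0]
                r2 = r * r  # NaN where either column is monomorphic
                b = np.minimum((dist - 1) // bin_width_bp, n_bins - 1).astype(int)
                ok = ~np.isnan(r2)
                np.add.at(sums, b[ok], r2[ok])
                np.add.at(counts, b[ok], 1)
        with np.errstate(invalid="ignore"):
            mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        out.append(pd.DataFrame({
            "group": gname,
            "bin_start": np.arange(n_bins) * bin_width_bp + 1,
            "bin_end": (np.arange(n_bins) + 1) * bin_width_bp,
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }))
    return pd.concat(out, ignore_index=True)
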