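"""Expression processing: raw counts -> TMM-normalized FPKM ->
log2(FPKM+1) profiles -> expressed-gene filter -> hidden-factor
residuals.

Each stage tags its output (``counts``, ``fpkm``, ``profile``,
``residual``) and downstream operations refuse inputs at the wrong
stage, so the pipeline order is enforced by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STAGES = ("counts", "fpkm", "profile", "residual")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values at a named processing stage."""

    values: pd.DataFrame  # genes x samples
    stage: str
    exon_lengths: pd.Series | None = None  # bp per gene

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def genes(self):
        return self.values.index

    @property
    def samples(self):
        return self.values.columns

    def require_stage(self, stage: str):
        if self.stage != stage:
            raise ValueError(f"expected stage {stage!r}, got {self.stage!r}")


@dataclass
class FactorModel:
    """k-factor linear latent model of an expression-profile matrix."""

    k: int
    scores: pd.DataFrame  # samples x k
    loadings: pd.DataFrame  # genes x k
    variance: np.ndarray  # variance captured per factor, non-increasing

    def relevance_table(self) -> pd.DataFrame:
        """Per-factor captured variance, for elbow diagnosis."""
        return pd.DataFrame({
            "factor": np.arange(1, self.k + 1),
            "variance": self.variance,
        })


def tmm_factors(
    counts: ExpressionMatrix,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, one per sample.

    Reference column: the sample whose upper quartile of nonzero counts
    is closest to the mean of those upper quartiles (ties: lowest column
    index).  Per sample, the factor is 2**(weighted trimmed mean of
    per-gene log2 ratios against the reference), where genes in the top
    and bottom ``logratio_trim`` fraction by M-value and ``abs_trim``
    fraction by A-value are discarded and weights are the usual
    asymptotic (delta-method) inverse variances.  Factors are rescaled
    to geometric mean 1.
    """
    counts.require_stage("counts")
    x = counts.values.to_numpy(dtype=float)
    n_samples = x.shape[1]
    if n_samples < 2:
        raise ValueError("TMM requires at least two samples")
    lib = x.sum(axis=0)
    for s in range(n_samples):
        if lib[s] == 0:
            raise ValueError(
                f"sample {counts.samples[s]!r} has all-zero counts"
            )
    uq = np.array([
        np.percentile(col[col > 0], 75) if (col > 0).any() else 0.0
        for col in x.T
    ])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(n_samples)
    xr, nr = x[:, ref], lib[ref]
    for s in range(n_samples):
        if s == ref:
            continue
        xs, ns = x[:, s], lib[s]
        ok = (xs > 0) & (xr > 0)
        if not ok.any():
            continue
        fs, fr = xs[ok] / ns, xr[ok] / nr
        m = np.log2(fs / fr)
        a = 0.5 * np.log2(fs * fr)
        w = (ns - xs[ok]) / (ns * xs[ok]) + (nr - xr[ok]) / (nr * xr[ok])
        n = m.size
        lo_m = np.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * abs_trim) + 1
        hi_a = n + 1 - lo_a
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.any() and w[keep].sum() > 0:
            factors[s] = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.samples, name="tmm_factor")


def fpkm(
    counts: ExpressionMatrix,
    factors: pd.Series,
    exon_lengths: pd.Series | None = None,
) -> ExpressionMatrix:
    """Fragments per kilobase of exon per million reads.

    FPKM[g,s] = count[g,s] / (exon_kb[g] * effective library size of s in
    millions), with effective library size = column sum x TMM factor.
    """
    counts.require_stage("counts")
    lengths = exon_lengths if exon_lengths is not None else counts.exon_lengths
    if lengths is None:
        raise ValueError("exon lengths required for FPKM")
    lengths = lengths.reindex(counts.genes)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("all genes need a positive exon length")
    lib = counts.values.sum(axis=0) * factors.reindex(counts.samples)
    if (lib <= 0).any():
        raise ValueError("zero effective library size")
    vals = counts.values.div(lengths / 1e3, axis=0).div(lib / 1e6, axis=1)
    return ExpressionMatrix(values=vals, stage="fpkm", exon_lengths=lengths)


def log_profile(fpkm_mat: ExpressionMatrix) -> ExpressionMatrix:
    """Expression profile: log2(FPKM + 1)."""
    fpkm_mat.require_stage("fpkm")
    return ExpressionMatrix(
        values=np.log2(fpkm_mat.values + 1.0),
        stage="profile",
        exon_lengths=fpkm_mat.exon_lengths,
    )


def expressed_filter(
    profiles: ExpressionMatrix,
    min_profile: float = 1.0,
    max_not_expressed_frac: float = 0.50,
):
    """Drop genes not expressed in more than half of the samples.

    A gene is "not expressed" in a sample when its profile is below
    ``min_profile``; it is excluded when the count of such samples
    strictly exceeds ``max_not_expressed_frac`` of the sample total.
    Returns (filtered ExpressionMatrix, dict of kept/removed counts).
    """
    profiles.require_stage("profile")
    n = profiles.values.shape[1]
    not_expr = (profiles.values < min_profile).sum(axis=1)
    keep = not_expr <= max_not_expressed_frac * n
    out = ExpressionMatrix(
        values=profiles.values.loc[keep],
        stage="profile",
        exon_lengths=(
            profiles.exon_lengths.loc[keep]
            if profiles.exon_lengths is not None else None
        ),
    )
    return out, {"kept": int(keep.sum()), "removed": int((~keep).sum())}


def hidden_factor_residuals(profiles: ExpressionMatrix, k: int = 5):
    """Remove k latent expression factors capturing hidden confounders.

    Fits a k-factor linear model to the gene-centered profile matrix by
    truncated SVD (principal factors) and returns the FactorModel plus
    the residual matrix (centered profile minus rank-k reconstruction).
    With k=0 the residuals are simply the centered profiles.
    """
    profiles.require_stage("profile")
    n_samples = profiles.values.shape[1]
    if k >= n_samples:
        raise ValueError(f"k={k} must be below the sample count {n_samples}")
    centered = profiles.values.sub(profiles.values.mean(axis=1), axis=0)
    c = centered.to_numpy()
    if k == 0:
        model = FactorModel(
            k=0,
            scores=pd.DataFrame(index=profiles.samples),
            loadings=pd.DataFrame(index=profiles.genes),
            variance=np.empty(0),
        )
        resid = ExpressionMatrix(values=centered, stage="residual")
        return model, resid
    u, s, vt = np.linalg.svd(c, full_matrices=False)
    loadings = u[:, :k] * s[:k]
    scores = vt[:k].T
    recon = loadings @ scores.T
    model = FactorModel(
        k=k,
        scores=pd.DataFrame(scores, index=profiles.samples,
                            columns=[f"factor{i+1}" for i in range(k)]),
        loadings=pd.DataFrame(loadings, index=profiles.genes,
                              columns=[f"factor{i+1}" for i in range(k)]),
        variance=(s[:k] ** 2) / c.size,
    )
    resid = ExpressionMatrix(
        values=pd.DataFrame(c - recon, index=profiles.genes,
                            columns=profiles.samples),
        stage="residual",
    )
    return model, resid
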